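"""Nuclear radiality: where loci sit and whether position predicts mobility.

Uses the radiality table of the pipeline run (02): per locus, the
normalized radial distance NRD = d/ρ of the mean locus position, its
histogram and empirical CDF, and the Pearson correlation between NRD and
the short-time diffusion constant.

Writes results/nrd_cdf.csv and results/nrd_correlations.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import chromotrace as ct

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rad = pd.read_csv(ROOT / "radiality.csv")
    cdf_rows, corr_rows = [], []
    for locus, g in rad.groupby("locus_id"):
        dist = ct.nrd_distribution(g["nrd"].to_numpy())
        for v, c in zip(dist.values, dist.cdf(dist.values)):
            cdf_rows.append({"locus_id": locus, "nrd": v, "cdf": c})
        res = ct.correlate_mobility_position(
            (g["nrd"].to_numpy(), g["D_eff"].to_numpy())
        )
        corr_rows.append(
            {
                "locus_id": locus,
                "median_nrd": float(np.median(g["nrd"])),
                "pearson_r_nrd_deff": res.r,
                "strength": res.label,
                "n": res.n,
            }
        )
    # pooled CDF over all loci
    pooled = ct.nrd_distribution(rad["nrd"].to_numpy())
    for v, c in zip(pooled.values, pooled.cdf(pooled.values)):
        cdf_rows.append({"locus_id": "all", "nrd": v, "cdf": c})
    pd.DataFrame(cdf_rows).to_csv(ROOT / "nrd_cdf.csv", index=False)
    corr = pd.DataFrame(corr_rows).sort_values("median_nrd")
    corr.to_csv(ROOT / "nrd_correlations.csv", index=False)
    print("radial position and mobility correlation per locus:")
    print(corr.round(3).to_string(index=False))
    print("\nmedian NRD increases from pericentromeric to near-telomeric loci."
          "\nPosition and mobility are generated independently here, so per-locus"
          "\ncorrelations scatter around zero (small-n groups can stray further).")


if __name__ == "__main__":
    main()
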