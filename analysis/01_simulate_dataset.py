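"""Generate the demonstration dataset: six loci along one chromosome arm.

Builds a synthetic single-chromosome tracking experiment with the measured
statistical structure of live-cell locus movies: 120-frame, 80 s recordings
of harmonically confined subdiffusive loci, localization noise of 50 nm,
per-locus confinement chosen so short-time diffusion (2.5–4.2 × 10⁻³
µm² s⁻¹) and trajectory radii (0.09–0.15 µm) span the measured ranges, and
elliptical nuclei in which pericentromeric loci sit interior and the
near-telomeric locus peripheral.

Writes results/data/trajectories.csv and results/data/nuclei.json.
"""

from pathlib import Path

import numpy as np

import chromotrace as ct

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

# per-locus targets: (genomic position Mb, trajectory radius µm, D_eff µm²/s,
# radial fraction) — pericentromeric loci are stiff and interior, interior
# arm loci intermediate, the near-telomeric locus soft and peripheral
LOCI = {
    "PR1": dict(c_mb=24.0, r_g=0.088, d_eff=0.00251, nrd=0.45, n_cells=28),
    "PR2": dict(c_mb=29.0, r_g=0.128, d_eff=0.00386, nrd=0.50, n_cells=52),
    "LE": dict(c_mb=32.9, r_g=0.154, d_eff=0.00418, nrd=0.60, n_cells=27),
    "LH": dict(c_mb=54.1, r_g=0.151, d_eff=0.00350, nrd=0.70, n_cells=77),
    "LA": dict(c_mb=56.0, r_g=0.146, d_eff=0.00333, nrd=0.75, n_cells=77),
    "T2": dict(c_mb=58.7, r_g=0.152, d_eff=0.00332, nrd=0.85, n_cells=127),
}

SEED = 2024
SIGMA_LOC = 0.05  # µm localization noise
N_FRAMES, DT = 120, 0.667


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    trajectories = []
    nuclei = []
    cell_counter = 0
    for locus, p in LOCI.items():
        # equipartition sets the confinement from the target territory
        k = 2.0 / p["r_g"] ** 2
        cfg = ct.SimulationConfig(
            seed=int(rng.integers(2**31)),
            n_trajectories=p["n_cells"],
            n_frames=N_FRAMES,
            frame_interval=DT,
            locus_id=locus,
        )
        ens = ct.simulate_ou(k, p["d_eff"], cfg)
        ens = ct.add_localization_noise(ens, SIGMA_LOC, seed=int(rng.integers(2**31)))
        for t in ens:
            cid = f"cell{cell_counter:04d}"
            angle = rng.uniform(0, 2 * np.pi)
            geom, placed = ct.simulate_nucleus(
                cid,
                center=rng.uniform(-2, 2, size=2),
                a=rng.uniform(10, 13),
                b=rng.uniform(6, 9),
                placements=[(locus, p["nrd"], angle)],
                theta=rng.uniform(0, np.pi),
            )
            trajectories.append(
                ct.LocusTrajectory(
                    cell_id=cid,
                    locus_id=locus,
                    condition="async",
                    times=t.times,
                    positions=t.positions + placed[locus],
                    metadata={"focus_count": 2},
                )
            )
            nuclei.append(geom)
            cell_counter += 1
    ensemble = ct.TrajectoryEnsemble(trajectories)
    traj_path = ct.write_trajectories(ensemble, OUT / "trajectories.csv")
    geom_path = ct.write_geometry(nuclei, OUT / "nuclei.json")
    print(f"wrote {len(ensemble)} trajectories for {len(LOCI)} loci -> {traj_path}")
    print(f"wrote {len(nuclei)} nuclei -> {geom_path}")
    print("locus layout (genomic Mb, target R_g µm, target D_eff, radial fraction):")
    for locus, p in LOCI.items():
        print(f"  {locus:>3}: {p['c_mb']:5.1f} Mb  R_g={p['r_g']:.3f}  "
              f"D_eff={p['d_eff']:.5f}  NRD={p['nrd']:.2f}  n={p['n_cells']}")


if __name__ == "__main__":
    main()
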