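"""End-to-end orchestration: filter → calibrate → dynamics → mechanics →
organization → group comparisons, emitting tidy report tables.

A run is described by a :class:`RunConfig` (or its YAML/JSON file form).
Every run writes its resolved configuration and the package version next to
the outputs, and a rerun with the same inputs and seed reproduces the
numeric tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import compute_eamsd, compute_rg, estimate_deff, fit_msd_power_law
from .io import (
    FilterRules,
    NucleusGeometry,
    TrajectoryEnsemble,
    correct_nuclear_motion,
    filter_ensemble,
    read_geometry,
    read_trajectories,
)
from .mechanics import estimate_keff, infer_tether, summarize_keff
from .organization import (
    compute_nrd,
    compute_pair_distance_series,
    decompose_variation,
    fit_compaction,
    mean_pair_distance,
)
from .stats import one_way_anova, welch_ttest

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("chromotrace")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run.

    ``pairs`` lists locus pairs for the compaction analysis as mappings with
    keys ``locus_a``, ``locus_b`` and ``s_mb``; ``tether`` optionally maps
    locus ids to genomic positions plus the assumed tether position ``c_t``.
    """

    trajectories: str
    out_dir: str
    geometry: str | None = None
    seed: int = 0
    motion_correction: bool = True
    min_length: int | None = 30
    max_focus_count: int | None = 3
    deff_lags: int = 4
    msd_max_lag: int | None = None  # default ⌊n_frames/4⌋ per ensemble
    fit_with_offset: bool = False
    averaging_window: int = 30
    pairs: list[dict] = field(default_factory=list)
    tether: dict | None = None
    compare_metrics: tuple[str, ...] = ("D_eff", "R_g", "k_eff")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        missing = {"trajectories", "out_dir"} - set(data)
        if missing:
            raise PipelineError(f"config: missing required key(s) {sorted(missing)}")
        if "compare_metrics" in data:
            data["compare_metrics"] = tuple(data["compare_metrics"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["compare_metrics"] = list(self.compare_metrics)
        return d


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with the stage
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapper

    return decorate


@_stage("load")
def _load(config: RunConfig) -> tuple[TrajectoryEnsemble, dict[str, NucleusGeometry]]:
    ensemble = read_trajectories(config.trajectories)
    geometries: dict[str, NucleusGeometry] = {}
    if config.geometry is not None:
        geometries = read_geometry(config.geometry)
    return ensemble, geometries


@_stage("filter")
def _filter(config: RunConfig, ensemble: TrajectoryEnsemble):
    rules = FilterRules(
        min_length=config.min_length, max_focus_count=config.max_focus_count
    )
    return filter_ensemble(ensemble, rules)


@_stage("motion_correction")
def _calibrate(
    config: RunConfig,
    ensemble: TrajectoryEnsemble,
    geometries: Mapping[str, NucleusGeometry],
) -> TrajectoryEnsemble:
    if not config.motion_correction or not geometries:
        return ensemble
    out = []
    for t in ensemble:
        geom = geometries.get(t.cell_id)
        out.append(correct_nuclear_motion(t, geom) if geom is not None else t)
    return TrajectoryEnsemble(out)


@_stage("dynamics")
def _per_trajectory(config: RunConfig, ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    rows = []
    for t in ensemble:
        deff = estimate_deff(t, n_lags=config.deff_lags)
        shape = compute_rg(t)
        max_lag = config.msd_max_lag or max(3, t.n_frames // 4)
        curve = compute_eamsd(TrajectoryEnsemble([t]), min(max_lag, t.n_frames - 1))
        fit = fit_msd_power_law(curve, with_offset=config.fit_with_offset)
        row = {
            "cell_id": t.cell_id,
            "locus_id": t.locus_id,
            "condition": t.condition,
            "n_frames": t.n_frames,
            "D_eff": deff.D_eff,
            "D_app": fit.D_app,
            "beta": fit.beta,
            "R_g": shape.R_g,
        }
        if fit.sigma is not None:
            row["sigma_loc"] = fit.sigma
        if deff.D_eff > 0:
            est = estimate_keff(t, deff)
            row["k_eff"] = est.k_eff
            row["keff_slope"] = est.slope
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("dynamics")
def _ensemble_msd(config: RunConfig, ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    frames = []
    for (locus, condition), group in ensemble.groupby("locus_id", "condition").items():
        n_min = min(t.n_frames for t in group)
        max_lag = config.msd_max_lag or max(3, n_min // 4)
        curve = compute_eamsd(group, min(max_lag, n_min - 1))
        df = curve.to_dataframe()
        df.insert(0, "condition", condition)
        df.insert(0, "locus_id", locus)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@_stage("organization")
def _compaction(config: RunConfig, ensemble: TrajectoryEnsemble) -> pd.DataFrame | None:
    if not config.pairs:
        return None
    rows = []
    points = []
    for pair in config.pairs:
        la, lb, s_mb = pair["locus_a"], pair["locus_b"], float(pair["s_mb"])
        series = []
        cells_a = {t.cell_id: t for t in ensemble.select(locus_id=la)}
        cells_b = {t.cell_id: t for t in ensemble.select(locus_id=lb)}
        for cell in sorted(set(cells_a) & set(cells_b)):
            series.append(
                compute_pair_distance_series(cells_a[cell], cells_b[cell], s_mb)
            )
        if not series:
            raise PipelineError(
                f"stage 'organization': no co-imaged cells for pair {la}/{lb}"
            )
        summary = mean_pair_distance(series, n_frames_avg=config.averaging_window)
        var = decompose_variation(series)
        rows.append(
            {
                "pair": summary.pair,
                "s_mb": s_mb,
                "mean_R_um": summary.mean,
                "sd_um": summary.sd,
                "n_cells": summary.n_cells,
                "cell_to_cell_sd": var.cell_to_cell_sd,
                "temporal_mean_abs_dev": var.temporal_mean_abs,
            }
        )
        points.append((s_mb, summary.mean))
    df = pd.DataFrame(rows)
    if len({p[0] for p in points}) >= 2:
        fit = fit_compaction(points, label="all pairs")
        df.attrs["compaction"] = {"delta": fit.delta, "prefactor": fit.prefactor}
    return df


@_stage("organization")
def _radiality(
    config: RunConfig,
    ensemble: TrajectoryEnsemble,
    geometries: Mapping[str, NucleusGeometry],
    per_traj: pd.DataFrame,
) -> pd.DataFrame | None:
    if not geometries:
        return None
    deff_map = {
        (r.cell_id, r.locus_id): r.D_eff for r in per_traj.itertuples(index=False)
    }
    rows = []
    for t in ensemble:
        geom = geometries.get(t.cell_id)
        if geom is None:
            continue
        mean_pos = t.positions.mean(axis=0)
        rec = compute_nrd(
            mean_pos,
            geom,
            cell_id=t.cell_id,
            locus_id=t.locus_id,
            d_eff=deff_map.get((t.cell_id, t.locus_id)),
        )
        rows.append(
            {
                "cell_id": rec.cell_id,
                "locus_id": rec.locus_id,
                "nrd": rec.nrd,
                "d_um": rec.d,
                "rho_um": rec.rho,
                "D_eff": rec.d_eff,
                "clipped": rec.clipped,
            }
        )
    return pd.DataFrame(rows) if rows else None


@_stage("comparisons")
def _comparisons(config: RunConfig, per_traj: pd.DataFrame) -> pd.DataFrame | None:
    conditions = sorted(per_traj["condition"].unique())
    if len(conditions) < 2:
        return None
    rows = []
    for metric in config.compare_metrics:
        if metric not in per_traj.columns:
            continue
        for locus in sorted(per_traj["locus_id"].unique()):
            sub = per_traj[per_traj["locus_id"] == locus]
            groups = {
                c: sub.loc[sub["condition"] == c, metric].dropna().to_numpy()
                for c in conditions
            }
            groups = {c: g for c, g in groups.items() if len(g) >= 2}
            if len(groups) < 2:
                continue
            if len(groups) > 2:
                cmp_all = one_way_anova(groups)
                rows.append(_comparison_row(metric, locus, "|".join(groups), cmp_all))
            for ca, cb in itertools.combinations(sorted(groups), 2):
                cmp_ab = welch_ttest(groups[ca], groups[cb], labels=(ca, cb))
                rows.append(_comparison_row(metric, locus, f"{ca} vs {cb}", cmp_ab))
    return pd.DataFrame(rows) if rows else None


def _comparison_row(metric: str, locus: str, contrast: str, cmp) -> dict:
    return {
        "metric": metric,
        "locus_id": locus,
        "contrast": contrast,
        "test": cmp.test,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "stars": cmp.stars,
        "groups": "; ".join(
            f"{g.label}: n={g.n}, mean={g.mean:.6g}, sd={g.sd:.6g}" for g in cmp.groups
        ),
    }


def run_pipeline(config: RunConfig | str | Path) -> dict[str, Path]:
    """Execute the full analysis; returns a mapping of table name → path.

    Emits ``per_trajectory.csv``, ``ensemble_msd.csv``, ``filter_report.json``
    and, when the config provides the inputs, ``compaction.csv``,
    ``radiality.csv``, ``comparisons.csv`` and ``tether.json``; the resolved
    config plus package version land in ``run_config.json``.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_file(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    ensemble, geometries = _load(config)
    log.info("loaded %d trajectories, %d nuclei", len(ensemble), len(geometries))
    ensemble, report = _filter(config, ensemble)
    if len(ensemble) == 0:
        raise PipelineError("stage 'filter': no trajectories survive the rules")
    # radiality is evaluated in the lab frame (positions vs boundary), so the
    # uncalibrated ensemble is kept; dynamics run on calibrated positions
    raw_ensemble = ensemble
    ensemble = _calibrate(config, ensemble, geometries)

    per_traj = _per_trajectory(config, ensemble)
    outputs["per_trajectory"] = out_dir / "per_trajectory.csv"
    per_traj.to_csv(outputs["per_trajectory"], index=False)

    eamsd = _ensemble_msd(config, ensemble)
    outputs["ensemble_msd"] = out_dir / "ensemble_msd.csv"
    eamsd.to_csv(outputs["ensemble_msd"], index=False)

    compaction = _compaction(config, ensemble)
    if compaction is not None:
        outputs["compaction"] = out_dir / "compaction.csv"
        compaction.to_csv(outputs["compaction"], index=False)

    radiality = _radiality(config, raw_ensemble, geometries, per_traj)
    if radiality is not None:
        outputs["radiality"] = out_dir / "radiality.csv"
        radiality.to_csv(outputs["radiality"], index=False)

    comparisons = _comparisons(config, per_traj)
    if comparisons is not None:
        outputs["comparisons"] = out_dir / "comparisons.csv"
        comparisons.to_csv(outputs["comparisons"], index=False)

    if config.tether is not None and "k_eff" in per_traj.columns:
        try:
            loci_pos = {k: float(v) for k, v in config.tether["loci"].items()}
            c_t = float(config.tether["c_t"])
            entries = []
            for locus, c_mb in loci_pos.items():
                summ = summarize_keff_from_frame(per_traj, locus)
                entries.append((locus, c_mb, summ))
            model = infer_tether(entries, c_t=c_t, allow_interior=bool(
                config.tether.get("allow_interior", False)))
            outputs["tether"] = out_dir / "tether.json"
            outputs["tether"].write_text(
                json.dumps(
                    {
                        "K_R": model.K_R,
                        "k_t": model.k_t,
                        "c_t": model.c_t,
                        "feasible": model.feasible,
                        "loci": model.loci,
                    },
                    indent=1,
                )
            )
        except (KeyError, ValueError) as exc:
            raise PipelineError(f"stage 'tether': {exc}") from exc

    resolved = {
        "version": __version__,
        "config": config.to_dict(),
        "filter_report": report,
    }
    outputs["run_config"] = out_dir / "run_config.json"
    outputs["run_config"].write_text(json.dumps(resolved, indent=1))
    return outputs


def summarize_keff_from_frame(per_traj: pd.DataFrame, locus: str) -> float:
    """Group-average k_eff for one locus (non-negative estimates only)."""
    vals = per_traj.loc[per_traj["locus_id"] == locus, "k_eff"].dropna().to_numpy()
    vals = vals[vals >= 0]
    if len(vals) == 0:
        raise ValueError(f"no usable k_eff estimates for locus {locus}")
    return float(vals.mean())
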