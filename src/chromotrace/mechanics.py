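"""Effective spring constants and Rouse tether inversion.

Short-time locus motion is modelled by an overdamped Langevin equation with
a Hookean restoring force of effective stiffness k_eff and friction given by
the Einstein relation γ = k_BT/D_eff.  The stiffness is estimated from the
regression of the step p((m+1)Δt) − p(mΔt) on the centroid-relative position
p(mΔt) − p_C: for slope s (fitted through the origin, x and y components
pooled),

    k_eff = −s · k_BT / (D_eff · Δt),

with energies expressed in k_BT so spring constants carry units k_BT µm⁻².
The equilibrium (equipartition) identity k_eff·Var = k_BT ties k_eff to the
locus territory: ⟨k_eff⟩ = a·⟨R_g²⟩^(−b) with a = 2 and b = 1 for a
harmonically confined 2D locus, which :func:`fit_keff_vs_territory` checks.

A chromosomal locus i tethered to a nuclear landmark behaves as two springs
in series — the chain segment of genomic length Δc_it (stiffness K_R/Δc_it)
and the tether itself (k_t):

    k_eff,i = k_t·K_R / (K_R + Δc_it·k_t)   ⇔   1/k_eff,i = 1/k_t + Δc_it/K_R,

so regressing 1/k_eff,i on Δc_it recovers K_R (1/slope) and k_t
(1/intercept); with exactly two loci this reproduces the closed form
K_R = (Δc_1t − Δc_2t)·k_eff,1·k_eff,2/(k_eff,2 − k_eff,1).

Here K_R carries per-genomic-distance units (k_BT µm⁻² Mb) so the series
formula is dimensionally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import DiffusionEstimate
from .io import LocusTrajectory

__all__ = [
    "SpringEstimate",
    "SpringTerritoryFit",
    "TetherModel",
    "estimate_keff",
    "estimate_keff_ensemble",
    "summarize_keff",
    "fit_keff_vs_territory",
    "predict_keff_tethered",
    "infer_tether",
    "two_locus_K_R",
]

#: energies are measured in units of k_BT
K_B_T = 1.0


@dataclass
class SpringEstimate:
    """Per-trajectory effective spring constant from step-size regression."""

    k_eff: float  # k_BT µm⁻² (raw; negative estimates are flagged, not clipped)
    slope: float  # pooled regression slope, dimensionless
    gamma: float  # k_BT s µm⁻², Einstein relation γ = k_BT/D_eff
    D_eff: float  # µm² s⁻¹ used in the conversion
    n_steps: int
    slope_x: float  # per-axis diagnostics
    slope_y: float
    method: str = "linear"

    @property
    def is_negative(self) -> bool:
        """Raw estimate implies an anti-restoring force; excluded from averages."""
        return self.k_eff < 0


@dataclass
class SpringTerritoryFit:
    """Power law ⟨k_eff⟩ = a·⟨R_g²⟩^(−b) fitted on log-log scale."""

    a: float
    b: float
    n_points: int
    r_squared: float
    degenerate: bool = False


@dataclass
class TetherModel:
    """Rouse chain + tether parameters inferred from per-locus stiffness."""

    K_R: float  # k_BT µm⁻² Mb, chain stiffness per genomic distance
    k_t: float  # k_BT µm⁻², tether stiffness
    c_t: float  # Mb, tether genomic position (supplied, not fitted)
    loci: list[tuple[str, float, float]]  # (locus_id, c_i Mb, k_eff,i)
    slope: float
    intercept: float
    feasible: bool

    def predict(self, c_i: float) -> float:
        return predict_keff_tethered(self.K_R, self.k_t, abs(c_i - self.c_t))


def estimate_keff(
    traj: LocusTrajectory,
    deff: DiffusionEstimate | float,
    method: str = "linear",
    center: Sequence[float] | None = None,
) -> SpringEstimate:
    """Effective spring constant from the step-vs-relative-position regression.

    Steps Δp_m = p((m+1)Δt) − p(mΔt) are regressed through the origin on the
    relative positions p(mΔt) − p_C, pooling x and y components.  ``center``
    defaults to the trajectory centroid p_C; a known equilibrium position can
    be supplied instead (useful for simulation oracles, where it removes the
    finite-movie centroid bias).

    ``method="linear"`` applies the first-order mapping k_eff = −s/(D_eff·Δt).
    ``method="exact"`` inverts the exact discrete OU conditional mean,
    k_eff = −ln(1 + s)/(D_eff·Δt), which corrects the ~Δt/(2τ) downward bias
    of the linear form when the frame interval is not ≪ the relaxation time.
    """
    d_eff = deff.D_eff if isinstance(deff, DiffusionEstimate) else float(deff)
    if d_eff <= 0:
        raise ValueError("D_eff must be positive (degenerate trajectory?)")
    if method not in {"linear", "exact"}:
        raise ValueError(f"unknown method {method!r}")
    pos = traj.positions
    n_steps = pos.shape[0] - 1
    if n_steps < 10:
        raise ValueError(f"need >= 10 steps, got {n_steps}")
    p_c = pos.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    steps = pos[1:] - pos[:-1]
    rel = pos[:-1] - p_c

    def _slope(s: np.ndarray, r: np.ndarray) -> float:
        denom = float(np.sum(r * r))
        if denom == 0.0:
            raise ValueError("zero variance in relative positions")
        return float(np.sum(s * r)) / denom

    slope = _slope(steps, rel)
    slope_x = _slope(steps[:, 0], rel[:, 0])
    slope_y = _slope(steps[:, 1], rel[:, 1])
    dt = traj.frame_interval
    if method == "exact":
        if slope <= -1.0:
            raise ValueError("slope <= -1: exact OU inversion undefined")
        k_eff = -np.log1p(slope) * K_B_T / (d_eff * dt)
    else:
        k_eff = -slope * K_B_T / (d_eff * dt)
    return SpringEstimate(
        k_eff=float(k_eff),
        slope=slope,
        gamma=K_B_T / d_eff,
        D_eff=d_eff,
        n_steps=n_steps,
        slope_x=slope_x,
        slope_y=slope_y,
        method=method,
    )


def estimate_keff_ensemble(
    trajectories: Sequence[LocusTrajectory],
    deff: DiffusionEstimate | float | None = None,
    method: str = "linear",
    center: Sequence[float] | None = None,
) -> SpringEstimate:
    """Pooled spring-constant estimate over an ensemble of movies.

    Sums the regression moments (Σ step·rel and Σ rel²) over all
    trajectories before taking the slope.  Unlike averaging per-movie
    estimates, the pooled ratio is insensitive to movie-to-movie
    fluctuations of the explored area — which bias the per-movie ratio when
    the movie is short compared with the slowest relaxation time — so it is
    the estimator of choice when many replicates of one locus are available.

    ``deff`` defaults to the mean of the per-trajectory short-time D_eff
    estimates; ``center`` defaults to each trajectory's own centroid.
    """
    from .dynamics import estimate_deff  # local import avoids a cycle

    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories supplied")
    dt = trajs[0].frame_interval
    for t in trajs:
        if abs(t.frame_interval - dt) > 1e-9:
            raise ValueError("trajectories must share one frame interval")
    if deff is None:
        d_eff = float(np.mean([estimate_deff(t).D_eff for t in trajs]))
    else:
        d_eff = deff.D_eff if isinstance(deff, DiffusionEstimate) else float(deff)
    if d_eff <= 0:
        raise ValueError("D_eff must be positive")
    num = den = 0.0
    num_x = den_x = num_y = den_y = 0.0
    n_steps = 0
    for t in trajs:
        pos = t.positions
        p_c = pos.mean(axis=0) if center is None else np.asarray(center, dtype=float)
        steps = pos[1:] - pos[:-1]
        rel = pos[:-1] - p_c
        num += float(np.sum(steps * rel))
        den += float(np.sum(rel * rel))
        num_x += float(np.sum(steps[:, 0] * rel[:, 0]))
        den_x += float(np.sum(rel[:, 0] ** 2))
        num_y += float(np.sum(steps[:, 1] * rel[:, 1]))
        den_y += float(np.sum(rel[:, 1] ** 2))
        n_steps += pos.shape[0] - 1
    if n_steps < 10:
        raise ValueError(f"need >= 10 steps, got {n_steps}")
    if den == 0.0:
        raise ValueError("zero variance in relative positions")
    slope = num / den
    if method == "exact":
        if slope <= -1.0:
            raise ValueError("slope <= -1: exact OU inversion undefined")
        k_eff = -np.log1p(slope) * K_B_T / (d_eff * dt)
    elif method == "linear":
        k_eff = -slope * K_B_T / (d_eff * dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpringEstimate(
        k_eff=float(k_eff),
        slope=float(slope),
        gamma=K_B_T / d_eff,
        D_eff=d_eff,
        n_steps=n_steps,
        slope_x=num_x / den_x if den_x else float("nan"),
        slope_y=num_y / den_y if den_y else float("nan"),
        method=method,
    )


def summarize_keff(estimates: Sequence[SpringEstimate]) -> dict:
    """Group summary: mean/sd over non-negative estimates plus QC counts."""
    values = np.array([e.k_eff for e in estimates])
    positive = values[values >= 0]
    return {
        "mean": float(positive.mean()) if len(positive) else float("nan"),
        "sd": float(positive.std(ddof=1)) if len(positive) > 1 else float("nan"),
        "n": int(len(positive)),
        "n_negative_excluded": int(np.sum(values < 0)),
    }


def fit_keff_vs_territory(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> SpringTerritoryFit:
    """Fit ⟨k_eff⟩ = a·⟨R_g²⟩^(−b) by OLS of ln k_eff on ln R_g².

    ``points`` is a sequence of (k_eff, R_g²) pairs, all strictly positive.
    Zero variance in the regressor yields a degenerate (flagged) fit.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (k_eff, R_g²) points")
    k, rg2 = arr[:, 0], arr[:, 1]
    if np.any(k <= 0) or np.any(rg2 <= 0):
        raise ValueError("k_eff and R_g² must be strictly positive")
    x, y = np.log(rg2), np.log(k)
    if np.ptp(x) == 0.0:
        return SpringTerritoryFit(
            a=float("nan"), b=float("nan"), n_points=len(k), r_squared=float("nan"),
            degenerate=True,
        )
    slope, intercept = np.polyfit(x, y, 1)
    pred = intercept + slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return SpringTerritoryFit(
        a=float(np.exp(intercept)), b=float(-slope), n_points=len(k), r_squared=r2
    )


def predict_keff_tethered(K_R: float, k_t: float, delta_c: float) -> float:
    """Series-spring stiffness of a tethered locus.

    k_eff = k_t·K_R/(K_R + Δc·k_t), i.e. 1/k_eff = 1/k_t + Δc/K_R.  Strictly
    decreasing in Δc, increasing in K_R and k_t, and always below both k_t
    and K_R/Δc.
    """
    if K_R <= 0 or k_t <= 0 or delta_c <= 0:
        raise ValueError("K_R, k_t and delta_c must be positive")
    return k_t * K_R / (K_R + delta_c * k_t)


def infer_tether(
    loci: Sequence[tuple],
    c_t: float,
    allow_interior: bool = False,
) -> TetherModel:
    """Invert per-locus stiffness to chain (K_R) and tether (k_t) parameters.

    ``loci`` holds >= 2 entries of ``(c_i, k_eff_i)`` or
    ``(locus_id, c_i, k_eff_i)`` with distinct genomic positions and positive
    stiffness.  ``c_t`` (Mb) is the assumed tether position — with only two
    loci the triple (K_R, k_t, c_t) is under-determined, so c_t is a required
    input; by default it must lie outside the labelled span (the physical
    picture of a landmark beyond the outermost locus), which
    ``allow_interior`` overrides.

    OLS of 1/k_eff,i on Δc_it gives K_R = 1/slope and k_t = 1/intercept; for
    exactly two loci this equals the closed-form two-locus K_R.  A negative
    slope or intercept marks the solution infeasible (the data do not fit a
    tethered-chain model).
    """
    parsed: list[tuple[str, float, float]] = []
    for entry in loci:
        if len(entry) == 2:
            c_i, k = entry
            parsed.append((f"c{c_i:g}", float(c_i), float(k)))
        else:
            name, c_i, k = entry
            parsed.append((str(name), float(c_i), float(k)))
    if len(parsed) < 2:
        raise ValueError("need >= 2 loci")
    c = np.array([p[1] for p in parsed])
    k = np.array([p[2] for p in parsed])
    if np.any(k <= 0):
        raise ValueError("k_eff values must be positive")
    if min(c) <= c_t <= max(c) and not allow_interior:
        raise ValueError(
            f"c_t={c_t} lies inside the labelled span [{min(c)}, {max(c)}]; "
            "pass allow_interior=True to override"
        )
    dc = np.abs(c - c_t)
    if len(np.unique(dc)) < len(dc):
        raise ValueError("loci must have distinct genomic distances to c_t")
    slope, intercept = np.polyfit(dc, 1.0 / k, 1)
    feasible = slope > 0 and intercept > 0
    K_R = 1.0 / slope if slope > 0 else float("inf") if slope == 0 else float("nan")
    k_t = 1.0 / intercept if intercept > 0 else float("inf") if intercept == 0 else float("nan")
    return TetherModel(
        K_R=float(K_R),
        k_t=float(k_t),
        c_t=float(c_t),
        loci=parsed,
        slope=float(slope),
        intercept=float(intercept),
        feasible=bool(feasible),
    )


def two_locus_K_R(dc1: float, dc2: float, k1: float, k2: float) -> float:
    """Closed-form chain stiffness from two tethered loci:
    K_R = (Δc_1t − Δc_2t)·k_eff,1·k_eff,2/(k_eff,2 − k_eff,1)."""
    if k1 == k2:
        raise ValueError("k_eff values must differ")
    return (dc1 - dc2) * k1 * k2 / (k2 - k1)
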