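"""Mean square displacement analysis, diffusion fitting and trajectory shape.

The time-averaged MSD of a trajectory p(t) at lag kΔt averages the squared
displacement over every start frame m:

    MSD(kΔt) = ⟨|p((m+k)Δt) − p(mΔt)|²⟩_m ,   n_pairs = n_frames − k.

Ensemble-averaged MSD is the unweighted mean of member time-averaged curves.
Curves are fitted with the anomalous-diffusion power law

    MSD(t) = 4·D_app·t^β            (log-log ordinary least squares)
    MSD(t) = 4·D_app·t^β + 4·σ²     (nonlinear fit with a localization
                                     noise floor, σ² ≥ 0)

and the short-time effective diffusion constant D_eff is the origin-
constrained slope of the first few MSD points divided by 4.  The gyration
(trajectory) radius R_g — the "locus territory" when squared — is the RMS
distance of the positions from their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import LocusTrajectory, TrajectoryEnsemble

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "DiffusionEstimate",
    "TrajectoryShape",
    "LocalizationPrecision",
    "compute_tamsd",
    "compute_eamsd",
    "fit_msd_power_law",
    "estimate_deff",
    "compute_rg",
    "estimate_localization_precision",
]


@dataclass
class MSDCurve:
    """Lag-indexed mean square displacement.

    ``n_pairs`` counts displacement pairs (time-averaged) or contributing
    trajectories (ensemble-averaged).
    """

    lags: np.ndarray  # seconds, k·Δt for k = 1..K
    values: np.ndarray  # µm²
    n_pairs: np.ndarray
    kind: str  # "time" or "ensemble"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "msd_um2": self.values, "n": self.n_pairs}
        )


@dataclass
class PowerLawFit:
    """Fitted MSD(t) = 4·D_app·t^β (+ 4σ² offset when requested)."""

    D_app: float  # µm² s⁻ᵝ
    beta: float
    sigma: float | None  # µm localization noise, offset fits only
    lag_range: tuple[float, float]
    r_squared: float
    with_offset: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        offset = 4.0 * self.sigma**2 if self.sigma is not None else 0.0
        return 4.0 * self.D_app * np.asarray(t, dtype=float) ** self.beta + offset


@dataclass
class DiffusionEstimate:
    """Short-time effective diffusion constant from the initial MSD slope."""

    D_eff: float  # µm² s⁻¹
    n_lags: int
    lags: np.ndarray
    degenerate: bool = False


@dataclass
class TrajectoryShape:
    """Gyration radius and centroid of a trajectory."""

    R_g: float  # µm
    centroid: np.ndarray  # µm


def compute_tamsd(traj: LocusTrajectory, max_lag_k: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all overlapping start frames."""
    n = traj.n_frames
    if max_lag_k is None:
        max_lag_k = n - 1
    if not 1 <= max_lag_k < n:
        raise ValueError(f"max_lag_k must be in [1, {n - 1}], got {max_lag_k}")
    pos = traj.positions
    values = np.empty(max_lag_k)
    n_pairs = np.empty(max_lag_k, dtype=int)
    for k in range(1, max_lag_k + 1):
        d = pos[k:] - pos[:-k]
        values[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k - 1] = n - k
    lags = np.arange(1, max_lag_k + 1) * traj.frame_interval
    return MSDCurve(lags=lags, values=values, n_pairs=n_pairs, kind="time")


def compute_eamsd(ensemble: TrajectoryEnsemble, max_lag_k: int) -> MSDCurve:
    """Ensemble-averaged MSD: unweighted mean of member time-averaged curves.

    Trajectories shorter than a given lag simply do not contribute there;
    ``n_pairs`` records how many trajectories contribute per lag.
    """
    trajs = list(ensemble)
    if not trajs:
        raise ValueError("empty ensemble")
    dt = trajs[0].frame_interval
    for t in trajs:
        if abs(t.frame_interval - dt) > 1e-9:
            raise ValueError("ensemble members must share one frame interval")
    sums = np.zeros(max_lag_k)
    counts = np.zeros(max_lag_k, dtype=int)
    for t in trajs:
        k_t = min(max_lag_k, t.n_frames - 1)
        if k_t < 1:
            continue
        curve = compute_tamsd(t, k_t)
        sums[:k_t] += curve.values
        counts[:k_t] += 1
    if counts[0] == 0:
        raise ValueError("no trajectory long enough for lag 1")
    keep = counts > 0
    lags = np.arange(1, max_lag_k + 1)[keep] * dt
    return MSDCurve(
        lags=lags, values=sums[keep] / counts[keep], n_pairs=counts[keep], kind="ensemble"
    )


def fit_msd_power_law(
    msd: MSDCurve,
    lag_range: tuple[float, float] | None = None,
    with_offset: bool = False,
) -> PowerLawFit:
    """Fit the anomalous-diffusion power law to an MSD curve.

    Without offset: ordinary least squares of ln MSD on ln t (β = slope,
    D_app = e^intercept / 4).  With offset: nonlinear least squares of
    MSD = 4·D_app·t^β + 4σ² with σ² ≥ 0, initialized from the log-log fit.

    ``lag_range`` restricts the fit to lags t with t_min ≤ t ≤ t_max
    (seconds).  A common default for locus movies is lag 1 through
    ⌊n_frames/4⌋ to keep poorly averaged long lags out of the fit.
    """
    mask = np.ones(len(msd.lags), dtype=bool)
    if lag_range is not None:
        mask &= (msd.lags >= lag_range[0] - 1e-12) & (msd.lags <= lag_range[1] + 1e-12)
    t = msd.lags[mask]
    y = msd.values[mask]
    n_min = 4 if with_offset else 3
    if len(t) < n_min:
        raise ValueError(f"need >= {n_min} lag points in range, got {len(t)}")
    used_range = (float(t[0]), float(t[-1]))
    if np.any(y <= 0):
        raise ValueError("non-positive MSD values in the fit range")
    slope, intercept = np.polyfit(np.log(t), np.log(y), 1)
    beta0 = float(slope)
    d0 = float(np.exp(intercept) / 4.0)
    if not with_offset:
        log_pred = intercept + slope * np.log(t)
        ss_res = np.sum((np.log(y) - log_pred) ** 2)
        ss_tot = np.sum((np.log(y) - np.mean(np.log(y))) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return PowerLawFit(
            D_app=d0, beta=beta0, sigma=None, lag_range=used_range, r_squared=r2
        )

    def residuals(params: np.ndarray) -> np.ndarray:
        d, b, s2 = params
        return 4.0 * d * t**b + 4.0 * s2 - y

    x0 = np.array([max(d0, 1e-12), float(np.clip(beta0, 1e-6, 2.0 - 1e-6)), 0.0])
    sol = least_squares(
        residuals,
        x0,
        bounds=([1e-300, 1e-6, 0.0], [np.inf, 2.0, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    d, b, s2 = sol.x
    pred = 4.0 * d * t**b + 4.0 * s2
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        D_app=float(d),
        beta=float(b),
        sigma=float(np.sqrt(s2)),
        lag_range=used_range,
        r_squared=float(r2),
        with_offset=True,
    )


def estimate_deff(traj: LocusTrajectory, n_lags: int = 4) -> DiffusionEstimate:
    """Short-time effective diffusion constant.

    Origin-constrained least squares of the time-averaged MSD on lag time
    over the first ``n_lags`` lags; D_eff = slope / 4.  The default window of
    4 lags targets the short-time regime of subdiffusive locus movies; the
    value used is recorded on the estimate.
    """
    if traj.n_frames < n_lags + 2:
        raise ValueError(
            f"need >= {n_lags + 2} frames for {n_lags} lags, got {traj.n_frames}"
        )
    curve = compute_tamsd(traj, n_lags)
    t, y = curve.lags, curve.values
    denom = float(np.sum(t * t))
    slope = float(np.sum(t * y)) / denom
    degenerate = bool(np.all(y == 0.0))
    return DiffusionEstimate(
        D_eff=slope / 4.0, n_lags=n_lags, lags=t, degenerate=degenerate
    )


def compute_rg(traj: LocusTrajectory | np.ndarray) -> TrajectoryShape:
    """Gyration radius: RMS distance of trajectory points from their centroid."""
    pos = traj.positions if isinstance(traj, LocusTrajectory) else np.asarray(traj, float)
    if pos.ndim != 2 or pos.shape[0] < 1:
        raise ValueError("need an (n, 2) array with n >= 1")
    centroid = pos.mean(axis=0)
    rel = pos - centroid
    r_g = float(np.sqrt(np.mean(np.einsum("ij,ij->i", rel, rel))))
    return TrajectoryShape(R_g=r_g, centroid=centroid)


@dataclass
class LocalizationPrecision:
    """Localization precision from nominally static fiducial beads.

    Per bead, the standard deviation of its positions about the bead mean;
    the distribution over beads is summarized as mean ± sd per axis and for
    the radial (2D) scatter.
    """

    per_bead: pd.DataFrame  # bead_id, sd_x, sd_y, sd_radial
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    mean_radial: float
    sd_radial: float
    n_beads: int


def estimate_localization_precision(
    beads: TrajectoryEnsemble | Iterable[LocusTrajectory],
) -> LocalizationPrecision:
    """Summarize position scatter of immobilized beads.

    Invariant to a common offset per bead (each bead is centred on its own
    mean).  Requires every bead trajectory to have >= 2 frames (guaranteed by
    the trajectory container).
    """
    rows = []
    for t in beads:
        sd = t.positions.std(axis=0, ddof=1)
        rows.append(
            {
                "bead_id": f"{t.cell_id}/{t.locus_id}",
                "sd_x": sd[0],
                "sd_y": sd[1],
                "sd_radial": float(np.sqrt(sd[0] ** 2 + sd[1] ** 2)),
            }
        )
    if not rows:
        raise ValueError("no bead trajectories supplied")
    df = pd.DataFrame(rows)
    return LocalizationPrecision(
        per_bead=df,
        mean_x=float(df["sd_x"].mean()),
        sd_x=float(df["sd_x"].std(ddof=1)) if len(df) > 1 else 0.0,
        mean_y=float(df["sd_y"].mean()),
        sd_y=float(df["sd_y"].std(ddof=1)) if len(df) > 1 else 0.0,
        mean_radial=float(df["sd_radial"].mean()),
        sd_radial=float(df["sd_radial"].std(ddof=1)) if len(df) > 1 else 0.0,
        n_beads=len(df),
    )
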