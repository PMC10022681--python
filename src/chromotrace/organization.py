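"""Chromosome organization: compaction, distance variation and radiality.

Locus-pair geometry
    The spatial distance R(t) = |P_A(t) − P_B(t)| between two labelled loci
    is averaged first over time (⟨R⟩_t, default 30 frames) and then over the
    cell population, ⟨R⟩ = ⟨⟨R⟩_t⟩_cell.  Chromatin compaction is the
    exponent δ of the power law ⟨R⟩ ∝ s^δ over genomic separations s (Mb);
    smaller δ means tighter packing.  Pair-distance variability decomposes
    into cell-to-cell variation (spread of ⟨R⟩_t across cells) and temporal
    variation δR(t) = |R(t) − ⟨R⟩_t| within cells.

Nuclear radiality
    The normalized radial distance NRD = d/ρ divides the centroid-to-locus
    distance d by the centroid-to-boundary distance ρ measured along the
    same ray, so 0 is the nuclear center and 1 the periphery.  NRD
    distributions (histogram/CDF) and the Pearson correlation between NRD
    and locus mobility (D_eff) quantify radial organization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import LocusTrajectory, NucleusGeometry

__all__ = [
    "LocusPairSeries",
    "PairDistanceSummary",
    "CompactionFit",
    "VariationDecomposition",
    "RadialityRecord",
    "NRDDistribution",
    "CorrelationResult",
    "compute_pair_distance_series",
    "mean_pair_distance",
    "fit_compaction",
    "decompose_variation",
    "compute_nrd",
    "nrd_distribution",
    "correlate_mobility_position",
]

#: raw NRD values in (1, 1 + NRD_CLIP_TOLERANCE] are clipped to 1 and flagged
NRD_CLIP_TOLERANCE = 0.05


@dataclass
class LocusPairSeries:
    """Per-frame spatial distance between two loci in one cell."""

    cell_id: str
    locus_a: str
    locus_b: str
    s_mb: float  # genomic separation, Mb
    times: np.ndarray
    distances: np.ndarray  # µm, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.times) != len(self.distances):
            raise ValueError("times and distances must align")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")

    @property
    def pair(self) -> str:
        return f"{self.locus_a}/{self.locus_b}"

    @property
    def n_frames(self) -> int:
        return len(self.distances)


def compute_pair_distance_series(
    traj_a: LocusTrajectory, traj_b: LocusTrajectory, s_mb: float = float("nan")
) -> LocusPairSeries:
    """Per-frame Euclidean distance between two co-imaged loci."""
    if traj_a.cell_id != traj_b.cell_id:
        raise ValueError(
            f"pair must come from one cell ({traj_a.cell_id} vs {traj_b.cell_id})"
        )
    if traj_a.n_frames != traj_b.n_frames or np.any(
        np.abs(traj_a.times - traj_b.times) > 1e-9
    ):
        raise ValueError("trajectories must cover the same frames")
    d = traj_a.positions - traj_b.positions
    return LocusPairSeries(
        cell_id=traj_a.cell_id,
        locus_a=traj_a.locus_id,
        locus_b=traj_b.locus_id,
        s_mb=s_mb,
        times=traj_a.times.copy(),
        distances=np.sqrt(np.einsum("ij,ij->i", d, d)),
    )


@dataclass
class PairDistanceSummary:
    """⟨R⟩_t per cell and the population average ⟨R⟩ = ⟨⟨R⟩_t⟩_cell."""

    pair: str
    s_mb: float
    cell_means: np.ndarray  # ⟨R⟩_t, one per cell
    mean: float  # ⟨R⟩, µm
    sd: float  # sd of ⟨R⟩_t across cells
    n_cells: int
    n_frames_avg: int


def mean_pair_distance(
    series: Sequence[LocusPairSeries], n_frames_avg: int = 30
) -> PairDistanceSummary:
    """Time-then-population average of a pair's spatial distance.

    Each cell contributes the mean of its first ``n_frames_avg`` frames;
    series shorter than the window raise an error.
    """
    series = list(series)
    if not series:
        raise ValueError("no series supplied")
    pair = series[0].pair
    s_mb = series[0].s_mb
    means = []
    for s in series:
        if s.n_frames < n_frames_avg:
            raise ValueError(
                f"{s.cell_id} ({s.pair}): {s.n_frames} frames < window {n_frames_avg}"
            )
        means.append(float(np.mean(s.distances[:n_frames_avg])))
    means_arr = np.asarray(means)
    return PairDistanceSummary(
        pair=pair,
        s_mb=s_mb,
        cell_means=means_arr,
        mean=float(means_arr.mean()),
        sd=float(means_arr.std(ddof=1)) if len(means_arr) > 1 else 0.0,
        n_cells=len(means_arr),
        n_frames_avg=n_frames_avg,
    )


@dataclass
class CompactionFit:
    """Power law ⟨R⟩ = prefactor·s^δ fitted over locus pairs."""

    delta: float
    prefactor: float  # µm Mb⁻ᵟ
    points: list[tuple[float, float]]  # (s, ⟨R⟩) used
    r_squared: float
    label: str = ""


def fit_compaction(
    points: Sequence[tuple[float, float]],
    label: str = "",
    max_span: float | None = None,
) -> CompactionFit:
    """OLS of ln⟨R⟩ on ln s → compaction exponent δ and prefactor.

    ``max_span`` restricts the fit to pairs with s ≤ max_span (Mb), which
    supports the nested-span convention of reporting δ over e.g. the
    sub-5 Mb pairs and over the full span separately.
    """
    pts = [(float(s), float(r)) for s, r in points]
    if max_span is not None:
        pts = [(s, r) for s, r in pts if s <= max_span + 1e-12]
    svals = np.array([p[0] for p in pts])
    rvals = np.array([p[1] for p in pts])
    if len(np.unique(svals)) < 2:
        raise ValueError("need >= 2 distinct genomic distances")
    if np.any(svals <= 0) or np.any(rvals <= 0):
        raise ValueError("genomic and spatial distances must be positive")
    slope, intercept = np.polyfit(np.log(svals), np.log(rvals), 1)
    pred = intercept + slope * np.log(svals)
    y = np.log(rvals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CompactionFit(
        delta=float(slope),
        prefactor=float(np.exp(intercept)),
        points=pts,
        r_squared=r2,
        label=label,
    )


@dataclass
class VariationDecomposition:
    """Cell-to-cell vs temporal variability of pair distances.

    ``cell_means`` is the distribution of per-cell time averages ⟨R⟩_t
    (cell-to-cell variation); ``temporal_deviations`` pools the absolute
    deviations δR(t) = |R(t) − ⟨R⟩_t| over frames and cells.
    """

    pair: str
    cell_means: np.ndarray
    temporal_deviations: np.ndarray  # pooled |R(t) − ⟨R⟩_t|
    cell_to_cell_sd: float
    temporal_mean_abs: float  # mean δR(t); = sd·√(2/π) for Gaussian jitter
    temporal_sd: float  # sd of R(t) − ⟨R⟩_t pooled
    n_cells: int


def decompose_variation(
    series: Sequence[LocusPairSeries],
) -> VariationDecomposition:
    """Split pair-distance variability into cell-to-cell and temporal parts."""
    series = list(series)
    if not series:
        raise ValueError("no series supplied")
    cell_means = np.array([float(np.mean(s.distances)) for s in series])
    devs = np.concatenate([s.distances - np.mean(s.distances) for s in series])
    n_cells = len(series)
    return VariationDecomposition(
        pair=series[0].pair,
        cell_means=cell_means,
        temporal_deviations=np.abs(devs),
        cell_to_cell_sd=float(cell_means.std(ddof=1)) if n_cells > 1 else float("nan"),
        temporal_mean_abs=float(np.mean(np.abs(devs))),
        temporal_sd=float(devs.std(ddof=0)),
        n_cells=n_cells,
    )


@dataclass
class RadialityRecord:
    """Normalized radial distance of one locus, with optional mobility."""

    cell_id: str
    locus_id: str
    nrd: float  # in [0, 1]
    d: float  # µm, centroid-to-locus
    rho: float  # µm, centroid-to-boundary along the same ray
    d_eff: float | None = None
    clipped: bool = False


def compute_nrd(
    point: Sequence[float],
    geometry: NucleusGeometry,
    cell_id: str | None = None,
    locus_id: str = "",
    d_eff: float | None = None,
) -> RadialityRecord:
    """Normalized radial distance NRD = d/ρ of a locus inside a nucleus.

    ρ is measured along the ray from the (reference) centroid through the
    locus.  A locus at the centroid has NRD 0 by convention; raw values in
    (1, 1.05] — segmentation jitter placing a locus marginally outside — are
    clipped to 1 and flagged, larger excursions raise an error.
    """
    p = np.asarray(point, dtype=float)
    origin = geometry.reference_centroid
    vec = p - origin
    d = float(np.hypot(*vec))
    if d == 0.0:
        return RadialityRecord(
            cell_id=cell_id or geometry.cell_id, locus_id=locus_id,
            nrd=0.0, d=0.0, rho=float("nan"), d_eff=d_eff,
        )
    rho = geometry.boundary_distance(vec)
    raw = d / rho
    clipped = False
    if raw > 1.0 + NRD_CLIP_TOLERANCE:
        raise ValueError(
            f"locus {locus_id or '?'} lies {raw:.3f}·ρ from the centroid, beyond "
            f"the {1 + NRD_CLIP_TOLERANCE:.2f} clipping tolerance"
        )
    if raw > 1.0:
        raw, clipped = 1.0, True
    return RadialityRecord(
        cell_id=cell_id or geometry.cell_id, locus_id=locus_id,
        nrd=float(raw), d=d, rho=float(rho), d_eff=d_eff, clipped=clipped,
    )


@dataclass
class NRDDistribution:
    """Histogram and right-continuous empirical CDF of NRD values on [0, 1]."""

    values: np.ndarray  # sorted
    hist: np.ndarray
    bin_edges: np.ndarray
    n: int

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        """Empirical CDF: fraction of values ≤ x (right-continuous)."""
        return np.searchsorted(self.values, np.asarray(x), side="right") / self.n

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"nrd": self.values, "cdf": self.cdf(self.values)})


def nrd_distribution(
    records: Iterable[RadialityRecord] | np.ndarray, bin_width: float = 0.1
) -> NRDDistribution:
    """Summarize NRD values as a histogram plus empirical CDF."""
    if isinstance(records, np.ndarray):
        values = np.sort(np.asarray(records, dtype=float))
    else:
        values = np.sort([r.nrd for r in records])
    if len(values) == 0:
        raise ValueError("no records supplied")
    n_bins = max(1, int(round(1.0 / bin_width)))
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return NRDDistribution(values=values, hist=hist, bin_edges=edges, n=len(values))


@dataclass
class CorrelationResult:
    """Pearson correlation with the descriptive strength class."""

    r: float
    n: int
    label: str  # negligible |r|<0.2, weak 0.2≤|r|<0.4, moderate+ otherwise


def _strength_label(r: float) -> str:
    a = abs(r)
    if a < 0.2:
        return "negligible"
    if a < 0.4:
        return "weak"
    return "moderate+"


def correlate_mobility_position(
    records: Iterable[RadialityRecord] | tuple[np.ndarray, np.ndarray],
) -> CorrelationResult:
    """Pearson correlation between NRD and D_eff across loci/cells."""
    if isinstance(records, tuple):
        x, y = (np.asarray(v, dtype=float) for v in records)
    else:
        recs = [r for r in records if r.d_eff is not None]
        x = np.array([r.nrd for r in recs])
        y = np.array([r.d_eff for r in recs])
    if len(x) < 3:
        raise ValueError("need >= 3 records with finite NRD and D_eff")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in NRD or D_eff")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(r=r, n=len(x), label=_strength_label(r))
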