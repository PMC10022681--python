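"""Trajectory and nuclear-geometry containers, readers, writers and filters.

The atom of every downstream analysis is a :class:`LocusTrajectory`: the
time-stamped 2D positions (µm) of one fluorescently labelled genomic locus in
one cell, sampled at a fixed frame interval.  Trajectories are grouped into a
:class:`TrajectoryEnsemble` keyed by locus and experimental condition.
Nuclear geometry (centroid plus boundary, either an ellipse or a polygon) is
carried by :class:`NucleusGeometry` and supports the nuclear-motion
calibration and radial-position analyses.

Conventions: coordinates in µm, time in seconds, frames are 0-based integers.
Trajectories with missing frames are rejected rather than interpolated, since
gap filling would bias the step-size regression used for spring-constant
estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "LocusTrajectory",
    "TrajectoryEnsemble",
    "Ellipse",
    "NucleusGeometry",
    "FilterRules",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "read_trajectories",
    "write_trajectories",
    "read_geometry",
    "write_geometry",
    "correct_nuclear_motion",
    "filter_ensemble",
]

#: required columns of the tabular trajectory format
TRAJECTORY_COLUMNS = ("cell_id", "locus_id", "frame", "t_s", "x_um", "y_um")

#: tolerance (s) for uniform frame spacing
TIME_TOLERANCE = 1e-9


class TrajectoryFormatError(ValueError):
    """A trajectory table does not conform to the expected schema."""


class TrajectoryValidationError(ValueError):
    """A trajectory violates an invariant (spacing, finiteness, length)."""


@dataclass
class LocusTrajectory:
    """2D positions of one genomic locus in one cell over a movie.

    Parameters
    ----------
    cell_id, locus_id
        Identifiers; ``locus_id`` names the labelled site (e.g. ``"PR1"``).
    times
        Strictly increasing sample times in seconds with constant spacing.
    positions
        ``(n, 2)`` array of x/y coordinates in µm.
    condition
        Free-form experimental label (cell-cycle stage, drug treatment, ...).
    frame_interval
        Frame spacing in seconds; inferred from ``times`` when omitted.
    frames
        0-based frame indices; defaults to ``0..n-1``.
    metadata
        Auxiliary per-trajectory flags (``focus_count``, ``nucleus_class``...).
    """

    cell_id: str
    locus_id: str
    times: np.ndarray
    positions: np.ndarray
    condition: str = ""
    frame_interval: float | None = None
    frames: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise TrajectoryValidationError(
                f"{self._tag}: positions must be (n, 2), got {self.positions.shape}"
            )
        n = len(self.times)
        if n < 2:
            raise TrajectoryValidationError(f"{self._tag}: need >=2 positions, got {n}")
        if self.positions.shape[0] != n:
            raise TrajectoryValidationError(
                f"{self._tag}: {n} times but {self.positions.shape[0]} positions"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.positions)):
            raise TrajectoryValidationError(f"{self._tag}: non-finite coordinate or time")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise TrajectoryValidationError(f"{self._tag}: times not strictly increasing")
        dt = float(dts[0]) if self.frame_interval is None else float(self.frame_interval)
        if np.any(np.abs(dts - dt) > TIME_TOLERANCE):
            raise TrajectoryValidationError(
                f"{self._tag}: non-uniform time spacing (expected {dt} s)"
            )
        self.frame_interval = dt
        if self.frames is None:
            self.frames = np.arange(n, dtype=int)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
            if len(self.frames) != n:
                raise TrajectoryValidationError(f"{self._tag}: frames length mismatch")
            if np.any(np.diff(self.frames) != 1):
                raise TrajectoryValidationError(
                    f"{self._tag}: missing frame(s); gapped trajectories are rejected"
                )

    @property
    def _tag(self) -> str:
        return f"trajectory ({self.cell_id}, {self.locus_id})"

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Total movie duration in seconds."""
        return float(self.times[-1] - self.times[0])

    def with_positions(self, positions: np.ndarray) -> "LocusTrajectory":
        """Copy of this trajectory with replaced positions."""
        return replace(self, positions=np.asarray(positions, dtype=float))

    def translated(self, offset: Sequence[float]) -> "LocusTrajectory":
        return self.with_positions(self.positions + np.asarray(offset, dtype=float))


@dataclass
class TrajectoryEnsemble:
    """A collection of trajectories with (locus_id, condition) grouping."""

    trajectories: list[LocusTrajectory]

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[LocusTrajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> LocusTrajectory:
        return self.trajectories[i]

    def select(
        self,
        locus_id: str | None = None,
        condition: str | None = None,
        cell_id: str | None = None,
    ) -> "TrajectoryEnsemble":
        out = [
            t
            for t in self.trajectories
            if (locus_id is None or t.locus_id == locus_id)
            and (condition is None or t.condition == condition)
            and (cell_id is None or t.cell_id == cell_id)
        ]
        return TrajectoryEnsemble(out)

    def groupby(self, *keys: str) -> dict[tuple, "TrajectoryEnsemble"]:
        """Group member trajectories by attribute names (e.g. 'locus_id')."""
        groups: dict[tuple, list[LocusTrajectory]] = {}
        for t in self.trajectories:
            key = tuple(getattr(t, k) for k in keys)
            groups.setdefault(key, []).append(t)
        return {k: TrajectoryEnsemble(v) for k, v in groups.items()}

    @property
    def loci(self) -> list[str]:
        return sorted({t.locus_id for t in self.trajectories})

    @property
    def conditions(self) -> list[str]:
        return sorted({t.condition for t in self.trajectories})

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trajectories:
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": t.cell_id,
                        "locus_id": t.locus_id,
                        "condition": t.condition,
                        "frame": t.frames,
                        "t_s": t.times,
                        "x_um": t.positions[:, 0],
                        "y_um": t.positions[:, 1],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["cell_id", "locus_id", "condition", *TRAJECTORY_COLUMNS[2:]]
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class Ellipse:
    """Elliptical nuclear boundary: center (µm), semi-axes a >= b, rotation."""

    center: np.ndarray
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, point: Sequence[float]) -> bool:
        x, y = self._to_frame(point)
        return (x / self.a) ** 2 + (y / self.b) ** 2 <= 1.0 + 1e-12

    def _to_frame(self, point: Sequence[float]) -> tuple[float, float]:
        p = np.asarray(point, dtype=float) - self.center
        c, s = np.cos(self.theta), np.sin(self.theta)
        return float(c * p[0] + s * p[1]), float(-s * p[0] + c * p[1])

    def ray_distance(self, origin: Sequence[float], direction: Sequence[float]) -> float:
        """Distance from ``origin`` (inside) to the boundary along ``direction``.

        Solves the quadratic for the positive root of
        ``(o + t u - center)^T M (o + t u - center) = 1``.
        """
        c, s = np.cos(self.theta), np.sin(self.theta)
        rot = np.array([[c, s], [-s, c]])
        o = rot @ (np.asarray(origin, dtype=float) - self.center)
        u = rot @ np.asarray(direction, dtype=float)
        norm = np.hypot(*u)
        if norm == 0:
            raise ValueError("direction must be non-zero")
        u = u / norm
        inv = np.array([1.0 / self.a**2, 1.0 / self.b**2])
        qa = float(np.sum(inv * u * u))
        qb = 2.0 * float(np.sum(inv * o * u))
        qc = float(np.sum(inv * o * o)) - 1.0
        disc = qb * qb - 4 * qa * qc
        if disc < 0:
            raise ValueError("ray does not intersect ellipse (origin outside?)")
        return (-qb + np.sqrt(disc)) / (2 * qa)


@dataclass
class NucleusGeometry:
    """Nuclear centroid (static or per-frame series) and boundary."""

    cell_id: str
    centroid: np.ndarray
    boundary: Ellipse | Polygon
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.ndim == 1:
            if self.centroid.shape != (2,):
                raise ValueError("static centroid must be a 2-vector")
        elif self.centroid.ndim == 2:
            if self.centroid.shape[1] != 2:
                raise ValueError("centroid series must be (n, 2)")
            if self.frames is None:
                self.frames = np.arange(self.centroid.shape[0], dtype=int)
            else:
                self.frames = np.asarray(self.frames, dtype=int)
                if len(self.frames) != self.centroid.shape[0]:
                    raise ValueError("frames length mismatch for centroid series")
        else:
            raise ValueError("centroid must be (2,) or (n, 2)")
        if isinstance(self.boundary, Polygon):
            if not self.boundary.is_valid or not self.boundary.is_simple:
                raise ValueError(f"nucleus {self.cell_id}: polygon must be simple")
            if len(self.boundary.exterior.coords) < 4:  # closed ring repeats first vertex
                raise ValueError(f"nucleus {self.cell_id}: polygon needs >=3 vertices")
            if not self.boundary.contains(Point(*self.reference_centroid)):
                raise ValueError(f"nucleus {self.cell_id}: centroid not inside boundary")
        elif isinstance(self.boundary, Ellipse):
            if not self.boundary.contains(self.reference_centroid):
                raise ValueError(f"nucleus {self.cell_id}: centroid not inside boundary")
        else:
            raise TypeError("boundary must be an Ellipse or shapely Polygon")

    @property
    def has_centroid_series(self) -> bool:
        return self.centroid.ndim == 2

    @property
    def reference_centroid(self) -> np.ndarray:
        """A single representative centroid (mean of the series if per-frame)."""
        if self.has_centroid_series:
            return self.centroid.mean(axis=0)
        return self.centroid

    def centroid_at(self, frame: int) -> np.ndarray:
        if not self.has_centroid_series:
            return self.centroid
        idx = np.nonzero(self.frames == frame)[0]
        if len(idx) == 0:
            raise KeyError(f"nucleus {self.cell_id}: no centroid for frame {frame}")
        return self.centroid[idx[0]]

    def boundary_distance(self, direction: Sequence[float]) -> float:
        """Centroid-to-boundary distance ρ along ``direction``.

        For polygons the farthest intersection of the outgoing ray with the
        exterior ring is used, matching a radial d/ρ definition.
        """
        origin = self.reference_centroid
        u = np.asarray(direction, dtype=float)
        norm = np.hypot(*u)
        if norm == 0:
            raise ValueError("direction must be non-zero")
        u = u / norm
        if isinstance(self.boundary, Ellipse):
            return self.boundary.ray_distance(origin, u)
        # ray length comfortably beyond the polygon extent
        minx, miny, maxx, maxy = self.boundary.bounds
        span = 2.0 * max(maxx - minx, maxy - miny, 1.0)
        ray = LineString([origin, origin + span * u])
        inter = ray.intersection(self.boundary.exterior)
        if inter.is_empty:
            raise ValueError(f"nucleus {self.cell_id}: ray misses the boundary")
        pts: list[tuple[float, float]] = []
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            pts.extend(np.atleast_2d(np.asarray(g.coords)))
        dists = [float(np.hypot(p[0] - origin[0], p[1] - origin[1])) for p in pts]
        return max(dists)


# ---------------------------------------------------------------------------
# tabular I/O


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_trajectories(path: str | Path) -> TrajectoryEnsemble:
    """Read a trajectory table (CSV, or TSV by extension).

    Expected header: ``cell_id, locus_id, frame, t_s, x_um, y_um`` with an
    optional ``condition`` column.  Rows are sorted by frame within each
    (cell, locus); duplicated frames and non-uniform time spacing raise
    errors naming the offending trajectory and rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_separator_for(path), float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing required column(s) {missing}")
    if "condition" not in df.columns:
        df["condition"] = ""
    df["condition"] = df["condition"].fillna("")
    dup = df.duplicated(subset=["cell_id", "locus_id", "frame"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based, plus header line
        keys = df.loc[dup, ["cell_id", "locus_id", "frame"]].drop_duplicates()
        raise TrajectoryFormatError(
            f"{path}: duplicate (cell_id, locus_id, frame) rows at file lines {rows}: "
            f"{keys.to_dict('records')}"
        )
    return ensemble_from_dataframe(df)


def ensemble_from_dataframe(df: pd.DataFrame) -> TrajectoryEnsemble:
    """Build an ensemble from a tidy trajectory table (one row per frame)."""
    meta_cols = [c for c in ("focus_count", "nucleus_class") if c in df.columns]
    trajectories = []
    for (cell_id, locus_id), g in df.groupby(["cell_id", "locus_id"], sort=True):
        g = g.sort_values("frame")
        condition = str(g["condition"].iloc[0]) if "condition" in g else ""
        metadata = {c: g[c].iloc[0] for c in meta_cols}
        trajectories.append(
            LocusTrajectory(
                cell_id=str(cell_id),
                locus_id=str(locus_id),
                condition=condition,
                times=g["t_s"].to_numpy(),
                positions=g[["x_um", "y_um"]].to_numpy(),
                frames=g["frame"].to_numpy() - int(g["frame"].iloc[0]),
                metadata=metadata,
            )
        )
    return TrajectoryEnsemble(trajectories)


def write_trajectories(ensemble: TrajectoryEnsemble, path: str | Path) -> Path:
    """Write an ensemble as a trajectory table readable by ``read_trajectories``.

    Floats are written with shortest-round-trip repr, so a read/write cycle
    reproduces every value bit-for-bit.
    """
    path = Path(path)
    df = ensemble.to_dataframe()
    # 17 significant digits guarantee exact float64 round trips
    df.to_csv(
        path,
        sep=_separator_for(path),
        index=False,
        float_format=lambda v: format(float(v), ".17g"),
    )
    return path


# ---------------------------------------------------------------------------
# geometry I/O (JSON)


def _geometry_to_dict(geom: NucleusGeometry) -> dict:
    if isinstance(geom.boundary, Ellipse):
        boundary = {
            "type": "ellipse",
            "center": geom.boundary.center.tolist(),
            "a_um": geom.boundary.a,
            "b_um": geom.boundary.b,
            "theta_rad": geom.boundary.theta,
        }
    else:
        boundary = {
            "type": "polygon",
            "vertices": [list(xy) for xy in geom.boundary.exterior.coords[:-1]],
        }
    d: dict = {"cell_id": geom.cell_id, "boundary": boundary}
    if geom.has_centroid_series:
        d["centroid_series"] = geom.centroid.tolist()
        d["frames"] = np.asarray(geom.frames).tolist()
    else:
        d["centroid"] = geom.centroid.tolist()
    return d


def _geometry_from_dict(d: Mapping) -> NucleusGeometry:
    b = d["boundary"]
    boundary: Ellipse | Polygon
    if b["type"] == "ellipse":
        boundary = Ellipse(
            center=np.asarray(b["center"], dtype=float),
            a=float(b["a_um"]),
            b=float(b["b_um"]),
            theta=float(b.get("theta_rad", 0.0)),
        )
    elif b["type"] == "polygon":
        boundary = Polygon(b["vertices"])
    else:
        raise ValueError(f"unknown boundary type {b['type']!r}")
    if "centroid_series" in d:
        return NucleusGeometry(
            cell_id=str(d["cell_id"]),
            centroid=np.asarray(d["centroid_series"], dtype=float),
            boundary=boundary,
            frames=np.asarray(d["frames"], dtype=int) if "frames" in d else None,
        )
    return NucleusGeometry(
        cell_id=str(d["cell_id"]),
        centroid=np.asarray(d["centroid"], dtype=float),
        boundary=boundary,
    )


def write_geometry(geometries: Iterable[NucleusGeometry], path: str | Path) -> Path:
    path = Path(path)
    payload = {"cells": [_geometry_to_dict(g) for g in geometries]}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_geometry(path: str | Path) -> dict[str, NucleusGeometry]:
    """Read nuclear geometry records; returns a mapping cell_id -> geometry."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for d in payload["cells"]:
        g = _geometry_from_dict(d)
        out[g.cell_id] = g
    return out


# ---------------------------------------------------------------------------
# pre-processing


def correct_nuclear_motion(
    traj: LocusTrajectory,
    geometry: NucleusGeometry,
    reference_frame: int | None = None,
) -> LocusTrajectory:
    """Calibrate locus positions by the motion of the nuclear centroid.

    Whole-cell movement is removed by expressing each position relative to
    the per-frame nuclear centroid (the default) or relative to the centroid
    of a single ``reference_frame``.  Times and frame interval are unchanged.
    """
    if reference_frame is not None:
        offset = geometry.centroid_at(reference_frame)
        return traj.with_positions(traj.positions - offset)
    if not geometry.has_centroid_series:
        return traj.with_positions(traj.positions - geometry.centroid)
    centroids = np.empty_like(traj.positions)
    for i, f in enumerate(traj.frames):
        centroids[i] = geometry.centroid_at(int(f))
    return traj.with_positions(traj.positions - centroids)


@dataclass
class FilterRules:
    """Inclusion rules applied before analysis.

    ``max_focus_count`` drops cells in late S/G2/M (replicated loci appear as
    extra foci); ``exclude_nucleus_classes`` drops e.g. small early-G1 nuclei.
    """

    min_length: int | None = None
    max_focus_count: int | None = None
    exclude_nucleus_classes: frozenset[str] = frozenset()


def filter_ensemble(
    ensemble: TrajectoryEnsemble, rules: FilterRules | None = None
) -> tuple[TrajectoryEnsemble, dict[str, int]]:
    """Apply inclusion rules; returns (surviving ensemble, removal report).

    Each removed trajectory is counted under the first rule it fails; the
    report also carries the number kept.
    """
    if rules is None:
        rules = FilterRules()
    report = {"short": 0, "focus_count": 0, "nucleus_class": 0, "kept": 0}
    kept = []
    for t in ensemble:
        if rules.min_length is not None and t.n_frames < rules.min_length:
            report["short"] += 1
            continue
        fc = t.metadata.get("focus_count")
        if (
            rules.max_focus_count is not None
            and fc is not None
            and int(fc) > rules.max_focus_count
        ):
            report["focus_count"] += 1
            continue
        nc = t.metadata.get("nucleus_class")
        if nc is not None and str(nc) in rules.exclude_nucleus_classes:
            report["nucleus_class"] += 1
            continue
        kept.append(t)
        report["kept"] += 1
    return TrajectoryEnsemble(kept), report
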