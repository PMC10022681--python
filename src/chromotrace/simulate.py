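"""Synthetic trajectory, polymer and nucleus generators.

These generators provide ground truth for every estimator in the package:

* :func:`simulate_brownian` — free diffusion (the null for spring estimates);
* :func:`simulate_ou` — the overdamped Langevin model of a harmonically
  confined locus, using the *exact* discrete Ornstein–Uhlenbeck transition so
  it can serve as an analytic oracle;
* :func:`simulate_fbm` — fractional Brownian motion for subdiffusive loci
  (ensemble MSD = 4·D_app·t^β), built by circulant embedding of the exact
  fractional Gaussian-noise covariance;
* :func:`simulate_rouse_chain` — an overdamped Euler–Maruyama Rouse chain of
  harmonically coupled beads with an optional tether to a fixed nuclear
  landmark;
* :func:`add_localization_noise` — i.i.d. Gaussian localization error;
* :func:`simulate_nucleus` — elliptical nuclei with loci placed at prescribed
  normalized radial distances;
* :func:`generate_pair_distances` — inter-locus distance series following
  ⟨R⟩ ∝ s^δ with separate cell-to-cell and temporal variation.

Units follow the imaging convention throughout: µm, seconds, energies in
k_BT (so spring constants are k_BT µm⁻² and the bead mobility equals its
diffusion coefficient).

Every generator is bit-reproducible under a fixed seed.  Each call consumes
a single ``numpy.random.default_rng`` stream in documented order (per-axis
increments are drawn together as ``(n_traj, n_frames, 2)`` blocks).

Default parameter scales mirror the live-cell measurements the analysis is
designed for: 120 frames at Δt = 0.667 s (an 80 s movie), effective
diffusion constants of a few 10⁻³ µm² s⁻¹, localization noise σ = 0.05 µm,
and subdiffusion exponents near 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Ellipse, LocusTrajectory, NucleusGeometry, TrajectoryEnsemble

__all__ = [
    "SimulationConfig",
    "RouseChainSpec",
    "simulate_brownian",
    "simulate_ou",
    "simulate_fbm",
    "simulate_rouse_chain",
    "add_localization_noise",
    "simulate_nucleus",
    "generate_pair_distances",
]


@dataclass
class SimulationConfig:
    """Common knobs shared by all trajectory generators.

    Defaults match the live-imaging regime the pipeline targets: 120-frame
    movies at 0.667 s per frame.
    """

    seed: int
    n_trajectories: int = 1
    n_frames: int = 120
    frame_interval: float = 0.667
    locus_id: str = "SIM"
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _wrap(paths: np.ndarray, config: SimulationConfig) -> TrajectoryEnsemble:
    """Wrap a (n_traj, n_frames, 2) array into an ensemble."""
    times = config.times()
    trajectories = [
        LocusTrajectory(
            cell_id=f"cell{i:04d}",
            locus_id=config.locus_id,
            condition=config.condition,
            times=times,
            positions=paths[i],
            frame_interval=config.frame_interval,
        )
        for i in range(paths.shape[0])
    ]
    return TrajectoryEnsemble(trajectories)


def simulate_brownian(
    D: float, config: SimulationConfig, origin: Sequence[float] = (0.0, 0.0)
) -> TrajectoryEnsemble:
    """Free 2D diffusion with per-axis step variance 2·D·Δt.

    ``D = 0`` produces constant trajectories.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = config.rng()
    n, m = config.n_trajectories, config.n_frames
    steps = rng.normal(0.0, np.sqrt(2.0 * D * config.frame_interval), size=(n, m - 1, 2))
    paths = np.zeros((n, m, 2))
    paths[:, 0] = np.asarray(origin, dtype=float)
    np.cumsum(steps, axis=1, out=paths[:, 1:])
    paths[:, 1:] += paths[:, :1]
    return _wrap(paths, config)


def simulate_ou(
    k: float,
    D: float,
    config: SimulationConfig,
    center: Sequence[float] = (0.0, 0.0),
) -> TrajectoryEnsemble:
    """Harmonically confined locus (overdamped Langevin / OU process).

    Exact discrete transition per axis with relaxation time τ = k_BT/(D·k)
    = 1/(D·k) in k_BT units: decay factor e^(−Δt/τ), stationary per-axis
    variance 1/k.  The initial point is drawn from the stationary law, so
    every frame is stationary.  ``k = 0`` falls back to free diffusion.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if D <= 0:
        raise ValueError("D must be positive")
    if k == 0:
        return simulate_brownian(D, config, origin=center)
    rng = config.rng()
    n, m = config.n_trajectories, config.n_frames
    center = np.asarray(center, dtype=float)
    tau = 1.0 / (D * k)
    decay = np.exp(-config.frame_interval / tau)
    stat_sd = 1.0 / np.sqrt(k)
    step_sd = stat_sd * np.sqrt(1.0 - decay**2)
    paths = np.empty((n, m, 2))
    paths[:, 0] = rng.normal(0.0, stat_sd, size=(n, 2))
    noise = rng.normal(0.0, step_sd, size=(n, m - 1, 2))
    for j in range(1, m):
        paths[:, j] = paths[:, j - 1] * decay + noise[:, j - 1]
    paths += center
    return _wrap(paths, config)


def _fgn_increments(
    rng: np.random.Generator, hurst: float, n_steps: int, n_series: int
) -> np.ndarray:
    """Standard fractional Gaussian noise via Davies–Harte circulant embedding.

    Returns ``(n_series, n_steps)`` increments with unit variance and exact
    fGn autocovariance; sums give fBm with E[B(k)²] = k^(2H).
    """
    k = np.arange(n_steps + 1, dtype=float)
    r = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    # first row of the circulant embedding, length 2*n_steps
    c = np.concatenate([r[:-1], r[-1:], r[-2:0:-1]]) if n_steps > 1 else np.array([r[0], r[1]])
    lam = np.fft.fft(c).real
    lam = np.where(lam < 0, 0.0, lam)  # clip tiny negative fp eigenvalues
    M = len(c)
    n_pairs = (n_series + 1) // 2
    z = rng.standard_normal((n_pairs, M)) + 1j * rng.standard_normal((n_pairs, M))
    y = np.fft.fft(np.sqrt(lam) * z, axis=1) / np.sqrt(M)
    samples = np.concatenate([y.real[:, :n_steps], y.imag[:, :n_steps]], axis=0)
    return samples[:n_series]


def simulate_fbm(
    beta: float, D_app: float, config: SimulationConfig
) -> TrajectoryEnsemble:
    """Subdiffusive (or superdiffusive) fractional Brownian motion.

    Scaled so the ensemble MSD obeys MSD(t) = 4·D_app·t^β exactly; ``beta=1``
    reduces to free diffusion with D = D_app.
    """
    if not 0 < beta < 2:
        raise ValueError("beta must lie in (0, 2)")
    if D_app <= 0:
        raise ValueError("D_app must be positive")
    rng = config.rng()
    n, m = config.n_trajectories, config.n_frames
    hurst = beta / 2.0
    scale = np.sqrt(2.0 * D_app * config.frame_interval**beta)
    incr = _fgn_increments(rng, hurst, m - 1, 2 * n) * scale
    incr = incr.reshape(n, 2, m - 1).transpose(0, 2, 1)
    paths = np.zeros((n, m, 2))
    np.cumsum(incr, axis=1, out=paths[:, 1:])
    return _wrap(paths, config)


@dataclass
class RouseChainSpec:
    """A Rouse chain: beads joined by harmonic springs, optionally tethered.

    Parameters
    ----------
    n_beads
        Chain length.
    neighbor_spring
        Nearest-neighbour spring constant in k_BT µm⁻².
    bead_diffusion
        Free-bead diffusion coefficient in µm² s⁻¹.
    tether
        Optional ``(bead_index, anchor_point, k_t)``: bead ``bead_index`` is
        harmonically bound (stiffness ``k_t``) to a fixed lab-frame anchor,
        modelling attachment to a nuclear landmark.
    labeled_beads
        Bead indices recorded as trajectories (default: all beads).
    genomic_spacing
        Genomic distance per bond in Mb; bead ``i`` sits at ``i·spacing`` Mb
        and the chain stiffness per genomic distance is
        ``K_R = neighbor_spring · genomic_spacing``.
    """

    n_beads: int
    neighbor_spring: float
    bead_diffusion: float
    tether: tuple[int, Sequence[float], float] | None = None
    labeled_beads: Sequence[int] | None = None
    genomic_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.neighbor_spring < 0 or self.bead_diffusion <= 0:
            raise ValueError("spring constants must be >= 0 and diffusion > 0")
        if self.labeled_beads is None:
            self.labeled_beads = tuple(range(self.n_beads))
        else:
            self.labeled_beads = tuple(int(i) for i in self.labeled_beads)
        for i in self.labeled_beads:
            if not 0 <= i < self.n_beads:
                raise ValueError(f"labeled bead {i} outside chain")
        if self.tether is not None:
            b, anchor, k_t = self.tether
            if not 0 <= int(b) < self.n_beads:
                raise ValueError(f"tether bead {b} outside chain")
            if k_t < 0:
                raise ValueError("tether spring constant must be >= 0")
            self.tether = (int(b), np.asarray(anchor, dtype=float), float(k_t))

    def stiffness_matrix(self) -> np.ndarray:
        """Per-axis harmonic coupling matrix K (force = −K·x + tether terms)."""
        n, ks = self.n_beads, self.neighbor_spring
        K = np.zeros((n, n))
        for i in range(n - 1):
            K[i, i] += ks
            K[i + 1, i + 1] += ks
            K[i, i + 1] -= ks
            K[i + 1, i] -= ks
        if self.tether is not None:
            b, _, k_t = self.tether
            K[b, b] += k_t
        return K

    def max_stiffness(self) -> float:
        """Upper bound on the largest eigenvalue of the stiffness matrix."""
        k_max = 4.0 * self.neighbor_spring
        if self.tether is not None:
            k_max += self.tether[2]
        return max(k_max, 1e-300)


def _rouse_equilibrium(
    spec: RouseChainSpec, rng: np.random.Generator, n_traj: int
) -> np.ndarray:
    """Exact Gaussian equilibrium configurations, shape (n_traj, n_beads, 2).

    A harmonic chain is a Gaussian network, so equilibrium is sampled in
    closed form: a tethered chain from the Cholesky factor of its stiffness
    matrix; a free chain from i.i.d. Gaussian bond vectors (its center of
    mass is unconstrained and is placed at the anchor-free origin).
    """
    n = spec.n_beads
    if spec.tether is not None and spec.tether[2] > 0:
        K = spec.stiffness_matrix()
        L = np.linalg.cholesky(K)
        z = rng.standard_normal((2 * n_traj, n))
        # x = mean + L^{-T} z has covariance K^{-1}
        x = np.linalg.solve(L.T, z.T).T.reshape(n_traj, 2, n).transpose(0, 2, 1)
        return x + spec.tether[1]
    if n == 1 or spec.neighbor_spring == 0:
        return np.zeros((n_traj, n, 2))
    bond_sd = 1.0 / np.sqrt(spec.neighbor_spring)
    bonds = rng.normal(0.0, bond_sd, size=(n_traj, n - 1, 2))
    x = np.zeros((n_traj, n, 2))
    np.cumsum(bonds, axis=1, out=x[:, 1:])
    x -= x.mean(axis=1, keepdims=True)
    return x


def simulate_rouse_chain(
    spec: RouseChainSpec,
    config: SimulationConfig,
    substep_factor: float = 0.01,
    burn_in: float = 0.0,
) -> TrajectoryEnsemble:
    """Overdamped Brownian dynamics of a (possibly tethered) Rouse chain.

    Euler–Maruyama integration with internal substep
    Δt_sub ≤ ``substep_factor``/(D_bead·k_max); labelled-bead positions are
    recorded every ``config.frame_interval``.  Initial configurations are
    drawn from the chain's exact Gaussian equilibrium, so no long burn-in is
    required (``burn_in`` seconds of unrecorded integration can be added for
    e.g. non-equilibrium protocols).

    Returns one trajectory per (replicate, labelled bead); the trajectory's
    ``locus_id`` is ``bead<i>`` and its metadata carries the genomic
    position ``c_mb = i·genomic_spacing``.

    Raises ``RuntimeError`` if the integration diverges (advice: reduce the
    substep via ``substep_factor``).
    """
    if substep_factor <= 0:
        raise ValueError("substep_factor must be positive")
    rng = config.rng()
    D = spec.bead_diffusion
    k_max = spec.max_stiffness()
    dt_bound = substep_factor / (D * k_max)
    n_sub = max(1, int(np.ceil(config.frame_interval / dt_bound)))
    dt = config.frame_interval / n_sub
    K = spec.stiffness_matrix()
    theta = D * dt
    noise_sd = np.sqrt(2.0 * D * dt)
    anchor_force = np.zeros((spec.n_beads, 2))
    if spec.tether is not None:
        b, anchor, k_t = spec.tether
        anchor_force[b] = k_t * anchor  # −K x already contains +k_t on the diagonal

    x = _rouse_equilibrium(spec, rng, config.n_trajectories)
    n_burn = int(np.ceil(burn_in / dt)) if burn_in > 0 else 0

    def _advance(x: np.ndarray, n_steps: int) -> np.ndarray:
        for _ in range(n_steps):
            drift = -np.einsum("ij,njd->nid", K, x) + anchor_force
            x = x + theta * drift + rng.normal(0.0, noise_sd, size=x.shape)
        return x

    x = _advance(x, n_burn)
    recorded = np.empty((config.n_trajectories, config.n_frames, spec.n_beads, 2))
    recorded[:, 0] = x
    for f in range(1, config.n_frames):
        x = _advance(x, n_sub)
        recorded[:, f] = x
    if not np.all(np.isfinite(recorded)):
        raise RuntimeError(
            "Rouse integration diverged; reduce the substep (smaller substep_factor)"
        )

    times = config.times()
    trajectories = []
    for rep in range(config.n_trajectories):
        for bead in spec.labeled_beads:
            trajectories.append(
                LocusTrajectory(
                    cell_id=f"cell{rep:04d}",
                    locus_id=f"bead{bead:02d}",
                    condition=config.condition,
                    times=times,
                    positions=recorded[rep, :, bead],
                    frame_interval=config.frame_interval,
                    metadata={"c_mb": bead * spec.genomic_spacing},
                )
            )
    return TrajectoryEnsemble(trajectories)


def add_localization_noise(
    ensemble: TrajectoryEnsemble, sigma: float, seed: int
) -> TrajectoryEnsemble:
    """Add i.i.d. per-axis Gaussian localization error (sd ``sigma`` µm)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return TrajectoryEnsemble(list(ensemble))
    rng = np.random.default_rng(seed)
    out = []
    for t in ensemble:
        noise = rng.normal(0.0, sigma, size=t.positions.shape)
        out.append(t.with_positions(t.positions + noise))
    return TrajectoryEnsemble(out)


def simulate_nucleus(
    cell_id: str,
    center: Sequence[float],
    a: float,
    b: float,
    placements: Sequence[tuple[str, float, float]],
    theta: float = 0.0,
    seed: int | None = None,
    centroid_jitter: float = 0.0,
    n_frames: int = 1,
) -> tuple[NucleusGeometry, dict[str, np.ndarray]]:
    """An elliptical nucleus with loci placed at prescribed radial fractions.

    ``placements`` is a sequence of ``(locus_id, target_nrd, angle)`` with the
    normalized radial distance in [0, 1] and the angle in radians measured in
    the lab frame from the nuclear centroid.  The placed locus sits at
    ``target_nrd · ρ(angle)`` along that ray, so ``compute_nrd`` recovers the
    target exactly.  Optional centroid jitter (per-frame Gaussian sd, µm)
    emulates whole-nucleus motion for calibration tests.
    """
    ellipse = Ellipse(center=np.asarray(center, dtype=float), a=a, b=b, theta=theta)
    centroid: np.ndarray = ellipse.center.copy()
    frames = None
    if centroid_jitter > 0 or n_frames > 1:
        rng = np.random.default_rng(seed)
        series = np.tile(ellipse.center, (n_frames, 1))
        if centroid_jitter > 0:
            series = series + rng.normal(0.0, centroid_jitter, size=(n_frames, 2))
        centroid = series
        frames = np.arange(n_frames)
    geometry = NucleusGeometry(
        cell_id=cell_id, centroid=centroid, boundary=ellipse, frames=frames
    )
    loci: dict[str, np.ndarray] = {}
    origin = geometry.reference_centroid
    for locus_id, nrd, angle in placements:
        if not 0.0 <= nrd <= 1.0:
            raise ValueError(f"target NRD must be in [0, 1], got {nrd}")
        u = np.array([np.cos(angle), np.sin(angle)])
        rho = geometry.boundary_distance(u)
        loci[locus_id] = origin + nrd * rho * u
    return geometry, loci


def generate_pair_distances(
    delta: float,
    prefactor: float,
    genomic_distances: Sequence[float],
    cell_sd: float,
    temporal_sd: float,
    n_cells: int,
    n_frames: int,
    seed: int,
    frame_interval: float = 0.667,
    pair_labels: Sequence[tuple[str, str]] | None = None,
):
    """Synthetic locus-pair distance series with ⟨R⟩ ∝ s^δ scaling.

    For every genomic separation ``s`` (Mb) and cell, the cell's latent mean
    distance is ``prefactor·s^δ`` plus a Gaussian cell offset (sd
    ``cell_sd``, truncated so the mean stays positive); frames jitter around
    the cell mean with sd ``temporal_sd``.  This mirrors the two variation
    sources the analysis decomposes: cell-to-cell variation of the
    time-averaged distance and temporal variation about it.

    Returns a list of :class:`~chromotrace.organization.LocusPairSeries`.
    """
    from .organization import LocusPairSeries  # local import avoids a cycle

    if delta <= 0:
        raise ValueError("delta must be positive")
    if cell_sd < 0 or temporal_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * frame_interval
    labels = pair_labels or [
        (f"L{i}A", f"L{i}B") for i in range(len(genomic_distances))
    ]
    series = []
    floor = 1e-6
    for (locus_a, locus_b), s in zip(labels, genomic_distances):
        base = prefactor * s**delta
        for c in range(n_cells):
            mean_c = base + rng.normal(0.0, cell_sd) if cell_sd > 0 else base
            while mean_c <= floor:  # truncate the cell offset to keep R > 0
                mean_c = base + rng.normal(0.0, cell_sd)
            if temporal_sd > 0:
                dist = mean_c + rng.normal(0.0, temporal_sd, size=n_frames)
                dist = np.clip(dist, floor, None)
            else:
                dist = np.full(n_frames, mean_c)
            series.append(
                LocusPairSeries(
                    cell_id=f"cell{c:04d}",
                    locus_a=locus_a,
                    locus_b=locus_b,
                    s_mb=float(s),
                    times=times,
                    distances=dist,
                )
            )
    return series
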