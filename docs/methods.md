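# Methods

## Scope and data model

The package analyses single-particle tracking of genomic loci imaged in 2D:
each observation is a locus trajectory p(t) — one labelled chromosomal site
in one nucleus, sampled at a fixed frame interval Δt (default movies:
120 frames at Δt = 0.667 s, i.e. 80 s). Coordinates are µm, times seconds,
and energies are expressed in units of k_BT, so spring constants carry
k_BT µm⁻² and the Einstein relation reads γ = 1/D_eff. Trajectories with
missing frames are rejected rather than interpolated: gap filling would
correlate consecutive steps and bias the step-size regression that the
spring-constant estimate rests on. Whole-cell movement is removed by
calibrating positions against the nuclear centroid, per frame by default (a
single reference frame is supported). Inclusion filters mirror standard
practice for this assay: minimum trajectory length, exclusion of cells with
extra foci (post-replication) and of flagged nucleus classes.

## Dynamics

**MSD.** The time-averaged MSD of one trajectory at lag kΔt averages the
squared displacement over all n − k overlapping start frames. The
ensemble-averaged MSD is the unweighted mean of member time-averaged curves
at each lag; short members simply stop contributing at long lags, and the
per-lag contributor count is reported.

**Power-law fits.** MSD(t) = 4·D_app·t^β is fitted by ordinary least
squares of ln MSD on ln t. The variant with a localization-noise floor,
MSD(t) = 4·D_app·t^β + 4σ², is a bounded nonlinear least-squares fit
(σ² ≥ 0, 0 < β < 2) initialized from the log-log solution. The default fit
window is lags 1 … ⌊n/4⌋ — long lags of a time-averaged curve are poorly
averaged and would dominate an unweighted fit; the window used is recorded
on the result. Identifiability caveat: on a *static* emitter the noisy
curve is flat and the split between a β ≈ 0 power term and the constant
offset is not identifiable, so σ should be estimated from moving loci
(where t^β and the constant separate) or from the flat noise floor
TA-MSD → 4σ² directly. The offset fit resolves σ best when 4σ² is
comparable to the first-lag displacement 4·D·Δt, which is precisely the
regime of locus imaging (≈ 0.01 µm² each).

**D_eff.** The short-time effective diffusion constant is the
origin-constrained least-squares slope of the time-averaged MSD over the
first 4 lags, divided by 4. Four lags (~2.7 s at the default Δt) balance
bias from MSD curvature against variance at 120-frame movies; the window is
configurable and recorded. For a confined locus sampled at finite Δt this
estimator sits below the true D by O(Δt/τ) — a property shared by any
slope-based short-time estimator — which propagates into k_eff (below).

**R_g.** The gyration radius is the RMS distance of trajectory points from
their centroid; R_g² is the locus territory. For a harmonically confined
2D locus in equilibrium, equipartition gives k·R_g² → 2 k_BT as the movie
grows long.

**Localization precision.** For nominally immobile fiducial beads, the
per-bead standard deviation about the bead mean is reported per axis and
radially, summarized as mean ± sd over beads.

## Mechanics

**Spring constant.** Short-time locus motion is modelled by an overdamped
Langevin equation with a Hookean restoring force. The regression of steps
on centroid-relative positions (x and y pooled, slope s through the origin)
gives k_eff = −s/(D_eff·Δt). This first-order mapping mirrors common
practice; an exact-OU option k_eff = −ln(1+s)/(D_eff·Δt) is provided
because at Δt/τ ≈ 0.2 (the regime of real movies) the linear form
underestimates the stiffness by ~10%. Per-axis slopes are kept as
diagnostics. Negative raw estimates (anti-restoring slopes, expected for
nearly free loci) are flagged and excluded from group means but counted in
the QC report.

Two finite-data artifacts matter and are deliberately surfaced by the test
suite rather than hidden:

* *Centroid referencing.* Referencing steps to the trajectory's own
  centroid produces a spurious apparent confinement for a free particle
  (order 1/(n·σ_step²)) and a positive bias ~2τ/T for confined loci whose
  movie length T is not ≫ the relaxation time τ. Supplying a known
  equilibrium position via the `center` argument removes this entirely —
  used by the simulation oracles.
* *Per-movie ratio bias.* The per-trajectory slope is a ratio whose
  denominator (explored area) fluctuates movie-to-movie; when T is short
  compared to the slowest relaxation, averaging per-movie estimates is
  biased. `estimate_keff_ensemble` pools the regression moments across
  movies first and is the recommended estimator when replicates of one
  locus are available.

**Territory law.** ⟨k_eff⟩ = a·⟨R_g²⟩^(−b) is fitted by log-log OLS over
(k_eff, R_g²) points. Equipartition predicts a = 2, b = 1; a sweep of
confined ensembles at Δt/τ = 0.02 recovers a within 0.2 and b within 0.05.
At experimental sampling (Δt/τ ≈ 0.2–0.4 plus 50 nm noise) the measured
prefactor a sits above 2, consistent with prefactors measured in nuclei.

**Tether model.** A locus i coupled through the chromatin chain to a
tether at genomic position c_t behaves as two springs in series: the chain
segment of genomic length Δc_it = |c_i − c_t| with stiffness K_R/Δc_it, and
the tether k_t:

    1/k_eff,i = 1/k_t + Δc_it/K_R.

Regressing 1/k_eff,i on Δc_it recovers K_R = 1/slope and k_t = 1/intercept;
with exactly two loci this coincides with the closed form
K_R = (Δc_1t − Δc_2t)·k_eff,1·k_eff,2/(k_eff,2 − k_eff,1). K_R carries
per-genomic-distance units (k_BT µm⁻² Mb) so the series formula is
dimensionally consistent. With two loci the triple (K_R, k_t, c_t) is
under-determined, so c_t is a required input; it must lie outside the
labelled span unless explicitly overridden. Solutions with non-positive
slope or intercept are flagged infeasible rather than clipped. For a
discrete tethered Rouse chain the law is exact: the marginal per-axis
variance of bead i is 1/k_t + m/k_s over m bonds to the tether (dangling
arms contribute no restoring potential), which the simulation round trip
exploits as ground truth.

## Organization

**Compaction.** The spatial distance R(t) = |P_A(t) − P_B(t)| of a locus
pair is averaged over the first 30 frames per cell (window configurable)
and then over cells, ⟨R⟩ = ⟨⟨R⟩_t⟩_cell. The compaction exponent δ is the
log-log OLS slope of ⟨R⟩ against genomic separation s. Fits are reported
per nested genomic span (e.g. sub-5 Mb pairs vs the full span) because
compaction is scale-dependent and a single global exponent hides the
short-range/long-range contrast.

**Variation split.** Pair-distance variability decomposes into the spread
of per-cell time means ⟨R⟩_t (cell-to-cell) and the pooled absolute
deviations δR(t) = |R(t) − ⟨R⟩_t| (temporal). For the additive Gaussian
generator these satisfy mean δR = sd·√(2/π) and the total variance is the
sum of the two components, which the tests verify.

**Radiality.** NRD = d/ρ, where d is the centroid-to-locus distance and ρ
the centroid-to-boundary distance along the same ray — a directional
normalization, not nearest-boundary distance, so an eccentric nucleus does
not distort the radial coordinate. For ellipses the ray intersection is
solved in closed form (general quadratic, so an off-center reference point
is handled); for polygons by segment intersection with the exterior ring,
taking the farthest intersection. Raw NRD in (1, 1.05] — segmentation
jitter placing a locus marginally outside — is clipped to 1 and flagged;
larger excursions are errors. NRD distributions are summarized as
histograms (default bin width 0.1) and right-continuous empirical CDFs;
mode calling is left to the user. Mobility–position association is the
Pearson correlation between NRD and D_eff with the descriptive classes
negligible (|r| < 0.2), weak (0.2 ≤ |r| < 0.4), moderate+ otherwise.
Radiality is evaluated in the lab frame (raw positions against the
boundary); nuclear-motion calibration applies to the dynamics stages only.

## Synthetic data

The generators emulate the statistical structure of locus-tracking
experiments; defaults are the experimental scales (120 frames, Δt =
0.667 s, σ_loc = 0.05 µm, D_eff in the low 10⁻³ µm² s⁻¹ range, β near 0.4,
R_g around 0.1 µm):

* **Brownian / OU** — free and harmonically confined diffusion. OU uses the
  exact discrete transition (decay e^(−Δt/τ), stationary variance 1/k per
  axis, stationary initial condition), so it serves as an analytic oracle
  with no integration error.
* **fBm** — subdiffusive trajectories with ensemble MSD 4·D_app·t^β, built
  from exact fractional Gaussian-noise covariance via Davies–Harte
  circulant embedding (tiny negative FFT eigenvalues from floating-point
  are clipped to zero).
* **Rouse chain** — overdamped Euler–Maruyama dynamics of beads coupled by
  nearest-neighbour springs, optionally tethered to a fixed lab-frame
  anchor (the nuclear-landmark picture; anchors do not move). The substep
  is bounded by 0.01·k_BT/(D·k_max) with k_max = 4·k_spring + k_tether, an
  upper bound on the stiffest mode; divergence raises with advice to lower
  the substep. Initial configurations are drawn from the chain's *exact*
  Gaussian equilibrium (Cholesky of the stiffness matrix when tethered,
  i.i.d. bond vectors when free), so recordings start in steady state
  without a long burn-in; an optional burn-in remains for non-equilibrium
  protocols. Euler–Maruyama inflates the stationary variance by O(D·k·dt/2)
  ≤ 0.5% at the default substep — below the resolution of every test that
  consumes it.
* **Localization noise** — i.i.d. per-axis Gaussian offsets; a static noisy
  emitter has a flat TA-MSD at 4σ².
* **Nuclei** — elliptical boundaries with loci placed at prescribed NRD
  along prescribed rays (placement is the exact inverse of the NRD
  computation), optional centroid jitter for calibration tests.
* **Pair distances** — per cell, a latent mean prefactor·s^δ plus a
  truncated Gaussian cell offset (sd `cell_sd`); frames jitter about the
  cell mean (sd `temporal_sd`). This reproduces exactly the two variation
  sources the decomposition targets.

What the generators do *not* emulate: viscoelastic memory beyond fBm,
locus-locus interactions other than harmonic chains, loop extrusion,
excluded volume, 3D motion projected to 2D, segmentation errors beyond
Gaussian centroid jitter, photobleaching and tracking failures. Passing
tests therefore demonstrate estimator correctness under the stated models
and realistic magnitudes — not robustness to every pathology of real
microscopy data.

All generators are bit-reproducible under a fixed seed; each call consumes
one `numpy.random.default_rng(seed)` stream in documented order.

## Statistics

Welch's unequal-variance t-test (Welch–Satterthwaite degrees of freedom,
two-tailed) and one-way ANOVA are implemented as closed forms, with scipy
supplying only distribution tails, so the pipeline's numerical surface is
fully testable against permutation oracles (the suite checks agreement and
a 5% null rejection rate within ±1 point at 10⁴ replicates). Degenerate
inputs use the conventions p = 1 for identical constant groups and p = 0
for constant groups with different means. Stars follow ns (p > 0.05),
* (p < 0.05), ** (p < 0.005), *** (p < 0.0005). No multiple-testing
correction is applied; pairwise comparisons emitted next to a multi-group
ANOVA are labelled uncorrected.

## Numerical choices and problem sizes

Tolerance-relevant defaults: time-spacing tolerance 1e-9 s; NRD clipping
tolerance 5%; D_eff window 4 lags; ⟨R⟩ window 30 frames; power-law window
⌊n/4⌋ lags. Estimator-recovery checks run at sizes where Monte-Carlo error
sits well inside the asserted tolerance: 100–500 movies of 120–4000 frames
for diffusion/stiffness recoveries (confined sweeps use Δt/τ = 0.02, where
mapping bias is ≪ the tolerance), 40 cells for the compaction round trip
(the experimental population size), 200 cells for the variation split, and
10⁴ replicates for test calibration. The tethered-chain inversion uses 200
movies of a 16-bead chain with the tether two and four bonds from the
labelled beads — the stiffness inversion amplifies k_eff noise into the
intercept, so labelled beads near the tether keep the inverse problem
well-conditioned.

## Known limitations

* k_eff values measured at experimental sampling (Δt/τ ≈ 0.2–0.4) carry the
  coupled D_eff and slope biases described above; compare like with like
  (same Δt, window, and reference convention) across conditions.
* The tether inversion assumes a single tether and no long-range
  intra-chain interactions; with two loci, c_t must be supplied.
* Radiality uses the mean locus position per movie against a static
  boundary; boundary motion within a movie is not modelled.
* 2D throughout, as imaged; no projection corrections are applied.
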