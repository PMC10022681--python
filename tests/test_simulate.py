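"""Generators against their own closed-form laws and reproducibility."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import chromotrace as ct


def pooled_positions(ensemble):
    return np.concatenate([t.positions for t in ensemble])


class TestBrownian:
    def test_zero_diffusion_is_constant(self):
        cfg = ct.SimulationConfig(seed=0, n_trajectories=3, n_frames=50)
        ens = ct.simulate_brownian(0.0, cfg)
        for t in ens:
            assert np.ptp(t.positions, axis=0).max() == 0.0

    def test_step_variance_matches_2_D_dt(self):
        cfg = ct.SimulationConfig(
            seed=1, n_trajectories=100, n_frames=101, frame_interval=1.0
        )
        ens = ct.simulate_brownian(0.01, cfg)
        steps = np.concatenate([np.diff(t.positions, axis=0) for t in ens])
        assert steps.shape[0] == 10_000
        np.testing.assert_allclose(steps.var(axis=0), 0.02, rtol=0.05)

    def test_origin_honoured(self):
        cfg = ct.SimulationConfig(seed=2, n_trajectories=2, n_frames=10)
        ens = ct.simulate_brownian(0.01, cfg, origin=(3.0, -1.0))
        for t in ens:
            np.testing.assert_allclose(t.positions[0], [3.0, -1.0])


class TestOrnsteinUhlenbeck:
    def test_stationary_variance_is_inverse_k(self):
        # per-axis stationary variance k_BT/k = 0.01 µm² at k = 100 k_BT/µm²
        cfg = ct.SimulationConfig(
            seed=3, n_trajectories=500, n_frames=100, frame_interval=5.0
        )
        ens = ct.simulate_ou(k=100.0, D=0.0035, config=cfg)
        var = pooled_positions(ens).var(axis=0)
        np.testing.assert_allclose(var, 0.01, rtol=0.03)

    def test_center_sets_stationary_mean(self):
        cfg = ct.SimulationConfig(seed=4, n_trajectories=200, n_frames=50)
        ens = ct.simulate_ou(k=50.0, D=0.01, config=cfg, center=(5.0, 5.0))
        mean = pooled_positions(ens).mean(axis=0)
        np.testing.assert_allclose(mean, [5.0, 5.0], atol=0.01)

    def test_long_interval_decorrelates_consecutive_frames(self):
        k, D = 100.0, 0.0035
        tau = 1.0 / (D * k)
        cfg = ct.SimulationConfig(
            seed=5, n_trajectories=100, n_frames=200, frame_interval=20 * tau
        )
        ens = ct.simulate_ou(k=k, D=D, config=cfg)
        x = np.concatenate([t.positions[:, 0] for t in ens])
        xs = np.concatenate([t.positions[:-1, 0] for t in ens])
        xn = np.concatenate([t.positions[1:, 0] for t in ens])
        rho = np.corrcoef(xs, xn)[0, 1]
        assert abs(rho) < 0.02
        assert x.var() == pytest.approx(1.0 / k, rel=0.05)

    def test_k_zero_falls_back_to_free_diffusion(self):
        cfg = ct.SimulationConfig(seed=6, n_trajectories=2, n_frames=20)
        a = ct.simulate_ou(k=0.0, D=0.01, config=cfg)
        b = ct.simulate_brownian(0.01, cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)


class TestFractionalBrownian:
    def test_beta_one_has_independent_increments_like_brownian(self):
        cfg = ct.SimulationConfig(
            seed=7, n_trajectories=200, n_frames=120, frame_interval=1.0
        )
        ens = ct.simulate_fbm(1.0, 0.01, cfg)
        steps = np.concatenate([np.diff(t.positions, axis=0) for t in ens])
        np.testing.assert_allclose(steps.var(axis=0), 0.02, rtol=0.05)
        lag1 = np.corrcoef(steps[:-1, 0], steps[1:, 0])[0, 1]
        assert abs(lag1) < 0.02

    def test_subdiffusive_exponent_recovered(self):
        cfg = ct.SimulationConfig(seed=8, n_trajectories=200, n_frames=120)
        ens = ct.simulate_fbm(0.4, 0.0035, cfg)
        curve = ct.compute_eamsd(ens, 30)
        fit = ct.fit_msd_power_law(curve)
        assert 0.35 <= fit.beta <= 0.45

    def test_ensemble_msd_magnitude(self):
        # E|p(t)|² = 4·D_app·t^β by construction
        cfg = ct.SimulationConfig(
            seed=9, n_trajectories=2000, n_frames=30, frame_interval=1.0
        )
        beta, d_app = 0.5, 0.02
        ens = ct.simulate_fbm(beta, d_app, cfg)
        pos = np.stack([t.positions for t in ens])
        disp2 = np.sum(pos[:, 10] ** 2, axis=1)
        assert disp2.mean() == pytest.approx(4 * d_app * 10**beta, rel=0.1)

    def test_beta_bounds(self):
        cfg = ct.SimulationConfig(seed=0, n_trajectories=1, n_frames=10)
        with pytest.raises(ValueError):
            ct.simulate_fbm(0.0, 0.01, cfg)
        with pytest.raises(ValueError):
            ct.simulate_fbm(2.0, 0.01, cfg)


class TestRouseChain:
    def test_single_tethered_bead_matches_ou_distribution(self):
        # a one-bead tethered chain is an OU process; compare stationary radii
        kt, D = 50.0, 0.01
        tau = 1.0 / (D * kt)
        spec = ct.RouseChainSpec(
            n_beads=1, neighbor_spring=0.0, bead_diffusion=D, tether=(0, (0, 0), kt)
        )
        cfg = ct.SimulationConfig(
            seed=10, n_trajectories=100, n_frames=100, frame_interval=3 * tau
        )
        chain = ct.simulate_rouse_chain(spec, cfg)
        cfg2 = ct.SimulationConfig(
            seed=11, n_trajectories=100, n_frames=100, frame_interval=3 * tau
        )
        ou = ct.simulate_ou(kt, D, cfg2)
        r_chain = np.hypot(*pooled_positions(chain).T)
        r_ou = np.hypot(*pooled_positions(ou).T)
        assert ks_2samp(r_chain, r_ou).pvalue > 0.01

    def test_free_chain_com_diffuses_with_D_over_n(self):
        n_beads, D = 16, 0.01
        spec = ct.RouseChainSpec(n_beads=n_beads, neighbor_spring=4.0, bead_diffusion=D)
        cfg = ct.SimulationConfig(
            seed=12, n_trajectories=100, n_frames=60, frame_interval=5.0
        )
        ens = ct.simulate_rouse_chain(spec, cfg)
        by = {(t.cell_id, t.locus_id): t for t in ens}
        com = []
        for rep in range(cfg.n_trajectories):
            cid = f"cell{rep:04d}"
            pos = np.mean(
                [by[(cid, f"bead{i:02d}")].positions for i in range(n_beads)], axis=0
            )
            com.append(
                ct.LocusTrajectory(
                    cell_id=cid, locus_id="COM", times=cfg.times(), positions=pos
                )
            )
        curve = ct.compute_eamsd(ct.TrajectoryEnsemble(com), 10)
        slope = np.sum(curve.lags * curve.values) / np.sum(curve.lags**2)
        assert slope / 4 == pytest.approx(D / n_beads, rel=0.1)

    def test_free_chain_interbead_scaling_is_ideal(self):
        # Gaussian chain: mean inter-bead distance ∝ separation^0.5
        spec = ct.RouseChainSpec(n_beads=32, neighbor_spring=4.0, bead_diffusion=0.01)
        cfg = ct.SimulationConfig(
            seed=13, n_trajectories=100, n_frames=15, frame_interval=2.0
        )
        ens = ct.simulate_rouse_chain(spec, cfg)
        by = {(t.cell_id, t.locus_id): t for t in ens}
        points = []
        for m in range(1, 17):
            dists = []
            for rep in range(cfg.n_trajectories):
                cid = f"cell{rep:04d}"
                for i in range(0, 32 - m, 4):
                    s = ct.compute_pair_distance_series(
                        by[(cid, f"bead{i:02d}")], by[(cid, f"bead{i + m:02d}")], float(m)
                    )
                    dists.append(s.distances.mean())
            points.append((float(m), float(np.mean(dists))))
        fit = ct.fit_compaction(points)
        assert fit.delta == pytest.approx(0.5, abs=0.05)

    def test_genomic_metadata_and_labels(self):
        spec = ct.RouseChainSpec(
            n_beads=4,
            neighbor_spring=10.0,
            bead_diffusion=0.01,
            labeled_beads=[0, 3],
            genomic_spacing=2.5,
        )
        cfg = ct.SimulationConfig(seed=14, n_trajectories=2, n_frames=5)
        ens = ct.simulate_rouse_chain(spec, cfg)
        assert len(ens) == 4  # 2 replicates × 2 labelled beads
        assert {t.locus_id for t in ens} == {"bead00", "bead03"}
        assert {t.metadata["c_mb"] for t in ens} == {0.0, 7.5}


class TestLocalizationNoise:
    def test_zero_sigma_is_identity(self):
        cfg = ct.SimulationConfig(seed=15, n_trajectories=2, n_frames=10)
        ens = ct.simulate_brownian(0.01, cfg)
        out = ct.add_localization_noise(ens, 0.0, seed=99)
        for a, b in zip(ens, out):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_noise_floor_msd_is_4_sigma_squared(self):
        sigma = 0.05
        static = ct.simulate_brownian(
            0.0, ct.SimulationConfig(seed=16, n_trajectories=1, n_frames=10_000)
        )
        noisy = ct.add_localization_noise(static, sigma, seed=17)
        curve = ct.compute_tamsd(noisy[0], 10)
        np.testing.assert_allclose(curve.values, 4 * sigma**2, rtol=0.1)

    def test_noise_is_frame_independent(self):
        static = ct.simulate_brownian(
            0.0, ct.SimulationConfig(seed=18, n_trajectories=1, n_frames=20_000)
        )
        noisy = ct.add_localization_noise(static, 0.05, seed=19)
        offsets = noisy[0].positions[:, 0]
        rho = np.corrcoef(offsets[:-1], offsets[1:])[0, 1]
        assert abs(rho) < 0.02


class TestSimulateNucleus:
    def test_circle_half_radius(self):
        geom, loci = ct.simulate_nucleus(
            "c1", (0, 0), 10.0, 10.0, [("L1", 0.5, 0.7)]
        )
        assert np.hypot(*loci["L1"]) == pytest.approx(5.0)
        rec = ct.compute_nrd(loci["L1"], geom)
        assert rec.nrd == pytest.approx(0.5, abs=1e-9)

    def test_nrd_zero_is_centroid(self):
        geom, loci = ct.simulate_nucleus("c1", (2, 3), 10.0, 5.0, [("L", 0.0, 0.0)])
        np.testing.assert_allclose(loci["L"], [2, 3])

    def test_ellipse_major_axis_placement(self):
        geom, loci = ct.simulate_nucleus("c1", (0, 0), 10.0, 5.0, [("L", 0.8, 0.0)])
        np.testing.assert_allclose(loci["L"], [8.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("nrd", [-0.1, 1.2])
    def test_target_nrd_out_of_range(self, nrd):
        with pytest.raises(ValueError, match="NRD"):
            ct.simulate_nucleus("c1", (0, 0), 10.0, 5.0, [("L", nrd, 0.0)])

    def test_placement_exact_for_many_targets(self):
        placements = [(f"L{i}", i / 10, 0.6 * i) for i in range(11)]
        geom, loci = ct.simulate_nucleus("c1", (1, -2), 12.0, 7.0, placements, theta=0.4)
        for locus_id, target, _ in placements:
            rec = ct.compute_nrd(loci[locus_id], geom)
            assert rec.nrd == pytest.approx(target, abs=1e-9)


class TestPairDistanceGenerator:
    def test_noiseless_distances_follow_power_law_exactly(self):
        series = ct.generate_pair_distances(
            delta=0.2, prefactor=0.4, genomic_distances=[29.0],
            cell_sd=0.0, temporal_sd=0.0, n_cells=3, n_frames=5, seed=0,
        )
        expected = 0.4 * 29.0**0.2
        assert expected == pytest.approx(0.7844, abs=5e-4)
        for s in series:
            np.testing.assert_allclose(s.distances, expected)

    def test_structure_one_series_per_cell_and_pair(self):
        series = ct.generate_pair_distances(
            delta=0.3, prefactor=0.4, genomic_distances=[2.0, 5.0],
            cell_sd=0.1, temporal_sd=0.05, n_cells=4, n_frames=10, seed=1,
        )
        assert len(series) == 8
        assert all(s.n_frames == 10 for s in series)
        assert all(np.all(s.distances > 0) for s in series)


@pytest.mark.parametrize(
    "factory",
    [
        lambda seed: ct.simulate_brownian(
            0.01, ct.SimulationConfig(seed=seed, n_trajectories=3, n_frames=20)
        ),
        lambda seed: ct.simulate_ou(
            50.0, 0.01, ct.SimulationConfig(seed=seed, n_trajectories=3, n_frames=20)
        ),
        lambda seed: ct.simulate_fbm(
            0.4, 0.01, ct.SimulationConfig(seed=seed, n_trajectories=3, n_frames=20)
        ),
        lambda seed: ct.simulate_rouse_chain(
            ct.RouseChainSpec(n_beads=4, neighbor_spring=10.0, bead_diffusion=0.01),
            ct.SimulationConfig(seed=seed, n_trajectories=2, n_frames=5),
        ),
    ],
    ids=["brownian", "ou", "fbm", "rouse"],
)
def test_generators_are_bit_reproducible(factory):
    a = factory(42)
    b = factory(42)
    c = factory(43)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.positions, tb.positions)
    assert any(
        not np.array_equal(ta.positions, tc.positions) for ta, tc in zip(a, c)
    )
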