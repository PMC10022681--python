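"""Pair distances, compaction scaling, variation split, nuclear radiality."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import chromotrace as ct
from chromotrace.organization import LocusPairSeries

from conftest import make_trajectory, rigid_motion


def pair_series(distances, cell_id="c1", s_mb=1.0):
    d = np.asarray(distances, dtype=float)
    return LocusPairSeries(
        cell_id=cell_id, locus_a="A", locus_b="B", s_mb=s_mb,
        times=np.arange(len(d), dtype=float), distances=d,
    )


class TestPairDistanceSeries:
    def test_static_3_4_5(self):
        a = make_trajectory(np.tile([0.0, 0.0], (10, 1)), locus_id="A")
        b = make_trajectory(np.tile([3.0, 4.0], (10, 1)), locus_id="B")
        series = ct.compute_pair_distance_series(a, b, s_mb=2.0)
        np.testing.assert_allclose(series.distances, 5.0)
        assert series.pair == "A/B"

    def test_identical_trajectories_give_zero(self):
        pos = np.random.default_rng(0).normal(size=(20, 2))
        a = make_trajectory(pos, locus_id="A")
        b = make_trajectory(pos, locus_id="B")
        assert np.all(ct.compute_pair_distance_series(a, b).distances == 0.0)

    def test_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(1)
        pa, pb = rng.normal(size=(30, 2)), rng.normal(size=(30, 2))
        base = ct.compute_pair_distance_series(
            make_trajectory(pa, locus_id="A"), make_trajectory(pb, locus_id="B")
        )
        moved = ct.compute_pair_distance_series(
            make_trajectory(rigid_motion(pa, 0.5, (3, 3)), locus_id="A"),
            make_trajectory(rigid_motion(pb, 0.5, (3, 3)), locus_id="B"),
        )
        np.testing.assert_allclose(base.distances, moved.distances, atol=1e-12)

    def test_cell_and_frame_mismatch_rejected(self):
        a = make_trajectory(np.zeros((5, 2)), cell_id="c1", locus_id="A")
        b = make_trajectory(np.zeros((5, 2)), cell_id="c2", locus_id="B")
        with pytest.raises(ValueError, match="one cell"):
            ct.compute_pair_distance_series(a, b)
        c = make_trajectory(np.zeros((7, 2)), cell_id="c1", locus_id="B")
        with pytest.raises(ValueError, match="frames"):
            ct.compute_pair_distance_series(a, c)


class TestMeanPairDistance:
    def test_constant_distance_any_window(self):
        summary = ct.mean_pair_distance([pair_series([0.5] * 40)], n_frames_avg=30)
        assert summary.mean == pytest.approx(0.5)
        assert summary.n_cells == 1

    def test_population_average_over_cells(self):
        series = [
            pair_series([0.4] * 30, cell_id="c1"),
            pair_series([0.6] * 30, cell_id="c2"),
        ]
        summary = ct.mean_pair_distance(series, n_frames_avg=30)
        assert summary.mean == pytest.approx(0.5)
        np.testing.assert_allclose(np.sort(summary.cell_means), [0.4, 0.6])

    def test_window_uses_only_first_frames(self):
        d = np.concatenate([np.full(30, 0.5), np.full(10, 5.0)])
        summary = ct.mean_pair_distance([pair_series(d)], n_frames_avg=30)
        assert summary.mean == pytest.approx(0.5)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ct.mean_pair_distance([pair_series([0.5] * 10)], n_frames_avg=30)

    def test_generator_with_zero_temporal_sd_is_exact(self):
        series = ct.generate_pair_distances(
            delta=0.3, prefactor=0.4, genomic_distances=[2.0],
            cell_sd=0.2, temporal_sd=0.0, n_cells=5, n_frames=40, seed=2,
        )
        summary = ct.mean_pair_distance(series, n_frames_avg=30)
        for s, m in zip(series, summary.cell_means):
            assert m == pytest.approx(s.distances[0], abs=1e-12)


class TestCompactionFit:
    def test_exact_power_law_recovery(self):
        s = [1.93, 2.69, 4.62]
        pts = [(x, 0.4 * x**0.4) for x in s]
        fit = ct.fit_compaction(pts)
        assert fit.delta == pytest.approx(0.40, abs=1e-12)
        assert fit.prefactor == pytest.approx(0.4, rel=1e-12)

    def test_nested_span_subsets(self):
        # short-span pairs scale steeply, long-span pairs flatten
        pts = [(1.93, 0.52), (2.69, 0.60), (4.62, 0.73), (25.82, 0.80), (29.05, 0.82)]
        short = ct.fit_compaction(pts, max_span=5.0)
        full = ct.fit_compaction(pts)
        assert short.delta > full.delta
        assert len(short.points) == 3 and len(full.points) == 5

    def test_generator_round_trip_at_experiment_scale(self):
        s_values = [1.93, 2.69, 4.62, 25.82, 29.05]
        series = ct.generate_pair_distances(
            delta=0.20, prefactor=0.4, genomic_distances=s_values,
            cell_sd=0.08, temporal_sd=0.1, n_cells=40, n_frames=30, seed=3,
        )
        points = []
        for s in s_values:
            sub = [x for x in series if x.s_mb == s]
            points.append((s, ct.mean_pair_distance(sub, 30).mean))
        fit = ct.fit_compaction(points)
        assert fit.delta == pytest.approx(0.20, abs=0.03)

    def test_needs_two_distinct_separations(self):
        with pytest.raises(ValueError, match="distinct"):
            ct.fit_compaction([(2.0, 0.5), (2.0, 0.6)])


class TestVariationDecomposition:
    def test_identical_constant_series_has_no_variation(self):
        series = [pair_series([0.5] * 20, cell_id=f"c{i}") for i in range(4)]
        dec = ct.decompose_variation(series)
        assert dec.cell_to_cell_sd == 0.0
        assert dec.temporal_mean_abs == 0.0

    def test_recovers_generator_variances(self):
        cell_sd, temporal_sd = 0.3, 0.1
        series = ct.generate_pair_distances(
            delta=0.2, prefactor=0.6, genomic_distances=[25.0],
            cell_sd=cell_sd, temporal_sd=temporal_sd,
            n_cells=200, n_frames=60, seed=4,
        )
        dec = ct.decompose_variation(series)
        assert dec.cell_to_cell_sd == pytest.approx(cell_sd, rel=0.15)
        # Gaussian jitter: mean absolute deviation = sd·√(2/π)
        assert dec.temporal_mean_abs == pytest.approx(
            temporal_sd * np.sqrt(2 / np.pi), rel=0.10
        )

    def test_variances_add_for_additive_generator(self):
        series = ct.generate_pair_distances(
            delta=0.2, prefactor=0.6, genomic_distances=[25.0],
            cell_sd=0.25, temporal_sd=0.12, n_cells=200, n_frames=60, seed=5,
        )
        dec = ct.decompose_variation(series)
        pooled = np.concatenate([s.distances for s in series])
        total_var = pooled.var()
        assert total_var == pytest.approx(
            dec.cell_to_cell_sd**2 + dec.temporal_sd**2, rel=0.1
        )

    def test_temporal_deviation_ignores_per_cell_offset(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0.5, 0.05, size=30).clip(min=0.01)
        a = ct.decompose_variation(
            [pair_series(base, "c1"), pair_series(base + 0.4, "c2")]
        )
        np.testing.assert_allclose(
            a.temporal_deviations[:30], a.temporal_deviations[30:], atol=1e-12
        )

    def test_single_cell_has_undefined_cell_variation(self):
        dec = ct.decompose_variation([pair_series([0.4, 0.5, 0.6])])
        assert np.isnan(dec.cell_to_cell_sd)
        assert dec.temporal_mean_abs > 0


class TestNRD:
    def circle(self, r=10.0, cell_id="c"):
        return ct.NucleusGeometry(
            cell_id=cell_id, centroid=np.zeros(2),
            boundary=ct.Ellipse(center=[0, 0], a=r, b=r),
        )

    def test_circle_half_radius(self):
        rec = ct.compute_nrd((5.0, 0.0), self.circle())
        assert rec.nrd == pytest.approx(0.5, abs=1e-12)
        assert rec.rho == pytest.approx(10.0)

    def test_boundary_locus_is_one(self):
        rec = ct.compute_nrd((0.0, 10.0), self.circle())
        assert rec.nrd == pytest.approx(1.0, abs=1e-12)
        assert not rec.clipped

    def test_ellipse_along_major_axis(self):
        geom = ct.NucleusGeometry(
            cell_id="c", centroid=np.zeros(2),
            boundary=ct.Ellipse(center=[0, 0], a=10.0, b=5.0),
        )
        rec = ct.compute_nrd((4.0, 0.0), geom)
        assert rec.nrd == pytest.approx(0.4, abs=1e-12)

    def test_rotated_ellipse_closed_form(self):
        theta = 0.7
        geom = ct.NucleusGeometry(
            cell_id="c", centroid=np.array([2.0, -1.0]),
            boundary=ct.Ellipse(center=[2.0, -1.0], a=8.0, b=4.0, theta=theta),
        )
        # point along the rotated major axis at 60% of a
        u = np.array([np.cos(theta), np.sin(theta)])
        rec = ct.compute_nrd(np.array([2.0, -1.0]) + 0.6 * 8.0 * u, geom)
        assert rec.nrd == pytest.approx(0.6, abs=1e-12)

    def test_centroid_locus_is_zero(self):
        rec = ct.compute_nrd((0.0, 0.0), self.circle())
        assert rec.nrd == 0.0

    def test_marginal_overshoot_clipped_and_flagged(self):
        rec = ct.compute_nrd((10.3, 0.0), self.circle())
        assert rec.nrd == 1.0
        assert rec.clipped

    def test_large_overshoot_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            ct.compute_nrd((11.0, 0.0), self.circle())

    def test_polygon_256gon_matches_ellipse(self):
        a, b = 10.0, 5.0
        phi = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        poly = Polygon(np.column_stack([a * np.cos(phi), b * np.sin(phi)]))
        geom_poly = ct.NucleusGeometry(cell_id="c", centroid=np.zeros(2), boundary=poly)
        geom_ell = ct.NucleusGeometry(
            cell_id="c", centroid=np.zeros(2), boundary=ct.Ellipse([0, 0], a, b)
        )
        rng = np.random.default_rng(7)
        for _ in range(25):
            ang = rng.uniform(0, 2 * np.pi)
            frac = rng.uniform(0.05, 0.95)
            u = np.array([np.cos(ang), np.sin(ang)])
            rho_e = geom_ell.boundary_distance(u)
            p = frac * rho_e * u
            n_poly = ct.compute_nrd(p, geom_poly).nrd
            n_ell = ct.compute_nrd(p, geom_ell).nrd
            assert n_poly == pytest.approx(n_ell, abs=1e-3)

    def test_rigid_motion_invariance(self):
        ang, off = 0.9, np.array([4.0, -7.0])
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        geom1 = ct.NucleusGeometry(
            cell_id="c", centroid=np.zeros(2),
            boundary=ct.Ellipse([0, 0], 10.0, 5.0, theta=0.0),
        )
        geom2 = ct.NucleusGeometry(
            cell_id="c", centroid=off.copy(),
            boundary=ct.Ellipse(off, 10.0, 5.0, theta=ang),
        )
        p = np.array([3.0, 1.0])
        rec1 = ct.compute_nrd(p, geom1)
        rec2 = ct.compute_nrd(rot @ p + off, geom2)
        assert rec1.nrd == pytest.approx(rec2.nrd, abs=1e-12)


class TestNRDDistribution:
    def test_single_record_step_function(self):
        dist = ct.nrd_distribution(np.array([0.8]))
        assert dist.cdf(0.79) == 0.0
        assert dist.cdf(0.8) == 1.0
        assert dist.cdf(1.0) == 1.0

    def test_cdf_reaches_one_at_boundary(self):
        rng = np.random.default_rng(8)
        dist = ct.nrd_distribution(rng.uniform(0, 1, size=100))
        assert dist.cdf(1.0) == 1.0

    def test_uniform_values_within_dkw_band(self):
        n = 10_000
        rng = np.random.default_rng(9)
        dist = ct.nrd_distribution(rng.uniform(0, 1, size=n))
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))  # DKW at α = 0.01
        grid = np.linspace(0, 1, 501)
        assert np.max(np.abs(dist.cdf(grid) - grid)) < eps

    def test_histogram_bins_cover_unit_interval(self):
        dist = ct.nrd_distribution(np.array([0.05, 0.15, 0.95]), bin_width=0.1)
        assert len(dist.hist) == 10
        assert dist.hist.sum() == 3


class TestMobilityPositionCorrelation:
    def test_perfect_linear_relation(self):
        nrd = np.linspace(0.1, 0.9, 20)
        res = ct.correlate_mobility_position((nrd, 2 * nrd))
        assert res.r == pytest.approx(1.0)
        assert res.label == "moderate+"

    def test_independent_variables_negligible(self):
        rng = np.random.default_rng(10)
        res = ct.correlate_mobility_position(
            (rng.uniform(0, 1, 10_000), rng.normal(size=10_000))
        )
        assert abs(res.r) < 0.05
        assert res.label == "negligible"

    def test_three_point_brute_force_oracle(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([1.0, 2.0, 1.0])
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        res = ct.correlate_mobility_position((x, y))
        assert res.r == pytest.approx(expected, abs=1e-14)

    def test_strength_labels(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=5000)
        for target, label in [(0.1, "negligible"), (0.3, "weak"), (0.6, "moderate+")]:
            y = target * x + np.sqrt(1 - target**2) * rng.normal(size=5000)
            res = ct.correlate_mobility_position((x, y))
            assert res.label == label, res.r

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ct.correlate_mobility_position((np.ones(5), np.arange(5.0)))

    def test_records_interface(self):
        from chromotrace.organization import RadialityRecord

        recs = [
            RadialityRecord("c", "L", nrd=v, d=v, rho=1.0, d_eff=2 * v)
            for v in (0.1, 0.4, 0.8)
        ]
        assert ct.correlate_mobility_position(recs).r == pytest.approx(1.0)
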