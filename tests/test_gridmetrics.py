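import numpy as np
import pytest

from gridcan.dynamics import ActivityTrace
from gridcan.trajectory import Arena, Trajectory
from gridcan.gridmetrics import (
    RateMap,
    compute_rate_map,
    detect_fields,
    grid_score,
    autocorrelogram,
    information_rate,
    sparsity,
    summarize_metrics,
    percent_change,
    diagonal_phase_profile,
)
from oracles import (
    brute_grid_score,
    brute_autocorrelogram,
    hexagonal_map,
    square_map,
)


def _gauss_bump(n_px, center, sigma, height=1.0):
    yy, xx = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    return height * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                           / (2 * sigma**2))


class TestRateMap:
    def test_constant_activity(self):
        arena = Arena(shape="square", extent=1.0)
        pos = np.array([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9], [0.5, 0.5]])
        traj = Trajectory(positions=pos, dt_sample=1e-3, arena=arena)
        trace = ActivityTrace(S=np.full((4, 1), 2.5), dt=1e-3)
        rm = compute_rate_map(trace, 0, traj, n_pixels=10, sigma_px=0)
        np.testing.assert_allclose(rm.values[rm.valid], 2.5)

    def test_occupancy_sums_to_one(self, circle_arena, short_trajectory):
        T = short_trajectory.n_samples
        trace = ActivityTrace(S=np.random.default_rng(0).random((T, 1)),
                              dt=1e-3)
        rm = compute_rate_map(trace, 0, short_trajectory, n_pixels=50)
        assert rm.occupancy.sum() == pytest.approx(1.0)

    def test_hand_computed_rates(self):
        arena = Arena(shape="square", extent=1.0)
        # two visits to one pixel (values 1 and 3), one to another (5)
        pos = np.array([[0.05, 0.05], [0.05, 0.05], [0.75, 0.75]])
        traj = Trajectory(positions=pos, dt_sample=1e-3, arena=arena)
        trace = ActivityTrace(S=np.array([[1.0], [3.0], [5.0]]), dt=1e-3)
        rm = compute_rate_map(trace, 0, traj, n_pixels=4, sigma_px=0)
        assert rm.values[0, 0] == pytest.approx(2.0)
        assert rm.values[3, 3] == pytest.approx(5.0)
        assert rm.occupancy[0, 0] == pytest.approx(2 / 3)

    def test_empty_trajectory_rejected(self, circle_arena):
        traj = Trajectory(positions=np.empty((0, 2)), dt_sample=1e-3,
                          arena=circle_arena)
        trace = ActivityTrace(S=np.empty((0, 1)), dt=1e-3)
        with pytest.raises(ValueError):
            compute_rate_map(trace, 0, traj)


class TestFieldDetection:
    def test_single_bump_single_field(self):
        m = _gauss_bump(40, (20, 20), 4.0)
        rm = RateMap.from_values(m, sigma_px=0)
        fs = detect_fields(rm)
        assert fs.n_fields == 1
        assert fs.labels[20, 20] == 0

    def test_two_separated_bumps(self):
        m = _gauss_bump(60, (15, 15), 3.0) + _gauss_bump(60, (45, 45), 3.0)
        fs = detect_fields(RateMap.from_values(m, sigma_px=0))
        assert fs.n_fields == 2

    def test_field_area_matches_threshold_contour(self):
        """A Gaussian bump's 20%-of-peak field covers the analytic disc
        area 2*pi*sigma^2*ln(5)."""
        sigma = 5.0
        m = _gauss_bump(80, (40, 40), sigma)
        fs = detect_fields(RateMap.from_values(m, sigma_px=0))
        expected = 2 * np.pi * sigma**2 * np.log(5)
        assert fs.areas[0] == pytest.approx(expected, rel=0.10)

    def test_low_peaks_discarded(self):
        m = _gauss_bump(40, (20, 20), 3.0, height=0.05)
        fs = detect_fields(RateMap.from_values(m, sigma_px=0))
        assert fs.n_fields == 0

    @pytest.mark.parametrize("n_bumps", [3, 5])
    def test_planted_bumps_recovered(self, n_bumps):
        rng = np.random.default_rng(n_bumps)
        sigma = 2.5
        n_px = 70
        centers = []
        while len(centers) < n_bumps:
            c = rng.uniform(8, n_px - 8, 2)
            if all(np.hypot(*(c - p)) > 4 * sigma + 6 for p in centers):
                centers.append(c)
        m = sum(_gauss_bump(n_px, c, sigma) for c in centers)
        fs = detect_fields(RateMap.from_values(m, sigma_px=0))
        assert fs.n_fields == n_bumps


class TestGridScore:
    def test_hexagonal_lattice_scores_high(self):
        m, circ = hexagonal_map(spacing=15, n_px=60, phase=(4.0, 2.0))
        rm = RateMap.from_values(np.where(circ, m, np.nan), valid=circ)
        assert grid_score(rm) > 0.5

    def test_square_lattice_scores_nonpositive(self):
        m, circ = square_map(spacing=15, n_px=60, phase=(3.0, 5.0))
        rm = RateMap.from_values(np.where(circ, m, np.nan), valid=circ)
        assert grid_score(rm) <= 0.0

    def test_flat_map_scores_zero(self):
        rm = RateMap.from_values(np.ones((40, 40)))
        assert grid_score(rm) == 0.0

    def test_scale_invariance(self):
        m, circ = hexagonal_map(spacing=14, n_px=50, phase=(1.0, 7.0))
        rm1 = RateMap.from_values(np.where(circ, m, np.nan), valid=circ)
        rm2 = RateMap.from_values(np.where(circ, 3.7 * m, np.nan), valid=circ)
        assert grid_score(rm1) == pytest.approx(grid_score(rm2), abs=1e-9)

    def test_autocorrelogram_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        m = rng.random((20, 20))
        valid = rng.random((20, 20)) > 0.2
        ac = autocorrelogram(m, valid)
        ref = brute_autocorrelogram(m, valid)
        both = np.isfinite(ac) & np.isfinite(ref)
        assert np.isnan(ac).sum() == np.isnan(ref).sum()
        np.testing.assert_allclose(ac[both], ref[both], atol=1e-7)


class TestInformationAndSparsity:
    def test_uniform_map(self):
        rm = RateMap.from_values(np.full((20, 20), 3.0))
        assert information_rate(rm) == pytest.approx(0.0, abs=1e-12)
        assert sparsity(rm) == pytest.approx(1.0)

    def test_single_active_pixel(self):
        n = 10
        vals = np.zeros((n, n))
        vals[4, 7] = 2.0
        rm = RateMap.from_values(vals)
        N = n * n
        assert information_rate(rm) == pytest.approx((2.0 / N) * np.log2(N))
        assert sparsity(rm) == pytest.approx(1.0 / N)

    def test_info_rate_scales_linearly(self):
        rng = np.random.default_rng(1)
        vals = rng.random((15, 15))
        a = information_rate(RateMap.from_values(vals))
        b = information_rate(RateMap.from_values(2 * vals))
        assert b == pytest.approx(2 * a)

    def test_sparsity_scale_invariant_and_bounded(self):
        rng = np.random.default_rng(2)
        vals = rng.random((15, 15))
        s1 = sparsity(RateMap.from_values(vals))
        s2 = sparsity(RateMap.from_values(5 * vals))
        assert s1 == pytest.approx(s2)
        assert 0 < s1 <= 1


class TestSummarize:
    def test_two_peak_spacing(self):
        m = _gauss_bump(60, (10, 10), 3.0) + _gauss_bump(60, (10, 40), 3.0)
        met = summarize_metrics(RateMap.from_values(m, sigma_px=0))
        assert met.avg_spacing == pytest.approx(30.0, abs=1.0)
        assert met.n_fields == 2

    def test_three_collinear_peaks_all_pairs(self):
        m = sum(_gauss_bump(80, (40, c), 2.5) for c in (15, 40, 65))
        met = summarize_metrics(RateMap.from_values(m, sigma_px=0))
        # pairwise distances d, d, 2d -> mean 4d/3
        assert met.avg_spacing == pytest.approx(4 * 25 / 3, abs=1.0)

    def test_nearest_neighbor_mode(self):
        m = sum(_gauss_bump(80, (40, c), 2.5) for c in (15, 40, 65))
        met = summarize_metrics(RateMap.from_values(m, sigma_px=0),
                                spacing_mode="nearest_neighbor")
        assert met.avg_spacing == pytest.approx(25.0, abs=1.0)

    def test_no_fields(self):
        met = summarize_metrics(RateMap.from_values(np.zeros((30, 30))))
        assert met.n_fields == 0
        assert met.mean_field_size == 0.0
        assert np.isnan(met.avg_spacing)


class TestPercentChange:
    def test_identity(self):
        assert percent_change(2.0, 2.0) == 0.0

    def test_total_loss(self):
        assert percent_change(0.0, 1.3) == pytest.approx(-100.0)

    def test_zero_reference_undefined(self):
        assert np.isnan(percent_change(1.0, 0.0))

    def test_vectorized_matches_loop(self):
        rng = np.random.default_rng(3)
        het = rng.normal(size=3600)
        homo = rng.normal(size=3600)
        homo[5] = 0.0
        vec = percent_change(het, homo)
        for i in range(0, 3600, 97):
            if homo[i] == 0:
                assert np.isnan(vec[i])
            else:
                assert vec[i] == pytest.approx(
                    100 * (het[i] - homo[i]) / abs(homo[i]))


class TestDiagonalProfile:
    def test_constant_map(self):
        prof = diagonal_phase_profile(RateMap.from_values(np.ones((30, 30))))
        np.testing.assert_allclose(prof[:, 1], 0.0)

    def test_length(self):
        prof = diagonal_phase_profile(RateMap.from_values(np.ones((25, 25))))
        assert len(prof) == 25

    def test_sinusoid_gives_closed_orbit(self):
        """A sinusoidal diagonal profile yields an elliptical orbit:
        extreme derivatives at activity zero-crossings."""
        n = 64
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        m = np.sin(2 * np.pi * (xx + yy) / 32.0)
        prof = diagonal_phase_profile(RateMap.from_values(m, sigma_px=0))
        act, der = prof[5:-5, 0], prof[5:-5, 1]
        i_max_der = np.argmax(np.abs(der))
        assert abs(act[i_max_der]) < 0.2 * np.abs(act).max()
        # orbit is closed: normalized (act, der) stay on an ellipse
        r = (act / np.abs(act).max()) ** 2 + (der / np.abs(der).max()) ** 2
        np.testing.assert_allclose(r, 1.0, atol=0.05)


def test_grid_score_equals_bruteforce_on_random_maps():
    """Pipeline grid score equals an independently coded brute-force
    rotation-correlation implementation."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        n_px = 24
        kind = trial % 3
        if kind == 0:
            m, circ = hexagonal_map(spacing=rng.uniform(7, 11), n_px=n_px,
                                    phase=tuple(rng.uniform(0, 8, 2)))
        elif kind == 1:
            m, circ = square_map(spacing=rng.uniform(7, 11), n_px=n_px,
                                 phase=tuple(rng.uniform(0, 8, 2)))
        else:
            m = rng.random((n_px, n_px))
            yy, xx = np.meshgrid(np.arange(n_px), np.arange(n_px),
                                 indexing="ij")
            circ = (yy - n_px / 2) ** 2 + (xx - n_px / 2) ** 2 <= (n_px / 2) ** 2
        rm = RateMap.from_values(np.where(circ, m, np.nan), valid=circ,
                                 sigma_px=0)
        ours = grid_score(rm)
        ref = brute_grid_score(np.where(circ, m, 0.0), circ)
        assert ours == pytest.approx(ref, abs=1e-6)
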