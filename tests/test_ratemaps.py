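"""Rate-map construction, information integral, optimizer, target sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

from fluoinfo import ratemaps as rm


def random_spline_map(seed, scale=1.0):
    rng = np.random.default_rng(seed)
    xs = np.concatenate(([0.0], np.sort(rng.uniform(0.1, 0.9, 3)), [1.0]))
    ys = scale * rng.standard_normal(5)
    return rm.RateMap(
        kind="spline",
        nodes=np.column_stack([xs, ys]),
        mean_rate=1.0,
        achieved_info_ap=np.nan,
        target_info_ap=np.nan,
    )


class TestEvaluate:
    def test_constant_log_rate_gives_uniform_profile(self):
        m = random_spline_map(0)
        m.nodes[:, 1] = 0.7  # any constant log rate
        vals = rm.evaluate_ratemap(m, np.linspace(0, 1, 101))
        assert np.allclose(vals, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_profile_integrates_to_one(self, seed):
        m = random_spline_map(seed, scale=2.0)
        grid = np.linspace(0, 1, 100_001)
        integral = np.trapezoid(rm.evaluate_ratemap(m, grid), grid)
        assert integral == pytest.approx(1.0, abs=1e-6)
        assert np.all(rm.evaluate_ratemap(m, grid) > 0)

    def test_matches_independent_dense_spline_oracle(self):
        # Re-evaluate with an independently constructed spline on a 10x
        # denser grid and trapezoid normalization.
        m = random_spline_map(5, scale=1.5)
        dense = np.linspace(0, 1, 100_001)
        s = CubicSpline(m.nodes[:, 0], m.nodes[:, 1], bc_type="natural")
        prof = np.exp(s(dense))
        oracle = prof / np.trapezoid(prof, dense)
        x = np.linspace(0, 1, 257)
        got = rm.evaluate_ratemap(m, x)
        want = np.interp(x, dense, oracle)
        assert np.allclose(got, want, rtol=1e-6, atol=1e-6)

    def test_non_increasing_nodes_rejected(self):
        m = random_spline_map(6)
        m.nodes[2, 0] = m.nodes[1, 0]  # duplicate x
        with pytest.raises(ValueError):
            rm.evaluate_ratemap(m, np.array([0.5]))


class TestInformation:
    def test_uniform_profile_carries_zero_bits(self):
        m = random_spline_map(0)
        m.nodes[:, 1] = -1.3
        assert rm.differential_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_single_occupied_sliver_matches_log2(self):
        # All rate concentrated on a 1/60 span: I = log2(60) by direct
        # evaluation of the information integral.
        grid = np.linspace(0, 1, rm.GRID_SIZE)
        p = np.where(grid < 1.0 / 60.0, 60.0, 0.0)
        p /= np.trapezoid(p, grid)
        info = rm._information_of_profile(p)
        assert info == pytest.approx(np.log2(60.0), rel=2e-3)

    def test_matches_monte_carlo_oracle(self):
        m = random_spline_map(7, scale=2.0)
        info = rm.differential_information(m)
        rng = np.random.default_rng(123)
        x = rng.uniform(0, 1, 1_000_000)
        p = rm.evaluate_ratemap(m, x)
        samples = np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
        mc = samples.mean()
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(info - mc) < 3 * se

    def test_information_ignores_mean_rate(self):
        m = random_spline_map(8, scale=1.5)
        i1 = rm.differential_information(m)
        m.mean_rate = 17.0
        assert rm.differential_information(m) == i1


class TestOptimizer:
    @pytest.mark.parametrize("target", [0.0, 0.3, 2.0, 5.0, 6.0])
    def test_hits_target(self, target):
        m = rm.optimize_ratemap(target, seed=3)
        assert abs(m.achieved_info_ap - target) <= 1e-9
        xs = m.nodes[1:4, 0]
        assert np.all(np.diff(xs) > 0) and xs.min() > 0 and xs.max() < 1

    def test_high_target_verified_by_monte_carlo(self):
        m = rm.optimize_ratemap(5.0, seed=11)
        rng = np.random.default_rng(99)
        x = rng.uniform(0, 1, 1_000_000)
        p = rm.evaluate_ratemap(m, x)
        samples = np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean() - 5.0) < 3 * se

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            rm.optimize_ratemap(6.5)


class TestSampler:
    def test_empty_and_negative(self):
        assert rm.sample_targets(0) == []
        with pytest.raises(ValueError):
            rm.sample_targets(-1)

    def test_bounds_and_decile_coverage(self):
        draws = rm.sample_targets(10_000, seed=42)
        i_ap = np.array([d.i_ap for d in draws])
        rate = np.array([d.mean_rate for d in draws])
        i_s = np.array([d.i_s for d in draws])
        assert np.all((i_ap >= 0) & (i_ap <= 6))
        assert np.all((rate >= 0.1) & (rate <= 30))
        assert np.all((i_s >= 0) & (i_s <= 24))
        assert np.allclose(i_s, rate * i_ap)
        counts, _ = np.histogram(i_ap, bins=10, range=(0, 6))
        assert counts.min() >= 100  # every decile holds >= 1% of draws


class TestGaussian:
    def test_zero_information_width(self):
        m = rm.gaussian_ratemap(0.0)
        assert m.sigma == pytest.approx(np.exp(-0.5) / np.sqrt(2 * np.pi), rel=1e-12)

    def test_width_decreases_with_information(self):
        sigmas = [rm.gaussian_ratemap(i).sigma for i in np.linspace(0, 5, 11)]
        assert np.all(np.diff(sigmas) < 0)

    def test_realized_information_near_target(self):
        m = rm.gaussian_ratemap(3.0)
        assert not m.truncation_warning
        assert rm.differential_information(m) == pytest.approx(3.0, abs=0.02)

    def test_truncation_flagged_at_low_information(self):
        # sigma ~ 0.24 at I=0: heavy mass outside the unit track
        assert rm.gaussian_ratemap(0.0).truncation_warning


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    ys=st.lists(st.floats(-3, 3), min_size=5, max_size=5),
    xs=st.lists(st.floats(0.05, 0.95), min_size=3, max_size=3, unique=True),
)
def test_information_nonnegative_for_arbitrary_splines(ys, xs):
    nodes = np.column_stack([np.concatenate(([0.0], np.sort(xs), [1.0])), ys])
    if np.min(np.diff(nodes[:, 0])) < 1e-3:
        return
    m = rm.RateMap("spline", 1.0, np.nan, np.nan, nodes=nodes)
    assert rm.differential_information(m) >= -1e-10


def test_library_csv_round_trip(tmp_path):
    maps = [rm.optimize_ratemap(1.5, seed=2), rm.gaussian_ratemap(2.0, mean_rate=3.0)]
    path = tmp_path / "lib.csv"
    rm.save_library(maps, path)
    loaded = rm.load_library(path)
    for a, b in zip(maps, loaded):
        x = np.linspace(0, 1, 101)
        assert np.allclose(a.profile(x), b.profile(x))
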