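"""SMGM, binned, and KSG estimators against oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoinfo import estimators as est
from fluoinfo import ratemaps as rm
from fluoinfo import spiketrain as spk
from tests.conftest import make_ramp_trace


def maps_from(p, a, units="hz"):
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    return est.SpatialMaps(p, a, np.ones(len(p), bool), units)


class TestSpatialMaps:
    def test_uniform_sweep_constant_activity(self):
        trace = make_ramp_trace(30.0, 600.0)
        frames = spk.FrameSeries(np.ones(18_000))
        maps = est.spatial_maps(frames, trace, None, source_units="dff")
        assert np.allclose(maps.occupancy, 1 / 60, atol=0.01)
        assert np.allclose(maps.activity, 1.0, atol=1e-9)

    def test_weighted_mean_consistency(self, ten_min_trace):
        rng = np.random.default_rng(0)
        frames = spk.FrameSeries(rng.poisson(0.2, int(ten_min_trace.duration * 30)))
        maps = est.spatial_maps(frames, ten_min_trace, None)
        direct = np.sum(maps.occupancy[maps.occupied] * maps.activity[maps.occupied])
        assert maps.overall_mean == pytest.approx(direct, abs=1e-10)

    def test_long_simulation_converges_to_ground_truth_profile(self, behavior_pool):
        from fluoinfo import experiments as ex

        m = rm.optimize_ratemap(1.2, seed=4)
        m.mean_rate = 8.0
        trace = ex._draw_session(behavior_pool, 30.0, np.random.default_rng(1))
        cif = spk.build_cif(m, trace)
        frames = spk.bin_to_frames(spk.generate_spikes(cif, seed=2))
        maps = est.spatial_maps(frames, trace, None)
        centers = (np.arange(60) + 0.5) / 60
        truth = m.profile(centers) * 8.0
        emp = maps.activity
        l1 = np.mean(np.abs(emp / emp.mean() - truth / truth.mean()))
        assert l1 < 0.1

    def test_degenerate_session_rejected(self):
        trace = make_ramp_trace(0.0001, 100.0)  # never leaves the first bin
        frames = spk.FrameSeries(np.ones(3000))
        with pytest.raises(ValueError):
            est.spatial_maps(frames, trace, None)


class TestSMGM:
    def test_flat_map_zero_information(self):
        maps = maps_from(np.full(60, 1 / 60), np.full(60, 3.0))
        assert est.smgm_bits_per_second(maps).value == pytest.approx(0.0, abs=1e-12)

    def test_single_active_bin_reaches_log2_n(self):
        a = np.zeros(60)
        a[17] = 60.0  # overall mean 1 Hz under uniform occupancy
        maps = maps_from(np.full(60, 1 / 60), a)
        assert est.smgm_bits_per_second(maps).value == pytest.approx(np.log2(60))
        assert est.smgm_bits_per_ap(maps).value == pytest.approx(np.log2(60))

    def test_two_bin_hand_computation(self):
        maps = maps_from([0.5, 0.5], [2.0, 0.0])
        assert est.smgm_bits_per_second(maps).value == pytest.approx(1.0)

    def test_per_ap_is_per_second_over_mean(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(60))
        a = rng.gamma(2.0, 1.5, 60)
        maps = maps_from(p, a)
        assert est.smgm_bits_per_ap(maps).value == pytest.approx(
            est.smgm_bits_per_second(maps).value / maps.overall_mean
        )

    def test_per_ap_invariant_to_activity_scale(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(60))
        a = rng.gamma(2.0, 1.5, 60)
        v1 = est.smgm_bits_per_ap(maps_from(p, a, "dff")).value
        v2 = est.smgm_bits_per_ap(maps_from(p, 7.3 * a, "dff")).value
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            est.smgm_bits_per_second(maps_from([0.5, 0.5], [0.0, 0.0]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_smgm_nonnegative_and_bounded(data):
    n = data.draw(st.integers(2, 60))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    p = rng.dirichlet(np.ones(n))
    a = rng.gamma(1.0, 2.0, n)
    if a.sum() == 0:
        return
    maps = maps_from(p, a)
    ap = est.smgm_bits_per_ap(maps).value
    assert est.smgm_bits_per_second(maps).value >= -1e-10
    assert -1e-10 <= ap <= np.log2(n) + 1e-10


class TestBinned:
    def _brute_force(self, joint):
        n = joint.sum()
        mi = 0.0
        for i in range(joint.shape[0]):
            for j in range(joint.shape[1]):
                if joint[i, j] > 0:
                    pij = joint[i, j] / n
                    mi += pij * np.log2(pij / (joint[i].sum() / n * joint[:, j].sum() / n))
        return mi

    def test_matches_brute_force_histogram_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 60, 5000)
        act = rng.normal(pos * 0.05, 1.0)
        got = est.binned_mi(act, pos, frame_rate=1.0).value
        # rebuild the same joint histogram independently
        edges = np.linspace(act.min(), act.max(), 11)
        lvl = np.clip(np.searchsorted(edges, act, side="left") - 1, 0, 9)
        joint = np.zeros((60, 10))
        np.add.at(joint, (pos, lvl), 1)
        assert got == pytest.approx(self._brute_force(joint), abs=1e-12)

    def test_shuffled_data_shows_plugin_bias(self):
        # independent activity: plug-in MI ~ Miller-Madow bias
        rng = np.random.default_rng(1)
        n = 60_000
        pos = rng.integers(0, 60, n)
        act = rng.normal(0, 1, n)
        got = est.binned_mi(act, pos, frame_rate=1.0).value
        expected_bias = (60 - 1) * (10 - 1) / (2 * n * np.log(2))
        assert got == pytest.approx(expected_bias, rel=0.35)

    def test_deterministic_activity_recovers_position_entropy(self):
        # activity = one distinct level per group of 6 position bins
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 60, 20_000)
        act = (pos // 6).astype(float)
        got = est.binned_mi(act, pos, activity_bins=10, frame_rate=1.0).value
        # MI = entropy of the 10 distinguishable levels
        counts = np.bincount(pos // 6, minlength=10) / len(pos)
        entropy = -np.sum(counts[counts > 0] * np.log2(counts[counts > 0]))
        assert got == pytest.approx(entropy, abs=0.01)

    def test_constant_activity_defined_as_zero(self):
        assert est.binned_mi(np.ones(100), np.arange(100) % 60, frame_rate=1.0).value == 0.0

    def test_occupancy_scheme_balances_counts(self):
        rng = np.random.default_rng(3)
        act = rng.exponential(1.0, 9000)
        pos = rng.integers(0, 60, 9000)
        v = est.binned_mi(act, pos, scheme="occupancy", frame_rate=30.0)
        assert np.isfinite(v.value) and v.units == "bits_per_sec"


class TestKSG:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 2000))
        mi = est.ksg_mi(x, y).value
        assert abs(mi) < 0.05

    def test_recovers_gaussian_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        cov = [[1, rho], [rho, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=5000).T
        mi = est.ksg_mi(x, y).value
        expected = -0.5 * np.log2(1 - rho**2)
        assert mi == pytest.approx(expected, abs=0.05)

    def test_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=3000)
        y = x + rng.normal(scale=0.5, size=3000)
        base = est.ksg_mi(x, y, jitter=None).value
        warped = est.ksg_mi(np.exp(x), y**3, jitter=None).value
        assert warped == pytest.approx(base, abs=0.1)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            est.ksg_mi(np.arange(4.0), np.arange(4.0), k=5)


class TestAnalytic:
    def test_zero_width_kernel_is_lossless_per_ap(self):
        v = est.analytic_approximations(2.7, tau=0.0, which="per_ap")
        assert v.value == pytest.approx(2.7, abs=1e-12)

    def test_information_decreases_with_kernel_tau(self):
        taus = np.linspace(0.0, 2.0, 21)
        vals = [est.analytic_approximations(3.0, tau=t, which="per_ap").value for t in taus]
        assert np.all(np.diff(vals) < 0)

    def test_per_second_prefactor_vanishes_at_zero_tau(self):
        v = est.analytic_approximations(3.0, mean_rate=2.0, tau=0.0, which="per_sec")
        assert v.value == 0.0
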