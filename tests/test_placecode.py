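"""Transient detection, place fields, Bayesian decoding, quantile splits."""

import numpy as np
import pytest

import fluoinfo as fi
from fluoinfo import behavior as bhv
from fluoinfo import fluorescence as fluo
from fluoinfo import placecode as pc
from fluoinfo import spiketrain as spk


@pytest.fixture(scope="module")
def gcamp6f():
    return fluo.get_kernel("gCaMP6f")


def simulate_dff(i_ap, rate, trace, kernel, seed):
    rng = np.random.default_rng(seed)
    m = fi.optimize_ratemap(i_ap, seed=rng)
    m.mean_rate = rate
    cif = spk.build_cif(m, trace)
    train = spk.generate_spikes(cif, seed=rng)
    return m, fluo.synth_fluorescence(train, kernel, seed=rng)


class TestTransients:
    def test_pure_noise_stays_below_false_positive_target(self):
        rng = np.random.default_rng(0)
        trace = spk.FrameSeries(rng.normal(0, 0.15, 40_000))
        tm = pc.detect_transients(trace, noise_sd_estimate=0.15)
        assert tm.mask.mean() <= 1e-4

    def test_all_zero_trace_gives_empty_mask(self):
        tm = pc.detect_transients(spk.FrameSeries(np.zeros(2000)))
        assert not tm.mask.any()

    def test_injected_transients_are_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.15, 30_000)
        starts = rng.integers(0, 29_000, 30)
        for s in starts:
            x[s : s + 30] += 0.15 * 5.0 * np.exp(-np.arange(30) / 10)
        tm = pc.detect_transients(spk.FrameSeries(x), noise_sd_estimate=0.15)
        hit = sum(tm.mask[s : s + 30].any() for s in starts)
        assert hit >= 25

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            pc.detect_transients(spk.FrameSeries(np.zeros(100)))


class TestPlaceFields:
    def test_field_neuron_yields_one_valid_field(self, ten_min_trace, gcamp6f):
        # ~40-cm firing field; the recovered field must satisfy the width rule
        _, dff = simulate_dff(2.0, 2.0, ten_min_trace, gcamp6f, seed=2)
        tm = pc.detect_transients(dff, noise_sd_estimate=0.15)
        mask = bhv.run_mask(ten_min_trace)
        fields = pc.find_place_fields(dff, ten_min_trace, tm, mask, n_boot=200, seed=3)
        assert len(fields) >= 1
        for f in fields:
            assert 20.0 <= f.width <= 120.0

    def test_narrow_candidate_rejected_by_width_rule(self):
        f = pc.PlaceField(10, 11)  # 2 bins = 10 cm
        assert f.width == 10.0 and not (20.0 <= f.width <= 120.0)

    def test_null_neurons_rarely_pass(self, ten_min_trace, gcamp6f):
        # spatially untuned neurons should almost never show a field
        hits = 0
        for seed in range(5):
            _, dff = simulate_dff(0.0, 2.0, ten_min_trace, gcamp6f, seed=10 + seed)
            tm = pc.detect_transients(dff, noise_sd_estimate=0.15)
            mask = bhv.run_mask(ten_min_trace)
            fields = pc.find_place_fields(
                dff, ten_min_trace, tm, mask, n_boot=150, seed=seed
            )
            hits += bool(fields)
        assert hits <= 1

    def test_no_transients_no_fields(self, ten_min_trace):
        dff = spk.FrameSeries(np.zeros(int(ten_min_trace.duration * 30)))
        tm = pc.TransientMask(np.zeros(len(dff.values), bool), [], 1e-4)
        assert pc.find_place_fields(dff, ten_min_trace, tm, None, n_boot=10) == []


class TestDecoder:
    def _population(self, trace, gcamp6f, n, seed0=100):
        pop = []
        for j in range(n):
            _, dff = simulate_dff(2.5, 3.0, trace, gcamp6f, seed=seed0 + j)
            tm = pc.detect_transients(dff, noise_sd_estimate=0.15)
            pop.append(spk.FrameSeries(tm.mask.astype(float), dff.frame_rate))
        return pop

    def test_delta_tuned_neuron_decodes_its_bin(self, ramp_trace):
        trace = ramp_trace(30.0, 200.0)
        pos = np.interp(
            (np.arange(int(200 * 30)) + 0.5) / 30, trace.timestamps, trace.position
        )
        bins = np.clip((pos / 3.0 * 60).astype(int), 0, 59)
        series = spk.FrameSeries((bins == 30).astype(float), 30.0)
        res = pc.bayes_decode([series], trace, window=0.1)
        active = [w for w in range(len(res.decoded_bin)) if res.truth_bin[w] == 30]
        assert active
        assert all(res.decoded_bin[w] == 30 for w in active)

    def test_flat_rates_fall_back_to_prior(self, ramp_trace):
        trace = ramp_trace(30.0, 100.0)
        series = spk.FrameSeries(np.zeros(3000), 30.0)
        res = pc.bayes_decode([series], trace, window=0.1)
        assert res.prior_fallback.all()

    def test_error_shrinks_with_population_size(self, ten_min_trace, gcamp6f):
        pop = self._population(ten_min_trace, gcamp6f, 12)
        errs = []
        for n in (2, 6, 12):
            res = pc.bayes_decode(pop[:n], ten_min_trace)
            errs.append(res.median_abs_error)
        assert errs[-1] <= errs[0]
        assert errs[-1] < 15.0  # a dozen tuned neurons localize well


class TestQuantiles:
    def test_equal_count_groups(self):
        import pandas as pd

        df = pd.DataFrame({"m": np.arange(9.0)})
        parts = pc.quantile_split(df, "m", 3)
        assert [len(p) for p in parts] == [3, 3, 3]
        assert parts[0].m.max() < parts[1].m.min() < parts[2].m.min()

    def test_boundaries_match_independent_quantiles(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        df = pd.DataFrame({"m": rng.uniform(0, 1, 99)})
        parts = pc.quantile_split(df, "m", 3)
        q1, q2 = np.quantile(df.m, [1 / 3, 2 / 3])
        assert parts[0].m.max() <= q1 + 1e-12
        assert parts[1].m.max() <= q2 + 1e-12

    def test_monotone_relabeling_preserves_partition(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        df = pd.DataFrame({"m": rng.uniform(0.1, 5, 30)})
        df2 = df.assign(m=np.log(df.m))
        a = [p.index.tolist() for p in pc.quantile_split(df, "m", 3)]
        b = [p.index.tolist() for p in pc.quantile_split(df2, "m", 3)]
        assert a == b

    def test_too_few_neurons_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            pc.quantile_split(pd.DataFrame({"m": [1.0, 2.0]}), "m", 3)
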