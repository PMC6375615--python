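import math

import numpy as np
import pytest

from stochdea import (RTEHistogram, StabilityParams, bin_pool,
                      density_stability, estimators, fig2_style_pool,
                      interval_stability, shannon_entropy, stability_report,
                      weighted_stability)
from stochdea.distribution import RTEPool, derived_log_bounds
from stochdea.exceptions import ValidationError


def hist(mass: dict[int, float], n: int = 100) -> RTEHistogram:
    freqs = [0.0] * 22
    for idx, f in mass.items():
        freqs[idx] = f
    return RTEHistogram(freqs=tuple(freqs), n=n)


class TestBinning:
    def test_low_score_goes_to_first_interval(self):
        pool = RTEPool.from_records([
            dict(dmu="A", scenario="S", simulation=0, orientation="input",
                 rte=0.02, efficiency_class="inefficient"),
        ])
        h = bin_pool(pool)
        assert h.freqs[0] == 1.0 and h.nint == 1

    def test_weakly_efficient_goes_to_penultimate_bin(self):
        pool = RTEPool.from_records([
            dict(dmu="A", scenario="S", simulation=0, orientation="input",
                 rte=1.0, efficiency_class="weakly_efficient"),
        ])
        assert bin_pool(pool).freqs[20] == 1.0

    def test_efficient_goes_to_last_bin(self):
        pool = RTEPool.from_records([
            dict(dmu="A", scenario="S", simulation=0, orientation="input",
                 rte=1.0, efficiency_class="efficient"),
        ])
        assert bin_pool(pool).freqs[21] == 1.0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        pool = RTEPool.from_records([
            dict(dmu="A", scenario="S", simulation=i, orientation="input",
                 rte=r, efficiency_class="inefficient")
            for i, r in enumerate(rng.uniform(0, 0.999, 500))
        ])
        assert math.isclose(sum(bin_pool(pool).freqs), 1.0)

    def test_empty_pool_signalled(self):
        with pytest.raises(ValidationError):
            bin_pool(RTEPool.from_records([]))


class TestEstimators:
    def make_pool(self, scores, classes):
        return RTEPool.from_records([
            dict(dmu="A", scenario="S", simulation=i, orientation="input",
                 rte=r, efficiency_class=c)
            for i, (r, c) in enumerate(zip(scores, classes))
        ])

    def test_all_efficient_pool(self):
        pool = self.make_pool([1.0] * 4, ["efficient"] * 4)
        rep = estimators(pool)
        assert rep.p_efficient == 1.0 and rep.mean == 1.0 and rep.sd == 0.0

    def test_p_above_by_brute_force_count(self):
        pool = self.make_pool([0.2, 0.4, 0.6, 0.8], ["inefficient"] * 4)
        rep = estimators(pool)
        assert rep.p_above(0.75) == 0.25
        assert rep.p_range(0.4, 0.8) == 0.5  # half-open: 0.4, 0.6 in; 0.8 out

    def test_class_probabilities_partition(self):
        pool = self.make_pool(
            [1.0, 1.0, 0.5, 0.7],
            ["efficient", "weakly_efficient", "inefficient", "inefficient"],
        )
        rep = estimators(pool)
        assert rep.p_efficient + rep.p_weak + rep.p_inefficient == \
            pytest.approx(1.0)
        assert rep.p_weak == 0.25


class TestStability:
    def test_five_populated_intervals(self):
        # 5 populated bins out of 22: 100 - 100 * 4 / 21
        assert interval_stability(hist({0: .4, 3: .2, 7: .2, 9: .1, 21: .1})) \
            == pytest.approx(80.95, abs=5e-3)

    def test_single_interval_is_completely_stable(self):
        assert interval_stability(hist({5: 1.0})) == 100.0

    def test_all_intervals_populated_is_completely_unstable(self):
        assert interval_stability(hist({i: 1 / 22 for i in range(22)})) == 0.0

    def test_density_accumulation_inputs_and_value(self):
        # descending accumulation crosses 0.8 at 3 bins with mass 0.88
        h = hist({14: .40, 15: .28, 16: .20, 17: .07, 18: .05})
        denstab, acprob, nintprob = density_stability(h)
        assert acprob == pytest.approx(0.88)
        assert nintprob == 3
        expected = 100 * (math.log(88 / 3) - 1.2909) / (4.6051 - 1.2909)
        assert denstab == pytest.approx(expected)
        assert denstab == pytest.approx(63.0, abs=5e-3)

    def test_all_mass_in_one_interval_is_completely_stable(self):
        denstab, acprob, nintprob = density_stability(hist({10: 1.0}))
        assert (denstab, acprob, nintprob) == (100.0, 1.0, 1)

    def test_density_lower_anchor(self):
        # when the accumulation density ratio equals e^minln exactly the
        # indicator sits at its 0 anchor
        h = hist({14: .40, 15: .28, 16: .20, 17: .07, 18: .05})
        params = StabilityParams(minln=math.log(88 / 3), maxln=math.log(100))
        denstab, acprob, nintprob = density_stability(h, params)
        assert acprob * 100 / nintprob == pytest.approx(
            math.exp(params.minln))
        assert denstab == pytest.approx(0.0, abs=1e-9)

    def test_derived_log_bounds_used_when_requested(self):
        params = StabilityParams(prob=0.8, inttot=22, derive_log_bounds=True)
        assert params.minln == pytest.approx(math.log(100 * 0.8 / 22))
        assert params.maxln == pytest.approx(math.log(100))

    def test_weighted_combination_of_printed_components(self):
        assert weighted_stability(80.95, 63.13) == pytest.approx(72.04)
        assert weighted_stability(80.0, 60.0,
                                  StabilityParams(w_int=1.0, w_den=0.0)) == 80.0
        assert weighted_stability(80.0, 60.0,
                                  StabilityParams(w_int=0.0, w_den=0.0)) == 0.0

    def test_published_log_anchors_match_closed_forms(self):
        minln, maxln = derived_log_bounds(prob=0.8, inttot=22)
        assert minln == pytest.approx(1.2909, abs=2e-4)
        assert maxln == pytest.approx(4.6051, abs=2e-4)

    def test_indicators_depend_on_frequencies_not_positions(self):
        a = hist({2: .5, 7: .3, 19: .2})
        b = hist({0: .3, 4: .2, 21: .5})  # same multiset of frequencies
        assert interval_stability(a) == interval_stability(b)
        assert density_stability(a)[0] == pytest.approx(density_stability(b)[0])

    def test_merging_mass_never_decreases_interval_stability(self):
        spread = hist({i: .2 for i in range(5)})
        merged = hist({0: .6, 1: .4})
        assert interval_stability(merged) > interval_stability(spread)


class TestEntropy:
    def test_single_bin_has_zero_entropy(self):
        assert shannon_entropy(hist({3: 1.0}))[0] == 0.0

    def test_two_equal_bins_give_one_bit(self):
        assert shannon_entropy(hist({3: .5, 9: .5}))[0] == pytest.approx(1.0)

    def test_uniform_histogram_is_maximal(self):
        entropy, pct = shannon_entropy(hist({i: 1 / 22 for i in range(22)}))
        assert entropy == pytest.approx(math.log2(22), abs=1e-12)
        assert pct == pytest.approx(100.0, abs=1e-9)


class TestReport:
    def test_full_report_consistency(self):
        h = hist({14: .40, 15: .28, 16: .20, 17: .07, 18: .05})
        rep = stability_report(h)
        assert rep.nint == 5
        assert rep.stab == pytest.approx(
            0.5 * rep.intstab + 0.5 * rep.denstab)
        assert 0 <= rep.entropy_pct_of_max <= 100

    def test_report_matches_engineered_pool(self):
        shape = [0.0] * 22
        shape[14], shape[15], shape[16] = 0.40, 0.28, 0.20
        shape[17], shape[18] = 0.07, 0.05
        rep = stability_report(bin_pool(fig2_style_pool(shape, n=100)))
        assert (rep.nint, rep.nintprob) == (5, 3)
        assert rep.acprob == pytest.approx(0.88)
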