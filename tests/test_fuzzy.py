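import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stochdea import (ConstructScores, FuzzyConfig, FuzzyPartition,
                      InterpretationRange, adjust_range, compute_constructs,
                      default_rule_base, defuzzify, fuzzify,
                      interpret_dataset, interpret_value)
from stochdea.exceptions import (ConfigurationError, ResolutionError,
                                 ValidationError)
from stochdea.fuzzy import LABELS, PROFILES, interpretation_ranges


@pytest.fixture
def unit_partition():
    return FuzzyPartition(universe=(0.0, 1.0))


class TestPartition:
    def test_degenerate_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            FuzzyPartition(universe=(1.0, 1.0))

    def test_default_peaks_evenly_spaced(self, unit_partition):
        np.testing.assert_allclose(
            unit_partition.peaks, [0.0, 0.25, 0.5, 0.75, 1.0]
        )

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-0.5, max_value=1.5, allow_nan=False))
    def test_partition_of_unity_with_at_most_two_active_sets(self, x):
        m = fuzzify(x, FuzzyPartition(universe=(0.0, 1.0)))
        assert abs(m.sum() - 1.0) < 1e-12
        assert np.count_nonzero(m) <= 2
        assert (m >= 0).all()

    def test_partition_of_unity_dense_scan(self, unit_partition):
        # the invariant holds across the whole universe, scanned finely
        xs = np.linspace(0.0, 1.0, 10_000)
        ms = np.array([fuzzify(x, unit_partition) for x in xs])
        np.testing.assert_allclose(ms.sum(axis=1), 1.0, atol=1e-12)
        assert (np.count_nonzero(ms, axis=1) <= 2).all()


class TestFuzzifyDefuzzify:
    def test_peak_membership_is_crisp(self, unit_partition):
        np.testing.assert_allclose(fuzzify(0.5, unit_partition),
                                   [0, 0, 1, 0, 0])

    def test_midpoint_between_peaks_splits_evenly(self, unit_partition):
        # halfway between the "little" and "standard" peaks
        np.testing.assert_allclose(fuzzify(0.375, unit_partition),
                                   [0, 0.5, 0.5, 0, 0])

    def test_below_universe_clamps_to_first_shoulder(self, unit_partition):
        np.testing.assert_allclose(fuzzify(-3.0, unit_partition),
                                   [1, 0, 0, 0, 0])

    def test_single_set_defuzzifies_to_its_peak(self, unit_partition):
        assert defuzzify([0, 0, 1, 0, 0], unit_partition) == 0.5

    def test_two_equal_memberships_give_peak_midpoint(self, unit_partition):
        assert defuzzify([0, 0.5, 0.5, 0, 0], unit_partition) == pytest.approx(
            0.375
        )

    def test_all_zero_memberships_signalled(self, unit_partition):
        with pytest.raises(ValidationError):
            defuzzify([0, 0, 0, 0, 0], unit_partition)

    def test_reconstruction_between_interior_peaks(self, unit_partition):
        # defuzzify(fuzzify(x)) = x wherever two interior sets share x
        for x in np.linspace(0.25, 0.75, 501):
            out = defuzzify(fuzzify(x, unit_partition), unit_partition)
            assert out == pytest.approx(x, abs=1e-12)


class TestConstructs:
    NORMS = {"d1": (0.0, 10.0), "d2": (0.0, 20.0), "o1": (0.0, 5.0)}

    def score(self, row):
        return compute_constructs(row, ("d1", "d2"), ("o1",), self.NORMS)

    def test_maximal_provision_scores_100(self):
        s = self.score({"d1": 10.0, "d2": 20.0, "o1": 5.0})
        assert s.D == pytest.approx(100.0) and s.O == pytest.approx(100.0)

    def test_no_provision_scores_0(self):
        s = self.score({"d1": 0.0, "d2": 0.0, "o1": 0.0})
        assert s.D == 0.0 and s.O == 0.0

    def test_monotone_in_each_provision_variable(self):
        base = {"d1": 2.0, "d2": 5.0, "o1": 1.0}
        prev = self.score(base).D
        for d1 in np.linspace(2.0, 10.0, 20):
            cur = self.score({**base, "d1": d1}).D
            assert cur >= prev - 1e-12
            prev = cur

    def test_missing_variable_is_resolution_error(self):
        with pytest.raises(ResolutionError):
            self.score({"d1": 1.0, "o1": 1.0})

    def test_scores_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            ConstructScores(D=101.0, O=0.0)


class TestRangeAdjustment:
    LEFT = FuzzyPartition(universe=(0.0, 2.0))

    def test_scarce_provision_displaces_range_right(self):
        # "IF O is very little and D is little THEN the floor is much":
        # scarce day/outpatient care raises the residential floor
        base = InterpretationRange(x_left=0.9753, x_right=1.0979, variable="TR12")
        out = adjust_range(base, ConstructScores(D=25.0, O=0.0),
                           default_rule_base(), self.LEFT)
        assert out.x_left > base.x_left
        assert out.width == base.width  # exact

    def test_width_preserved_exactly_for_any_scores(self):
        base = InterpretationRange(x_left=0.9753, x_right=1.0979)
        rules = default_rule_base()
        for d in np.linspace(0, 100, 11):
            for o in np.linspace(0, 100, 11):
                out = adjust_range(base, ConstructScores(D=d, O=o), rules,
                                   self.LEFT)
                assert out.width == base.width

    def test_fixed_point_when_consequent_matches_base(self):
        # abundant D and O fire only "very little" -> new floor at 0.0;
        # a base already at that floor is unchanged
        base = InterpretationRange(x_left=0.0, x_right=0.5)
        out = adjust_range(base, ConstructScores(D=100.0, O=100.0),
                           default_rule_base(), self.LEFT)
        assert out.x_left == pytest.approx(0.0) and out.x_right == \
            pytest.approx(0.5)

    def test_no_firing_rules_falls_back_to_base(self):
        base = InterpretationRange(x_left=0.2, x_right=0.4)
        out = adjust_range(base, ConstructScores(D=50.0, O=50.0), [], self.LEFT)
        assert out is base

    def test_rule_base_is_monotone_in_scarcity(self):
        # lower provision never lowers the displaced floor
        base = InterpretationRange(x_left=0.0, x_right=0.1)
        rules = default_rule_base()
        floors = [
            adjust_range(base, ConstructScores(D=v, O=v), rules, self.LEFT).x_left
            for v in np.linspace(100, 0, 21)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(floors, floors[1:]))


class TestValueInterpretation:
    RANGE = InterpretationRange(x_left=0.9753, x_right=1.0979, variable="TR12")

    def test_width_minus_value_profile_reproduces_published_transform(self):
        # x_int = (x_right - x_left) - x with the TR12 appropriateness range
        out = interpret_value(0.9753, self.RANGE, "width_minus_value")
        assert out == pytest.approx((1.0979 - 0.9753) - 0.9753)
        assert out == pytest.approx(-0.8527, abs=5e-5)

    def test_identity_profile_passes_through(self):
        assert interpret_value(1.03, self.RANGE, "identity") == 1.03

    def test_tent_profile_peaks_at_range_centre(self):
        c = 0.5 * (self.RANGE.x_left + self.RANGE.x_right)
        w = self.RANGE.width
        assert interpret_value(c, self.RANGE, "centred_tent") == pytest.approx(
            w / 2
        )
        assert interpret_value(self.RANGE.x_left, self.RANGE,
                               "centred_tent") == pytest.approx(0.0)

    @pytest.mark.parametrize("name", sorted(PROFILES))
    def test_profiles_monotone_within_each_piece(self, name):
        profile = PROFILES[name]
        breaks, _ = profile.pieces(self.RANGE)
        edges = [self.RANGE.x_left - 0.5, *breaks, self.RANGE.x_right + 0.5]
        for lo, hi in zip(edges, edges[1:]):
            xs = np.linspace(lo + 1e-9, hi - 1e-9, 50)
            ys = [interpret_value(x, self.RANGE, name) for x in xs]
            diffs = np.diff(ys)
            assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            interpret_value(1.0, self.RANGE, "nope")


class TestDatasetInterpretation:
    def test_identity_profiles_leave_matrix_unchanged(self, eco):
        cfg = FuzzyConfig.default_for(eco)
        profiles = {name: "identity" for name in cfg.profiles}
        ranges = {
            dmu: interpretation_ranges(
                eco, cfg, dict(zip(eco.variable_names, eco.values[i]))
            )
            for i, dmu in enumerate(eco.dmu_names)
        }
        out = interpret_dataset(eco.values, eco, ranges, profiles)
        np.testing.assert_array_equal(out, eco.values)

    def test_non_interpreted_columns_pass_through(self, eco):
        cfg = FuzzyConfig.default_for(eco)
        ranges = {
            dmu: interpretation_ranges(
                eco, cfg, dict(zip(eco.variable_names, eco.values[i]))
            )
            for i, dmu in enumerate(eco.dmu_names)
        }
        out = interpret_dataset(eco.values, eco, ranges, cfg.profiles)
        interpreted = set(cfg.profiles)
        for j, name in enumerate(eco.variable_names):
            if name not in interpreted:
                np.testing.assert_array_equal(out[:, j], eco.values[:, j])
        # interpreted residential columns do change
        assert any(
            not np.array_equal(out[:, eco.variable_index(n)],
                               eco.values[:, eco.variable_index(n)])
            for n in interpreted
        )

    def test_default_config_targets_residential_inputs_only(self, eco):
        cfg = FuzzyConfig.default_for(eco)
        for name in cfg.profiles:
            desc = eco.descriptor(name)
            assert desc.care_group == "R" and desc.role == "input"
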