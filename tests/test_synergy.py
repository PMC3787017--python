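"""Fixed-dose shift and fixed-ratio isobolographic analysis."""

import pytest
from _oracles import mc_additive_ci
from hypothesis import given
from hypothesis import strategies as st

from nocisyn import (
    DoseResponseFit,
    FixedRatioDesign,
    additive_ed50,
    additive_ed50_ci,
    analyze_fixed_ratio,
    fixed_dose_shift,
    fractional_multiplier,
    isobologram_verdict,
)

ATX = DoseResponseFit.from_interval(27.8, (22.0, 36.0), "atomoxetine")
MOR = DoseResponseFit.from_interval(2.3, (2.0, 2.5), "morphine")

ed50s = st.floats(min_value=0.1, max_value=100.0)
ratios = st.floats(min_value=0.01, max_value=100.0)


class TestFractionalMultiplier:
    def test_worked_example(self):
        assert fractional_multiplier(3, 27.8, 2.3) == pytest.approx(0.1988472622478386)

    def test_pure_drug_b(self):
        assert fractional_multiplier(0, 27.8, 2.3) == 0.0

    def test_pure_drug_a_limit(self):
        assert fractional_multiplier(1e12, 27.8, 2.3) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_nonpositive_ed50(self):
        with pytest.raises(ValueError):
            fractional_multiplier(3, 0.0, 2.3)


class TestAdditiveEd50:
    @pytest.mark.parametrize("ratio, expected", [(3, 7.4), (10, 13.8)])
    def test_atomoxetine_morphine_examples(self, ratio, expected):
        f = fractional_multiplier(ratio, 27.8, 2.3)
        assert round(additive_ed50(f, 27.8, 2.3), 1) == expected

    def test_equal_potency_identity(self):
        for f in (0.0, 0.3, 1.0):
            assert additive_ed50(f, 5.0, 5.0) == pytest.approx(5.0)

    def test_rejects_f_outside_unit_interval(self):
        with pytest.raises(ValueError):
            additive_ed50(1.2, 1.0, 1.0)

    @given(a=ed50s, b=ed50s, r=ratios)
    def test_bracketed_by_component_ed50s(self, a, b, r):
        z = additive_ed50(fractional_multiplier(r, a, b), a, b)
        assert min(a, b) - 1e-9 <= z <= max(a, b) + 1e-9

    @given(a=ed50s, b=ed50s)
    def test_monotone_in_ratio(self, a, b):
        grid = [0.01, 0.1, 1.0, 10.0, 100.0, 1e4]
        zs = [additive_ed50(fractional_multiplier(r, a, b), a, b) for r in grid]
        diffs = [z2 - z1 for z1, z2 in zip(zs, zs[1:])]
        # moves monotonically from ed50_b toward ed50_a as the mixture enriches in A
        assert all(d >= -1e-9 for d in diffs) or all(d <= 1e-9 for d in diffs)

    @given(a=ed50s, b=ed50s, r=ratios)
    def test_relabeling_invariance(self, a, b, r):
        z_ab = additive_ed50(fractional_multiplier(r, a, b), a, b)
        z_ba = additive_ed50(fractional_multiplier(1.0 / r, b, a), b, a)
        assert z_ab == pytest.approx(z_ba, rel=1e-9)


class TestAdditiveCi:
    def test_degenerate_components_give_point_interval(self):
        a = DoseResponseFit.from_interval(10.0, (10.0 - 1e-12, 10.0 + 1e-12))
        b = DoseResponseFit.from_interval(2.0, (2.0 - 1e-12, 2.0 + 1e-12))
        lo, hi = additive_ed50_ci(0.3, a, b)
        z = additive_ed50(0.3, 10.0, 2.0)
        assert lo == pytest.approx(z, abs=1e-9)
        assert hi == pytest.approx(z, abs=1e-9)

    def test_f_zero_reduces_to_drug_b_interval(self):
        lo, hi = additive_ed50_ci(0.0, ATX, MOR)
        # symmetric-SE interval around morphine's ED50 (mean half-width 0.25)
        assert lo == pytest.approx(2.3 - 0.25, abs=1e-9)
        assert hi == pytest.approx(2.3 + 0.25, abs=1e-9)

    def test_missing_component_ci_gives_none(self):
        no_ci = DoseResponseFit(
            drug_label="x", log_ed50=0.0, ed50=1.0, hill=1.0,
            ci95=None, n_points=4, converged=True,
        )
        assert additive_ed50_ci(0.5, no_ci, MOR) is None

    def test_matches_monte_carlo_oracle(self):
        f = fractional_multiplier(3, 27.8, 2.3)
        se_a = ((27.8 - 22.0) + (36.0 - 27.8)) / 2 / 1.96
        se_b = ((2.3 - 2.0) + (2.5 - 2.3)) / 2 / 1.96
        lo, hi = additive_ed50_ci(f, ATX, MOR)
        mc_lo, mc_hi = mc_additive_ci(f, 27.8, se_a, 2.3, se_b, seed=1)
        assert lo == pytest.approx(mc_lo, rel=0.02)
        assert hi == pytest.approx(mc_hi, rel=0.02)


class TestVerdicts:
    def test_printed_3to1_combination_is_synergistic(self):
        obs = DoseResponseFit.from_interval(2.4, (2.0, 3.0), "3:1 mixture")
        res = isobologram_verdict(obs, 7.4, (6.3, 8.2))
        assert res.verdict == "synergistic"
        assert res.interaction_index == pytest.approx(2.4 / 7.4)

    def test_printed_10to1_combination_is_synergistic(self):
        obs = DoseResponseFit.from_interval(7.8, (6.6, 9.2), "10:1 mixture")
        assert isobologram_verdict(obs, 13.8, (11.2, 17.8)).verdict == "synergistic"

    def test_overlapping_intervals_are_additive(self):
        obs = DoseResponseFit.from_interval(7.4, (6.3, 8.2))
        assert isobologram_verdict(obs, 7.4, (6.3, 8.2)).verdict == "additive"

    def test_touching_intervals_are_additive(self):
        obs = DoseResponseFit.from_interval(5.0, (4.0, 6.3))
        assert isobologram_verdict(obs, 7.4, (6.3, 8.2)).verdict == "additive"

    def test_observed_above_additive_is_antagonistic(self):
        obs = DoseResponseFit.from_interval(12.0, (9.0, 15.0))
        assert isobologram_verdict(obs, 7.4, (6.3, 8.2)).verdict == "antagonistic"

    def test_missing_ci_is_indeterminate(self):
        obs = DoseResponseFit.from_interval(2.4, (2.0, 3.0))
        assert isobologram_verdict(obs, 7.4, None).verdict == "indeterminate"


class TestFixedDoseShift:
    def test_atomoxetine_10_shifts_morphine_left(self):
        alone = DoseResponseFit.from_interval(2.3, (2.0, 2.5))
        combo = DoseResponseFit.from_interval(0.6, (0.4, 0.8))
        assert fixed_dose_shift(alone, combo) == "significant_leftward"

    def test_duloxetine_5_fails_to_shift_morphine(self):
        alone = DoseResponseFit.from_interval(2.3, (2.0, 2.5))
        combo = DoseResponseFit.from_interval(2.0, (1.3, 3.0))
        assert fixed_dose_shift(alone, combo) == "no_shift"

    def test_fit_against_itself_is_no_shift(self):
        assert fixed_dose_shift(MOR, MOR) == "no_shift"

    def test_rightward_shift_detected(self):
        alone = DoseResponseFit.from_interval(2.3, (2.0, 2.5))
        worse = DoseResponseFit.from_interval(5.0, (4.0, 6.0))
        assert fixed_dose_shift(alone, worse) == "significant_rightward"

    def test_missing_ci_is_indeterminate(self):
        no_ci = DoseResponseFit(
            drug_label="x", log_ed50=0.0, ed50=1.0, hill=1.0,
            ci95=None, n_points=4, converged=True,
        )
        assert fixed_dose_shift(MOR, no_ci) == "indeterminate"


class TestAnalyzeFixedRatio:
    def test_full_analysis_from_printed_fits(self):
        obs = DoseResponseFit.from_interval(2.4, (2.0, 3.0), "3:1 mixture")
        res = analyze_fixed_ratio(ATX, MOR, obs, ratio=3)
        assert round(res.z_add, 1) == 7.4
        assert res.verdict == "synergistic"
        assert res.design.f == pytest.approx(fractional_multiplier(3, 27.8, 2.3))

    def test_design_validates_ratio(self):
        with pytest.raises(ValueError):
            FixedRatioDesign("a", "b", ratio=0.0, ed50_a=ATX, ed50_b=MOR)
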