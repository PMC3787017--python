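"""Constrained variable-slope sigmoid fitting."""

import math

import numpy as np
import pytest
from _oracles import grid_search_ed50
from hypothesis import given, settings
from hypothesis import strategies as st

from nocisyn import (
    DoseResponseFit,
    GeneratorConfig,
    fit_ed50,
    fit_from_dataset,
    gen_single_drug,
    predict_inhibition,
)


class TestPredictInhibition:
    def test_midpoint_is_exactly_50(self):
        for hill in (0.5, 1.0, 3.7):
            assert predict_inhibition(10**0.7, 0.7, hill) == pytest.approx(50.0)

    def test_asymptotes(self):
        assert predict_inhibition(1e9, 0.0, 1.0) == pytest.approx(100.0, abs=1e-6)
        assert predict_inhibition(1e-9, 0.0, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_point(self):
        # ED50 = 1, hill = 1, dose 10: 100/(1 + 10^-1)
        assert predict_inhibition(10.0, 0.0, 1.0) == pytest.approx(1000.0 / 11.0)

    def test_rejects_nonpositive_dose_and_slope(self):
        with pytest.raises(ValueError):
            predict_inhibition(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            predict_inhibition(1.0, 0.0, -1.0)


def _exact_points(log_ed50, hill, doses=(0.3, 1.0, 3.0, 10.0), reps=2):
    d = np.repeat(doses, reps)
    return d, predict_inhibition(d, log_ed50, hill)


class TestFitEd50:
    def test_exact_data_recovery(self):
        true_log, true_hill = math.log10(2.3), 1.5
        d, y = _exact_points(true_log, true_hill)
        fit = fit_ed50(d, y)
        assert fit.converged
        assert fit.ed50 == pytest.approx(2.3, abs=1e-4)
        assert fit.hill == pytest.approx(1.5, abs=1e-4)
        # noise-free data: the CI collapses onto the estimate (or is dropped
        # as numerically degenerate)
        if fit.ci95 is not None:
            assert fit.ci95[0] < fit.ed50 < fit.ci95[1]

    def test_requires_three_distinct_doses(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_ed50([1, 1, 3, 3], [10, 20, 70, 80])

    def test_rejects_nonpositive_doses(self):
        with pytest.raises(ValueError):
            fit_ed50([0, 1, 3], [0, 50, 90])

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            true_log = rng.uniform(-0.5, 0.8)
            true_hill = rng.uniform(0.8, 2.5)
            d, y = _exact_points(true_log, true_hill)
            y = y + rng.normal(0, 8, size=y.shape)
            fit = fit_ed50(d, y)
            sse_fit = ((y - predict_inhibition(d, fit.log_ed50, fit.hill)) ** 2).sum()
            sse_grid, _, _ = grid_search_ed50(d, y)
            assert sse_fit <= sse_grid * (1 + 1e-9) + 1e-8

    @given(c=st.floats(min_value=0.05, max_value=20.0))
    @settings(max_examples=15, deadline=None)
    def test_dose_rescaling_shifts_log_ed50(self, c):
        d, y = _exact_points(0.3, 1.2)
        rng = np.random.default_rng(11)
        y = y + rng.normal(0, 5, size=y.shape)
        base = fit_ed50(d, y)
        scaled = fit_ed50(d * c, y)
        assert scaled.log_ed50 - base.log_ed50 == pytest.approx(math.log10(c), abs=1e-5)
        assert scaled.hill == pytest.approx(base.hill, abs=1e-5)
        assert scaled.residual_sd == pytest.approx(base.residual_sd, rel=1e-6)

    def test_row_permutation_leaves_fit_unchanged(self):
        rng = np.random.default_rng(5)
        d, y = _exact_points(0.2, 1.4)
        y = y + rng.normal(0, 6, size=y.shape)
        perm = rng.permutation(d.size)
        a, b = fit_ed50(d, y), fit_ed50(d[perm], y[perm])
        # row order only permutes the residual vector; the optimum is the
        # same up to floating summation order
        assert b.log_ed50 == pytest.approx(a.log_ed50, rel=1e-7)
        assert b.hill == pytest.approx(a.hill, rel=1e-7)

    def test_ci_width_shrinks_with_group_size(self):
        """Asymptotic CI narrows (in expectation) as per-dose n grows."""

        def mean_width(n_per_group, n_reps=25):
            widths = []
            for s in range(n_reps):
                cfg = GeneratorConfig(
                    seed=s,
                    true_log_ed50=math.log10(2.3),
                    doses=(0.3, 1.0, 3.0, 10.0),
                    n_per_group=n_per_group,
                )
                fit = fit_from_dataset(gen_single_drug(cfg, drug="m"), drug="m")
                if fit.ci95:
                    widths.append(fit.ci95[1] - fit.ci95[0])
            return np.mean(widths)

        assert mean_width(16) < mean_width(4)


class TestFitFromDataset:
    def test_recovers_generator_truth(self, morphine_dataset):
        fit = fit_from_dataset(morphine_dataset, drug="morphine")
        assert fit.converged
        assert fit.ed50 == pytest.approx(2.3, rel=0.35)  # single noisy experiment

    def test_total_dose_axis_requires_no_drug_name(self, morphine_dataset):
        fit = fit_from_dataset(morphine_dataset, dose_axis="total")
        assert fit.converged

    def test_drug_axis_requires_name(self, morphine_dataset):
        with pytest.raises(ValueError, match="requires a drug name"):
            fit_from_dataset(morphine_dataset)


class TestDoseResponseFitType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DoseResponseFit(
                drug_label="x", log_ed50=0.0, ed50=2.0, hill=1.0,  # ed50 != 10**log
                ci95=None, n_points=5, converged=True,
            )
        with pytest.raises(ValueError):
            DoseResponseFit.from_interval(5.0, (6.0, 7.0))  # CI must bracket ED50

    def test_from_interval_wraps_published_values(self):
        fit = DoseResponseFit.from_interval(2.3, (2.0, 2.5), "morphine")
        assert fit.ci95 == (2.0, 2.5)
        assert fit.log_ed50 == pytest.approx(math.log10(2.3))
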