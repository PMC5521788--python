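"""Survival-curve fitting, iso-survival doses, alpha/beta and RBE arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import invitrodose as iv
from invitrodose.survival import (
    ClonogenicDataset,
    SurvivalFit,
    alpha_beta_ratio,
    dose_at_survival,
    fit_sf_curve,
    fit_survival,
    rbe,
    surviving_fraction,
)

from oracles import brute_force_lq

DOSES = (0.5, 1.0, 2.0, 4.0, 5.0, 6.0, 8.0, 10.0)


def _noise_free_dataset(alpha, beta, doses=DOSES, seeded=500, pe=0.4):
    rows = [(0.0, seeded * pe, seeded, 0)]
    for d in doses:
        sf = math.exp(-alpha * d - beta * d * d)
        rows.append((d, seeded * pe * sf, seeded, 0))
    df = pd.DataFrame(rows, columns=["dose_gy", "colonies", "seeded", "replicate"])
    return ClonogenicDataset(records=df)


def _lq_fit(alpha, beta):
    return SurvivalFit(
        model="lq", alpha=alpha, alpha_se=0.0, beta=beta, beta_se=0.0,
        covariance=np.zeros((2, 2)),
    )


class TestSurvivingFraction:
    def test_full_survival(self):
        sf, _ = surviving_fraction(200, 500, 0.4)
        assert sf == 1.0

    def test_zero_colonies(self):
        sf, se = surviving_fraction(0, 500, 0.4)
        assert sf == 0.0 and se == 0.0

    def test_typical_treated_well(self):
        sf, se = surviving_fraction(30, 500, 0.4)
        assert sf == pytest.approx(0.15)
        assert se == pytest.approx(math.sqrt(0.06 * 0.94 / 500) / 0.4)

    def test_colonies_above_seeded_rejected(self):
        with pytest.raises(ValueError):
            surviving_fraction(501, 500, 0.4)


class TestDatasetValidation:
    def test_pe_pooled_from_controls(self):
        df = pd.DataFrame(
            {"dose_gy": [0.0, 0.0, 2.0], "colonies": [190, 210, 100], "seeded": [500] * 3}
        )
        assert ClonogenicDataset(records=df).plating_efficiency == pytest.approx(0.4)

    def test_no_controls_no_pe_rejected(self):
        df = pd.DataFrame({"dose_gy": [2.0], "colonies": [100], "seeded": [500]})
        with pytest.raises(ValueError, match="plating efficiency"):
            ClonogenicDataset(records=df)

    def test_colonies_exceeding_seeded_rejected(self):
        df = pd.DataFrame({"dose_gy": [0.0], "colonies": [600], "seeded": [500]})
        with pytest.raises(ValueError):
            ClonogenicDataset(records=df)


class TestFitRecovery:
    @pytest.mark.parametrize("objective", ["poisson", "lsq"])
    def test_lq_exact_on_noise_free_curve(self, objective):
        fit = fit_survival(_noise_free_dataset(0.21, 0.05), "lq", objective=objective)
        assert fit.alpha == pytest.approx(0.21, abs=1e-6)
        assert fit.beta == pytest.approx(0.05, abs=1e-6)
        assert not fit.alpha_at_bound

    @pytest.mark.parametrize("objective", ["poisson", "lsq"])
    def test_linear_exact_on_noise_free_curve(self, objective):
        fit = fit_survival(_noise_free_dataset(0.87, 0.0), "linear", objective=objective)
        assert fit.alpha == pytest.approx(0.87, abs=1e-6)
        assert fit.beta is None

    def test_alpha_pins_at_zero_for_pure_quadratic(self):
        """A curvature-dominated cell line reports alpha at its bound."""
        fit = fit_survival(_noise_free_dataset(0.0, 0.12), "lq")
        assert fit.alpha == 0.0
        assert fit.alpha_at_bound
        assert fit.beta == pytest.approx(0.12, abs=1e-6)
        assert fit.alpha_se > 0.0  # upper-bound style uncertainty

    def test_published_sf_points_match_least_squares_oracle(self):
        doses = [2.0, 4.0, 6.0, 8.0]
        sf = [0.60, 0.15, 0.043, 0.036]
        fit = fit_sf_curve(doses, sf, "lq")
        a_ref, b_ref = brute_force_lq(doses, -np.log(sf))
        assert fit.alpha == pytest.approx(a_ref, abs=1e-5)
        assert fit.beta == pytest.approx(b_ref, abs=1e-5)

    def test_all_zero_survival_rejected(self):
        df = pd.DataFrame(
            {
                "dose_gy": [0.0, 2.0, 4.0, 6.0],
                "colonies": [200, 0, 0, 0],
                "seeded": [500] * 4,
            }
        )
        with pytest.raises(ValueError, match="zero"):
            fit_survival(ClonogenicDataset(records=df), "lq")

    def test_too_few_distinct_doses_rejected(self):
        df = pd.DataFrame(
            {"dose_gy": [0.0, 2.0, 2.0], "colonies": [200, 50, 55], "seeded": [500] * 3}
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_survival(ClonogenicDataset(records=df), "lq")

    def test_zero_colony_wells_excluded_from_lsq_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "dose_gy": [0.0, 1.0, 2.0, 4.0, 6.0],
                "colonies": [200, 150, 110, 40, 0],
                "seeded": [500] * 5,
            }
        )
        with caplog.at_level("WARNING", logger="invitrodose.survival"):
            fit_survival(ClonogenicDataset(records=df), "lq", objective="lsq")
        assert "excluding 1 zero-colony" in caplog.text


class TestDoseAtSurvival:
    def test_pure_log_linear(self):
        assert dose_at_survival(_lq_fit(math.log(10.0), 0.0), 0.1) == pytest.approx(1.0)

    def test_lq_closed_form(self):
        d10 = dose_at_survival(_lq_fit(0.21, 0.05), 0.1)
        assert d10 == pytest.approx(5.0036, abs=1e-3)

    def test_survival_one_gives_zero_dose(self):
        assert dose_at_survival(_lq_fit(0.21, 0.05), 1.0) == 0.0

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            dose_at_survival(_lq_fit(0.0, 0.0), 0.1)

    def test_monotone_decreasing_in_parameters(self):
        base = dose_at_survival(_lq_fit(0.21, 0.05), 0.1)
        assert dose_at_survival(_lq_fit(0.30, 0.05), 0.1) < base
        assert dose_at_survival(_lq_fit(0.21, 0.08), 0.1) < base

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        alpha=st.floats(0.01, 2.0),
        beta=st.floats(0.0, 0.5),
        dose=st.floats(0.1, 20.0),
    )
    def test_round_trip_through_model_survival(self, alpha, beta, dose):
        fit = _lq_fit(alpha, beta)
        sf = float(fit.sf(dose))
        if sf > 1e-300:
            assert dose_at_survival(fit, sf) == pytest.approx(dose, rel=1e-9)


class TestRbeAndRatio:
    @pytest.mark.parametrize(
        "d_ref,d_test,expected",
        [(5.1, 2.6, 2.0), (17.8, 3.3, 5.4), (4.0, 4.0, 1.0)],
    )
    def test_rbe_ratios(self, d_ref, d_test, expected):
        assert round(rbe(d_ref, d_test), 1) == expected

    def test_rbe_scale_invariance(self):
        assert rbe(5.1, 2.6) == pytest.approx(rbe(51.0, 26.0))

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            rbe(0.0, 1.0)

    def test_alpha_beta_direct_ratio(self):
        fit = fit_survival(_noise_free_dataset(0.21, 0.05), "lq")
        ratio, se = alpha_beta_ratio(fit)
        assert ratio == pytest.approx(4.2, abs=1e-4)

    def test_alpha_pinned_gives_zero_ratio(self):
        fit = fit_survival(_noise_free_dataset(0.0, 0.12), "lq")
        assert alpha_beta_ratio(fit) == (0.0, 0.0)

    def test_beta_zero_unbounded(self):
        fit = _lq_fit(0.5, 0.0)
        with pytest.warns(RuntimeWarning, match="unbounded"):
            ratio, se = alpha_beta_ratio(fit)
        assert math.isinf(ratio)
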