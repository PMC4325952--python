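"""Posterior-predictive imputation and Rubin's-rules pooling."""

import math

import numpy as np
import pytest

import spatmiss.imputation as imp
from spatmiss.imputation import (
    combine_lognormal,
    impute_once,
    n_imputations,
    pool_fit,
    rubin_combine,
)


class TestImputationCount:
    @pytest.mark.parametrize(
        "prop,expected",
        [(0.05, 3), (0.10, 5), (0.15, 5), (0.25, 5), (0.50, 10), (0.75, 10)],
    )
    def test_policy(self, prop, expected):
        assert n_imputations(prop) == expected

    def test_off_policy_snaps_with_warning(self):
        with pytest.warns(UserWarning):
            assert n_imputations(0.30) == 5


class TestRubinCombine:
    def test_hand_computed_example(self):
        pooled = rubin_combine([1.0, 3.0], [1.0, 1.0])
        assert pooled.point == 2.0
        assert pooled.within == 1.0
        assert pooled.between == 2.0
        assert pooled.variance == pytest.approx(4.0)

    def test_identical_estimates_have_no_between_variance(self):
        pooled = rubin_combine([2.5] * 5, [0.3] * 5)
        assert pooled.point == 2.5
        assert pooled.between == 0.0
        assert pooled.variance == pytest.approx(0.3)

    def test_single_imputation_allowed(self):
        pooled = rubin_combine([1.7], [0.2])
        assert pooled.point == 1.7
        assert pooled.between == 0.0
        assert pooled.variance == pytest.approx(0.2)

    def test_permutation_invariance(self):
        a = rubin_combine([1.0, 2.0, 4.0], [0.1, 0.2, 0.3])
        b = rubin_combine([4.0, 1.0, 2.0], [0.3, 0.1, 0.2])
        assert a.point == b.point
        assert a.variance == pytest.approx(b.variance)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rubin_combine([1.0, 2.0], [0.1])


class TestLognormalCombine:
    def test_degenerate_case(self):
        pooled = combine_lognormal([0.0, 0.0], [0.0, 0.0])
        assert pooled.point == pytest.approx(1.0)
        assert pooled.variance == pytest.approx(0.0)

    def test_closed_form_moments(self):
        # single pseudo-imputation with m=0, V=1
        pooled = combine_lognormal([0.0], [1.0])
        assert pooled.point == pytest.approx(math.exp(0.5), rel=1e-12)
        assert pooled.variance == pytest.approx(
            (math.e - 1.0) * math.e, rel=1e-12
        )

    def test_scale_equivariance(self):
        base = combine_lognormal([0.2, 0.5], [0.1, 0.1])
        shifted = combine_lognormal([1.2, 1.5], [0.1, 0.1])
        assert shifted.point == pytest.approx(base.point * math.e, rel=1e-12)

    def test_log_point_recovers_m_plus_half_v(self):
        log_est, log_var = [0.3, 0.9], [0.2, 0.4]
        pooled = combine_lognormal(log_est, log_var)
        ref = rubin_combine(log_est, log_var)
        assert math.log(pooled.point) == pytest.approx(
            ref.point + ref.variance / 2.0, rel=1e-12
        )

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_lognormal([np.inf], [0.1])


class TestImputeOnce:
    def test_zero_unobserved_returns_copy(self, toy_dataset):
        class Converged:
            converged = True

        out = impute_once(Converged(), toy_dataset, 0)
        assert np.array_equal(out.outcome, toy_dataset.outcome)
        assert out is not toy_dataset

    def test_unconverged_fit_refused(self, toy_dataset):
        class Failed:
            converged = False

        toy_dataset.observed[:5] = False
        with pytest.raises(ValueError):
            impute_once(Failed(), toy_dataset, 0)

    def test_degenerate_probabilities_give_deterministic_outcomes(
        self, toy_dataset, monkeypatch
    ):
        toy_dataset.observed[:20] = False

        class Converged:
            converged = True

        monkeypatch.setattr(
            imp, "posterior_predict", lambda f, d, s: np.ones(20)
        )
        out = impute_once(Converged(), toy_dataset, 0)
        assert np.all(out.outcome[:20] == 1)
        assert out.observed.all()

    def test_observed_rows_untouched(self, toy_dataset, monkeypatch):
        toy_dataset.observed[:20] = False

        class Converged:
            converged = True

        monkeypatch.setattr(
            imp, "posterior_predict", lambda f, d, s: np.full(20, 0.5)
        )
        out = impute_once(Converged(), toy_dataset, 1)
        assert np.array_equal(out.outcome[20:], toy_dataset.outcome[20:])


class TestPoolFit:
    def _fit_small(self, dataset, field_model):
        import spatmiss as sm
        from tests.conftest import SMALL_GRID

        return sm.fit(
            dataset,
            field_model=field_model,
            grid=SMALL_GRID,
            covariate_columns=["log_herd_size"],
            marginal_strategy="gaussian",
        )

    def test_identical_members_pool_to_single_fit(
        self, small_dataset, small_field_model
    ):
        f = self._fit_small(small_dataset, small_field_model)
        pooled = pool_fit([f, f, f])
        assert pooled.M == 3
        assert pooled.pooled["alpha"].between == 0.0
        assert pooled.pooled["alpha"].point == pytest.approx(
            f.summary["alpha"]["mean"]
        )
        assert pooled.pooled["range"].between == 0.0

    def test_order_invariance(self, small_dataset, small_field_model):
        f1 = self._fit_small(small_dataset, small_field_model)
        ds2 = small_dataset.copy()
        ds2.outcome[:3] = 1 - ds2.outcome[:3]
        f2 = self._fit_small(ds2, small_field_model)
        a = pool_fit([f1, f2])
        b = pool_fit([f2, f1])
        for name in a.pooled:
            assert a.pooled[name].point == pytest.approx(b.pooled[name].point)
            assert a.pooled[name].variance == pytest.approx(
                b.pooled[name].variance
            )

    def test_all_failures_rejected(self):
        with pytest.raises(ValueError):
            pool_fit([None, None])

    def test_nonspatial_imputation_underestimates_field_variance(
        self, small_dataset, small_field_model
    ):
        """Imputing from a logistic model without the spatial component
        destroys spatial structure in the completed data: the pooled σ²
        comes out smaller than with spatial-model imputation."""
        import spatmiss as sm
        from spatmiss.imputation import make_imputations
        from spatmiss.missingness import (
            MissingnessModel,
            apply_mask,
            calibrate,
            simulate_mask,
        )
        from tests.conftest import SMALL_GRID

        model = calibrate(
            MissingnessModel(mechanism="MCAR", target_prop=0.5),
            small_dataset,
        )
        pooled_sigma2 = {"spatial": [], "nonspatial": []}
        for rep in range(3):
            masked = apply_mask(
                small_dataset, simulate_mask(model, small_dataset, rep)
            )
            for tag, imp_model in (
                ("spatial", small_field_model),
                ("nonspatial", None),
            ):
                imp_fit = sm.fit(
                    masked,
                    field_model=imp_model,
                    grid=SMALL_GRID,
                    marginal_strategy="gaussian",
                )
                imps = make_imputations(imp_fit, masked, 3, rep)
                members = [
                    self._fit_small(d, small_field_model)
                    for d in imps.completed_datasets
                ]
                pooled_sigma2[tag].append(
                    pool_fit(members).pooled["sigma2"].point
                )
        assert np.median(pooled_sigma2["nonspatial"]) < np.median(
            pooled_sigma2["spatial"]
        )
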