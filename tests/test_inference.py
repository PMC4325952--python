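"""Laplace-plus-grid inference for the spatial logistic model."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import expit

import spatmiss as sm
from spatmiss.datasets import SpatialDataset
from spatmiss.fields import SpdeFieldModel
from spatmiss.inference import (
    GridSettings,
    PriorSpec,
    default_hyper_means,
    laplace_latent,
    posterior_predict,
)
from spatmiss.mesh import grid_mesh, make_projector
from spatmiss.missingness import MissingnessModel, apply_mask, calibrate, simulate_mask

from tests._oracles import irls_penalised_logistic

FAST_GRID = GridSettings(size=3, max_expansions=0, mode_search_budget=40)


def _toy_spde_pieces(dataset):
    mesh = grid_mesh((-3, -3, 13, 13), 2.0)
    model = SpdeFieldModel(mesh, dataset.locations)
    return mesh, model


def _design(dataset, model):
    X = dataset.covariates.to_numpy(dtype=float)
    ones = np.ones((dataset.n, 1))
    return sp.hstack(
        [sp.csr_matrix(ones), sp.csr_matrix(X), model.A], format="csr"
    )


class TestLaplaceLatent:
    def test_suppressed_field_matches_penalised_irls(self, toy_dataset):
        """With the field precision scaled enormous the latent mode's (α, β)
        must agree with an independent ridge-IRLS logistic fit."""
        _mesh, model = _toy_spde_pieces(toy_dataset)
        B = _design(toy_dataset, model)
        Q = model.precision(0.5, 1.0) * 1e8
        P = sp.block_diag([sp.diags([0.001, 0.001]), Q], format="csc")
        res, _lu, _H = laplace_latent(
            toy_dataset.outcome.astype(float), B, P, logdet_P=0.0
        )
        oracle = irls_penalised_logistic(
            np.column_stack(
                [np.ones(toy_dataset.n), toy_dataset.covariates["x"]]
            ),
            toy_dataset.outcome,
            precision=0.001,
        )
        assert res.converged
        assert abs(res.mode[0] - oracle[0]) < 1e-4
        assert abs(res.mode[1] - oracle[1]) < 1e-4

    def test_constant_negative_data_pushes_alpha_down(self):
        rng = np.random.default_rng(0)
        locs = rng.uniform(0, 10, (50, 2))
        ds = SpatialDataset(
            locs, pd.DataFrame({"x": np.zeros(50)}), np.zeros(50, dtype=np.int8)
        )
        _mesh, model = _toy_spde_pieces(ds)
        B = _design(ds, model)
        Q = model.precision(0.5, 1.0)
        P = sp.block_diag([sp.diags([0.001, 0.001]), Q], format="csc")
        res, _lu, _H = laplace_latent(ds.outcome.astype(float), B, P, 0.0)
        assert res.mode[0] < -2.0
        assert np.max(np.abs(res.mode[2:])) < 0.5

    def test_mode_is_objective_minimum(self, toy_dataset):
        _mesh, model = _toy_spde_pieces(toy_dataset)
        B = _design(toy_dataset, model)
        Q = model.precision(0.5, 1.0)
        P = sp.block_diag([sp.diags([0.001, 0.001]), Q], format="csc")
        y = toy_dataset.outcome.astype(float)
        res, _lu, _H = laplace_latent(y, B, P, 0.0)

        def objective(x):
            eta = B @ x
            ll = float(np.sum(y * eta - np.logaddexp(0, eta)))
            return -ll + 0.5 * float(x @ (P @ x))

        rng = np.random.default_rng(1)
        base = objective(res.mode)
        for _ in range(5):
            pert = res.mode + 0.05 * rng.standard_normal(res.mode.size)
            assert objective(pert) >= base

    def test_marginal_invariant_to_row_order(self, toy_dataset):
        _mesh, model = _toy_spde_pieces(toy_dataset)
        B = _design(toy_dataset, model)
        Q = model.precision(0.5, 1.0)
        P = sp.block_diag([sp.diags([0.001, 0.001]), Q], format="csc")
        y = toy_dataset.outcome.astype(float)
        res1, _, _ = laplace_latent(y, B, P, 0.0)
        perm = np.random.default_rng(2).permutation(toy_dataset.n)
        res2, _, _ = laplace_latent(y[perm], B[perm], P, 0.0)
        assert res1.log_marginal == pytest.approx(
            res2.log_marginal, abs=1e-8
        )


class TestFit:
    def test_masked_and_restricted_rows_agree(self, toy_dataset):
        """Unobserved rows contribute nothing: fitting a masked dataset and
        the corresponding row-subset dataset gives identical summaries."""
        mesh = grid_mesh((-3, -3, 13, 13), 2.0)
        mask = np.zeros(toy_dataset.n, dtype=bool)
        mask[::4] = True
        masked = apply_mask(toy_dataset, mask)
        restricted = masked.restrict_observed()
        priors = PriorSpec(hyper_means=(-1.0, 0.5))
        f1 = sm.fit(
            masked,
            field_model=SpdeFieldModel(mesh, masked.locations),
            priors=priors,
            grid=FAST_GRID,
            marginal_strategy="gaussian",
        )
        f2 = sm.fit(
            restricted,
            field_model=SpdeFieldModel(mesh, restricted.locations),
            priors=priors,
            grid=FAST_GRID,
            marginal_strategy="gaussian",
        )
        for name in f1.summary:
            for stat in ("mean", "median", "sd"):
                assert f1.summary[name][stat] == f2.summary[name][stat]

    def test_no_observed_outcomes_rejected(self, toy_dataset):
        masked = apply_mask(toy_dataset, np.ones(toy_dataset.n, dtype=bool))
        with pytest.raises(ValueError):
            sm.fit(masked, field_model=None)

    def test_single_class_data_warns(self):
        rng = np.random.default_rng(3)
        locs = rng.uniform(0, 10, (40, 2))
        ds = SpatialDataset(
            locs,
            pd.DataFrame({"x": rng.normal(size=40)}),
            np.zeros(40, dtype=np.int8),
        )
        f = sm.fit(ds, field_model=None)
        assert any("class" in w for w in f.warnings)

    def test_grid_weights_normalised(self, small_dataset, small_field_model):
        from tests.conftest import SMALL_GRID

        f = sm.fit(
            small_dataset,
            field_model=small_field_model,
            grid=SMALL_GRID,
            covariate_columns=["log_herd_size"],
            marginal_strategy="gaussian",
        )
        assert f.hyper_grid[:, 2].sum() == pytest.approx(1.0, abs=1e-9)
        # range = sqrt(8)/kappa respected node by node
        ranges = np.sqrt(8.0) / np.exp(f.hyper_grid[:, 0])
        assert (ranges > 0).all()

    def test_posterior_sd_grows_with_missingness(self, small_dataset,
                                                 small_field_model):
        """Removing observations cannot sharpen the posterior: median SDs
        at 100% observation are no larger than at 25% observation."""
        from tests.conftest import SMALL_GRID

        model = calibrate(
            MissingnessModel(mechanism="MCAR", target_prop=0.75),
            small_dataset,
        )
        sds_full, sds_quarter = [], []
        for rep in range(5):
            f_full = sm.fit(
                small_dataset,
                field_model=small_field_model,
                grid=SMALL_GRID,
                covariate_columns=["log_herd_size"],
                marginal_strategy="gaussian",
            )
            masked = apply_mask(
                small_dataset, simulate_mask(model, small_dataset, rep)
            )
            f_quarter = sm.fit(
                masked,
                field_model=small_field_model,
                grid=SMALL_GRID,
                covariate_columns=["log_herd_size"],
                marginal_strategy="gaussian",
            )
            sds_full.append(f_full.summary["alpha"]["sd"])
            sds_quarter.append(f_quarter.summary["alpha"]["sd"])
        assert np.median(sds_full) <= np.median(sds_quarter)

    def test_hyper_prior_insensitive_on_complete_data(
        self, small_dataset, small_field_model
    ):
        """With complete data the range posterior barely reacts to the
        hyper-prior precision (0.1 vs 0.001)."""
        from tests.conftest import SMALL_GRID

        fits = {}
        for prec in (0.1, 0.001):
            fits[prec] = sm.fit(
                small_dataset,
                field_model=small_field_model,
                priors=PriorSpec(hyper_precision=prec),
                grid=SMALL_GRID,
                covariate_columns=["log_herd_size"],
                marginal_strategy="gaussian",
            )
        diff = abs(
            fits[0.1].summary["range"]["median"]
            - fits[0.001].summary["range"]["median"]
        )
        sd = max(
            fits[0.1].summary["range"]["sd"],
            fits[0.001].summary["range"]["sd"],
        )
        assert diff < sd


class TestPosteriorPredict:
    def _fit_masked(self, toy_dataset, n_hide=15):
        mesh = grid_mesh((-3, -3, 13, 13), 2.0)
        mask = np.zeros(toy_dataset.n, dtype=bool)
        mask[:n_hide] = True
        masked = apply_mask(toy_dataset, mask)
        model = SpdeFieldModel(mesh, masked.locations)
        f = sm.fit(
            masked,
            field_model=model,
            grid=FAST_GRID,
            marginal_strategy="gaussian",
        )
        return f, masked

    def test_deterministic_under_seed(self, toy_dataset):
        f, masked = self._fit_masked(toy_dataset)
        p1 = posterior_predict(f, masked, 99)
        p2 = posterior_predict(f, masked, 99)
        assert np.array_equal(p1, p2)
        assert p1.shape == (15,)

    def test_empty_when_fully_observed(self, toy_dataset):
        mesh = grid_mesh((-3, -3, 13, 13), 2.0)
        f = sm.fit(
            toy_dataset,
            field_model=SpdeFieldModel(mesh, toy_dataset.locations),
            grid=FAST_GRID,
            marginal_strategy="gaussian",
        )
        assert posterior_predict(f, toy_dataset, 0).size == 0

    def test_degenerate_posterior_gives_deterministic_probabilities(
        self, toy_dataset
    ):
        """With the regression block pinned at zero by an enormous prior
        precision and no field, every sampled probability is 1/2."""
        mask = np.zeros(toy_dataset.n, dtype=bool)
        mask[:10] = True
        masked = apply_mask(toy_dataset, mask)
        f = sm.fit(
            masked,
            field_model=None,
            priors=PriorSpec(regression_precision=1e12),
        )
        p = posterior_predict(f, masked, 5)
        assert np.allclose(p, 0.5, atol=1e-3)

    def test_sampler_consistent_with_mixture_mean(self, toy_dataset):
        """The Monte-Carlo mean of sampled success probabilities at one
        held-out location matches the deterministic mixed posterior mean
        (Gauss–Hermite over each node's Gaussian) within 3 MC SEs."""
        f, masked = self._fit_masked(toy_dataset, n_hide=8)
        ctx = f._model
        unobs = ~masked.observed
        b = ctx.B_full[unobs][0].toarray().ravel()

        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(40)
        mix_mean = 0.0
        for node in f._nodes:
            if node.weight <= 0:
                continue
            res, lu, _H, _P = ctx.laplace(
                node.log_kappa, node.log_tau, want_factor=True
            )
            m = float(b @ res.mode)
            s2 = float(b @ lu.solve(b))
            vals = expit(m + np.sqrt(max(s2, 0.0)) * gh_x)
            mix_mean += node.weight * float(
                (gh_w * vals).sum() / gh_w.sum()
            )

        draws = np.array(
            [posterior_predict(f, masked, seed)[0] for seed in range(600)]
        )
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mix_mean) < 3 * se + 1e-3

    def test_default_hyper_means_scale_with_domain(self):
        small = default_hyper_means(np.array([[0.0, 0.0], [1.0, 1.0]]))
        large = default_hyper_means(np.array([[0.0, 0.0], [100.0, 100.0]]))
        assert small[0] > large[0]  # bigger domain, smaller kappa
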