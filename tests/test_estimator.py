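import numpy as np
import pandas as pd
import pytest

import survrrr as s
from survrrr.cox import StratifiedCoxProblem, fit_lasso_cox
from survrrr.estimator import build_a_step_problem, build_gamma_step_problem


class TestAStepDesign:
    def test_rank1_all_ones_gamma_reproduces_predictors(self, small_synthetic):
        data, _ = small_synthetic
        arr = data.to_arrays()
        prob = build_a_step_problem(data, np.ones((data.n_outcomes, 1)))
        np.testing.assert_array_equal(prob.design, arr.X[arr.row_subject])

    def test_zero_gamma_row_zeroes_that_stratum(self, small_synthetic):
        data, _ = small_synthetic
        G = np.ones((data.n_outcomes, 1))
        G[1, 0] = 0.0
        prob = build_a_step_problem(data, G)
        arr = data.to_arrays()
        assert np.all(prob.design[arr.row_stratum == 1] == 0)
        assert np.any(prob.design[arr.row_stratum == 0] != 0)

    def test_p2_r2_expansion_and_column_order(self):
        # design for coefficient A[p, r] sits at column r*P + p and holds
        # Gamma[q, r] * x_p
        rec = pd.DataFrame(
            [("s1", "d1", 0.0, 2.0, 1)],
            columns=["subject_id", "outcome", "entry", "exit", "status"],
        )
        pred = pd.DataFrame({"subject_id": ["s1"], "x1": [3.0], "x2": [5.0]})
        data = s.MultiOutcomeSurvivalData(rec, pred)
        G = np.array([[2.0, 7.0]])  # Q=1, R=2: (g1, g2)
        prob = build_a_step_problem(data, G)
        np.testing.assert_array_equal(
            prob.design[0], [2.0 * 3.0, 2.0 * 5.0, 7.0 * 3.0, 7.0 * 5.0]
        )

    def test_all_zero_gamma_rejected(self, small_synthetic):
        data, _ = small_synthetic
        with pytest.raises(ValueError, match="zero"):
            build_a_step_problem(data, np.zeros((data.n_outcomes, 1)))


class TestGammaStepDesign:
    def test_unit_vector_a_gives_predictor_times_indicator(self, small_synthetic):
        data, _ = small_synthetic
        arr = data.to_arrays()
        A = np.zeros((data.n_predictors, 1))
        A[2, 0] = 1.0
        prob = build_gamma_step_problem(data, A)
        for i in range(min(50, data.n_rows)):
            q = arr.row_stratum[i]
            expected = np.zeros(data.n_outcomes)
            expected[q] = arr.X[arr.row_subject[i], 2]
            np.testing.assert_array_equal(prob.design[i], expected)

    def test_decoupled_per_stratum_fits_match_joint(self, small_synthetic):
        data, _ = small_synthetic
        rng = np.random.default_rng(0)
        A = rng.standard_normal((data.n_predictors, 2))
        lam = 0.02
        arr = data.to_arrays()
        prob = build_gamma_step_problem(data, A)
        joint = fit_lasso_cox(prob, lam, tol=1e-10)
        Q = data.n_outcomes
        G_joint = joint.coef.reshape(2, Q).T
        scores = arr.X @ A
        for q in range(Q):
            rows = arr.row_stratum == q
            sub = StratifiedCoxProblem(
                arr.row_stratum[rows], arr.entry[rows], arr.exit[rows],
                arr.status[rows], scores[arr.row_subject[rows]],
                n_norm=data.n_subjects,
            )
            g_q = fit_lasso_cox(sub, lam, tol=1e-10).coef
            np.testing.assert_allclose(G_joint[q], g_q, atol=1e-8)

    def test_zero_a_column_gives_zero_score_column(self, small_synthetic):
        data, _ = small_synthetic
        A = np.zeros((data.n_predictors, 2))
        A[0, 0] = 1.0  # column 2 dead
        scores = s.rank_scores(s.Factorization(A, np.ones((data.n_outcomes, 2))),
                               data.predictors.to_numpy())
        assert np.all(scores[:, 1] == 0)
        assert np.any(scores[:, 0] != 0)

    def test_all_zero_a_rejected(self, small_synthetic):
        data, _ = small_synthetic
        with pytest.raises(ValueError, match="zero"):
            build_gamma_step_problem(data, np.zeros((data.n_predictors, 1)))


class TestSurvRRRFitting:
    def test_full_rank_unpenalized_matches_per_outcome_cox(self):
        from lifelines import CoxPHFitter

        cfg = s.GeneratorConfig(
            n_subjects=200, P=5, Q=2, R_true=1, sparsity=0.2, seed=3,
            death_outcome_index=None, baseline_rates=0.05,
        )
        data, _ = s.generate(cfg)
        data, _ = s.standardize(data)
        g0 = np.random.default_rng(1).standard_normal((2, 2))
        fit = s.fit_survrrr(data, R=2, alpha=0.0, gamma_init=g0,
                            tol=1e-10, max_outer_iter=300, inner_tol=1e-9)
        arr = data.to_arrays()
        B_oracle = np.zeros((5, 2))
        for q in range(2):
            rows = arr.row_stratum == q
            df = pd.DataFrame(arr.X[arr.row_subject[rows]], columns=[f"x{i}" for i in range(5)])
            df["exit"], df["status"] = arr.exit[rows], arr.status[rows]
            cph = CoxPHFitter().fit(df, duration_col="exit", event_col="status")
            B_oracle[:, q] = cph.params_.values
        assert np.abs(fit.factorization.B - B_oracle).max() <= 1e-3

    def test_trace_non_increasing_block_ascent(self, small_synthetic):
        data, _ = small_synthetic
        fit = s.fit_survrrr(data, R=2, alpha=0.01,
                            gamma_init=np.random.default_rng(2).standard_normal((3, 2)))
        tr = np.asarray(fit.objective_trace)
        # monotone until the stopping rule (which may add one final uptick)
        assert np.all(np.diff(tr)[:-1] <= 1e-8)

    def test_huge_lambda_collapses_to_rank_zero(self, small_synthetic):
        data, _ = small_synthetic
        fit = s.fit_survrrr(data, R=1, alpha=1e3, gamma_init=np.ones((3, 1)))
        assert fit.effective_rank == 0
        assert fit.converged

    def test_best_iterate_returned(self, small_synthetic):
        data, _ = small_synthetic
        fit = s.fit_survrrr(data, R=1, alpha=0.02,
                            gamma_init=np.random.default_rng(3).standard_normal((3, 1)))
        n = data.n_subjects
        from survrrr.model_selection import _loglik_at_B

        O_returned = (
            -2.0 * _loglik_at_B(data, fit.factorization.B) / n
            + 2.0 * fit.alpha * fit.factorization.penalty
        )
        assert O_returned == pytest.approx(min(fit.objective_trace), abs=1e-9)

    def test_rebalance_preserves_B_and_objective(self, small_synthetic):
        data, _ = small_synthetic
        g0 = np.random.default_rng(4).standard_normal((3, 1))
        plain = s.fit_survrrr(data, R=1, alpha=0.02, gamma_init=g0, tol=1e-8)
        reb = s.fit_survrrr(data, R=1, alpha=0.02, gamma_init=g0, tol=1e-8, rebalance=True)
        np.testing.assert_allclose(plain.factorization.B, reb.factorization.B, atol=1e-4)
        # rebalancing equalizes column l1 norms without hurting the objective
        assert reb.objective <= plain.objective + 1e-6

    def test_multi_init_stability_of_B(self, small_synthetic):
        # well-conditioned instance: path runs from different random starts
        # end at the same solution at the shared final penalty
        data, _ = small_synthetic
        train, test = s.split_train_test(data, 0.3, seed=0)
        lams = s.generate_lambda_sequence(train, 1, np.ones((3, 1)), n_lambda=6, min_ratio=3e-3)
        fits = []
        for seed in (10, 20, 30):
            pc = s.PathConfig(rank=1, lambdas=lams, random_state=seed, tol=1e-8)
            fits.append(s.fit_path(train, test, pc).entries[-1].fit)
        B0 = fits[0].factorization.B
        assert np.any(B0 != 0)
        for f in fits[1:]:
            np.testing.assert_allclose(f.factorization.B, B0, atol=1e-3)

    def test_rank_bounds_validated(self, small_synthetic):
        data, _ = small_synthetic
        with pytest.raises(ValueError, match="rank"):
            s.SurvRRR(rank=4).fit(data)  # Q = 3


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self):
        est = s.SurvRRR(rank=2, alpha=0.1)
        params = est.get_params()
        assert params["rank"] == 2
        est.set_params(alpha=0.5, max_iter=7)
        assert est.alpha == 0.5 and est.max_iter == 7
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = s.SurvRRR(rank=2, alpha=0.3, random_state=5)
        cl = clone(est)
        assert cl.get_params() == est.get_params()

    def test_fit_sets_trailing_underscore_attributes(self, small_synthetic):
        data, _ = small_synthetic
        est = s.SurvRRR(rank=1, alpha=0.02, random_state=0).fit(data)
        assert est.A_.shape == (data.n_predictors, 1)
        assert est.Gamma_.shape == (data.n_outcomes, 1)
        assert est.B_.shape == (data.n_predictors, data.n_outcomes)
        assert est.n_parameters_ == s.n_free_parameters(data.n_predictors, data.n_outcomes, 1)

    def test_transform_and_predict_shapes(self, small_synthetic):
        data, _ = small_synthetic
        est = s.SurvRRR(rank=1, alpha=0.02, random_state=0).fit(data)
        Xnew = np.random.default_rng(0).standard_normal((7, data.n_predictors))
        assert est.transform(Xnew).shape == (7, 1)
        assert est.predict(Xnew).shape == (7, data.n_outcomes)
        np.testing.assert_allclose(est.predict(Xnew), Xnew @ est.B_)

    def test_unfitted_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            s.SurvRRR().transform(np.ones((3, 2)))

    def test_fit_accepts_matrix_and_records(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        rec = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(50), 2),
                "outcome": np.tile(["a", "b"], 50),
                "exit": rng.uniform(1, 5, 100),
                "status": rng.integers(0, 2, 100),
            }
        )
        est = s.SurvRRR(rank=1, alpha=0.05, random_state=1).fit(X, rec)
        assert est.B_.shape == (3, 2)
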