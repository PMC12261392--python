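"""Alternating estimation of the penalized reduced-rank Cox model.

The model: Q time-to-event outcomes share a P x Q coefficient matrix
B = A @ Gamma.T of rank <= R, so the stratum-q hazard is

    h_q(t; x) = h_q0(t) * exp( sum_r gamma_qr * alpha_r' x )

Estimation alternates two lasso-penalized stratified Cox fits: with Gamma
fixed, the A-step uses the Kronecker-expanded covariates gamma_qr * x_p;
with A fixed, the Gamma-step uses the rank scores alpha_r' x interacted with
outcome indicators (which decouples over strata, since risk sets never cross
outcomes). Both steps share a single penalty strength lambda (the factor
scaling freedom lets lambda_A = lambda_Gamma without loss of generality).

Progress is tracked by the penalized deviance

    O = -2 * l(A Gamma') / n_subjects + 2 * lambda * (|A|_1 + |Gamma|_1)

which each half-step can only decrease; the loop stops when the improvement
falls below ``tol`` or turns negative (numerical noise near convergence),
and the best-O iterate is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .cox import CoxFitResult, StratifiedCoxProblem, fit_lasso_cox
from .data import FitArrays, MultiOutcomeSurvivalData
from .factorization import Factorization, canonicalize, n_free_parameters, rank_scores

__all__ = [
    "SurvRRR",
    "SurvRRRFit",
    "fit_survrrr",
    "build_a_step_problem",
    "build_gamma_step_problem",
]


def _as_arrays(data) -> FitArrays:
    if isinstance(data, MultiOutcomeSurvivalData):
        return data.to_arrays()
    if isinstance(data, FitArrays):
        return data
    raise TypeError("expected MultiOutcomeSurvivalData or FitArrays")


def build_a_step_problem(data, Gamma: np.ndarray) -> StratifiedCoxProblem:
    """Stratified Cox problem for the A half-step (Gamma fixed).

    One row per survival record; the design vector has length P*R with the
    column for coefficient A[p, r] at index ``r * P + p`` holding
    ``Gamma[q, r] * x_p`` for the record's outcome q.
    """
    arr = _as_arrays(data)
    Gamma = np.asarray(Gamma, dtype=float)
    if np.all(Gamma == 0):
        raise ValueError("Gamma is entirely zero: the hazard no longer depends on A")
    P = arr.X.shape[1]
    R = Gamma.shape[1]
    Xrows = arr.X[arr.row_subject]                      # (rows, P)
    Grows = Gamma[arr.row_stratum]                      # (rows, R)
    design = (Grows[:, :, None] * Xrows[:, None, :]).reshape(len(Xrows), R * P)
    return StratifiedCoxProblem(
        strata=arr.row_stratum, entry=arr.entry, exit=arr.exit, status=arr.status,
        design=design, n_norm=arr.X.shape[0],
    )


def build_gamma_step_problem(data, A: np.ndarray) -> StratifiedCoxProblem:
    """Stratified Cox problem for the Gamma half-step (A fixed).

    Design length Q*R with column ``r * Q + q`` equal to the rank score
    alpha_r' x on rows of outcome q and zero elsewhere. Because risk sets
    never cross strata this joint fit decouples into Q independent
    R-covariate problems; the joint form is used here and the equivalence is
    asserted in tests.
    """
    arr = _as_arrays(data)
    A = np.asarray(A, dtype=float)
    if np.all(A == 0):
        raise ValueError("A is entirely zero: the hazard no longer depends on Gamma")
    Q = int(arr.row_stratum.max()) + 1
    R = A.shape[1]
    scores = arr.X @ A                                  # (n, R)
    Srows = scores[arr.row_subject]                     # (rows, R)
    design = np.zeros((len(Srows), Q * R))
    rows = np.arange(len(Srows))
    for r in range(R):
        design[rows, r * Q + arr.row_stratum] = Srows[:, r]
    return StratifiedCoxProblem(
        strata=arr.row_stratum, entry=arr.entry, exit=arr.exit, status=arr.status,
        design=design, n_norm=arr.X.shape[0],
    )


@dataclass
class SurvRRRFit:
    """Result of one alternating fit at fixed rank and penalty."""

    factorization: Factorization
    alpha: float
    objective_trace: list[float]
    converged: bool
    n_iterations: int
    init_descriptor: str = ""
    inner_results: tuple[CoxFitResult | None, CoxFitResult | None] = (None, None)

    @property
    def effective_rank(self) -> int:
        return self.factorization.effective_rank

    @property
    def objective(self) -> float:
        """Best penalized deviance reached (the returned iterate's O)."""
        return min(self.objective_trace) if self.objective_trace else float("nan")


class SurvRRR:
    """Penalized reduced-rank regression for multi-outcome survival data.

    A stratified Cox model over Q outcomes whose P x Q coefficient matrix is
    factorized as ``B = A @ Gamma.T`` with rank ``R``, both factors fitted
    under a lasso penalty of strength ``alpha`` by alternating penalized
    stratified Cox fits.

    Parameters
    ----------
    rank : int
        Number of latent factors R, 1 <= R <= min(P, Q).
    alpha : float
        Penalty strength lambda (shared by both half-steps), on the
        per-subject deviance scale.
    gamma_init : "random" or (Q, R) array
        Initial outcome loadings Gamma(0). ``"random"`` draws standard
        normals with ``random_state``.
    tol : float
        Stopping threshold on the penalized-deviance improvement.
    max_iter : int
        Maximum alternating (outer) iterations.
    inner_tol, inner_max_iter
        KKT tolerance and IRLS round limit of each half-step solver.
    rebalance : bool
        If True, rescale each active column r by c_r =
        sqrt(|gamma_r|_1 / |alpha_r|_1) after every full iteration. Leaves B
        and the likelihood unchanged and never increases the penalty term;
        off by default so the alternating scheme runs verbatim.
    random_state : int or None
        Seed for the random Gamma(0).

    Attributes
    ----------
    A_ : (P, R) predictor loadings.
    Gamma_ : (Q, R) outcome loadings.
    B_ : (P, Q) coefficient matrix A_ @ Gamma_.T.
    objective_trace_ : per-iteration penalized deviance O(k).
    converged_ : whether the stopping rule (rather than the iteration cap or
        an inner-solver failure) ended the loop.
    effective_rank_, n_iter_, n_parameters_
    """

    def __init__(
        self,
        rank: int = 1,
        alpha: float = 0.0,
        gamma_init="random",
        tol: float = 1e-6,
        max_iter: int = 100,
        inner_tol: float = 1e-7,
        inner_max_iter: int = 100,
        rebalance: bool = False,
        random_state: int | None = None,
    ):
        self.rank = rank
        self.alpha = alpha
        self.gamma_init = gamma_init
        self.tol = tol
        self.max_iter = max_iter
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.rebalance = rebalance
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "rank": self.rank, "alpha": self.alpha, "gamma_init": self.gamma_init,
            "tol": self.tol, "max_iter": self.max_iter, "inner_tol": self.inner_tol,
            "inner_max_iter": self.inner_max_iter, "rebalance": self.rebalance,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SurvRRR":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for SurvRRR")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        return f"SurvRRR(rank={self.rank}, alpha={self.alpha})"

    # -- fitting -----------------------------------------------------------
    def _initial_gamma(self, Q: int) -> np.ndarray:
        if isinstance(self.gamma_init, str):
            if self.gamma_init != "random":
                raise ValueError(f"unknown gamma_init {self.gamma_init!r}")
            rng = np.random.default_rng(self.random_state)
            return rng.standard_normal((Q, self.rank))
        G = np.asarray(self.gamma_init, dtype=float)
        if G.shape != (Q, self.rank):
            raise ValueError(f"gamma_init must be (Q={Q}, R={self.rank})")
        if np.all(G == 0):
            raise ValueError("gamma_init must not be entirely zero")
        return G

    def fit(self, X, y=None) -> "SurvRRR":
        """Fit the model.

        ``X`` may be a :class:`MultiOutcomeSurvivalData` (``y`` ignored), or
        an (n, P) predictor matrix with ``y`` a long-format records
        DataFrame whose ``subject_id`` indexes rows of ``X`` (0..n-1).
        """
        data = _coerce_training_data(X, y)
        arr = data.to_arrays()
        P = arr.X.shape[1]
        Q = int(arr.row_stratum.max()) + 1
        if not 1 <= self.rank <= min(P, Q):
            raise ValueError(f"rank must satisfy 1 <= R <= min(P={P}, Q={Q})")
        gamma0 = self._initial_gamma(Q)
        fit = _alternate(
            arr, self.rank, self.alpha, gamma0,
            tol=self.tol, max_iter=self.max_iter,
            inner_tol=self.inner_tol, inner_max_iter=self.inner_max_iter,
            rebalance=self.rebalance,
            init_descriptor=f"gamma_init={self.gamma_init!r}, random_state={self.random_state}",
        )
        self.fit_result_ = fit
        self.A_ = fit.factorization.A
        self.Gamma_ = fit.factorization.Gamma
        self.B_ = fit.factorization.B
        self.objective_trace_ = fit.objective_trace
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iterations
        self.effective_rank_ = fit.effective_rank
        self.n_parameters_ = n_free_parameters(P, Q, self.rank)
        self.n_features_in_ = P
        self.n_outcomes_ = Q
        if isinstance(X, MultiOutcomeSurvivalData):
            self.feature_names_in_ = np.asarray(X.predictor_names, dtype=object)
            self.outcome_labels_ = list(X.outcome_labels)
        return self

    def transform(self, X) -> np.ndarray:
        """Rank scores alpha_r' x_i for new subjects, shape (n, R)."""
        self._check_fitted()
        if isinstance(X, MultiOutcomeSurvivalData):
            X = X.predictors.to_numpy(dtype=float)
        return rank_scores(Factorization(self.A_, self.Gamma_), np.asarray(X, dtype=float))

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def predict(self, X) -> np.ndarray:
        """Per-outcome linear predictors x_i' B, shape (n, Q)."""
        self._check_fitted()
        if isinstance(X, MultiOutcomeSurvivalData):
            X = X.predictors.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (n, P={self.n_features_in_})")
        return X @ self.B_

    def canonicalized(self) -> "SurvRRR":
        """Copy of the fitted estimator with (A_, Gamma_) in canonical form."""
        self._check_fitted()
        import copy

        out = copy.deepcopy(self)
        fact = canonicalize(Factorization(self.A_, self.Gamma_))
        out.A_, out.Gamma_, out.B_ = fact.A, fact.Gamma, fact.B
        return out

    def _check_fitted(self):
        if not hasattr(self, "B_"):
            raise AttributeError("this SurvRRR instance is not fitted yet")


def _coerce_training_data(X, y) -> MultiOutcomeSurvivalData:
    if isinstance(X, MultiOutcomeSurvivalData):
        return X
    if y is None:
        raise ValueError("y (long-format records) is required when X is a matrix")
    X = np.asarray(X, dtype=float)
    records = pd.DataFrame(y)
    pred = pd.DataFrame(X, index=pd.RangeIndex(len(X)))
    pred.index.name = "subject_id"
    return MultiOutcomeSurvivalData(records, pred)


def _alternate(
    arr: FitArrays,
    R: int,
    alpha: float,
    gamma0: np.ndarray,
    tol: float,
    max_iter: int,
    inner_tol: float,
    inner_max_iter: int,
    rebalance: bool,
    init_descriptor: str = "",
) -> SurvRRRFit:
    """Alternating A/Gamma estimation at fixed rank and penalty."""
    n = arr.X.shape[0]
    P = arr.X.shape[1]
    Q = int(arr.row_stratum.max()) + 1
    Gamma = gamma0.copy()
    A = np.zeros((P, R))
    trace: list[float] = []
    best: tuple[float, np.ndarray, np.ndarray] = (np.inf, A.copy(), Gamma.copy())
    converged = False
    res_a = res_g = None

    def objective(A_, G_, ll):
        pen = np.abs(A_).sum() + np.abs(G_).sum()
        return -2.0 * ll / n + 2.0 * alpha * pen

    k = 0
    for k in range(1, max_iter + 1):
        # A half-step
        prob_a = build_a_step_problem(arr, Gamma)
        res_a = fit_lasso_cox(prob_a, alpha, init=A.T.ravel(), tol=inner_tol,
                              max_iter=inner_max_iter)
        A = res_a.coef.reshape(R, P).T
        if np.all(A == 0):
            # penalty wiped out A: rank collapse to 0, B = 0
            O_k = objective(A, Gamma, res_a.log_partial_likelihood)
            trace.append(O_k)
            if O_k < best[0]:
                best = (O_k, A.copy(), Gamma.copy())
            converged = True
            break
        # Gamma half-step
        prob_g = build_gamma_step_problem(arr, A)
        res_g = fit_lasso_cox(prob_g, alpha, init=Gamma.T.ravel(), tol=inner_tol,
                              max_iter=inner_max_iter)
        Gamma = res_g.coef.reshape(R, Q).T
        ll = res_g.log_partial_likelihood
        O_k = objective(A, Gamma, ll)
        trace.append(O_k)
        if O_k < best[0]:
            best = (O_k, A.copy(), Gamma.copy())
        if np.all(Gamma == 0):
            converged = True  # collapse: next A-step would be degenerate
            break
        if not (res_a.converged and res_g.converged):
            converged = False  # inner solver failure propagates, not raises
            break
        if k > 1:
            improvement = trace[-2] - trace[-1]
            if improvement < 0:  # numerical noise near the optimum
                converged = True
                break
            if improvement < tol:
                converged = True
                break
        if rebalance:
            a_l1 = np.abs(A).sum(axis=0)
            g_l1 = np.abs(Gamma).sum(axis=0)
            live = (a_l1 > 0) & (g_l1 > 0)
            c = np.ones(R)
            c[live] = np.sqrt(g_l1[live] / a_l1[live])
            A = A * c
            Gamma = Gamma / c

    _, A_best, G_best = best
    return SurvRRRFit(
        factorization=Factorization(A_best, G_best),
        alpha=alpha,
        objective_trace=trace,
        converged=converged,
        n_iterations=k,
        init_descriptor=init_descriptor,
        inner_results=(res_a, res_g),
    )


def fit_survrrr(
    data,
    R: int,
    alpha: float,
    gamma_init,
    tol: float = 1e-6,
    max_outer_iter: int = 100,
    rebalance: bool = False,
    inner_tol: float = 1e-7,
    inner_max_iter: int = 100,
) -> SurvRRRFit:
    """Functional wrapper over :class:`SurvRRR` returning a :class:`SurvRRRFit`."""
    est = SurvRRR(
        rank=R, alpha=alpha, gamma_init=gamma_init, tol=tol, max_iter=max_outer_iter,
        inner_tol=inner_tol, inner_max_iter=inner_max_iter, rebalance=rebalance,
    )
    est.fit(data)
    return est.fit_result_
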