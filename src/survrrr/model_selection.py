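"""Penalty paths, out-of-sample deviance, and data-driven rank selection.

Out-of-sample fit is judged by the Verweij-van Houwelingen construction:
the log partial likelihood is evaluated at the trained coefficients on the
training set and on the full data (train and test combined), and the
difference is the test contribution. Scaled to a deviance,

    D_test = -2 * (l_full(B) - l_train(B)) / n_test .

Evaluating the difference rather than a test-only partial likelihood avoids
a predictive likelihood of zero when a test event falls at a time present in
no training risk set. ``n_test`` counts distinct test subjects by default
(the unit of the train/test split); a flag switches to long-format rows.

The lambda path is fitted from large to small penalties with warm starts:
Gamma(0) for the next lambda is the previous solution plus a small constant
epsilon added to every entry, which revives all-zero columns so the fit can
escape a collapsed smaller-rank solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cox import StratifiedCoxProblem, fit_lasso_cox, lambda_max as _kkt_lambda_max
from .data import MultiOutcomeSurvivalData, combine
from .estimator import SurvRRRFit, _alternate, build_a_step_problem
from .factorization import Factorization

__all__ = [
    "PathConfig",
    "PathEntry",
    "PathResult",
    "RankSelection",
    "test_deviance",
    "null_deviances",
    "generate_lambda_sequence",
    "fit_path",
    "select_rank",
    "flag_divergent_runs",
    "svd_gamma_init",
]


def _loglik_at_B(data: MultiOutcomeSurvivalData, B: np.ndarray) -> float:
    arr = data.to_arrays()
    eta = np.einsum("ij,ji->i", arr.X[arr.row_subject], B[:, arr.row_stratum])
    prob = StratifiedCoxProblem(
        strata=arr.row_stratum, entry=arr.entry, exit=arr.exit, status=arr.status,
        design=np.zeros((len(eta), 0)), n_norm=arr.X.shape[0],
    )
    return prob.loglik(eta)


def _extract_B(fit) -> np.ndarray:
    if isinstance(fit, SurvRRRFit):
        return fit.factorization.B
    if isinstance(fit, Factorization):
        return fit.B
    if hasattr(fit, "B_"):
        return fit.B_
    return np.asarray(fit, dtype=float)


def test_deviance(
    fit,
    train: MultiOutcomeSurvivalData,
    test: MultiOutcomeSurvivalData,
    normalization: str = "subjects",
) -> float:
    """Verweij-van Houwelingen deviance of ``fit`` on the test set.

    ``fit`` may be a :class:`SurvRRRFit`, a :class:`Factorization`, a fitted
    estimator, or a raw (P, Q) coefficient matrix; the penalty plays no role
    here. ``normalization`` is ``"subjects"`` (default) or ``"rows"``.
    """
    B = _extract_B(fit)
    if test.n_rows == 0 or test.n_subjects == 0:
        raise ValueError("test set is empty")
    full = combine(train, test)
    ll_full = _loglik_at_B(full, B)
    ll_train = _loglik_at_B(train, B)
    if normalization == "subjects":
        n_test = test.n_subjects
    elif normalization == "rows":
        n_test = test.n_rows
    else:
        raise ValueError("normalization must be 'subjects' or 'rows'")
    return -2.0 * (ll_full - ll_train) / n_test


def null_deviances(
    train: MultiOutcomeSurvivalData,
    test: MultiOutcomeSurvivalData,
    normalization: str = "subjects",
) -> tuple[float, float]:
    """(train, test) deviances of the null model B = 0."""
    B0 = np.zeros((train.n_predictors, train.n_outcomes))
    n_train = train.n_subjects if normalization == "subjects" else train.n_rows
    train_null = -2.0 * _loglik_at_B(train, B0) / n_train
    return train_null, test_deviance(B0, train, test, normalization)


def generate_lambda_sequence(
    data: MultiOutcomeSurvivalData,
    R: int,
    gamma_init: np.ndarray,
    n_lambda: int = 10,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Log-spaced decreasing penalty sequence starting at lambda_max.

    lambda_max is the smallest penalty at which the first A half-step (at
    ``gamma_init``, A = 0) is all zero, read off the KKT threshold
    ``max_k |grad_k l(0)| / n_norm``.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    prob = build_a_step_problem(data, np.asarray(gamma_init, dtype=float))
    lam_max = _kkt_lambda_max(prob)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


@dataclass
class PathConfig:
    """Configuration of one lambda-path run at fixed rank."""

    rank: int = 1
    lambdas: np.ndarray | None = None       # explicit decreasing sequence, or:
    n_lambda: int = 10
    lambda_min_ratio: float = 0.01
    epsilon: float = 1e-2                   # warm-start perturbation, standardized scale
    init: str = "random"                    # "random" or "svd" Gamma(0) for the first lambda
    random_state: int | None = None
    tol: float = 1e-6
    max_iter: int = 300
    inner_tol: float = 1e-7
    inner_max_iter: int = 100
    rebalance: bool = False
    backward_pass: bool = True              # refine each lambda from its smaller neighbor

    def __post_init__(self):
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            if lam.ndim != 1 or len(lam) < 1 or np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
                raise ValueError("lambdas must be strictly decreasing and positive")
            self.lambdas = lam
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class PathEntry:
    lam: float
    fit: SurvRRRFit | None
    train_pen_deviance: float
    test_deviance: float
    converged: bool
    effective_rank: int
    fitted: bool = True


@dataclass
class PathResult:
    rank: int
    entries: list[PathEntry]
    config: PathConfig
    run_label: str = ""

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([e.lam for e in self.entries])

    def best_entry(self) -> PathEntry:
        """Converged entry with minimal test deviance."""
        ok = [e for e in self.entries if e.fitted and e.converged]
        if not ok:
            raise ValueError("no converged fit on this path")
        return min(ok, key=lambda e: e.test_deviance)


def svd_gamma_init(
    train: MultiOutcomeSurvivalData, R: int, penalty_scale: float = 0.1
) -> np.ndarray:
    """Gamma(0) from an SVD of stacked single-outcome lasso fits.

    Each outcome is fitted on its own (at ``penalty_scale`` times its own
    KKT lambda_max), the coefficient vectors are stacked into a provisional
    B, and Gamma(0) is taken from its top-R right singular vectors scaled by
    the square roots of the singular values. Falls back to all ones if the
    provisional B is entirely zero.
    """
    arr = train.to_arrays()
    Q = train.n_outcomes
    B = np.zeros((train.n_predictors, Q))
    for q in range(Q):
        rows = arr.row_stratum == q
        prob = StratifiedCoxProblem(
            strata=arr.row_stratum[rows], entry=arr.entry[rows], exit=arr.exit[rows],
            status=arr.status[rows], design=arr.X[arr.row_subject[rows]],
            n_norm=arr.X.shape[0],
        )
        lam_q = _kkt_lambda_max(prob) * penalty_scale
        B[:, q] = fit_lasso_cox(prob, lam_q).coef
    if np.all(B == 0):
        return np.ones((Q, R))
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    G = Vt[:R].T * np.sqrt(s[:R])
    if np.all(G == 0):
        return np.ones((Q, R))
    return G


def _perturbed_warm_start(Ghat: np.ndarray, fallback: np.ndarray, epsilon: float) -> np.ndarray:
    """Gamma-hat plus epsilon on live columns; dead columns take ``fallback``."""
    nxt = Ghat + epsilon
    dead = np.abs(Ghat).sum(axis=0) == 0
    nxt[:, dead] = fallback[:, dead]
    return nxt


def fit_path(
    train: MultiOutcomeSurvivalData,
    test: MultiOutcomeSurvivalData,
    config: PathConfig,
) -> PathResult:
    """Fit the decreasing-lambda path with warm starts.

    The first lambda uses the configured Gamma(0); every subsequent fit
    starts from the previous Gamma-hat with ``epsilon`` added to every
    entry, which revives collapsed columns. A column of Gamma-hat that is
    entirely zero carries no scale information, so it inherits its column of
    the current initialization instead of restarting at bare epsilon:
    otherwise one full collapse would shrink the warm start to the epsilon
    scale and the penalty at which the model re-activates would depend on
    the collapse history rather than on the data. If a fit fails to
    converge the remaining (smaller) lambdas are skipped and flagged,
    mirroring the small-penalty failure regime of the alternating scheme.

    The all-zero factorization is a stationary trap of the alternating
    scheme: for moderate penalties the A half-step can produce a weak A
    whose rank scores are then too small for any Gamma coefficient to
    survive its own threshold, even though a self-sustaining nonzero
    optimum exists. The forward (large-to-small lambda) sweep can therefore
    report collapsed fits in a region where the backward neighbor is
    active. With ``backward_pass`` (default on), each lambda is refitted
    warm-started from the solution at the next-smaller lambda, and the fit
    with the better *training* objective is kept — a pure multi-start
    refinement of the penalized optimization; the test deviance plays no
    role in the choice.
    """
    R = config.rank
    if config.init == "random":
        rng = np.random.default_rng(config.random_state)
        gamma0 = rng.standard_normal((train.n_outcomes, R))
    elif config.init == "svd":
        gamma0 = svd_gamma_init(train, R)
    else:
        raise ValueError(f"unknown init {config.init!r}")
    lambdas = (
        config.lambdas
        if config.lambdas is not None
        else generate_lambda_sequence(train, R, gamma0, config.n_lambda, config.lambda_min_ratio)
    )
    arr = train.to_arrays()
    entries: list[PathEntry] = []
    gamma_start = gamma0
    failed = False
    for lam in lambdas:
        if failed:
            entries.append(PathEntry(float(lam), None, np.nan, np.nan, False, 0, fitted=False))
            continue
        fit = _alternate(
            arr, R, float(lam), gamma_start,
            tol=config.tol, max_iter=config.max_iter,
            inner_tol=config.inner_tol, inner_max_iter=config.inner_max_iter,
            rebalance=config.rebalance,
            init_descriptor=f"{config.init}, random_state={config.random_state}, lambda={lam:g}",
        )
        dev = test_deviance(fit, train, test)
        entries.append(
            PathEntry(
                lam=float(lam), fit=fit, train_pen_deviance=fit.objective,
                test_deviance=dev, converged=fit.converged,
                effective_rank=fit.effective_rank,
            )
        )
        if not fit.converged:
            failed = True
            continue
        gamma_start = _perturbed_warm_start(fit.factorization.Gamma, gamma_start, config.epsilon)

    if config.backward_pass:
        for j in range(len(entries) - 2, -1, -1):
            e, nxt_e = entries[j], entries[j + 1]
            if not (e.fitted and nxt_e.fitted and nxt_e.fit.converged):
                continue
            Gnxt = nxt_e.fit.factorization.Gamma
            if np.all(Gnxt == 0):
                continue
            refit = _alternate(
                arr, R, e.lam,
                _perturbed_warm_start(Gnxt, Gnxt + config.epsilon, config.epsilon),
                tol=config.tol, max_iter=config.max_iter,
                inner_tol=config.inner_tol, inner_max_iter=config.inner_max_iter,
                rebalance=config.rebalance,
                init_descriptor=f"backward from lambda={nxt_e.lam:g}",
            )
            better = refit.converged and (
                refit.objective < e.train_pen_deviance - 1e-12 or not e.converged
            )
            if better:
                entries[j] = PathEntry(
                    lam=e.lam, fit=refit, train_pen_deviance=refit.objective,
                    test_deviance=test_deviance(refit, train, test),
                    converged=refit.converged, effective_rank=refit.effective_rank,
                )
    return PathResult(
        rank=R, entries=entries, config=config,
        run_label=f"R={R}, init={config.init}, seed={config.random_state}",
    )


@dataclass
class RankSelection:
    """Outcome of comparing candidate ranks on the test criterion."""

    candidates: dict  # rank -> (best_lambda, best_test_deviance)
    selected_rank: int
    selected_fit: SurvRRRFit
    selected_lambda: float


def select_rank(results: dict[int, list[PathResult]], tie_tol: float = 1e-3) -> RankSelection:
    """Pick the rank whose best converged fit has the lowest test deviance.

    ``results`` maps each candidate rank to its path runs. For each rank the
    best fit is the converged entry (across runs) with minimal test
    deviance; the selected rank attains the overall minimum, ties broken
    toward the smaller rank (parsimony). Two ranks whose best deviances lie
    within ``tie_tol`` of each other count as tied: a higher-rank model
    always contains the lower-rank one, so on data of lower true rank the
    two best fits are the same model up to fitting noise, and a strict
    floating-point comparison would pick a rank at random. ``tie_tol`` is on
    the per-subject deviance scale, commensurate with the default fit
    tolerances. Ranks without any converged fit are dropped with a warning;
    if none remain an error is raised.
    """
    if not results:
        raise ValueError("no candidate ranks supplied")
    per_rank: dict[int, tuple[float, float, SurvRRRFit]] = {}
    for R in sorted(results):
        best = None
        for run in results[R]:
            for e in run.entries:
                if e.fitted and e.converged and np.isfinite(e.test_deviance):
                    if best is None or e.test_deviance < best[1]:
                        best = (e.lam, e.test_deviance, e.fit)
        if best is None:
            warnings.warn(f"rank {R}: no converged fit; dropped from selection", UserWarning)
        else:
            per_rank[R] = best
    if not per_rank:
        raise ValueError("no converged fit for any candidate rank")
    dev_min = min(v[1] for v in per_rank.values())
    selected = min(R for R, v in per_rank.items() if v[1] <= dev_min + tie_tol)
    lam, dev, fit = per_rank[selected]
    return RankSelection(
        candidates={R: (v[0], v[1]) for R, v in per_rank.items()},
        selected_rank=selected,
        selected_fit=fit,
        selected_lambda=lam,
    )


def flag_divergent_runs(runs: list[PathResult], tol: float = 1e-6) -> list[bool]:
    """Mark runs whose train-deviance curve departs from the pointwise
    minimum across runs by more than 10 x tol at any shared lambda."""
    by_lam: dict[float, list[float]] = {}
    for run in runs:
        for e in run.entries:
            if e.fitted:
                by_lam.setdefault(round(e.lam, 12), []).append(e.train_pen_deviance)
    mins = {lam: min(v) for lam, v in by_lam.items() if len(v) > 1}
    flags = []
    for run in runs:
        bad = any(
            e.fitted
            and round(e.lam, 12) in mins
            and e.train_pen_deviance > mins[round(e.lam, 12)] + 10 * tol
            for e in run.entries
        )
        flags.append(bad)
    return flags
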