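import numpy as np
import pandas as pd
import pytest

import survrrr as s
from survrrr.cox import StratifiedCoxProblem


def naive_stratified_loglik(strata, entry, exit_, status, eta):
    """Double-loop Breslow log partial likelihood (independent oracle).

    For every event, the denominator sums exp(eta) over subjects of the same
    stratum whose counting-process interval covers the event time.
    """
    strata = np.asarray(strata)
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    status = np.asarray(status)
    eta = np.asarray(eta, dtype=float)
    ll = 0.0
    for i in range(len(eta)):
        if status[i] != 1:
            continue
        t = exit_[i]
        denom = 0.0
        for j in range(len(eta)):
            if strata[j] == strata[i] and entry[j] < t <= exit_[j]:
                denom += np.exp(eta[j])
        ll += eta[i] - np.log(denom)
    return ll


def random_cox_instance(rng, n_max=30, n_strata=3, K=2, with_ties=True):
    """Small random stratified instance with delayed entry and (rounded) ties."""
    n = int(rng.integers(5, n_max + 1))
    strata = rng.integers(0, n_strata, n)
    entry = np.round(rng.uniform(0, 2, n), 1)
    gap = np.round(rng.uniform(0.1, 3, n), 1) if with_ties else rng.uniform(0.1, 3, n)
    exit_ = entry + gap + 0.05
    status = rng.integers(0, 2, n)
    design = rng.standard_normal((n, K))
    return StratifiedCoxProblem(strata, entry, exit_, status, design, n_norm=n)


def toy_data(records_rows, predictors=None, outcome_labels=None):
    """Build a MultiOutcomeSurvivalData from a list of record tuples
    (subject_id, outcome, entry, exit, status)."""
    rec = pd.DataFrame(records_rows, columns=["subject_id", "outcome", "entry", "exit", "status"])
    if predictors is None:
        ids = rec["subject_id"].unique()
        rng = np.random.default_rng(0)
        predictors = pd.DataFrame(
            {"subject_id": ids, "x1": rng.standard_normal(len(ids)), "x2": rng.standard_normal(len(ids))}
        )
    return s.MultiOutcomeSurvivalData(rec, predictors, outcome_labels)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small, quick synthetic data set (standardized), with its truth."""
    cfg = s.GeneratorConfig(n_subjects=300, P=6, Q=3, R_true=1, sparsity=0.3, seed=7)
    data, truth = s.generate(cfg)
    data, _ = s.standardize(data)
    return data, truth


def run_recovery_replicate(seed, n_lambda=10, min_ratio=1e-3, ranks=(1, 2)):
    """One replicate of the default recovery experiment.

    Generates the default scenario, splits in half by subject, standardizes
    each split on itself, fits one shared log-spaced lambda path per
    candidate rank (shared grid so ranks are directly comparable), and
    selects the rank with the lowest test deviance.
    """
    cfg = s.GeneratorConfig(seed=seed)
    data, truth = s.generate(cfg)
    train, test = s.split_train_test(data, 0.5, seed=seed)
    train, _ = s.standardize(train)
    test, _ = s.standardize(test)
    rng = np.random.default_rng(seed)
    g0 = rng.standard_normal((cfg.Q, 1))
    lams = s.generate_lambda_sequence(train, 1, g0, n_lambda=n_lambda, min_ratio=min_ratio)
    results = {}
    for R in ranks:
        pc = s.PathConfig(rank=R, lambdas=lams, random_state=seed)
        results[R] = [s.fit_path(train, test, pc)]
    selection = s.select_rank(results)
    Xt = test.predictors.to_numpy()
    est = s.rank_scores(s.canonicalize(selection.selected_fit.factorization), Xt)[:, 0]
    orc = s.oracle_rank_score(truth, Xt)[:, 0]
    corr = float(np.corrcoef(est, orc)[0, 1])
    return {
        "selection": selection,
        "results": results,
        "holdout_corr": corr,
        "truth": truth,
        "train": train,
        "test": test,
    }


@pytest.fixture(scope="session")
def recovery_replicates():
    """Ten seeded replicates of the default recovery experiment (shared by
    the rank-selection and overfitting-reversal checks)."""
    return {seed: run_recovery_replicate(seed) for seed in range(1, 11)}
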