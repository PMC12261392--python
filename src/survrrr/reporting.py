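"""Reporting surfaces: deviance tables, score comparisons, biplot coordinates,
and JSON/CSV serialization of fits."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .estimator import SurvRRRFit
from .factorization import Factorization, canonicalize
from .model_selection import PathResult

__all__ = [
    "deviance_table",
    "compare_scores",
    "biplot_coordinates",
    "fit_to_json",
    "fit_from_json",
    "export_factorization_csv",
]


def deviance_table(runs: list[PathResult]) -> pd.DataFrame:
    """Long table of per-lambda results across runs, one row per (run, lambda).

    Columns: run, R, lambda, train_pen_deviance, test_deviance, converged,
    effective_rank — the inputs of the deviance-path plots.
    """
    rows = []
    for i, run in enumerate(runs):
        for e in run.entries:
            rows.append(
                {
                    "run": run.run_label or str(i),
                    "R": run.rank,
                    "lambda": e.lam,
                    "train_pen_deviance": e.train_pen_deviance,
                    "test_deviance": e.test_deviance,
                    "converged": bool(e.converged) and e.fitted,
                    "effective_rank": e.effective_rank,
                }
            )
    return pd.DataFrame(rows)


def compare_scores(scores_a, scores_b, label_a: str = "score_a", label_b: str = "score_b"):
    """Pearson correlation between two per-subject scores plus a paired table.

    Returns ``(r, table)`` where ``table`` has one row per subject, ready for
    scatter plotting. Both inputs must have equal length >= 3 and nonzero
    variance.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired scores")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance score vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, pd.DataFrame({label_a: a, label_b: b})


def biplot_coordinates(fact: Factorization, top_k: int = 20,
                       predictor_names=None, outcome_labels=None) -> pd.DataFrame:
    """Coordinates for a rank-2 biplot of a factorization.

    The factorization is canonicalized first; the first two canonical
    columns give predictor loadings (the ``top_k`` predictors by loading
    norm) and outcome loadings. Requires effective rank >= 2.
    """
    if fact.effective_rank < 2:
        raise ValueError("biplot requires effective rank >= 2")
    cf = canonicalize(fact)
    A2 = cf.A[:, :2]
    G2 = cf.Gamma[:, :2]
    pnames = list(predictor_names) if predictor_names is not None else [f"x{p}" for p in range(cf.P)]
    onames = list(outcome_labels) if outcome_labels is not None else [f"outcome_{q}" for q in range(cf.Q)]
    pn = np.linalg.norm(A2, axis=1)
    keep = np.argsort(-pn, kind="stable")[: min(top_k, cf.P)]
    rows = [
        {"label": pnames[p], "kind": "predictor", "dim1": A2[p, 0], "dim2": A2[p, 1]}
        for p in keep
    ]
    rows += [
        {"label": onames[q], "kind": "outcome", "dim1": G2[q, 0], "dim2": G2[q, 1]}
        for q in range(cf.Q)
    ]
    return pd.DataFrame(rows)


def fit_to_json(fit: SurvRRRFit, path=None) -> dict:
    """Serialize a fit (factorization, penalty, trace, status) to JSON."""
    doc = {
        "A": fit.factorization.A.tolist(),
        "Gamma": fit.factorization.Gamma.tolist(),
        "B": fit.factorization.B.tolist(),
        "lambda": fit.alpha,
        "objective_trace": list(map(float, fit.objective_trace)),
        "converged": bool(fit.converged),
        "n_iterations": fit.n_iterations,
        "effective_rank": fit.effective_rank,
        "init": fit.init_descriptor,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc


def fit_from_json(path) -> SurvRRRFit:
    with open(path) as fh:
        doc = json.load(fh)
    return SurvRRRFit(
        factorization=Factorization(np.array(doc["A"]), np.array(doc["Gamma"])),
        alpha=doc["lambda"],
        objective_trace=doc["objective_trace"],
        converged=doc["converged"],
        n_iterations=doc["n_iterations"],
        init_descriptor=doc.get("init", ""),
    )


def export_factorization_csv(fact: Factorization, out_dir, predictor_names=None,
                             outcome_labels=None) -> None:
    """Write A.csv (P x R), Gamma.csv (Q x R) and B.csv (P x Q, labeled)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pnames = list(predictor_names) if predictor_names is not None else [f"x{p}" for p in range(fact.P)]
    onames = list(outcome_labels) if outcome_labels is not None else [f"outcome_{q}" for q in range(fact.Q)]
    rcols = [f"r{r + 1}" for r in range(fact.R)]
    pd.DataFrame(fact.A, index=pnames, columns=rcols).to_csv(out / "A.csv", float_format="%.17g")
    pd.DataFrame(fact.Gamma, index=onames, columns=rcols).to_csv(out / "Gamma.csv", float_format="%.17g")
    pd.DataFrame(fact.B, index=pnames, columns=onames).to_csv(out / "B.csv", float_format="%.17g")
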