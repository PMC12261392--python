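"""Low-rank factorization B = A @ Gamma.T and its canonical form.

The decomposition of a P x Q coefficient matrix into predictor loadings
A (P x R) and outcome loadings Gamma (Q x R) is unique under an l1 penalty
only up to a permutation of the columns, a joint sign flip of a column pair,
and a scaling (c*alpha_r, gamma_r/c). ``canonicalize`` fixes all three:
columns are rebalanced to equal l1 norms (the penalty-minimizing scaling,
c* = sqrt(|gamma|_1 / |alpha|_1)), sorted by decreasing outcome-loading
norm, and sign-flipped so each column's largest-|.| outcome loading is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Factorization", "canonicalize", "rank_scores", "n_free_parameters"]


@dataclass(frozen=True)
class Factorization:
    """The pair (A: P x R, Gamma: Q x R) with derived B = A @ Gamma.T."""

    A: np.ndarray
    Gamma: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        G = np.asarray(self.Gamma, dtype=float)
        if A.ndim != 2 or G.ndim != 2 or A.shape[1] != G.shape[1]:
            raise ValueError("A and Gamma must be 2-D with the same number of columns")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Gamma", G)

    @property
    def P(self) -> int:
        return self.A.shape[0]

    @property
    def Q(self) -> int:
        return self.Gamma.shape[0]

    @property
    def R(self) -> int:
        return self.A.shape[1]

    @property
    def B(self) -> np.ndarray:
        return self.A @ self.Gamma.T

    @property
    def effective_rank(self) -> int:
        """Columns r where neither A[:, r] nor Gamma[:, r] is all zero."""
        a = np.abs(self.A).sum(axis=0) > 0
        g = np.abs(self.Gamma).sum(axis=0) > 0
        return int(np.sum(a & g))

    @property
    def penalty(self) -> float:
        """l1 penalty term |A|_1 + |Gamma|_1."""
        return float(np.abs(self.A).sum() + np.abs(self.Gamma).sum())


def canonicalize(fact: Factorization) -> Factorization:
    """Canonical representative of the trivial-transformation equivalence class.

    B is preserved exactly; the operation is idempotent and never increases
    the penalty term (c|a|_1 + |g|_1/c is minimized at c* = sqrt(|g|_1/|a|_1),
    giving equal l1 norms). Columns with an all-zero factor on either side are
    placed last, untouched, preserving their relative order.
    """
    A = fact.A.copy()
    G = fact.Gamma.copy()
    a_l1 = np.abs(A).sum(axis=0)
    g_l1 = np.abs(G).sum(axis=0)
    live = (a_l1 > 0) & (g_l1 > 0)
    for r in np.flatnonzero(live):
        c = np.sqrt(g_l1[r] / a_l1[r])
        A[:, r] *= c
        G[:, r] /= c
        top = np.argmax(np.abs(G[:, r]))
        if G[top, r] < 0:
            A[:, r] *= -1.0
            G[:, r] *= -1.0
    live_idx = np.flatnonzero(live)
    dead_idx = np.flatnonzero(~live)
    g_norm = np.linalg.norm(G[:, live_idx], axis=0)
    a_norm = np.linalg.norm(A[:, live_idx], axis=0)
    # decreasing |gamma_r|_2, ties by decreasing |alpha_r|_2; stable
    order = np.lexsort((-a_norm, -g_norm))
    perm = np.concatenate([live_idx[order], dead_idx]).astype(int)
    return Factorization(A[:, perm], G[:, perm])


def rank_scores(fact: Factorization, X: np.ndarray) -> np.ndarray:
    """Per-subject latent scores alpha_r' x_i, shape (n, R)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fact.P:
        raise ValueError(f"predictors must be (n, P={fact.P})")
    return X @ fact.A


def n_free_parameters(P: int, Q: int, R: int) -> int:
    """Free parameters of a rank-R coefficient matrix: R(P + Q - R)."""
    if not 1 <= R <= min(P, Q):
        raise ValueError("requires 1 <= R <= min(P, Q)")
    return R * (P + Q - R)
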