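"""The adaptive Fisher (AF) p-value combination operator.

Given a stack of p-value vectors — row 0 observed, rows 1..B from
permutation replicates — the operator combines each row's d p-values
adaptively:

1. transform ``R = -log p`` and weight ``W = omega * R``;
2. sort each row's W descending and form partial sums ``S_k`` of the k
   largest terms;
3. reference every ``S_k`` against the whole stack:
   ``P_Sk(b) = (1/(B+1)) * #{b*: S_k(b*) >= S_k(b)}`` (self included, so
   the floor is 1/(B+1));
4. take ``T_AF(b) = min_k P_Sk(b)`` and reference it the same way:
   ``P_AF(b) = (1/(B+1)) * #{b*: T_AF(b*) <= T_AF(b)}``.

``P_AF(0)`` is the combined p-value; the full vector ``P_AF(b)`` can serve
as a column of a higher-level ensemble, which is how one-sided tests are
merged into two-sided ones and the four abundance measures into the final
community-level p-value.  The minimizing prefix length h yields a heuristic
selection: the h taxa with the largest observed weighted -log p.  That
selection is exploratory and should not be over-interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["AFCombination", "af_combine", "select_taxa"]


@dataclass
class AFCombination:
    """Full output of the AF operator on a (B+1) x d p-value stack."""

    W: np.ndarray          # (B+1, d) weighted -log p
    order0: np.ndarray     # descending-W column order for the observed row
    S: np.ndarray          # (B+1, d) row-wise sorted partial sums
    P_Sk: np.ndarray       # (B+1, d) permutation-referenced prefix p-values
    T_AF: np.ndarray       # (B+1,) min_k P_Sk per row
    P_AF: np.ndarray       # (B+1,) permutation p-value of T_AF per row
    h: int                 # minimizing prefix length for the observed row
    B: int

    @property
    def p_value(self) -> float:
        """The combined p-value (observed row)."""
        return float(self.P_AF[0])


def af_combine(pvals: np.ndarray, omega: Optional[np.ndarray] = None) -> AFCombination:
    """Apply the AF operator ``AF{p; omega}`` to a p-value stack.

    ``pvals`` has B+1 rows (observed first) and d columns, entries in
    (0, 1]; ``omega`` is an optional non-negative weight vector of length d
    (defaults to ones).  Requires B >= 1.
    """
    P = np.asarray(pvals, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a 2-D stack with at least 2 rows (B >= 1)")
    if P.shape[1] < 1:
        raise ValueError("no testable OTUs (empty p-value ensemble)")
    if np.any(P <= 0) or np.any(P > 1) or not np.all(np.isfinite(P)):
        raise ValueError("p-values must lie in (0, 1]")
    nrow, d = P.shape
    B = nrow - 1
    if omega is None:
        omega = np.ones(d)
    else:
        omega = np.asarray(omega, dtype=float)
        if omega.shape != (d,):
            raise ValueError("weight vector length must match the number of columns")
        if np.any(omega < 0) or not np.all(np.isfinite(omega)):
            raise ValueError("weights must be finite and >= 0")

    W = omega * -np.log(P)
    # stable descending sort: ties broken by original column index
    order0 = np.argsort(-W[0], kind="stable")
    S = np.cumsum(-np.sort(-W, axis=1), axis=1)
    # count of rows with S_k >= this row's S_k, ties included (max-rank of -S)
    P_Sk = rankdata(-S, method="max", axis=0) / (B + 1)
    T_AF = P_Sk.min(axis=1)
    P_AF = rankdata(T_AF, method="max") / (B + 1)
    h = int(np.argmin(P_Sk[0]) + 1)  # argmin returns the smallest tied k
    return AFCombination(
        W=W, order0=order0, S=S, P_Sk=P_Sk, T_AF=T_AF, P_AF=P_AF, h=h, B=B
    )


def select_taxa(comb: AFCombination, labels: Sequence[str]) -> list:
    """The h taxa with the largest observed weighted -log p, in W order.

    Heuristic by construction: the minimizer points at the prefix of the
    sorted weight sequence that drives the AF statistic, not at a set with
    controlled error rates.
    """
    if len(labels) != comb.W.shape[1]:
        raise ValueError("label count must match the number of columns")
    return [labels[j] for j in comb.order0[: comb.h]]
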