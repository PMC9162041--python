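"""Community-level association test: the full MiAF pipeline.

The test aggregates per-taxon score-test p-values into a single
community-level p-value through three nested applications of the adaptive
Fisher (AF) operator, sharing one residual-permutation null throughout:

level 1   for each abundance measure (u, w, .5, a) and each tail
          (lower/upper), combine the d per-taxon one-sided p-values with
          the measure's UniFrac-like weights;
level 2   per measure, combine the two one-sided community p-values into a
          two-sided one (unweighted);
level 3   combine the four two-sided p-values into the final P_MiAF
          (unweighted).

The null is built by residualizing each abundance column on the covariates
and permuting the residual rows B times; the same row permutations are
applied to every measure so that the cross-measure and cross-tail
correlation survives into the upper combination levels.  The observed data
always occupy index b = 0, giving every permutation p-value a floor of
1/(B+1).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .af_core import AFCombination, af_combine, select_taxa
from .score_tests import (
    NullModelFit,
    ResidualizedAbundance,
    P_CEIL,
    P_FLOOR,
    V_TOL,
    fit_null_model,
    residualize,
)
from .tree_abundance import (
    MEASURES,
    PhyloTree,
    build_extended_table,
    make_representation,
    relative_abundance,
)

__all__ = [
    "PermutationPlan",
    "MeasureTestResult",
    "MiAFResult",
    "permute_residuals",
    "run_measure_test",
    "run_miaf",
]


@dataclass
class PermutationPlan:
    """B seeded row-permutations of the n samples."""

    B: int
    seed: int
    perms: np.ndarray  # (B, n) permutation index arrays

    @classmethod
    def from_seed(cls, n: int, B: int, seed: int) -> "PermutationPlan":
        if B < 1:
            raise ValueError("need at least one permutation (B >= 1)")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(B)])
        return cls(B=B, seed=seed, perms=perms)

    @property
    def n(self) -> int:
        return self.perms.shape[1]


def permute_residuals(res: ResidualizedAbundance, plan: PermutationPlan) -> List[np.ndarray]:
    """The B row-permuted copies of the residual matrix, in plan order."""
    Mt = res.resid
    if Mt.shape[0] != plan.n:
        raise ValueError("permutation plan size does not match residual rows")
    return [Mt[p] for p in plan.perms]


def _scatter_stack(vec: np.ndarray, plan: PermutationPlan) -> np.ndarray:
    """Column b+1 holds ``vec`` aligned to the rows of the b-th permuted
    residual matrix, so that ``Mt.T @ out`` scores all replicates at once."""
    n = vec.size
    out = np.empty((n, plan.B + 1))
    out[:, 0] = vec
    cols = np.arange(1, plan.B + 1)[:, None]
    out[plan.perms, cols] = vec[None, :]
    return out


@dataclass
class MeasureTestResult:
    """Level-1 output for one abundance measure: both tails, full stacks."""

    kind: str
    lower: AFCombination
    upper: AFCombination
    kept_labels: List[str]
    removed_labels: List[str]
    omega: np.ndarray  # weights of the kept columns


def run_measure_test(
    repr_,  # AbundanceRepresentation
    null_fit: NullModelFit,
    plan: PermutationPlan,
    Z=None,
    _stacks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> MeasureTestResult:
    """Score one abundance measure across the observed data and all
    permutation replicates, then AF-combine each tail.

    Returns the lower- and upper-tail AF combinations whose ``P_AF``
    vectors (length B+1) feed the next combination level.
    """
    res = residualize(repr_.M, Z)
    Mt = res.resid
    if _stacks is None:
        _stacks = (
            _scatter_stack(null_fit.resid, plan),
            _scatter_stack(null_fit.var_weights, plan),
        )
    Rmat, Vmat = _stacks
    U = Mt.T @ Rmat              # (d, B+1)
    V = (Mt * Mt).T @ Vmat       # (d, B+1)
    kept = V[:, 0] > V_TOL
    if not np.any(kept):
        raise ValueError(f"all taxa removed (zero score variance) for measure {repr_.kind!r}")
    U, V = U[kept], V[kept]
    U_std = U / np.sqrt(V)
    p_lower = np.clip(norm.cdf(U_std), P_FLOOR, P_CEIL).T   # (B+1, d)
    p_upper = np.clip(norm.sf(U_std), P_FLOOR, P_CEIL).T
    omega = repr_.omega[kept]
    labels = np.asarray(repr_.col_labels, dtype=object)
    return MeasureTestResult(
        kind=repr_.kind,
        lower=af_combine(p_lower, omega),
        upper=af_combine(p_upper, omega),
        kept_labels=list(labels[kept]),
        removed_labels=list(labels[~kept]),
        omega=omega,
    )


@dataclass
class MiAFResult:
    """The full hierarchy of component p-values plus taxon selections."""

    p_values: Dict[str, float]
    p_final: float
    alpha: float
    significant: bool
    selected: Dict[str, List[dict]]     # "<measure>:<tail>" -> taxa records
    h: Dict[str, int]                   # "<measure>:<tail>" -> minimizer
    removed: Dict[str, List[str]]
    measures: Tuple[str, ...]
    B: int
    seed: int
    n: int
    runtime_s: float = 0.0


def _tail_key(kind: str, tail: str) -> str:
    return f"P_{kind}{tail[0]}"  # P_ul, P_.5u, ...


def run_miaf(
    Y,
    Z,
    counts,
    tree: PhyloTree,
    outcome_type: str = "binary",
    B: int = 10_000,
    seed: int = 0,
    measures: Sequence[str] = MEASURES,
    alpha: float = 0.05,
) -> MiAFResult:
    """Run the complete community-level association test.

    Parameters
    ----------
    Y : array-like
        Outcome vector (binary {0,1} or continuous), one entry per sample.
    Z : array-like or None
        Covariate matrix (n x c), or None for no adjustment.
    counts : pandas.DataFrame
        Sample-by-OTU leaf counts; columns must match the tree's leaves.
    tree : PhyloTree
        Rooted phylogeny with branch lengths.
    outcome_type : {"binary", "continuous"}
    B : int
        Number of residual permutations (default 10,000; 300-1,000 is
        adequate for simulation screening).
    seed : int
        Seed for the permutation plan.
    measures : subset of ("u", "w", ".5", "a")
        Abundance transforms to combine.
    alpha : float
        Significance level for the reported association call.
    """
    t0 = time.perf_counter()
    measures = tuple(measures)
    if not measures or any(m not in MEASURES for m in measures):
        raise ValueError(f"measures must be a non-empty subset of {MEASURES}")
    ext = build_extended_table(counts, tree)
    A = relative_abundance(ext)
    null_fit = fit_null_model(Y, Z, outcome_type)
    plan = PermutationPlan.from_seed(ext.n, B, seed)
    stacks = (
        _scatter_stack(null_fit.resid, plan),
        _scatter_stack(null_fit.var_weights, plan),
    )

    p_values: Dict[str, float] = {}
    selected: Dict[str, List[dict]] = {}
    h: Dict[str, int] = {}
    removed: Dict[str, List[str]] = {}
    level2_cols = []
    for kind in measures:
        repr_ = make_representation(A, kind)
        mt = run_measure_test(repr_, null_fit, plan, Z, _stacks=stacks)
        removed[kind] = mt.removed_labels
        for tail, comb in (("lower", mt.lower), ("upper", mt.upper)):
            key = _tail_key(kind, tail)
            p_values[key] = comb.p_value
            h[f"{kind}:{tail}"] = comb.h
            labels = select_taxa(comb, mt.kept_labels)
            W0 = comb.W[0]
            selected[f"{kind}:{tail}"] = [
                {"taxon": lab, "W": float(W0[comb.order0[r]]), "rank": r + 1}
                for r, lab in enumerate(labels)
            ]
        # level 2: two-sided combination of the two one-sided stacks
        two_sided = af_combine(np.column_stack([mt.lower.P_AF, mt.upper.P_AF]))
        p_values[f"P_MiAF_{kind}"] = two_sided.p_value
        level2_cols.append(two_sided.P_AF)

    final = af_combine(np.column_stack(level2_cols))
    p_values["P_MiAF"] = final.p_value
    return MiAFResult(
        p_values=p_values,
        p_final=final.p_value,
        alpha=alpha,
        significant=final.p_value < alpha,
        selected=selected,
        h=h,
        removed=removed,
        measures=measures,
        B=B,
        seed=seed,
        n=ext.n,
        runtime_s=time.perf_counter() - t0,
    )
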