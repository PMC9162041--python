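"""Synthetic microbiome communities, signals and simulation harness.

The generator emulates the ingredients of a covariate-adjusted microbiome
association study:

* a random rooted binary phylogeny (coalescent-style topology, exponential
  branch lengths) standing in for a real 16S tree;
* absolute OTU abundances from a Gaussian copula with zero-inflated
  log-normal marginals, read counts by multinomial sampling at a random
  (log-normal) sequencing depth;
* phylogenetically clustered association signals: outcomes generated from
  the standardized total absolute abundance of one k-medoids cluster of
  leaves plus covariates, through a logistic model for binary outcomes or
  a Gaussian model for continuous ones;
* a type-I-error / power harness that repeatedly simulates data, runs the
  community test and reports the empirical rejection rate.

The covariate Z1 is Bernoulli(0.5); Z2 is either independent standard
normal or deliberately confounded with the signal cluster
(Z2 = scale(cluster total) + N(0,1) noise), which is the regime where
covariate adjustment and residual permutation earn their keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, ndtri
from scipy.stats import norm

from .pipeline import run_miaf
from .tree_abundance import PhyloTree

__all__ = [
    "CommunityModel",
    "SignalConfig",
    "RejectionRateResult",
    "EFFECT_SIZE_PRESETS",
    "simulate_tree",
    "simulate_abundances",
    "cluster_otus",
    "scale",
    "simulate_outcome",
    "estimate_rejection_rate",
]

# effect-size grids used in the power study, per outcome type and
# covariate regime (the correlated regime doubles the independent one)
EFFECT_SIZE_PRESETS = {
    ("binary", "independent"): (0.6, 0.8, 1.2, 1.6, 2.0),
    ("binary", "correlated"): (1.2, 1.6, 2.4, 3.2, 4.0),
    ("continuous", "independent"): (0.2, 0.4, 0.6, 0.8, 1.0),
    ("continuous", "correlated"): (0.4, 0.8, 1.2, 1.6, 2.0),
}


def simulate_tree(q: int, seed: int, rate: float = 1.0) -> PhyloTree:
    """Random rooted binary tree with q labelled leaves.

    Topology by repeated random joins of active lineages; every edge gets
    an independent Exponential(rate) length.  Leaves are labelled
    ``OTU1..OTUq`` in tree order.
    """
    if q < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    children_tmp: dict = {i: [] for i in range(q)}
    bl_tmp: dict = {}
    active = list(range(q))
    next_id = q
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        children_tmp[next_id] = [a, b]
        bl_tmp[a] = float(rng.exponential(1.0 / rate))
        bl_tmp[b] = float(rng.exponential(1.0 / rate))
        active = [v for v in active if v not in (a, b)] + [next_id]
        next_id += 1
    root_tmp = active[0]

    # renumber to preorder with root at 0
    order = []
    stack = [root_tmp]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children_tmp[v]))
    new_id = {v: i for i, v in enumerate(order)}
    n_nodes = len(order)
    parent = np.full(n_nodes, -1, dtype=np.intp)
    bl = np.full(n_nodes, np.nan)
    children: list = [[] for _ in range(n_nodes)]
    labels: list = [None] * n_nodes
    for v in order:
        nv = new_id[v]
        for c in children_tmp[v]:
            parent[new_id[c]] = nv
            children[nv].append(new_id[c])
            bl[new_id[c]] = bl_tmp[c]
    # node indices are preorder, so index order of leaves is tree order
    li = 0
    for v in range(n_nodes):
        if not children[v]:
            li += 1
            labels[v] = f"OTU{li}"
    return PhyloTree(parent=parent, branch_length=bl, labels=labels, children=children)


@dataclass
class CommunityModel:
    """Zero-inflated log-normal copula model for absolute abundances.

    Marginal j: zero with probability ``pi[j]``, otherwise
    LogNormal(mu[j], sigma[j]); marginals are coupled by a Gaussian copula
    with the given correlation matrix.  Sequencing depth is log-normal.
    """

    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    correlation: np.ndarray
    depth_meanlog: float = float(np.log(1e4))
    depth_sdlog: float = 0.3

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        q = self.pi.size
        C = self.correlation
        if C.shape != (q, q) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1):
            raise ValueError("correlation must be symmetric with unit diagonal")
        if np.any(self.pi < 0) or np.any(self.pi > 1) or np.any(self.sigma <= 0):
            raise ValueError("need 0 <= pi <= 1 and sigma > 0")
        try:
            self._chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            raise ValueError("correlation matrix is not positive definite") from None

    @property
    def q(self) -> int:
        return self.pi.size

    @classmethod
    def default(cls, q: int, seed: int, corr_density: float = 0.1,
                corr_strength: float = 0.4) -> "CommunityModel":
        """A realistic preset: mostly-rare taxa (zero-inflation 0.2-0.9),
        unit-scale log-normal spread, a sparse random copula correlation
        and ~10k-read sequencing depth."""
        rng = np.random.default_rng(seed)
        pi = rng.uniform(0.2, 0.9, size=q)
        mu = rng.normal(0.0, 1.0, size=q)
        sigma = rng.uniform(0.5, 1.5, size=q)
        A = np.zeros((q, q))
        iu = np.triu_indices(q, 1)
        mask = rng.random(iu[0].size) < corr_density
        vals = rng.uniform(-corr_strength, corr_strength, size=iu[0].size) * mask
        A[iu] = vals
        A = A + A.T
        C = np.eye(q) + A
        # project to the nearest comfortable PD correlation
        w, V = np.linalg.eigh(C)
        C = (V * np.maximum(w, 1e-3)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        return cls(pi=pi, mu=mu, sigma=sigma, correlation=C)


def simulate_abundances(model: CommunityModel, n: int, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Draw absolute abundances X (n x q) and multinomial read counts.

    The Gaussian copula draw is pushed through each zero-inflated
    log-normal marginal's quantile function: latent normals below
    ``Phi^{-1}(pi_j)`` map to structural zeros, the rest to log-normal
    quantiles of the renormalized upper tail.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, model.q)) @ model._chol.T
    U = norm.cdf(G)
    X = np.zeros((n, model.q))
    nz = U >= model.pi[None, :]
    frac = (U - model.pi[None, :]) / (1.0 - model.pi[None, :] + 1e-300)
    frac = np.clip(frac, 1e-12, 1 - 1e-12)
    Xnz = np.exp(model.mu[None, :] + model.sigma[None, :] * ndtri(frac))
    X[nz] = Xnz[nz]
    tot = X.sum(axis=1)
    depth = np.maximum(1, np.round(rng.lognormal(model.depth_meanlog, model.depth_sdlog, n))).astype(np.int64)
    # a sample that drew an all-zero community yields zero reads; downstream
    # consumers treat zero leaf totals as an error where it matters
    reads = np.vstack([
        rng.multinomial(depth[i], X[i] / tot[i]) if tot[i] > 0
        else np.zeros(model.q, dtype=np.int64)
        for i in range(n)
    ])
    return X, reads


def cluster_otus(tree: PhyloTree, k: int, seed: int = 0) -> np.ndarray:
    """Partition leaves into k clusters by PAM on cophenetic distances.

    Deterministic: greedy BUILD initialisation followed by best-improvement
    SWAP passes; ties resolved by lowest index.  ``seed`` is accepted for
    interface symmetry but the procedure has no random step.
    """
    q = tree.n_leaves
    if not 2 <= k <= q:
        raise ValueError("need 2 <= k <= number of leaves")
    D = tree.cophenetic_distances()
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    def cost(ms):
        return D[:, ms].min(axis=1).sum()
    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        non = [j for j in range(q) if j not in medoids]
        best_trial = None
        for mi in range(k):
            for j in non:
                trial = sorted(medoids[:mi] + medoids[mi + 1:] + [j])
                c = cost(trial)
                if c < best - 1e-12:
                    best, best_trial = c, trial
        if best_trial is not None:
            medoids, improved = best_trial, True
    labels = np.argmin(D[:, medoids], axis=1)
    return labels


def scale(x: np.ndarray) -> np.ndarray:
    """Standardize to sample mean 0 and standard deviation 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


@dataclass
class SignalConfig:
    """Which leaves carry the association and how strong it is."""

    cluster: Optional[np.ndarray]        # leaf positions (tree order); None => no signal term
    beta: float = 0.0
    outcome_type: str = "binary"
    covariate_mode: str = "independent"

    def __post_init__(self):
        if self.covariate_mode not in ("independent", "correlated"):
            raise ValueError("covariate_mode must be 'independent' or 'correlated'")
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError("outcome_type must be 'binary' or 'continuous'")
        if self.beta != 0 and self.cluster is None:
            raise ValueError("a non-zero effect size needs an associated cluster")
        if self.covariate_mode == "correlated" and self.cluster is None:
            raise ValueError("the correlated covariate regime needs a cluster")


def simulate_outcome(X: np.ndarray, signal: SignalConfig, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (Y, Z) given absolute abundances X.

    Binary:      logit E[Y] = 0.5*scale(Z1+Z2) + beta*scale(sum_C X)
    Continuous:  Y = 0.5*scale(Z1+Z2) + beta*scale(sum_C X) + N(0,1)

    Z1 ~ Bernoulli(0.5); Z2 ~ N(0,1) (independent regime) or
    scale(sum_C X) + N(0,1) (correlated regime).  The signal enters through
    the *absolute* abundance total of the cluster, while the test only ever
    sees read-count-derived relative abundances.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    sig = None
    if signal.cluster is not None:
        sig = scale(X[:, np.asarray(signal.cluster, dtype=np.intp)].sum(axis=1))
    Z1 = rng.binomial(1, 0.5, size=n).astype(float)
    if signal.covariate_mode == "independent":
        Z2 = rng.standard_normal(n)
    else:
        Z2 = sig + rng.standard_normal(n)
    lin = 0.5 * scale(Z1 + Z2)
    if signal.beta != 0:
        lin = lin + signal.beta * sig
    if signal.outcome_type == "binary":
        Y = rng.binomial(1, expit(lin)).astype(float)
    else:
        Y = lin + rng.standard_normal(n)
    return Y, np.column_stack([Z1, Z2])


@dataclass
class RejectionRateResult:
    rate: float
    se: float
    n_reject: int
    replicates: int
    p_values: np.ndarray


def estimate_rejection_rate(
    tree: PhyloTree,
    model: CommunityModel,
    signal: SignalConfig,
    n: int,
    replicates: int,
    B: int,
    alpha: float = 0.05,
    seed: int = 0,
    measures: Sequence[str] = ("u", "w", ".5", "a"),
) -> RejectionRateResult:
    """Monte-Carlo rejection rate of the community test under one scenario.

    Each replicate draws a fresh community and outcome from the fixed tree
    and community model, runs the full test, and counts P_MiAF < alpha.
    Reports the empirical rate and its binomial standard error.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    import pandas as pd

    master = np.random.default_rng(seed)
    leaf_labels = tree.leaf_labels
    pvals = np.empty(replicates)
    for r in range(replicates):
        rep_seed = int(master.integers(2**31 - 1))
        X, reads = simulate_abundances(model, n, rep_seed)
        Y, Z = simulate_outcome(X, signal, rep_seed + 1)
        counts = pd.DataFrame(reads, columns=leaf_labels,
                              index=[f"S{i+1}" for i in range(n)])
        try:
            res = run_miaf(Y, Z, counts, tree, signal.outcome_type,
                           B=B, seed=rep_seed + 2, measures=measures, alpha=alpha)
        except ValueError as e:
            raise ValueError(f"replicate {r} failed: {e}") from None
        pvals[r] = res.p_final
    n_reject = int(np.sum(pvals < alpha))
    rate = n_reject / replicates
    se = float(np.sqrt(rate * (1 - rate) / replicates))
    return RejectionRateResult(rate=rate, se=se, n_reject=n_reject,
                               replicates=replicates, p_values=pvals)
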