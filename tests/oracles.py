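"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the vectorized code paths they are checking:
plain Python loops, explicit indicator sums, grid-search likelihoods.
"""

import numpy as np


def af_brute_force(P, omega=None):
    """Double-loop evaluation of the adaptive Fisher estimators.

    Enumerates the indicator sums over all (b, b*) pairs directly.
    Returns (S, P_Sk, T_AF, P_AF, h) with h the smallest minimizing k of
    the observed row.
    """
    P = np.asarray(P, dtype=float)
    nrow, d = P.shape
    if omega is None:
        omega = np.ones(d)
    W = np.asarray(omega, dtype=float) * -np.log(P)
    S = np.empty((nrow, d))
    for b in range(nrow):
        S[b] = np.cumsum(sorted(W[b], reverse=True))
    P_Sk = np.empty((nrow, d))
    for b in range(nrow):
        for k in range(d):
            count = 0
            for bs in range(nrow):
                if S[bs, k] >= S[b, k]:
                    count += 1
            P_Sk[b, k] = count / nrow
    T = np.array([P_Sk[b].min() for b in range(nrow)])
    P_AF = np.array(
        [sum(1 for bs in range(nrow) if T[bs] <= T[b]) / nrow for b in range(nrow)]
    )
    h = 1 + min(k for k in range(d) if P_Sk[0, k] == P_Sk[0].min())
    return S, P_Sk, T, P_AF, h


def logistic_grid_mle(Y, Z, half=10.0, rounds=12, width=61):
    """Maximize the logistic log-likelihood over a shrinking (a0, a1) grid.

    The grid shrinks slowly (x0.35 per round) so the search cannot lose the
    optimum along the correlated intercept/slope ridge.
    """
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float)

    def loglik(a0, a1):
        eta = a0 + a1 * Z
        return float(np.sum(Y * eta - np.log1p(np.exp(eta))))

    c0, c1 = 0.0, 0.0
    for _ in range(rounds):
        g0 = np.linspace(c0 - half, c0 + half, width)
        g1 = np.linspace(c1 - half, c1 + half, width)
        best, arg = -np.inf, (c0, c1)
        for a0 in g0:
            for a1 in g1:
                ll = loglik(a0, a1)
                if ll > best:
                    best, arg = ll, (a0, a1)
        c0, c1 = arg
        half *= 0.35
    return c0, c1


def extended_counts_naive(leaf_counts, tree):
    """Internal-node counts by explicitly walking up from every leaf."""
    q = tree.n_leaves
    label_to_col = {lab: j for j, lab in enumerate(leaf_counts.columns)}
    X = leaf_counts.to_numpy()
    out = {}
    for v in tree.internal_nonroot():
        total = np.zeros(X.shape[0], dtype=np.int64)
        for i, leaf in enumerate(tree.leaves):
            # climb from leaf to root, noting if v is on the path
            u = int(leaf)
            while u != tree.root:
                if u == int(v):
                    total += X[:, label_to_col[tree.labels[leaf]]]
                    break
                u = int(tree.parent[u])
        out[int(v)] = total
    return out
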