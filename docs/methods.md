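# Methods

## Model and test statistic

The community test treats every node of the rooted phylogeny except the
root as a taxon. Internal-node counts are sums over descendant leaves, so
a signal concentrated in a clade re-appears, aggregated, at its ancestral
nodes; relative abundance always divides by the per-sample *leaf* total,
which keeps internal values in [0, 1] without double-counting the
denominator. Four transforms of the relative-abundance matrix are scored:
presence/absence (`u`), raw (`w`), square root (`.5`, damping dominant
taxa the way generalized UniFrac does) and leaf-only raw (`a`, for
signals with no phylogenetic structure).

Per taxon, the score statistic of the GLM with logit (binary) or identity
(continuous) link is `U_k = Σ_i (Y_i − μ̂_i) M̃_ik`, where `μ̂` is the
covariate-only null fit and `M̃` the column-wise OLS residual of the
transform on intercept + covariates. The null variance used for
standardization is the diagonal surrogate

    V_kk = Σ_i v_i M̃_ik²,   v_i = μ̂_i(1 − μ̂_i)  (binary)
                             v_i = σ̂²            (continuous, ML estimate),

i.e. the variance of `U_k` given the residualized design. Because final
inference is permutation-based and the identical formula is applied to
observed and permuted data, the role of `V_kk` is standardization only;
any consistent choice yields a valid permutation p-value. Columns with
`V_kk ≤ 1e-12` are removed: a column that is constant after
residualization (e.g. a taxon present in every sample under the
presence/absence transform) carries only machine noise, and on these
[0, 1]-scaled matrices every informative column has `V_kk` many orders of
magnitude larger.

One-sided p-values `Φ(Ũ_k)` / `1 − Φ(Ũ_k)` are clamped to
`[1e-300, 1 − 1e-16]` so `−log p` stays finite; analytically the bounds
are never attained, so the clamp only guards floating-point underflow.

## The adaptive Fisher operator

`AF{p; ω}` sorts `W_k = ω_k(−log p_k)` (natural log; any base is absorbed
by the operator's scale invariance) in decreasing order, forms partial
sums `S_k`, references each against the permutation stack
(`P_Sk = #{S_k^{(b*)} ≥ S_k^{(b)}}/(B+1)`, ties counted, self included)
and minimizes over k. Tie-breaking is deterministic throughout: the W
sort is stable with original column index as tie-breaker, indicator
comparisons count equalities as satisfying the inequality, and a tied
minimizer h resolves to the smallest k (the most conservative selection
set). Zero-weight columns are retained — they extend the partial-sum
sequence without changing any prefix p-value and can never enter the
selection ahead of a positive-weight column.

## Permutation scheme

The null is built by permuting the rows of the residual matrix `M̃`
(never the outcome): residualizing first removes the linear
covariate–abundance association, so permuted replicates preserve the
confounding structure that a naive outcome permutation would destroy.
The observed null fit (`μ̂`, `v`) is held fixed and each permuted residual
matrix is scored directly with the same formulas as the observed one,
keeping rows b = 0..B exchangeable under the null. One permutation plan
is shared by all four measures and both tails within a run; this is what
makes the b-indexed component p-values correlated in the right way when
the upper combination levels (two-sided per measure, then the final
four-measure combination, both unweighted) re-apply the AF operator to
their `P_AF^{(b)}` vectors. All reported p-values live on the lattice
`{1/(B+1), …, 1}`.

Weights are computed once from the raw representation `M` (not from
`M̃`), use the sample standard deviation (n − 1 denominator; the choice is
a per-column rescale and is fixed and documented here), and are held
constant across permutations so replicates stay exchangeable.

## Synthetic data generator

The generator emulates a cross-sectional 16S study. Absolute abundances
follow zero-inflated log-normal marginals coupled by a Gaussian copula:
the latent normal is mapped through each marginal's quantile function,
with the lower `π_j` mass mapped to structural zeros. Read counts are
multinomial draws at a log-normal depth (median ≈ 10,000 reads, log-SD
0.3). The default preset draws `π_j ~ U(0.2, 0.9)` (mostly-rare taxa,
~60% zeros overall), `μ_j ~ N(0, 1)`, `σ_j ~ U(0.5, 1.5)` and a sparse
random copula correlation (10% of pairs, magnitudes ≤ 0.4, projected to a
positive-definite correlation); these are one-time choices representing a
moderately sparse, moderately correlated community, not fits to any
particular dataset. A sample that draws an all-zero community yields zero
reads and is rejected downstream where relative abundance is undefined.

Outcomes follow
`logit E[Y] = 0.5·scale(Z1 + Z2) + β·scale(Σ_{j∈C} X_j)` (binary) or the
same linear predictor plus N(0, 1) noise (continuous), with
`Z1 ~ Bernoulli(0.5)` and `Z2` either standard normal or confounded,
`Z2 = scale(Σ_C X) + N(0, 1)`. The signal uses *absolute* cluster
abundance while the test sees only read-count-derived relative
abundances, preserving the compositional gap a real study faces.
Associated clusters come from deterministic PAM (greedy BUILD + SWAP) on
the cophenetic distance matrix; the cluster count k is a configuration
parameter. Effect-size grids: binary {0.6, 0.8, 1.2, 1.6, 2}, continuous
{0.2, 0.4, 0.6, 0.8, 1}, doubled in the confounded regime.

What the generator does not emulate: parameters fitted to a real
microbial profile, taxon-specific depth biases, overdispersion beyond the
copula/multinomial layers, or longitudinal structure. Passing calibration
tests on this generator therefore demonstrates validity of the inference
machinery under a realistic sparsity/correlation regime, not agreement
with any particular real cohort.

## Study sizes used in validation

The null-calibration and power checks run at 100 OTUs, 100 samples,
B = 300 permutations (B = 99 for the distributional-uniformity check) and
100–300 replicates per scenario, with the confounded-covariate study
averaging over k = 5 clusters. These sizes put Monte-Carlo standard
errors around 0.01–0.016 on a rejection proportion, small enough to
detect meaningful miscalibration at α = 0.05. Default B for a real
analysis is 10,000.

## Degenerate inputs and numerical choices

Missing branch lengths are an error unless explicitly substituted with 0;
samples with zero leaf totals are an error; binary outcomes require both
classes and fail loudly on perfect separation; rank-deficient covariate
designs are rejected. Unary internal nodes (duplicating their single
child) are retained as distinct columns; genuine degeneracy is handled by
the `V_kk` removal rule. `scale(·)` uses the n − 1 standard deviation and
rejects constant input.

## Limitations

Taxon selection is marginal and heuristic: p-values come from univariate
models, so a selected taxon may be associated only through correlated
neighbours, and no error rate is controlled. The permutation null makes
runtime linear in B × (number of extended taxa); for tens of thousands of
taxa at B = 10,000 a run takes minutes, not seconds. Survival and
longitudinal outcomes are out of scope, as is fitting the generator to
user data.
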