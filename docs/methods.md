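# Methods

## Problem and scope

Two-colour microarray matrices (genes × samples, log-ratio scale) routinely
contain 1–10% missing entries. Downstream analyses — clustering,
differential-expression calling, network inference — require complete
matrices, so missing entries are imputed. Which imputer to use depends on
the dataset: regression-based local methods tend to win on smooth
time-series data with strong gene–gene linear structure, neighbour-averaging
methods are competitive on noisy non-time-series data, and no single method
dominates. `arrayimpute` implements nine classical imputers, the masking
simulation protocol used to compare them, three performance indices, and a
selection workflow that picks the best imputer for a user's matrix by
simulation on that matrix itself.

## The imputation algorithms

All imputers share two hard invariants: originally observed entries are
returned bit-for-bit unchanged, and the output contains no missing or
non-finite values.

**KNN family.** For a missing entry (g, s), candidate genes are those
observed at sample s that share at least one observed column with g.
Distance is Euclidean over the columns observed in both genes, scaled to a
per-column root mean square, so candidates with different numbers of shared
columns are comparable. The estimate is the inverse-distance-weighted mean
of the k nearest candidates' values at s (weights 1/(d + 1e-12); exact
matches short-circuit to the plain mean of the zero-distance candidates), so
every estimate is a convex combination of candidate values. *SKNN* imputes
genes in order of ascending missing count (ties by row order) and lets each
completed gene join the candidate pool. *IKNN* starts from row averages and
repeats whole-matrix KNN passes, with distances over all columns of the
current completed matrix, until the imputed entries stabilise. Default
k = 15, with k = 10 for the sequential variant on time-series data,
following standard practice for these methods.

**Local least squares (LLS) family.** For a target gene with observed
columns O and missing columns M, the k genes most similar to the target
(absolute Pearson correlation over O; Euclidean selectable) are used as
regressors: x = argmin ‖Aᵀx − b‖² with A the k×|O| neighbour values and b
the target's observed values, solved through ridge-stabilised normal
equations (ridge 1e-8; with ridge 0 the solver switches to min-norm least
squares, i.e. the exact pseudo-inverse solution). The missing values are
Bᵀx with B the neighbours' values at M. Candidates must be observed on all
of O ∪ M; when fewer than k qualify, the pool is relaxed to
row-average-filled candidates (logged). *SLLS* is the sequential variant,
*ILLS* the iterative one (row-average start, whole-matrix passes in which
similarity uses all columns of the current completed matrix while each
regression is still fitted on the target's originally observed columns).

**Automatic neighbour count.** k may be set to `"auto"`: a small probe
fraction (default 1%) of the observed entries is hidden with a seeded draw,
the imputer is run at each candidate k (default 5, 10, 15, 20, 50, 100,
150, 200, capped at G−1), and the k with the smallest probe NRMSE wins,
ties to the smallest k. The sequential and iterative variants estimate k
with a single-pass LLS probe, which selects the same neighbourhood scale at
a fraction of the cost.

**Adaptive least squares (LSA, historically "LS").** Each missing entry
gets two univariate-regression estimates: a gene-wise one (the 10 genes
most correlated with the target, pairwise-deletion statistics, predictions
combined with weights (r²/(1 − r² + 1e-6))²) and an array-wise one (the
same construction with samples as variables). The final estimate is
p·gene + (1−p)·array, with p fitted once per matrix on held-out probes over
the grid p = 0, 0.05, …, 1.

**SVD imputation.** Row-average start; each iteration takes the top-q
right-singular vectors (eigengenes) of the current completed matrix and
refits every incomplete gene on its observed columns only, replacing its
missing entries with the fitted values. The observed-entry reconstruction
error is tracked per iteration and is non-increasing. q defaults to 15
(clamped to the matrix size); `"auto"` selects ~20% of the available
eigengenes, the classic recommendation for expression data and the sensible
choice when the sample dimension is small.

**Bayesian PCA.** Variational EM on y = Wx + μ + ε with isotropic noise
precision τ and an automatic-relevance-determination prior on the loading
columns (α_j = S/‖w_j‖²), starting from the SVD of the row-average-filled
matrix with a seeded 1e-4 jitter. Gene scores use only the gene's observed
rows of W; missing entries are refilled with the posterior predictive mean
each sweep. Irrelevant loading columns are driven to zero, so
q = min(G, S) − 1 ("auto") self-selects the effective dimensionality.
Numerical collapse (non-finite updates, τ ≤ 0) aborts with diagnostics
rather than silently falling back.

## Numerical choices

* Convergence of all iterative imputers is monitored on the vector of
  imputed entries as ‖new − old‖₂ / max(‖old‖₂, 1e-12) < tol (default
  1e-6). A per-entry relative criterion is unusable on log-ratio data,
  where individual entries near zero make the ratio unbounded.
* ILLS on noisy data does not reach a fixed point — neighbour reselection
  keeps churning at the noise level — so it runs to `max_iter` and reports
  `converged=False`; benchmark plans cap it at ~10 passes, past which the
  estimates only drift.
* Degenerate cases (no candidates, all-zero designs) fall back to the
  gene's row average with a logged warning, keeping the benchmark protocol
  total; failures of one algorithm in one round are recorded as missing
  scores, never fatal.

## Masking simulation and indices

`inject_missing` hides round(rate·G·S) entries uniformly at random without
replacement, re-drawing (bounded retries) if a full row or column would
result. Positions are kept in row-major canonical order so the truth vector
`y_answer` and every algorithm's `y_guess` align. One master seed drives the
whole benchmark; round r at rate ρ uses a child seed derived through
numpy's SeedSequence, so rounds are independent and the run is reproducible
bit-for-bit.

* **NRMSE** = sqrt(mean[(y_guess − y_answer)²] / variance[y_answer]), with
  population variance (divide by n). The square root is included and the
  index is affine-invariant. Note that with very few masked entries (e.g. a
  1% rate on a small matrix) the sample variance in the denominator is
  noisy and the *mean* NRMSE over rounds is inflated by the heavy tail of
  its reciprocal; comparisons across rates at small mask counts inherit
  this bias.
* **CPP**: k-means (10 clusters by default, k-means++ with 10 restarts,
  seeded) is run on the complete and the imputed matrix with the *same*
  seed, isolating the effect of imputation from initialisation noise. CPP
  is the fraction of gene pairs co-clustered in the complete-data partition
  that remain co-clustered after imputation — directional by design, since
  the question is how much of the reference structure survives.
* **BLCI** = n(B_CD ∩ B_ID)/n(B_CD) + n(B_CDᶜ ∩ B_IDᶜ)/n(B_CDᶜ) − 1, where
  B_CD and B_ID are the significant gene sets called on complete and
  imputed data by the SAM caller below. Undefined (and recorded as missing)
  when B_CD is empty or the whole universe.

## The SAM caller

Two-class unpaired statistic d = (mean₂ − mean₁)/(s + s₀) with pooled
standard error s. s₀ is chosen from the percentiles {0, 5, …, 100} of s to
minimise the coefficient of variation of the d-spread (windowed MAD) across
ten s-quantile windows. The null distribution comes from seeded random
relabelings (default 200); the true-null fraction π₀ is estimated from the
central quartile band. The significance cutoff on |d| is the smallest one
whose estimated FDR (π₀ × permutation false-call count / observed calls) is
at or below the target (default 0.05). The false-call count is summarised
by its permutation **mean**; the median variant is config-selectable but
is anti-conservative at the very top of the ranking (a single lucky
observed maximum gets an estimated FDR of zero in half of null datasets),
which breaks the estimator's conservativeness on null data.

## Benchmark aggregation

Within each round and index the algorithms are ranked (1 = best; NRMSE
lower-better, CPP/BLCI higher-better; ties share the average position, so
ranks always sum to n(n+1)/2). Per algorithm and index, ranks are averaged
over all rounds and rates with a standard error (sample SD/√n). The
*average index* is the unweighted mean of the per-index average ranks.
Robustness between two dataset types is σ = |avg rank A − avg rank B| per
algorithm, read as robust when σ < 1.5 (strict). `select_optimal` picks the
winner by smallest mean NRMSE across all rates and rounds (default,
matching the rate-vs-NRMSE report the selection workflow emits) or by the
average index; ties break by mean NRMSE, then plan order. Missing scores
exclude an algorithm from that round's ranking rather than assigning a
worst rank — a crash should not reward competitors.

## Synthetic data

The generators stand in for the classic benchmark compendia (yeast cell
cycle and stress compendia, lymphoma and HeLa panels, ~600–6800 genes ×
8–60 samples after completeness filtering):

* `make_lowrank` — U·Vᵀ + noise with standard-normal factors; captures the
  dominant feature real expression matrices share, strong gene–gene
  correlation / low effective rank. The benchmark-scale tests use rank 2 at
  200×10 with noise_sd 0.14 (≈10:1 signal-to-noise on a rank-2 signal).
* `make_timeseries` — amplitude·sin(2πt/period + phase) with a small set of
  shared phase groups, emulating cell-cycle-style smooth, strongly
  correlated profiles.
* `make_twogroup` — iid noise with a planted mean shift
  (effect_size·noise_sd) in the first n_de genes of group 2, for
  recall/precision checks of the differential-expression pipeline.
* `make_clustered` — well-separated cluster centres with round-robin gene
  assignment, for the clustering-concordance pipeline.

What the generators do **not** emulate: intensity-dependent noise,
missingness that correlates with expression level (real missingness is not
MCAR), batch structure, and probe-level artifacts. Passing the suite shows
the algorithms and the protocol are implemented correctly and behave as
expected on data with the stated structure; it does not certify relative
algorithm performance on any particular real dataset — that is exactly what
the `select` workflow measures per dataset.

## Problem sizes and defaults used by the shipped tests

Desk-scale runs are used throughout so the whole suite runs in minutes on
one CPU: oracle-equivalence sweeps at 10×6 (200 matrices), exact-recovery
runs at 40–50 × 10–12, the full-protocol benchmark at 200×10 with 30
rounds, 5 rates and all nine algorithms plus the row-average control
(k = 15 for the KNN family, the probe-based automatic k for the LLS
family, and `auto` components for the global methods), and the
differential-expression simulation at 500 genes, 6 vs 6 samples. The
protocol itself is scale-free: `rounds`, `rates` and the algorithm roster
are plan fields, with 110 rounds and rates 1/5/10/15/20% as the
full-study defaults.

## Known limitations

* The adaptive blend's two routes are mathematically linked at low rank
  (exact affine column structure forces exact row structure), so the blend
  weight p is informative only on data with asymmetric noise structure.
* BPCA's variational update treats refilled missing entries as point
  estimates in the M-step (their posterior covariance contribution enters
  only through the score covariance); the classic trade-off of speed
  against a slightly underestimated noise level.
* NRMSE comparisons across missing rates are biased at very small mask
  counts (see above); conclusions at a 1% rate on small matrices should
  rest on the other indices or on larger matrices.
* The masking simulator is MCAR by construction; selection results carry
  over to real data only to the extent that real missingness is
  value-independent.
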