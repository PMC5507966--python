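# Methods

This note documents the estimator conventions, parameter defaults, the
synthetic benchmark model, and the numerical and design choices behind
`assocnet`, at the level of detail a user needs to interpret (and distrust)
its numbers.

## Estimator conventions

All fourteen pairwise measures operate on two finite real vectors of equal
length n and are exchange-symmetric.  Degenerate inputs (constant vectors,
all-tied ranks, all points on a Blomqvist median line, no concordant or
discordant pair for γ) raise typed exceptions rather than returning NaN;
the pairwise-scoring stage catches these, records a NaN sentinel that is
excluded from ranking, and counts the skip.  This prevents silently ranking
meaningless scores into a ROC sweep.

Rank conventions: average ranks for ties throughout, except Hoeffding's
bivariate rank Qᵢ = #{j : Xⱼ < Xᵢ and Yⱼ < Yᵢ}, which counts strict
inequalities as its definition requires.  The empirical copula transform is
uᵢ = rank(xᵢ)/n with average ranks, values in (0, 1].

Per-measure notes:

* **Pearson / Spearman / Kendall / Goodman.**  Standard.  Kendall is the
  τ-a form: tied pairs count as neither concordant nor discordant but the
  denominator stays n(n−1)/2; γ divides the same numerator by n_s + n_d
  only.  Spearman with ties is Pearson on average ranks, which coincides
  with the 1 − 6Σdᵢ²/(n(n²−1)) form in the tie-free case.
* **Hoeffding's D** is implemented as the classical rational expression in
  D₁, D₂, D₃ *without* the conventional factor 30.  Its attainable range is
  therefore [−1/60, 1/30] asymptotically (identity data at n = 5 give
  17/60), not the nominal [0, 1]; range checks treat it as exempt and the
  test suite logs its observed bounds.  Ranking and AUC only use the
  ordering, which is unaffected.
* **Blomqvist's β** drops points lying exactly on either sample median line
  before counting quadrants — the standard medial-correlation convention,
  which also covers odd n.
* **WWH** needs an indicator F over length-k subsequences; we take F = 1
  iff the within-subsequence rank patterns of x and y are identical or
  exactly reversed.  Matching only identical patterns would score
  inhibitory regulation *below* the independence null (reversed patterns
  become vanishingly rare under strong negative coupling), so the
  two-sided indicator — the convention of the published count-statistic
  coexpression measures — is required for the statistic to rank negative
  regulations at all.  The
  default sums over all C(n, k) index subsets with k = 3 (guarded at 10⁶
  subsets); `consecutive=True` restricts to the n−k+1 sliding windows,
  which is the intended special case for time-ordered samples and is much
  less informative for i.i.d. samples (only n−k+1 terms).
* **MI** is the non-negative plug-in estimate I = ΣP log[P_joint/(P_x P_y)]
  in nats on an equal-frequency discretisation.  The default bin count is
  ⌈n^(1/3)⌉: the plug-in bias on independent data is roughly
  (b−1)²/(2n), so the cube-root rule keeps the null near zero across the
  n used here (b = ⌈√n⌉ would give ≈ 0.5 nats of pure bias at n = 5000).
  Bins are formed from interior quantiles; duplicate quantile edges
  collapse, so heavily tied or constant inputs map to fewer bins.
* **MIC** maximises grid MI (in bits, normalised by log₂ min(p, q)) over
  all grid shapes p·q < B with the default budget B = n^0.6, using
  equal-frequency axis partitions for every shape.  The exhaustive
  partition-boundary optimisation of the original MINE algorithm is not
  performed, so values are a deterministic lower bound of full MIC; the
  normalisation and budget are unchanged.  Note B ≤ 4 admits no grid and
  is rejected, which in particular requires n > 10 at the default budget.
* **Wilks' W** reduces to r² for two univariate vectors; the
  implementation satisfies this identity to 1e−12 and the suite asserts it.
* **KCCA** uses a Gaussian kernel with the median heuristic per variable,
  centred Gram matrices, and a ridge term reg·I (default reg = 0.1) on each
  Gram factor; the score is the largest singular value of
  (K_x + reg·I)⁻¹K_x · K_y(K_y + reg·I)⁻¹, the generalised-eigenproblem
  form of regularised kernel CCA.  Unregularised empirical KCCA is
  degenerate (it saturates at 1 for any data), so reg > 0 is mandatory.
  With the default, identical inputs at n = 100 score ≳ 0.99 while
  independent normals at n = 200 average ≈ 0.29 (simulated null).
* **dCor** is the double-centred distance-matrix form; 0 is returned when
  either marginal distance variance vanishes.
* **CMMD** transforms both margins to copula values and computes a Gaussian
  kernel MMD.  The default `independence_contrast` variant is the MMD
  between the paired copula sample and the product of its marginals, which
  has the closed form √(tr(HK_uHK_v))/n (H the centring matrix): it is
  deterministic, exactly exchange-symmetric, and zero in population exactly
  under independence.  The `as_printed` variant evaluates the literal
  two-marginal U-statistic (1/(n(n−1)))Σ_{i≠j}[Φ(uᵢ,uⱼ)+Φ(vᵢ,vⱼ)
  −Φ(uᵢ,vⱼ)−Φ(uⱼ,vᵢ)]; because both copula marginals are near-uniform it
  is ≈ 0 regardless of dependence, and it is kept only so the formula can
  be audited against a direct double-loop evaluation.  Values are clipped
  to [0, 1] (the kernel is bounded by 1).
* **RDC** copula-transforms each argument, appends an intercept, projects
  through k = 20 standard-normal weights scaled by s = 0.6, takes sine
  features, and returns the first canonical correlation between the two
  feature sets (SVD-based, rank-guarded).  One weight matrix drawn from the
  seed is shared by both arguments; the usual construction draws one per
  argument, but sharing makes the coefficient exactly symmetric under
  argument exchange and exactly invariant under strictly increasing
  transforms, at no cost to its behaviour as a dependence score.  RDC is
  the only stochastic measure; its value is a deterministic function of
  (inputs, k, s, seed).

## Conditional measures

Partial correlation, conditional MI and liquid association condition on a
single gene Z.  Partial correlation equals Pearson on the residuals of X
and Y after linear regression on Z (asserted to 1e−10 as an independent
oracle); collinearity of an argument with Z raises an error.  CMI uses the
same discretisation rule as MI on all three variables; a constant Z
collapses to one bin so CMI then equals MI exactly.  Beware the three-way
table: for conditioning analyses pass a small explicit bin count (the
suite uses 5 bins at n = 5000), since even the cube-root rule leaves the
joint table sparse.  Liquid association z-scores X and Y and maps Z to
Blom normal scores before averaging XᵢYᵢZᵢ — the raw triple-product mean is
scale-dependent and incomparable across genes; `transform=False` evaluates
the raw mean for pre-standardised input.

How to choose Z when pruning a network is not fixed by any of the measure
definitions.  The package's default strategy
(`conditional.conditional_association`) conditions each pair on its
strongest common neighbor — the gene k maximising min(|s_ik|, |s_jk|) in
the unconditional association matrix — which targets exactly the
single-gene explanations (chains and common regulators) these measures can
remove.  This is a design choice of this package, not a published rule.

## Network inference and evaluation protocol

Pairs are ranked descending; for signed measures the default key is
|score|, because strong inhibition is as much a regulation as strong
activation and a signed top-5 % cut would silently discard it (raw-score
ranking is available for sensitivity analysis).  Ties break
lexicographically by gene pair, and top-fraction selection keeps
⌈fraction·E⌉ edges, so rankings and selections are bit-reproducible.
TF orientation maps TF–nonTF edges to TF→target, keeps TF–TF edges in both
directions, and leaves nonTF–nonTF edges undirected.

Evaluation collapses the directed gold standard to unordered pairs (a pair
is positive iff either direction is a known regulation) and scores the
full universe of C(m, 2) pairs.  Point metrics use the standard
definitions; MCC is 0 by convention when any denominator factor is zero
(logged).  The ROC sweep produces one operating point per distinct ranking
key; tie groups (including one sentinel group of unranked/skipped pairs at
the bottom) contribute diagonal segments, so the trapezoidal AUC equals
the tie-corrected normalised Mann–Whitney statistic — the suite asserts
this against brute-force pair counting.  The default operating point for
point metrics is the top-5 % selection, matching the selection rule of the
inference protocol; the threshold is configurable.

## Synthetic benchmark

The generator is a stand-in for ODE-based community benchmark simulators,
not a reimplementation of one.  Topologies are random DAGs over a random
gene order: Erdős–Rényi (each forward pair wired with probability
expected_edges/C(n, 2); default expected_edges = n, i.e. average total
degree 2, within the 10–25-edge range of the published 10-node benchmark
gold standards) or scale-free (each new gene picks 2 regulators with
probability ∝ out-degree + 1).  Expression follows a structural-equation
model in topological order: source genes are standard normal; a regulated
gene is link(Σ w·parent) + ε, with the regulator sum standardised to unit
sample scale so that the noise level is comparable across in-degrees,
weights of magnitude U(0.5, 1.5) with random sign, ε Gaussian with
noise_sd = 0.3 by default, links linear, tanh or square.  n = 100 samples
by default.  Everything is reproducible from a single seed; the CLI fans a
master seed out to per-stage seeds via SeedSequence keyed by stage and
replicate index.

The `dream10`/`dream50`/`dream100` presets (10/50/100 genes with 4/23/46
replicate datasets, mirroring the dataset counts of the three benchmark
sizes) share the 10-node preset's graph density (edge probability 10/45).
Matching density rather than degree is what reproduces the benchmark
phenomenon that inference degrades with network size (measured mean
Pearson AUC ≈ 0.90/0.64/0.57 across the three sizes); its cost is that the
larger presets are much denser in degree than real regulatory networks —
a deliberate trade-off, documented here.

What passing benchmarks do *not* show: the simulator has Gaussian noise,
static (non-temporal) samples, no saturation kinetics, no knockout designs
and no measurement-noise model, so measure rankings obtained on it
demonstrate correctness of the machinery and the linear/non-linear
distinction (quadratic links reliably favour MI and dCor over Pearson),
not expected performance on microarray or RNA-seq data.

## Numerical details

* Scores are clipped to their declared ranges only to absorb rounding at
  the boundaries (e.g. |r| ≤ 1 + 1e−16); no statistic is truncated away
  from its formula value in the interior.
* KCCA and the RDC canonical correlation guard rank deficiency: feature
  matrices are orthonormalised by SVD with a relative 1e−9 singular-value
  cut-off.
* Kernel Gram PSD tolerance after centring is 1e−8.
* Written TSV artifacts serialise floats at 17 significant digits, so
  write→read round trips are exact; provenance comment lines carry tool
  version, command, parameters and seeds, with timestamps left empty by
  default so identical runs produce byte-identical files.
* The top-level CLI seed derives per-stage seeds as
  SeedSequence([master, stage_index, replicate]) reduced mod 2³¹.

## Known limitations

* MIC is a lower bound of the full dynamic-programming MIC; values on
  strongly non-functional patterns can be conservative.
* The `as_printed` CMMD variant is auditable but uninformative by
  construction; use the default variant for analysis.
* Hoeffding's D range caveat above; its magnitude is not comparable across
  the other [0, 1] measures.
* Plug-in MI/CMI are biased upward at small n; compare values only across
  pairs at a common n and bin count (as the pipeline does).
* Conditioning is restricted to a single gene; order-k conditioning sets
  and structure-learning approaches are out of scope.
* No time-lagged variants: samples are treated as exchangeable.
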