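# Methods

This note records the statistical and numerical choices behind `msfeast`:
what each stage computes, which parameters matter, and what the synthetic
benchmarks do and do not demonstrate.

## Inputs and pre-treatment

The pipeline consumes an MGF file (one MS/MS spectrum per feature), a
features × samples quantification CSV, and a sample → group CSV with a
designated reference/control group. Feature identifiers are taken from the
first present of `FEATURE_ID`, `SCANS`, `TITLE`, matching common
FBMN-export dialects. Zero-intensity fragment peaks are dropped at parse
time (they cannot contribute to cosine-family scores); peaks are re-sorted
ascending in m/z.

Quantification values are used **as loaded**. No normalisation, imputation
or log transformation is applied by default: any scaling (TIC
normalisation, batch correction) is the user's upstream responsibility.
Whether intensities should be log-transformed before testing is an open
user choice, exposed as `log_transform` (default off); fold changes always
use the raw table. The statistic standardises each feature anyway, so the
transform affects only the shape, not the scale, of per-feature
distributions.

## Modified cosine

For spectra $a, b$ with precursor difference $\Delta$, candidate fragment
pairs satisfy the direct window $|mz_i - mz_j| \le \tau$ or the
$\Delta$-shifted window $|mz_i - mz_j - \Delta| \le \tau$; a pair
satisfying both counts once. Pair weight is the product of square-root
intensities (the common variance-stabilising choice for cosine-family
MS/MS scores; a raw-intensity mode is available via
`sqrt_intensity=False`). The score is the maximum-weight **one-to-one**
matching over the candidate graph divided by the product of square-root
intensity L2 norms, computed with an exact assignment solver rather than
the common greedy heuristic. This makes the score deterministic,
verifiable against exhaustive enumeration, and never smaller than the
greedy value (which is kept as `greedy_modified_cosine` for parity checks
with other implementations). Defaults: fragment tolerance 0.1 Da, no
intensity noise floor. The pairwise driver accepts any symmetric
`(Spectrum, Spectrum) -> (score, n_matched)` callable, so learned
similarity scores can be plugged in without changing downstream stages.

## k-medoids and Silhouette

Clustering uses a PAM-style alternating optimisation on the precomputed
distance matrix $d = 1 - s$: seeded random medoid initialisation, then
alternating nearest-medoid assignment and per-cluster medoid updates until
a fixed point (cap 300 iterations), with 5 random restarts keeping the
lowest cost. Ties are fully specified — nearest-medoid ties go to the
lower cluster index, medoid ties to the lexicographically smallest feature
id, and final cluster indices are ordered by medoid id — so results are
reproducible across platforms. Per-iteration costs are recorded and are
non-increasing by construction. Local search can miss the global optimum;
on random instances with $n \le 8$, $k \le 3$ the measured miss rate with
5 restarts is under 10% (the restart count is a parameter when a stronger
guarantee is wanted on small problems).

Silhouette uses the standard $(b-a)/\max(a,b)$ per point with the
convention that members of singleton clusters score 0. The $k$ grid runs
each $k$ with derived seed `seed + k` so entries do not depend on grid
composition. Grids are advisory output: the package never auto-selects
$k$, since cluster granularity is a research-question decision, not an
optimisation target.

## Embedding and distance preservation

The 2-D overview uses t-SNE in precomputed-distance mode (exact method,
random initialisation from the given seed), with the standard feasibility
bound $2 \le \text{perplexity} < (n-1)/3$ enforced. Coordinates are
mean-centred before return so serialised layouts are stable. One numerical
caveat found during development: scikit-learn's t-SNE modifies a
precomputed distance matrix in place, so the backend always passes a copy —
otherwise repeated calls silently operate on squared distances and the
determinism contract breaks.

Distance preservation is the Pearson correlation between the
$n(n-1)/2$ original distances and the corresponding embedded Euclidean
distances (Spearman available via `method="spearman"`). Pearson is the
simplest defensible default for a quality score whose exact published form
varies between tools; it is invariant under rotation, translation and
uniform scaling of the embedding. The perplexity grid, like the $k$ grid,
is advisory only.

## The set test

For one cluster (feature set) and one two-group contrast, let $X$ be the
samples × $m$ intensity submatrix with columns standardised to mean 0 and
unit sample SD (`ddof=1`; zero-variance columns are dropped with a log
line, and a fully constant set is marked *untestable*, carried as $p = 1$
— conservative), and let $c = y - \bar y$ for the binary group indicator
$y$. The statistic is the self-contained quadratic form

$$Q = c^\top \frac{XX^\top}{m} c = \frac{\lVert X^\top c \rVert^2}{m},$$

zero when no feature co-varies with the labels and sensitive to any — not
necessarily concordant — association, with highest power for small
concordant shifts across the set.

Significance uses a permutation null on the labels rather than the
asymptotic eigenvalue-mixture null of the classical global test: at the
sample sizes typical of exploratory metabolomics (three to six per group)
asymptotic results are unreliable, while permutation is exact and
assumption-light. When the number of distinct labelings
$\binom{n}{n_1} \le n_\text{perm}$, **all** labelings are enumerated and
$p = \#\{Q_\pi \ge Q_\text{obs}\}/\binom{n}{n_1}$ (the observed labeling
is included, so $p > 0$); otherwise $n_\text{perm}$ (default 9999) uniform
permutations are drawn and the add-one estimate
$p = (1 + \#\{Q_\pi \ge Q_\text{obs}\})/(1 + n_\text{perm})$ is used.
Because standardisation uses full-sample moments it is
permutation-constant, so $X$ is standardised once.

Two discreteness facts matter when auditing calibration. First, with
3 + 3 samples there are 20 labelings and every exact p is a multiple of
1/20. Second, $Q$ is invariant under label complementation
($c \to -c$), so labelings tie in complementary pairs and the attainable
exact p-values for a 3 + 3 design are $\{0.1, 0.2, \ldots, 1.0\}$.
Uniformity of null p-values is therefore checked at the attainable
levels — the empirical CDF must match the uniform CDF at each achievable
$\alpha$ (the correct validity notion for a discrete p-value); a
continuous one-sample KS statistic against U(0,1) is bounded below by the
level spacing and would flag any correct exact test.

Per-feature univariate p-values are the $m = 1$ specialisation with the
same permutation scheme; for fixed group sizes the single-feature $Q$
ranks permutations identically to the squared two-sample t statistic, so
the permutation p coincides with a permutation $t^2$ test. Univariate
p-values are deliberately **not** multiplicity-adjusted: they are
descriptive node-size inputs. Fold changes are
$\log_2((\bar x_T + pc)/(\bar x_R + pc))$ with pseudocount defaulting to
half the smallest nonzero intensity in the table, a standard stabiliser
for zero-heavy intensity data.

Set p-values are Bonferroni-adjusted at family size #clusters ×
#contrasts (untestable pairs counted). Contrasts are reference vs each
non-reference group, in sorted group order; multi-level single-model
designs are out of scope. Child seeds per (cluster, contrast) are derived
as `sha256(master|cluster|contrast) mod 2^31` — a cryptographic digest
because Python's built-in hash is not stable across runs. Univariate
p-values reuse the feature's cluster child seed, which makes a singleton
cluster's set p bitwise equal to its feature's univariate p.

## Bundle

The JSON bundle (`msfeast-bundle/1`) is self-contained: settings (all
parameters and seeds used), groups, contrasts, nodes, edges, clusters,
heatmap. Node sizes are linear maps to pixel width: for p-values
$s_{\min} + (1-p)(s_{\max}-s_{\min})$; for fold changes
$|{\rm lfc}|$ capped at `fc_cap` (default 5) then scaled. Defaults
$s_{\min}, s_{\max} = 10, 50$ px. Edges are **directed** top-K neighbour
records per node (default K = 30, capped at $n-1$), drawn regardless of
absolute similarity; the symmetric union is the renderer's concern.
Discrete similarity bins weak/moderate/strong use half-open intervals at
thresholds (0.4, 0.7), all configurable. Numbers are serialised at 6
significant digits with fixed key order, so identical runs give
byte-identical files. `validate_bundle` checks the shipped schema (via a
small in-repo subset validator), referential integrity, the Bonferroni
identity, significance-flag consistency at $\alpha$ (default 0.05), node
size bounds, and — when given the similarity matrix — edge/matrix
consistency to 1e-6. The schema is a clean-room definition; no byte
compatibility with any external dashboard is claimed.

## Synthetic benchmark generator

`simulate.SyntheticScenario` plants unambiguous structure: each cluster
owns a disjoint m/z region (width 100 Da, gap 50 Da) with a shared random
backbone of 8 fragment peaks; members jitter peak positions (±0.01 Da),
perturb intensities log-normally (σ = 0.3), and drop/add up to 20% of
peaks. Disjoint regions make the true partition recoverable by
construction, so clustering accuracy is assertable exactly. Quantification
is log-normal: per-feature log-mean ~ N(5, 1), within-group log-SD
`noise_sd` = 0.5; differential clusters shift the treatment log-mean by
`effect_size × noise_sd` (default effect 2, i.e. two within-group SDs).
Defaults use two groups of three samples — deliberately small, matching
exploratory mushroom-metabolomics-scale designs where the exact
permutation path is exercised.

What passing these benchmarks shows: the matching, clustering, testing and
export machinery is correct, calibrated (type-I error ≈ α on the
Monte-Carlo path, exact uniformity on the enumeration path) and powerful
against concordant shifts. What it does not show: performance on real
spectra, where clusters overlap in m/z space, fragmentation chemistry
produces correlated peaks across clusters, intensity distributions are
heavier-tailed, and differential effects are rarely uniform across a
cluster. The generator makes no attempt at adducts, isotopes or
chromatographic effects.

## Problem sizes and determinism

The default test and acceptance workloads use 15-feature fixtures, 50
small clustering instances, 500 null and 200 power simulation repetitions
with 199–999 permutations — sizes chosen so the whole suite verifies the
statistical claims in well under a minute each while keeping Monte-Carlo
standard errors (≈1% on rejection rates) far below the asserted margins.
Every random quantity is driven by explicit integer seeds through numpy's
PCG64; the pipeline additionally caches each stage keyed by a content hash
of its inputs, and the settings block of a bundle suffices to reproduce it
bit-identically.

## Known limitations

- Two-group contrasts only; no covariate adjustment, no FDR alternatives
  (Bonferroni only).
- Asymptotic p-values are not offered; very large `n_perm` is the only way
  to refine small p-values on the Monte-Carlo path.
- Pairwise similarity is O(n²) assignment solves; fine for thousands of
  features, not for hundreds of thousands.
- k-medoids is a local search; global optimality is only probable, not
  guaranteed (restarts trade time for reliability).
- The exact-path p-value granularity (multiples of 1/20 at 3 + 3) bounds
  attainable significance after Bonferroni at small n; this is a property
  of the design, not the implementation.
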