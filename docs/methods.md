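# Methods

## Model and procedure

### Univariate step fit

Given n finite observations of one variable, the observations are sorted
ascending and fitted with the two-level step function
f(i) = μ₁·I(i ≤ t) + μ₂·I(i > t). For each candidate split t ∈ [1, n−1],
μ₁ and μ₂ are the segment means, the *signal* is the deviation of f from
the grand mean, Σ(f(i) − μ)², and the *noise* is the residual against the
sorted data, Σ(f(i) − x₍ᵢ₎)². The fit maximizes SNR = signal/noise by
exhaustive enumeration of all splits; no minimum segment size is imposed.
The threshold is the midpoint of the order statistics straddling the
optimal split, (x₍t*₎ + x₍t*+1₎)/2, and dichotomization uses the
"≤ threshold → LOW" convention (a value landing exactly on the threshold is
LOW/unmethylated).

Implementation note: because the candidate means partition the sorted data,
noise(t) = SS_total − signal(t) exactly (the within/between ANOVA
identity). The search therefore runs on prefix sums of the centered data —
O(n) after sorting, numerically stabler than accumulating residuals, and
the identity is verified against literal-definition recomputation in the
tests.

Degenerate and boundary behaviour:

* fewer than 2 observations, or non-finite values → `InvalidInputError`;
* all values identical → `DegenerateInputError` (signal is zero for every
  split; no threshold exists);
* noise exactly zero (perfectly separated values) → SNR is `inf`, ordered
  above every finite value;
* ties among equal-SNR splits break by larger signal, then smaller t.
  Ties are detected to relative 1e-10, so exactly symmetric series resolve
  by the rule rather than by float noise in the last bits.

The maximal SNR has sharp distributional limits which double as end-to-end
checks: 3 for uniform data, ≈1.7519 for Gaussian data of any mean and
variance (both segment deviations δ² = 2/π against within-variance
1 − 2/π at the balanced split), and +∞ for a two-delta mixture.

### Bivariate step fit

For paired observations (x_k, y_k), k = 1..n:

1. Both variables are standardized to zero mean, unit variance. The sample
   standard deviation (n−1 denominator) is used; zero variance in either
   variable raises `DegenerateInputError`.
2. Each sample maps to its rank pair (i, j) — ranks 1..n per axis, ties
   broken by original sample index via stable sort, making the map a
   bijection onto grid points.
3. The height at a mapped rank point is z = x̃ + ỹ. Unmapped points take
   the lower-left running maximum z(i,j) = max_{u≤i, v≤j} z(u,v); a point
   with an empty lower-left prefix takes the global minimum height (the
   least-informative value that preserves monotonicity). The completed
   surface is non-decreasing along both axes, which the constructor
   asserts.
4. The surface is approximated on a G×G grid (G = 50 by default): each
   rank axis is cut into G near-equal-count bins (edges at
   round(k·n/G)), a cell takes the *maximum* height among samples mapped
   into it (global minimum if empty), and the monotone fill is applied at
   bin resolution by running maxima along both axes. Max-aggregation
   commutes with the lower-left max fill, so the binned surface equals the
   bin-wise max of the full-resolution surface exactly — the property the
   brute-force oracle tests exploit. Construction is O(n log n + G²).
5. The four-block step function is fitted by exhaustive search over all
   (tx, ty) ∈ [1, G−1]², maximizing SNR = Σ(f − μ̄)²/Σ(f − z)² over the G²
   cells (μ̄ the grid mean of z). The same ANOVA identity and 2D prefix
   sums make the whole search O(G²). Tie-break: larger signal, then
   smaller tx, then smaller ty; a constant surface raises
   `DegenerateInputError`.
6. The winning grid split maps back to the data scale through the upper
   rank edge r of the winning bin: threshold_x = (x₍r₎ + x₍r+1₎)/2, and
   likewise for y. With n ≥ G every edge lies in [1, n−1]; with n < G the
   constructor warns and thresholds may be unavailable.

With n samples on a G×G grid the finite-sample SNR carries a small
downward bias relative to the analytic limits (cell maxima sit slightly
below the upper cell corner, and the fill flattens sparse lower-left
regions); at n = 5,000 and G = 50 the independent-pair limits are
reproduced within a few percent (uniform ≈ 2.98 vs 3; Gaussian ≈ 1.73 vs
1.75 at seed 1).

Invariance: ranks — and hence the binning — are invariant under any
strictly increasing per-variable transform, but the surface heights are
standardized *values*, so only positive-affine transforms leave the fitted
split and SNR exactly unchanged (standardization absorbs them); a general
monotone warp reshapes the surface and may move the optimal split. The
tests assert both facts. Swapping the two variables transposes the surface
and swaps (tx, ty) and the thresholds.

### Silencing test

Dichotomizing both variables reduces a pair to quadrant counts. With N
samples, R methylated (right margin), U high-expression (upper margin) and
K in the upper-right quadrant, the one-sided p-value is
P(k ≤ K) = Σ_{k=lo}^{K} C(U,k)·C(N−U,R−k)/C(N,R), lo = max(0, R+U−N).
The sum is computed in log space (log-gamma binomial coefficients, exp-sum
rescaled by the largest term), exact to ~1e-12 relative against both
integer enumeration (N ≤ 60, every margin) and an independent
hypergeometric CDF implementation up to N = 10⁵. K = min(R, U) returns
exactly 1.0: such a table — including the R = 0 case of a group with no
methylated samples — carries no depletion evidence at all, which is why
thresholds cannot be found (and associations cannot be established) within
a single homogeneous tissue; pooling heterogeneous groups is what
populates both margins.

The direction filter excludes a pair when
upper_right − lower_left > fraction·N (strict; fraction 0.1 by default):
an excess of methylated-and-high samples of that size contradicts
silencing regardless of the p-value. The filter is applied before multiple
testing but filtered pairs still count toward the Bonferroni family size m
(the conservative choice; the alternative would shrink m after looking at
the data). Significance is p < α/m with α = 0.01 and m = the number of
pairs submitted to the screen; per-group results form their own family of
the same m tests.

Per-group testing reuses the cohort-wide thresholds by default, so a
group's quadrants are directly comparable to the pooled ones; a
`refit` mode re-derives thresholds within each group (groups where the
refit is degenerate are marked untestable, as are groups with fewer than
2 samples).

## Preprocessing

Applied in order, each with the strict inequality its wording implies:
(1) drop CpG sites whose annotated gene is absent from the expression
matrix (or unannotated); (2) drop sites with missing fraction > 1%;
(3) drop sites with β < 0.01 in > 95% of samples. Expression is
log-transformed after replacing each gene's zeros by its smallest positive
value across samples (genes zero everywhere are dropped and logged).
Log base 2 by default; ranks — and hence every 2D fit — are base-invariant,
only reported expression thresholds change, and the base is configurable.
Pairing is per CpG site (a gene with several CpGs contributes several
pairs); samples missing a value in either member are dropped from that
pair only, and pairs left with fewer than 4 samples are excluded and
logged. Sample intersection between the modalities is exact identifier
matching, performed once before filtering; all operations preserve the
shared sample order.

## Synthetic data

The generator produces cohorts with the structure the method assumes, with
ground-truth labels attached so tests never re-infer structure.

* Methylation: Beta mixtures — Beta(2, 30) for the unmethylated component
  (mean β ≈ 0.06) and Beta(15, 4) for the methylated one (mean β ≈ 0.79),
  matching the strongly bimodal [0,1]-supported marginals of promoter
  probes.
* Expression: Gaussian mixture on the log₂ scale, modes N(2, 0.8) and
  N(6, 0.8); cohort matrices are emitted on the raw scale (2^value) with a
  ~1% sprinkling of exact zeros to exercise the zero-replacement rule.
* Silencing: 40% of samples methylated; methylated → low expression mode;
  unmethylated → high mode with probability 0.5, low otherwise.
* Cohort: 992 samples in five groups of 313/227/208/129/115 — a
  pan-cancer-style design in which both methylation states are populated
  only across groups for part of the sites. Planted site classes:
  silencing in all groups; silencing in a subset of groups (independence
  elsewhere); association purely from between-group composition (each
  group internally independent and unimodal, groups differing jointly in
  level); nulls (independent bimodal marginals); plus dedicated targets
  for each preprocessing filter and a 0.2% background missing-beta rate.

What the generator does *not* emulate: probe chemistry and batch effects,
beta-value compression near the support boundaries, expression
overdispersion families, correlated sites within a gene, or realistic
group-specific marginal shifts in null sites. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
assumed mixture structure, not performance on any particular real cohort.

## Problem sizes and numerical choices

The suite exercises the analytic limits at n = 200,000 (1D) and n = 5,000
pairs at G = 50 (2D), where the limits are resolved well within their
sampling noise; oracle equivalence uses 500 random instances at n ≤ 12
(1D) and n ≤ 30, G ≤ 6 (2D); hypergeometric correctness is exhaustive over
every margin with N ≤ 60 (~635,000 tables); parameter recovery uses 200
replicates of 500-sample silencing pairs; and the end-to-end screen runs
the full 992-sample five-group cohort with 1,000 null sites. On the
planted cohort, recovery of group-restricted associations is asserted at
≥95% sensitivity: in the smallest group (115 samples) a single
unmethylated-tail sample entering the upper-right quadrant can push a
borderline table just past the Bonferroni cutoff, which is the expected
behaviour of the exact test at that group size, not an implementation
artifact. Null sites are checked to reject at no more than the nominal
rate plus binomial noise — the margin-conditional test is conservative.

Floating-point conventions collected in one place: noise values within
relative 1e-12 of zero count as exact fits (SNR = ∞); SNR/signal ties are
detected to relative 1e-10 and resolved by the deterministic tie-break;
both conventions are mirrored by the brute-force oracles.

## Known limitations

* The 50×50 grid approximation is one of several defensible binning
  schemes; the equal-count/max-aggregation choice was made for its exact
  commutation with the monotone fill, but thresholds from other schemes
  would differ slightly for heavily tied data.
* Bonferroni over all submitted pairs is deliberately conservative; no
  FDR alternative is provided.
* The SNR measures joint multi-modality, not association — two
  independently bimodal variables can produce a large SNR. Association
  claims rest entirely on the hypergeometric test, which is why both are
  reported.
* Only two-level (2×2-block) fits are supported; multi-step extensions
  and confidence intervals on thresholds are out of scope.
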