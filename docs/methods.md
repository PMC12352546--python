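# Methods

## Model and statistic

`prominet` treats a weighted connectivity matrix and a fixed node partition
as the two *observed* priors of a stochastic block model and asks how
prominent the partition is on the graph. Because both `G` and `σ` are
observed, inference is closed-form rather than posterior sampling:
`p = Ω/n` by the law of large numbers, and `W = C / C_max` elementwise,
where `C` accumulates per-block-pair edge counts (binary mode) or absolute
edge-weight sums (weighted mode) and `C_max` counts the available node
pairs per block pair. The community profile matrix `PQ = n·diag(p)·W` then
has entry (i, j) equal to the expected number of community-`j` neighbors of
a community-`i` node, and the prominence statistic is `SNR = λ₂²/λ₁` over
its eigenvalues ordered by descending magnitude. `SNR > 1` (strict) is the
Kesten–Stigum weak-recovery condition; the degree-scaling factor is pinned
at `s_t = 1` (constant-degree regime), which is the regime in which that
threshold applies. Binary mode infers genuine Bernoulli edge probabilities;
weighted mode is an extension of the same algebra to absolute weights and
is read as a prominence measure, not a generative fit.

Signs are dropped deliberately: both thresholding (`|a_uv| ≥ τ`) and the
weighted sums use magnitudes, so anticorrelations count as coupling
strength. A `signed=True` escape hatch retains only `a_uv ≥ τ` for users
who want positive-only graphs.

## Pair-counting convention

`C_max` uses unordered pairs with self-pairs excluded: diagonal
`Ω_i(Ω_i−1)/2`, off-diagonal `Ω_iΩ_j`, with `C` counting unordered pairs.
This is exact for simple graphs. The alternative literal outer-product
convention `C_max = ΩΩᵀ` (self-pairs included on the diagonal, ordered
sums) is available as `cmax="outer"`; the two give identical off-diagonal
`W` and differ on the diagonal by a factor `(Ω_i−1)/Ω_i`, i.e. an `O(1/Ω)`
term that vanishes for communities of realistic size.

## Numerical choices

* `PQ = nPW` is nonsymmetric but similar to `S = n P^{1/2} W P^{1/2}`
  under conjugation by `P^{1/2}`, so its spectrum is real; eigenvalues are
  computed on `S` with a symmetric solver. The test suite keeps a direct
  dense eigensolve of `PQ` as an independent oracle (agreement to 1e−8 on
  200 random instances) plus the analytic two-block closed form
  `(a−b)²/(2(a+b))` (agreement to 1e−10).
* λ₂ may be negative; squaring makes the statistic sign-free.
* Degenerate inputs never abort a sweep: `k = 1`, an empty thresholded
  graph, or `λ₁ ≤ 1e−12` all return SNR = 0 with a logged warning.
  Blocks of size 1 have no within pairs; their diagonal `W` entry is 0.
* Thresholds compare with `≥`, so an entry equal to a grid point is
  retained and grid endpoints are reproducible; exact zeros are never
  edges. The default grid is 0 to 1 inclusive in steps of 0.05 (21 points).
* Ties in `argmax_τ SNR` resolve to the smallest τ (mildest pruning). If
  the super-threshold set of the vetting profile is non-contiguous,
  `[a_w, b_w]` is the longest run, earliest on ties, and the full boolean
  mask is kept on the result for transparency.
* An empty vetting interval is reported (all membership flags False, loud
  warning), not raised, since individual optima may still be of interest.

## Null model, modularity, AMI

The null model permutes the node-to-community assignment uniformly
(community sizes preserved exactly), 100 shuffles by default with shuffle
`s` seeded `seed + s`. Modularity is the standard configuration-null form
`Q = (1/2m) Σ (A_uv − α k_u k_v / 2m) δ(σ_u, σ_v)` with tuning parameter
`α` (default 1); weighted graphs substitute weighted degrees and total
weight. Q maximization uses a seeded single-pass Louvain-style multi-level
heuristic; AMI uses the exact hypergeometric expected-MI correction with
arithmetic-mean normalization (plain NMI behind a flag). Full posterior
weighted-SBM inference is out of scope; `ami` accepts any externally
inferred partition for comparison.

## Synthetic data

The generators emulate the situation the pipeline targets: a cohort of
FC-like matrices with planted block structure. `sample_fc` draws entries
directly from block-conditional Gaussians — mean `mu_within` (default 0.6)
inside blocks, `mu_between` (default 0.1) across, entry noise `sd` (default
0.02), clipped to ±0.999 — rather than simulating latent time series and
correlating them; this keeps the contrast analytically controlled so
binomial/normal standard-error checks on parameter recovery are exact.
`sample_cohort` jitters each subject's two block means by
`Normal(0, subject_sd)` (default 0.05) with per-subject seed `seed + i`,
emulating individual differences in coupling strength as the dominant
heterogeneity: subject optima then scatter around the group optimum.

The default noise scale is the well-estimated-FC regime (block contrast
25× the entry noise): a subject's optimal threshold is set by the upper
tail of its between-block weights, so the gap between the mean individual
optimum and the group-average optimum grows with `sd` (≈ 2.75·sd for these
grids); at `sd = 0.02` the two agree to within one grid step, while the
subject jitter still dominates and produces realistic spread in the
individual optima. What these synthetics do **not** emulate: heavy-tailed
and spatially autocorrelated Pearson noise, negative mean couplings,
hub/degree structure inside blocks, and non-assortative (core–periphery,
disassortative) mesoscale organization. Tests passing on them show the
machinery is correct and self-consistent, not that any particular brain
dataset is in the weak-recovery regime.

Acceptance-scale study conditions, chosen once: the null ensemble runs on
one planted-partition graph with n = 400, four equal blocks, within-block
edge probability 0.25, between 0.02 (closed-form-strong contrast), 100
shuffles; the pipeline and back-test run on a Γ = 20 cohort of n = 120
(four blocks of 30) with the generator defaults above and seed 7.

## Back-test peak comparison

On strong synthetics the AMI-vs-τ curve attains its maximum on a plateau
(detection recovers the planted blocks exactly over a range of τ), so
"the SNR and AMI peaks agree" is operationalized as: the distance from the
SNR argmax to the *nearest* AMI maximizer is at most two grid steps. The Q
score, by contrast, keeps rising past the SNR peak into the fragmented
high-τ range — reproducing its known failure as a threshold guide for an
a priori partition.

## Limitations

* Weighted-mode SNR inherits the weak-recovery interpretation only by
  analogy; the theorem is stated for Bernoulli SBMs.
* The Louvain back-test is a single seeded pass, not consensus clustering;
  detected partitions can vary with the seed on weak structure.
* Exact recovery (Chernoff–Hellinger) criteria are not implemented.
* No neuroimaging formats or preprocessing: inputs are dense delimited-text
  matrices and two-column partition files.
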