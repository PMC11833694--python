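# Methods

## The model

Nascent RNA sequencing (NRS) protocols such as PRO-seq record the 3' ends
of nascent transcripts, which mark the active sites of transcriptionally
engaged RNA polymerase II at single-nucleotide resolution.  Within a gene
body at steady state, polymerase density at a site is inversely
proportional to the local elongation rate: polymerase spends more time
where it moves slowly, in the same way that cars pile up where traffic is
slow.  `elongrate` turns this into a generative model for read counts.

For gene *j* with sites *i = 1..N_j*, the local relative elongation rate
is a log-linear function of per-nucleotide covariates,

    zeta_ij = exp(kappa . Y_ij),

with a single coefficient vector `kappa` shared across all sites and
genes, so that sparse information about rate correlates pools across the
genome.  Read counts are conditionally Poisson,

    X_ij ~ Poisson(lam * chi_j / zeta_ij),

where `lam` is the mean read depth over all analyzed sites and `chi_j` is
a per-gene compound parameter — the read-depth-scaled ratio of productive
initiation rate to average elongation rate.  Initiation rate, gene-average
elongation rate, and depth are not separately identifiable from
steady-state data; only `chi_j` is.  `zeta_ij` is therefore a relative
(dimensionless) rate: values below 1 mark local slow-downs, above 1 local
speed-ups.

Dropping terms constant in the parameters, the joint log likelihood is

    l = sum_j [ s_j log chi_j - kappa . T_j - lam * chi_j * U_j ]

with sufficient statistics `s_j = sum_i X_ij`, `T_j = sum_i X_ij Y_ij`
(computed once) and `U_j = sum_i exp(-kappa . Y_ij)` (recomputed per
iteration).  Some presentations absorb `lam` into `chi`; we keep it
explicit so that the analytic conditional optimum takes the form
`chi_j = s_j / (lam * U_j)` while the objective remains exactly the
Poisson likelihood.  The two parameterizations produce identical fits
because only the product `lam * chi_j` enters the model.

### Optimization

`glm.fit` runs gradient ascent on `kappa` with `chi` fully re-optimized
analytically at every step.  Gradient component *n* is
`sum_j [lam * chi_j * V_jn - T_jn]` with
`V_j = sum_i exp(-kappa . Y_ij) Y_ij`.  Design choices:

- **Learning rate.**  Default 1e-7, with adaptive control: a step that
  would decrease the (penalized) objective is rejected and the rate is
  halved; accepted steps grow the rate by 1.05x.  The growth factor is
  ours: with a fixed rate, problems whose read totals differ by orders of
  magnitude from the one the default was tuned on either diverge or crawl.
  The objective trace is monotone by construction.  A fixed-rate mode
  (`adapt_lr=False`) aborts after ten consecutive objective decreases.
- **Stopping.**  `max |delta kappa| < 1e-8` or 50 000 iterations.
- **Initialization.**  `kappa = 0`, which makes `chi_j = s_j/(lam N_j)`
  analytic.
- **Intercept.**  None by default: a free intercept rescales every
  `zeta_ij` uniformly and is absorbed by the per-gene `chi_j`, so it is
  not identifiable.
- **Masked sites** (internal TSS windows, regulatory-element peaks) are
  excluded from all sums rather than zero-filled; a zero count at an
  analyzed site is informative (it suggests fast elongation), so
  zero-filling masked sites would mimic infinitely fast regions.
- **Degenerate genes** with `s_j = 0` are excluded with a warning;
  their `chi` would be 0 and they contribute no information about kappa.

### L1 penalty and selection of nu

For high-dimensional k-mer features the objective gains an L1 term
`-nu * sum_n |kappa_n|` (L2 and elastic-net variants are available behind
the same interface but L1 is the default for sparse feature sets).  The
subgradient convention: coefficients at exactly 0 move only when the
unpenalized gradient exceeds `nu` in magnitude, and a coefficient whose
update would cross 0 is clipped to exactly 0.  This is the proximal
reading of `sgn(0) = 0`; it yields exact zeros, so "number of nonzero
coefficients" is well defined rather than an artifact of the final step
size.  Nonzeros are counted above a threshold of 1e-6.

`glm.select_nu` chooses the penalty strength on held-out genes: genes are
split 80/20 once (seeded); for each `nu` in a grid (strongest first, each
fit warm-started from the previous solution) the model is fitted on the
training genes and scored on the test genes by `AIC = 2k - 2 l_test`,
where `k` counts nonzero coefficients and `l_test` re-optimizes the test
genes' `chi` analytically.  Held-out `chi` parameters are not counted in
`k`: they are re-estimated in closed form on both arms, so they cancel in
comparisons across `nu`.  The default grid is log-spaced over
`[0.25, 8] * sqrt(total reads)` — under the null, per-feature score
components fluctuate with sd of order `sqrt(sum_j s_j)` for standardized
features, so penalties bracketing that scale span the useful range.

A caveat worth stating: scoring on a held-out arm charges each retained
coefficient 2 likelihood units against the *test-arm* information, which
is ~1/4 of the training information under an 80/20 split.  Weak but real
features whose per-coefficient held-out gain is below 2 are therefore
dropped, and the smaller the gene set, the more real features fall below
that line.  This matters for the scaled-down 5-mer benchmark; see
"Benchmark scales" below.

### Sparse sufficient statistics

Indicator features are almost all zero before standardization but dense
afterwards.  `U_j` and `V_j` are therefore computed from the raw sparse
values and mapped through the affine standardization transform:
`kappa . Y_i = (kappa/sd) . Yraw_i - kappa . (mean/sd)` gives the
exponent via a sparse product, and
`V_j = (Vraw_j - mean * U_j) / sd` recovers the standardized-scale
statistics.  Cost per iteration is proportional to the nonzero raw
entries; the result agrees with the dense computation to ~1e-10.

### 3'-nucleotide sequence bias variant

PRO-seq library construction could in principle prefer particular 3'
bases.  The bias variant pre-estimates bulk 3'-base frequencies `pi_b`
from the read counts themselves and rescales the per-base read-depth
factor as `rho_b = 4 pi_b`.  Each site's exponent gains an offset
`-log rho_i`, and the objective gains `sum_i X_i log rho_i`;
overrepresented bases are discounted so that k-mer coefficients reflect
departures from the bulk composition.  With uniform composition
(`rho = 1`) the code path is identical to the unbiased model, bit for bit.

## Feature construction

- **k-mer indicators.**  One 0/1 feature per k-mer.  For odd k the k-mer's
  middle base aligns with the polymerase active site; for even k the
  1-based position k/2 does, so the active site sits just left of center.
  Windows that overrun the TU or contain N score 0.  A signed shift slides
  the whole alignment up- or downstream (negative = upstream), used to
  probe sequence context ahead of or behind the active site.
- **Smoothing filters.**  `filtered[i] = (1/Z) sum_k raw[i+k+delta] F(k)`
  over lags `[-r, r]`, zero-padded at the boundaries, `Z = sum F(k)`.
  Gaussian filters (`F(k) = exp(-(k/sigma)^2/2)/sigma`) suit broad
  chromatin-immunoprecipitation-scale features: defaults r=400, sigma=100
  for CTCF/histone marks and r=500, sigma=200 for RNA stem-loops.
  Generalized filters carry explicit non-negative weights per lag,
  estimated from read-depth metaplots around the feature of interest as
  the profile's excess over its median floored at zero (the estimation
  rule is this package's choice; only the "estimated from metaplots" idea
  is inherited).  Filters are applied before standardization so the
  standardization invariants hold for the covariates the GLM sees.
- **Standardization.**  Each feature is shifted/rescaled to mean 0, sd 1
  over analyzed, defined sites (population sd — divide by n — fixed for
  determinism).  Features defined only at a subset of sites (DNA
  methylation at CpGs) are standardized over their defined sites and set
  to exactly 0 elsewhere so undefined positions carry no signal; this is
  what lets methylation coefficients separate from plain cytosine
  effects.  Constant features are dropped with a warning.  Standardizing
  twice composes affine transforms and is a no-op.

## SimPol

The simulator tracks individual polymerases per cell.  A polymerase at
site *i* steps forward at rate `zeta_bar * zeta_i` (moves/min) unless the
polymerase ahead blocks it (footprint default 1 nt — collisions are rare
in the regimes simulated, so footprint effects are second order); new
polymerases enter at site 1 at rate `alpha` when it is free; polymerases
leaving the last site exit.  `zeta_bar` defaults to 2000 moves/min, i.e.
the ~2 kb/min mammalian average gene-body elongation rate.

Two integrators:

- **Time slices** (the reference definition): Bernoulli move attempts per
  slice of 1e-4 min, at most one move per slice; per-slice probability
  `zeta_bar * zeta_i * dt` must not exceed 1.
- **Event-driven** (fast path): because polymerases cannot pass one
  another, trajectories can be generated front to back; the departure
  time of polymerase k from site i is
  `max(arrival_k(i), departure_{k-1}(i+footprint)) + Exp(rate_i)`, which
  is exact for the continuous-time model by memorylessness.  Initiation
  events form a Poisson process thinned by first-site availability.

The two schemes share mean sojourn times, hence identical expected
occupancy (`alpha / (zeta_bar * zeta_i)` in the rare-collision regime —
the 1/zeta law); the suite checks their statistical agreement.
Occupancy is averaged over the second half of the simulated time
(default total 20 min, enough for equilibration at these rates: a
polymerase traverses 10 kb in ~5 min); a final-state snapshot is
available by flag.  Read counts are Poisson with mean proportional to
occupancy, scaled to a target mean depth.

## Synthetic benchmarks

**Epigenomic benchmark.**  Six features named for the tracks they
emulate: CTCF, four histone marks (H3K36me3, H3K9me1, H4K20me1,
H3K79me2), and RNA stem-loops.  Covariates are sampled in 1-kb blocks
from a built-in synthetic library and tiled jointly across features,
preserving the library's cross-feature correlation structure.  The
library itself draws per-block feature presence by thresholding a shared
latent Gaussian (histone marks mutually correlated at latent r = 0.3-0.6,
narrow features weakly coupled), paints present features as
annotation-width indicator runs (20 nt for CTCF, 30 nt for stem-loops,
block-wide for marks), and smooths each with its standard filter.  True
coefficients are the six published K562 estimates for these features
(-0.022, -0.095, -0.067, -0.041, +0.030, -0.051); local rates are
`zeta_i = exp(kappa . Y_i) + delta_i` with `delta_i ~ N(0, 0.1 sd)`
floored at 1e-3 (additive noise can push the rate non-positive; the
floor preserves positivity with negligible distortion).  Per-TU
initiation rates are log-normal with median 1 event/min (the median is
the stated condition; the log-normal shape with sigma_log = 0.8 is our
choice of a realistic long-tailed form).  Target mean read depth
defaults to 0.5 reads/nt, a realistic gene-body depth for robustly
expressed genes in deep PRO-seq libraries.  TUs are split 80/20 into
train/test per replicate.

**5-mer benchmark.**  Random uniform-base sequences; 100 of the 1024
5-mers receive coefficients uniform in [-0.3, 0.3] applied to the *raw*
0/1 indicators, so the true rate at a site is `exp(kappa)` of the 5-mer
centered there (range ~[0.74, 1.35]); remaining 5-mers are 0; no additive
noise.  The fit operates on standardized indicators as in real analyses;
predictions and truth are compared by squared Pearson correlation, which
is invariant to the affine change of scale between the two
parameterizations.

**What the generators do not emulate:** promoter-proximal pausing and
termination peaks, premature termination, internal TSSs, U-shaped
gene-body trends, mappability artifacts, and overdispersion beyond
Poisson.  Passing benchmarks therefore demonstrate correct recovery of
the model's own data-generating process under realistic polymerase
physics — not robustness to the full messiness of real NRS data, which
is what the preprocessing module exists to mitigate.

### Benchmark scales

Desk-scale defaults keep the full pipeline inside a few CPU-minutes per
replicate: epigenomic runs use 2 replicates x 20 TUs x 10 kb x 500 cells
(the published experiment: 10 x 100 TUs x 5000 cells); 5-mer runs use 50
TUs (published: 200) with the event-driven integrator.  Parameter
recovery holds at these scales.  One behavior is strongly
scale-dependent: held-out-AIC penalty selection.  With 200 TUs the
per-coefficient held-out likelihood gain of a true 5-mer feature
(~`s_test * kappa_std^2 / 2` ~ 3) exceeds AIC's charge of 2, so the
selected model keeps ~100 features; with 50 TUs the same gain is ~0.7,
and the AIC minimum sits at the sparsest model.  This is a property of
the published selection rule under 4x down-scaling, not of the
implementation; the acceptance harness reports what the rule produces at
the stated scale.

## Preprocessing

- **Gene-body trimming**: [TSS+2250, TTS-250) in transcription
  orientation; bodies under 6 kb dropped.  The TSS offset clears
  promoter-proximal pause peaks; the TTS offset clears termination
  pile-ups.
- **Internal-signal masking**: peak intervals, plus 2-kb windows centered
  on capped-RNA 5'-end sites with counts strictly greater than 10.
- **LOESS flattening**: genes mapped to 1000 relative-position bins,
  median-normalized, cross-gene mean profile smoothed by LOESS
  (statsmodels lowess, span 0.3 — the bin count and span are our
  defaults; the published analysis states neither), curve rescaled to
  mean height 1 and floored at 0.1 to avoid division blow-ups at the
  extreme ends; counts divided by the curve height at their position.
- **Pausing locations**: non-overlapping 200-bp windows tiled from the
  5' end (partial final window dropped), ranked by summed counts, top 5,
  ties to the 5'-most window.
- **Coverage ratio**: counts divided by the gene-body mean, pooled mean
  over feature-covered sites divided by pooled mean over uncovered sites.

## Evaluation

Windowed r2 averages predicted and observed counts in non-overlapping
windows per TU, pools windows across TUs (a per-gene averaging mode is
available by flag), and reports squared Pearson correlation per window
size.  5-mer coefficient summaries split k-mers by coefficient sign, take
the top 50 per group by |kappa|, K-means-cluster the scalar coefficient
values (K = 2, 10 restarts, seeded), and emit per-cluster
position-frequency matrices (unweighted base frequencies across member
5-mers) for logo rendering.

## Known limitations

- The model reads *relative* rates only; absolute elongation speeds
  require time-course data.
- Poisson sampling understates technical overdispersion in real
  libraries; batch-resampling standard errors (`fit_batches`) partly
  compensate.
- The event-driven integrator assumes initiation attempts lost while the
  first site is occupied are dropped (thinning), matching the slice
  scheme's semantics; queued initiation would need a different model.
- Held-out-AIC penalty selection is conservative on small gene sets (see
  "Benchmark scales").
- bigWig input requires the optional pyBigWig dependency; bedGraph is
  the native, bit-exact format.
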