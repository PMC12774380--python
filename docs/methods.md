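# Methods

## Model

For gene *i* in cell *j*, the reference-allele count m_ij out of the total
allelic count n_ij is modeled as beta-binomial,

    P(m | n, α, β) = C(n, m) · B(α + m, β + n − m) / B(α, β),   α, β > 0,

parameterized by the mean allelic ratio μ = α/(α+β) and the dispersion
θ = 1/(α+β).  θ → 0 recovers binomial sampling; θ > 1 produces U-shaped
per-cell ratio distributions in which individual cells express mostly one
allele.  Cells with n_ij = 0 carry no allelic information and contribute
nothing to the likelihood.

Per-gene maximum likelihood runs in (log α, log β) with L-BFGS-B and
analytic digamma gradients, so positivity holds by construction.
Initialization is method-of-moments on per-cell ratios (intraclass
correlation inverted to α+β), falling back to (1, 1); because the
likelihood flattens along the θ → 0 valley, a second start from (1, 1) is
tried whenever the moment start is far from it, and the better optimum
kept.  α+β is capped at 1e6 and floored at 1e-6: (near-)monoallelic genes
are legitimate downstream signal, so boundary fits are reported with a
flag, never raised as errors.  All computations use log-gamma forms; no
factorials are expanded.

## Dispersion trend and selective shrinkage

Allelic dispersion falls with coverage.  The transcriptome-wide trend

    log θ̂_i = f(log n̄_i) + ε_i,

with n̄_i the mean total count over informative cells, is fit by robust
local regression (statsmodels lowess, local-linear, span 0.75, three
robustness iterations; configurable span).  Outside the fitted range the
trend extends as a constant.  The trend value θ̄SH_i is the expected
dispersion for genes at matched expression, and each gene's moderated
dispersion is the weighted-likelihood closed form

    θ̂WL_i = ( (N/(N−1)) · θ̂_i + δ̃ · θ̄SH_i ) / (1 + δ̃),   δ̃ = δ/(N−K),

with defaults N = 30, δ = 50, K = 2 (δ̃ ≈ 1.79).  The δ/(N−K) reading of
the overfitting adjustment is the default because shrinkage should weaken
as effective information grows; multiplication is available via
configuration, as is gamma-MLE fitting of the dispersion distribution for
diagnostics.

Genes with intrinsically tiny dispersion — biologically constrained
allelic output — would be *inflated* by shrinkage, costing power.  They
are flagged (θ̂ below 0.001 for real data, 0.005 for simulated data; an
alternative residual rule based on the MAD of ε_i is available, in both a
signed-threshold and the literal squared-MAD form) and keep their
empirical estimate.  For the single-dataset tests the trend is refit after
excluding flagged genes and the shared estimates re-evaluated for all
genes; if too few genes remain the all-gene trend is kept.

## Tests

All four tests are beta-binomial likelihood-ratio tests on genes passing
the coverage filter (≥ 5 cells with ≥ 5 reads, after removal of genes
detected in < 10 cells).  Estimation and shrinkage run on raw counts;
when size factors are supplied, testing runs on counts scaled cell-wise
and re-integerized (round half-to-even, reference clipped to total).

**Mean.**  H0: μ = x with the gene's moderated dispersion (empirical for
flagged genes); H1: μ free at the same dispersion, profiled by
golden-section on the logit scale.  LRT against χ²₁, BH-FDR across tested
genes.  The background x is 0.5 for simulated data or the pooled
sum(ref)/sum(total) over autosomal non-imprinted genes for real data
(count-weighted pooling is the default estimator; a per-gene-mean variant
exists).  The reported effect is μ̂ and the allele-symmetric odds ratio
log2(μ̂/(1−μ̂)) − log2(x/(1−x)).

**Variance.**  H0: θ = θ̄SH (trend); H1: θ = θ̂WL, with μ fixed at the
gene's MLE throughout.  Because the alternative is a moderated estimate,
not a free parameter, χ² theory does not apply; calibration is by
parametric permutation: B = 500 replicates of reference counts drawn from
BetaBinomial(n_ij, μ̂, θ̄SH) conditioned on the observed totals, each
replicate's dispersion re-estimated by profile MLE (golden section on
log θ) and re-shrunk against the *fixed* original trend (refitting the
trend per replicate would be circular and 500× costlier).  The observed
statistic passes through the identical functional, so observed and
replicate values compare like with like.  p = (1 + #{LR* ≥ LR_obs})/(1+B)
— the add-one estimator, never exactly zero.  Direction is "over" when
θ̂WL > θ̄SH.  Replicate flag status is re-derived from the replicate's own
dispersion via the θ-threshold rule.  Null-regime p-values lean slightly
conservative (replicate dispersions inherit the estimator's downward bias
twice); they never lean anti-conservative in our calibration runs.

**Group-mean / group-var.**  Cells carry discrete group labels; parameter
estimation, trend fitting and shrinkage run globally and per group.  Two
deliberate choices differ from the single-dataset pipeline, both because
group designs can place entire parameter regimes below the low-variance
cutoff: the trend is fit on all genes, and shrinkage is non-selective.
The group-var test compares H0 (μ_glob, θ̂WL-global) against
H1 = Σ_g ℓ(μ_glob, θ̂WL_g).  The group-mean test lets per-group means vary
(joint per-group MLEs) against a shared-mean null; its default null shares
the alternative's per-group dispersions ("matched"), so the LRT isolates
the mean change and per-gene dispersion noise cancels — with a
single-dispersion null (trend or global shrunken, both available) that
noise leaks into the statistic and grows with coverage, which measurably
destroys specificity on deeply covered homogeneous genes.  Both tests are
referred to χ² with 1 degree of freedom by default, reproducing the
published operating characteristics; the classical L−1 choice is a
configuration away.  Statistics are clamped at zero when numerical error
makes a nested difference marginally negative.  The recommended coverage
filter for group-var is stricter (≥ 15 cells per group with ≥ 5 reads):
variance changes need more information than mean changes.

**Multiple testing.**  Benjamini-Hochberg step-up across the tested gene
set; NA (untested) genes pass through.

## Monoallelic classification

From the fitted shapes: monoallelic iff α < 1 or β < 1, with α the shape
tied to the reference allele (α < 1 ≤ β means cells rarely express the
reference, i.e. monoallelic for the alternate).  Random monoallelic
expression (RME): both shapes < 1 and |α−β| < 0.5 (candidate), confirmed
when the variance test supports over-dispersion at FDR < 0.05.  Incomplete
X inactivation: an X-linked, predominantly monoallelic gene with per-cell
ratios in [0.25, 0.75] in ≥ 15% of informative cells and ≥ 5 such cells;
informative means ≥ 2 reads, since a single read cannot show biallelism,
and the fraction uses informative cells as denominator.  Precedence:
rme_confirmed > rme_candidate > incomplete_xci > monoallelic_* >
biallelic.

## Synthetic data

The generator emulates droplet scRNA-seq allelic counts over a panel of
highly variable genes.  Totals: gene relative abundances log-normal on the
ln-CPM scale (σ = 2.1, chosen so the realized expression quantiles match
the strata used for benchmarking — the top 10% of genes form the high
stratum, the next 50% medium, the remaining 40% low, with the low/medium
and medium/high boundaries near ln TPM 3 and 8); gamma per-cell size
factors (shape 10); two cell archetypes along a latent pseudotime axis
scaling gene means (log-fold sd 0.35), standing in for low-dimensional
latent cell structure; negative-binomial counts (size 1.0) with 5%
zero-inflation; median panel depth 60,000 counts per cell, the coverage
regime in which most panel genes are testable, as in the benchmark designs
this reproduces.  Allelic counts: per-gene beta-binomial at configurable
(μ, θ), or explicit (α, β) pairs for RME genes (independent uniforms on
(0.2, 0.9) conditioned on |α−β| < 0.5 by default — a stand-in for
estimates from real RME genes).  Group scenarios cut the pseudotime axis
into equal tertiles and draw per-bin counts; the canonical designs are
mean change (0.45, 0.5, 0.55) at θ = 1e-3, variance change (1e-3, 0.05,
0.2) at μ = 0.5, and an all-control run at (0.5, 1e-3).  Scenario and
control are scored as separate datasets so the two are not coupled
through one BH threshold.  RME benchmark panels embed RME genes at a 1:3
ratio against balanced background genes (θ log-uniform on 0.005–0.3) at
matched expression (~1 count/cell) with heavy-tailed totals (NB size
0.15): real RME genes are detected in a minority of cells yet still carry
multi-read cells, which only a strongly overdispersed totals model
reproduces at that mean.

What the generator does *not* emulate: ambient RNA and doublets, gene
length effects (UMI convention: TPM ≡ CPM), mapping bias (the background
ratio is exactly the configured μ), batch structure, and continuous
trajectories beyond the single latent axis.  Passing benchmarks therefore
demonstrate correct operating characteristics under the stated generative
model, not robustness to those artifacts.

Benchmark scoring uses all simulated genes as denominator (an untestable
signal gene is a miss; an untested control gene is a correct
non-rejection); per-tested-gene rates are available via an option.
Dispersion strata: θ < 0.005 low, ≥ 0.45 high (0.45 vs 0.4 is
configurable), between medium.

## Numerical choices

Golden-section profile searches run on logit μ ∈ [−13, 13] and
log θ ∈ [log 1e-6, log 100]; permutation log-likelihoods use count-table
log-gamma evaluation for UMI-scale counts and direct broadcasting for
deeply covered genes.  LRT statistics are clamped at 0; permutation ties
count toward the p-value (≥ with 1e-12 slack).  Per-gene permutation
streams derive from (seed, gene index), so results are reproducible and
independent of which other genes are tested.  Benchmarks at desk scale use
1,000-gene × 3,000-cell panels for the group designs and 2 replicates of
500 RME + 1,500 background genes at 500 cells for RME recovery.

## Known limitations

The group tests' 1-df reference is anti-conservative in principle for
3-group alternatives; it is the published convention and is paired here
with dispersion-matched nulls that keep control-data false positives near
zero, but users wanting strict type-I guarantees should set group_df =
L−1.  The variance test's empirical p is mildly conservative in the null
regime (see above).  Size-factor estimation is out of scope — supply
externally computed factors (pooled deconvolution and the like); a
library-size fallback exists.  Haplotype phasing, read mapping, and
covariate-adjusted allelic models are out of scope.
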