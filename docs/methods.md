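# Methods

This note documents the statistical procedures implemented in
`methburden`, the choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Synthetic cohorts

Methylation is simulated on the logit(β) (M-value-like) scale and
back-transformed, which keeps β strictly inside (0, 1) and reproduces the
characteristic bimodal β distribution.  Per probe the signal is

    logit-signal = baseline + sex term + diagnosis term (by sex)
                 + cell term + batch term + noise,

with the whole signal multiplied by a compression factor (default 0.8)
for type-II probes, emulating the type-I/II chemistry bias that BMIQ
exists to correct.  Planted effect sizes are specified on the β scale and
converted to logit offsets at each probe's baseline (dividing by the
compression factor), so the realized group difference in β matches the
configured magnitude regardless of probe chemistry.

Key defaults and why:

- **Sample sizes** 41/41 female and 41/72 male case/control, 24 F / 72 M
  among controls for the baseline sex-difference analysis, and 9/11 +
  26/30 for the replication cohort — the discovery/replication design the
  pipeline targets.
- **Planted effects** |Δβ| = 0.08 (female) and 0.05 (male); shared
  probes carry same-sign effects in both sexes by default (a config
  switch flips the male sign to exercise the interaction analysis).
  These magnitudes are typical of brain case/control EWAS top hits; the
  female > male asymmetry is the regime under study, not an estimate of
  any real cohort's effect distribution.
- **Effect placement**: planted probes draw mid-range baselines
  (logit ~ N(0, 0.5)); variable, disease-responsive CpGs are
  predominantly intermediate-methylation in brain, and it keeps the
  β-scale magnitude interpretable.  Effects are planted only on clean
  autosomal probes so QC filtering does not silently remove truth.
- **Noise** sd 0.35 on the logit scale (≈ 0.05–0.09 β-scale sd at
  mid-range), **batch shift** 0.05 β units between two batches, probe
  annotation with ~30 % promoter features, ~0.5 % flagged probes per QC
  category, chrX/chrY fractions 4 % / 0.2 %.
- **Sex chromosomes**: chrY probes are intermediate-to-methylated in
  males and near β = 0.1 with high noise in females (no Y chromosome,
  only cross-hybridization); female chrX signal is pulled toward
  intermediate values, a coarse stand-in for X-inactivation mosaicism.
- **Regulatory resources**: genotypes are generated by cutting a
  liability correlated with the probe's realized β at Hardy–Weinberg
  quantiles (r = 0.5 by default), expression correlates with logit(β) at
  |ρ| = 0.8 with configured sign, GWAS hits are placed inside the windows
  of female-DMP-linked SNPs when enrichment is requested, and the PPI
  graph is a sparse random graph with a planted densely connected module
  over genes carrying DMP promoter probes.
- A single seed fans out to per-component substreams
  (`numpy.random.SeedSequence.spawn`), so each stage is reproducible in
  isolation.  A replication cohort can be generated against an existing
  cohort's annotation and truth table, sharing the planted biology while
  drawing fresh subjects.

What the generator does **not** emulate: spatial correlation along the
genome, LD beyond the single-SNP liability construction, probe-specific
measurement error, age/PMI-dependent drift, and any dependence between
baseline sex differences and case/control effects — sDMP status is
planted independently of the diagnosis effects, so enrichment odds ratios
of DMPs in sDMPs hover near (or below) 1 on synthetic data; the in-study
printed contingency tables are the reference for that statistic.
Passing tests therefore establish the correctness and calibration of the
procedures, not the effect sizes to be expected on real cohorts.

## Preprocessing

- **Probe filters** (fixed order, counts reported per criterion):
  detection p > 0.01 in strictly more than 5 % of samples; beadcount < 3
  in at least 5 % of samples (the "at least" wording makes this bound
  inclusive, unlike the strict detection-p rule); then the non-CpG,
  SNP-related, multi-mapping and low-quality annotation flags.
  Sex-chromosome probes are retained.  Samples lose their place only when
  their failed-probe fraction strictly exceeds 10 %.  Filtering is
  idempotent.
- **Sex prediction**: 2-means on standardized (mean chrX β, mean chrY β);
  the cluster with the higher chrY mean is male.  Mismatches against the
  reported sex are listed, never auto-dropped.
- **BMIQ**: per sample, a 3-state (U/H/M) beta mixture is fit by EM
  separately to type-I and type-II probes.  The M step uses weighted
  method-of-moments beta estimates; EM stops on a 1e-4 relative
  log-likelihood increment *or* when the parameters stabilize
  (the MoM-EM likelihood has a long flat tail during which the fitted
  mapping no longer changes), with a 200-iteration cap; a sample whose
  fit still fails passes through unchanged with a warning.  Type-II U
  probes are mapped through the beta CDF onto the type-I U quantiles, M
  probes through the upper tail onto type-I M, and H probes are linearly
  dilated between the transformed U maximum and M minimum.  Type-I
  values are bit-identical in the output, and the transform is monotone
  within each type-II state.
- **Cell deconvolution**: per sample, constrained least squares
  ‖β − Fρ‖² with ρ ≥ 0 and Σρ ≤ 1 over the probes shared with the
  reference (SLSQP; at least 50 shared probes required).
- **Batch correction**: ComBat-style parametric empirical Bayes on
  logit(β).  Batch locations get a normal prior, scales an inverse-gamma
  prior (moment-matched), solved by the standard fixed-point iteration;
  the biological design (diagnosis, sex) is protected in the
  standardization.  A single batch is the identity; a batch perfectly
  confounded with a protected covariate is an error naming the
  confounding.  A second batch variable (e.g. chip position) is applied
  by calling the correction sequentially.
- **Surrogate variables**: logit(β) is residualized on the design
  (intercept added if absent) and decomposed by SVD.  k is chosen by
  permutation parallel analysis — entries are permuted within each probe,
  the *permuted matrix is residualized the same way* (otherwise the
  observed residual, confined to an (n − rank)-dimensional space,
  systematically beats the null), and observed singular values must
  exceed the null's 95th percentile, counted from the top until the
  first failure.  This is a deliberate simplification of iterative SVA:
  one residualization, no probe reweighting.

## Differential methylation

Per probe, OLS of the response (β by default; M-values optional, with
Δβ still reported from a parallel β-scale fit) on the contrast plus
covariates.  Categorical covariates are one-hot encoded, zero-variance
columns dropped with a warning, rank-deficient designs rejected naming
the aliased columns.  Empirical-Bayes moderation fits a scaled
inverse-χ² prior to the residual variances by the method of moments on
log s² (the trigamma-inverse construction); the moderated t uses the
posterior variance on d + d₀ df.  When the variances are no more
dispersed than χ² sampling alone the prior df is infinite and all
variances shrink to the common value.  Probes with zero residual variance
and zero effect get t = 0, p = 1.

Conventions: Δβ = case − control, or F − M for the sex contrast (so a
female-hypermethylated probe has Δβ > 0).  chrY probes are excluded from
the female stratum.  BH runs within declared families — the genome-wide
family covers all tested CpGs (including sex chromosomes), and
chrX-only / chrY-only families are adjusted separately.  The interaction
model (sex + diagnosis + sex×diagnosis + covariates) reports the product
term, which without covariates equals the stratified female-minus-male
effect difference exactly.  Meta-analysis is inverse-variance with
DerSimonian–Laird τ²; both fixed- and random-effects results are kept.
Replication re-applies BH within the discovery-significant subset only
and requires direction agreement.

## Burden comparisons

- **Down-sampling**: male cases and controls are sampled without
  replacement to the female case and control counts (preserving the
  case:control ratio rather than pooling), the stratified model refit,
  and DMPs counted at adj.p < 0.05 per iteration; the female count is
  computed once on all females.  The one-sided 95 % interval is
  [0, 95th percentile] of the (female − male) difference distribution,
  and the empirical p is the fraction of iterations in which the male
  count reached the female count.  Covariates are held fixed across
  iterations (surrogate variables are not re-estimated per subsample).
- **RRHO**: both lists ranked by sign(Δβ)·(−log₁₀ p) descending; at each
  grid point the one-sided hypergeometric tail of the top-tail overlap,
  stored as −log₁₀ p signed positive for over-enrichment, capped at
  ±300; default step ⌊N/100⌋.  A single top-tail grid suffices: the
  bottom-tail overlap is an affine function of the top-tail overlap, so
  the near corner carries the up/up signal and the far corner carries
  down/down.  Concordant CpGs are those with raw p < 0.05 in both sexes
  and matching direction.
- **Magnitude**: OLS slope (with intercept) of Δβ_male on Δβ_female
  (slope < 1 ⇔ larger female effects), two-sided paired t on
  |Δβ_f| − |Δβ_m| (defined as t = 0, p = 1 when all differences vanish),
  Spearman ρ of the signed effects.
- **Enrichment**: Fisher's exact test on the 2×2 table; the primary odds
  ratio is the conditional MLE (consistent with the exact test), with the
  sample OR a·d/(b·c) reported alongside.

## Regulatory integration

DMPs at p < 1e-4 (strict; an inclusive threshold meant to feed
enrichment analyses that need more loci) join the meQTL table on CpG id
to form SDPs and the GCP table to form DGPs; CpGs in both define triads,
with SNPs aggregated per (CpG, gene).  DGP consistency compares the
expected expression direction — sign(correlation) × sign(Δβ) — with the
supplied differential-expression status.  The GWAS test is a permutation
stand-in for LD-score-based enrichment: the fraction of SDP SNPs whose
CpG window (closed interval, ±200 kb, same chromosome) contains a
genome-wide-significant SNP (p < 5e-8), against the same statistic for
random same-size SNP sets from the meQTL background pool, MAF-decile
matched when MAF is available.  Empirical p carries the +1 correction;
with no significant GWAS SNP anywhere the result degenerates to
fold = 1, p = 1 with a warning.

## PPI modules

Gene statistics come from promoter CpGs (TSS200/TSS1500): the signed
−log₁₀ p of the minimum-p promoter CpG (averaging signed statistics
would cancel opposite-direction CpGs; the mean promoter Δβ is reported
alongside).  The module score is the induced edge weight per member gene,
edge weight being the mean |statistic| of the endpoints — singletons
score 0, so a seed always absorbs its best neighbor, and growth continues
while the score strictly improves, up to 100 genes.  Seeds are the
top-|statistic| genes not absorbed by earlier modules (degree-0 seeds
skipped); overlapping modules merge at Jaccard > 0.5.  Significance
permutes the gene statistics over the fixed topology and **re-selects the
seed at the same rank** before re-growing, so the null accounts both for
greedy growth and for the seed having been chosen as a top gene; without
the re-selection the test is anti-conservative.  This greedy procedure is
a deliberate reimplementation of the functional-epigenetic-modules idea
(spin-glass optimization replaced by deterministic expansion +
permutation), chosen for determinism and desk-scale runtime.  Direction
is the AUROC of member ranks against the signed-statistic ordering (ties
broken by gene id); gene-set enrichment uses the hypergeometric upper
tail over sets whose universe-restricted size lies in [10, 500], BH
across tested sets.

## Numerical conventions

β values are clipped to [1e-6, 1 − 1e-6] before any logit; p-values are
floored at 1e-300 before −log₁₀; permutation p-values always use the
(1 + #extreme)/(n + 1) form; ranking ties anywhere are broken by
identifier for determinism.  All "greater than" thresholds are strict
unless the defining wording says "at least".

## Problem sizes

The default drivers run 20,000 probes with 200 down-sampling iterations
and 500–1,000 permutations for module and GWAS tests; the test suite uses
1,000–5,000-probe cohorts and 100–200 permutations.  These sizes give
stable statistics (the down-sampling difference quantiles move by < 1
count between independent 1,000-iteration runs) while keeping a full run
in minutes on one core.

## Known limitations

BMIQ's H-state dilation anchors on the transformed U/M extremes, so
hemimethylated probes at state boundaries can move slightly even when the
two designs' distributions already agree.  The SVA simplification (one
residualization, no reweighting) can under-count weak confounders.  The
greedy module search is not guaranteed to find the globally best-scoring
subnetwork, only a seed-stable local one.  The GWAS window test ignores
LD structure beyond window containment.  Replication meta-analysis
assumes independent studies with normal within-study errors.
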