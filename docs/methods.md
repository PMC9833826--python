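# Methods

## Model

Every association is tested under the single-SNP mixed model

    y = 1 μ + x β + u + e,   var(u) = σᵤ² K,   var(e) = σₑ² I,

with y a strain-level feature (protein strain-mean abundance in log2
ratio-to-reference, or a trait), x the alternate-allele dosage in
{0, 1, 2}, and K the identity-by-state kinship averaged over all SNPs
with pairwise-complete handling of missing calls
(K_ij = mean(1 − |gᵢ − gⱼ|/2), diagonal exactly 1).  The polygenic term
u absorbs population structure; inbred panels have strong strain
relatedness, and an uncorrected scan on a structured panel is inflated
(the package's calibration check measures λ_GC ≈ 1.7 uncorrected
vs ≈ 1.0 corrected on a two-subpopulation synthetic panel).

### REML fitting

Variance components are estimated once per feature on the null model
(β = 0).  With the eigendecomposition K = U diag(s) Uᵀ, the rotated
model ỹ = Uᵀy has diagonal covariance σᵤ²(s + δ) in the variance ratio
δ = σₑ²/σᵤ²; σᵤ² profiles out of the restricted likelihood in closed
form, leaving a one-dimensional criterion in δ that is evaluated on a
100-point log-spaced grid over [1e-5, 1e5] and refined with bounded
scalar minimisation between the best grid point's neighbours
(tolerance 1e-8 on log₁₀ δ).  Heritability is reported as
σ̂ᵤ²/(σ̂ᵤ² + σ̂ₑ²) = 1/(1 + δ̂).

Numerical choices: kinship eigenvalues are clipped at 1e-8 and K is
regularized by +1e-6·I (with a logged warning) only if clipping occurs;
a minimum eigenvalue below −1e-8 is an error; constant features are
rejected ("zero variance feature"); p-values of exactly 0 are reported
as the smallest positive representable double.

### Genome scan

Each SNP is tested by GLS under covariance σᵤ²(K + δ̂ I) with δ̂ fixed
from the null fit (the classic null-reuse approximation; exact per-SNP
REML re-estimation of δ is available behind `refit_delta=True` and is
used only for validation, as it is orders of magnitude slower and
changes p-values negligibly on these panels).  The residual scale is
re-estimated per SNP, so F = (β̂/se)² is an exact F(1, n−2) statistic in
the rotated model.  Degrees of freedom use strains as the unit —
replicates are collapsed to strain means before mapping, because
genotype varies only at the strain level and anything else would
pseudo-replicate.  SNPs monomorphic among the used strains or below the
MAF floor (default 0.05 on used strains) are skipped with a logged
count.  Strains missing a genotype at a SNP are dropped pairwise for
that SNP (no imputation); those SNPs take a direct Cholesky GLS path on
the strain subset since the shared rotation no longer applies.

Per feature, q-values are computed across SNPs from the p-value
distribution: Storey's π̂₀ = min(1, mean(p > 0.5)/0.5) followed by the
step-up q_i = min over t ≥ p_(i) of π̂₀ m t / rank(t) (method
`"storey"`, the default) or the same with π̂₀ = 1 (`"bh"`).

### cis/trans classification

Distance is measured from the SNP to the nearer gene boundary (0 inside
the gene, ∞ on another chromosome) — the window is defined around the
gene body, not the TSS.  A cis call requires distance ≤ 10 Mb, a
window-local FDR-adjusted p < 1e-4 (BH over the SNPs inside the window
only — "local adjusted" is read as window-restricted FDR, the natural
counterpart of the genome-wide "global adjusted"), and q < 0.1.  A
trans call requires distance > 10 Mb or another chromosome, global
BH-adjusted p < 5e-8, and q < 0.1.  The lead SNP minimises p with ties
broken by genomic position, making classification invariant to input
order.  A feature can carry one cis and one trans call; no single
association is both.  Variants are annotated intragenic when they fall
inside any gene interval on their chromosome; consequence labels are
passed through verbatim from the input annotation.

Trans hotspots: the genome is tiled in 4-Mb bins, each trans-regulated
feature contributes once to the bin of its lead SNP, and a bin is
flagged when its Poisson upper-tail p at the genome-wide mean rate
survives BH across bins at α = 1e-3.  Bin width and the Poisson/BH rule
are operational choices; hotspot-like loci are usually identified
visually, and this scan simply formalises "many distinct features, one
locus".

## Correlation and multivariate layer

Protein–trait association uses biweight midcorrelation in its pure
form: deviations from the median are weighted by (1 − u²)² with
u = d/(9·MAD) (unscaled MAD), zeroing observations beyond 9 MADs; a
zero-MAD vector falls back to Pearson with a logged flag.  Significance
is the Student transform t = r√(n−2)/√(1−r²) on n−2 df, with BH
q-values across all pairs.  The shortlist filter keeps pairs with
(r ≤ −0.3 or r ≥ 0.6) and p < 0.05 — an asymmetric union reflecting
that negative associations of moderate size are already interesting
while positive ones are abundant.  Network edges require |r| above a
cutoff and q < 0.05, deduplicated as undirected pairs.

Coefficients of variation are computed on the linear scale (2^log2),
since the CV of log-ratios centred at 0 is ill-defined: intra-strain CV
is the per-protein median over strains with ≥ 2 replicates of
100·sd/mean, inter-strain CV is 100·sd/mean across strain means.

Repeatability R uses the one-way random-effects ANOVA estimator:
σ̂²_w = MS_within, σ̂²_b = max(0, (MS_between − MS_within)/n₀) with
n₀ = (N − Σnᵢ²/N)/(a−1), R = σ̂²_b/(σ̂²_b + σ̂²_w).  Screen-style
differential tests are classical pooled-variance Student t (unpaired)
or one-sample t on paired differences, with BH FDR across features;
zero-variance features are flagged rather than given a p-value.

OPLS fits one predictive plus one orthogonal component by orthogonal
signal correction: PLS weight w ∝ Xᵀy, one component with loading
orthogonal to w is extracted and deflated, then the predictive
component is fit on the deflated matrix; scores of the two components
are exactly orthogonal by construction.  Columns are centred and
unit-variance scaled by default (the common default of OPLS workflows;
the original scaling is unstated, so a flag disables it), y is centred,
and the predictive component is oriented so corr(t_p, y) ≥ 0.  Q² is
leave-one-strain-out.  Missing data are handled by complete-case
columns — proteins with any missing strain are dropped with a logged
count — rather than imputation, which would silently manufacture
signal; in practice this means OPLS models the fully quantified protein
subset.

## Three-step integration

Step 1 intersects the protein's cis-significant SNP ids with the
trait's q < 0.1 SNP ids — exact id matching, not LD-window overlap
(the simplest faithful reading; an LD-slack mode would be a natural
extension).  The lead shared SNP minimises max(p_protein, p_trait).
Step 2 is the bicor shortlist filter.  Step 3 contrasts the two
homozygous allele groups at the lead shared SNP (heterozygotes
excluded, ≥ 3 strains per group) by pooled-variance Student t on the
protein and on the trait; both must reach p < 0.05 and, by default,
the allelic effect directions must be concordant with the correlation
sign (sign(Δprotein·Δtrait) = sign(r)) — this concordance requirement
is toggleable since reasonable analysts differ on it.  A protein
passing all three steps is *prioritized*; records are sorted by lead
shared-SNP strength.  Recoding the coded allele (0↔2) flips both t
signs and leaves every verdict unchanged.

## Synthetic panel generator

The generator emulates the data structure of an inbred-panel proteomics
study; defaults (chosen once as the study conditions):

| parameter | default | rationale |
|---|---|---|
| strains × replicates | 75 × U{2..4} | panel of ~73 strains, n = 2–4 per strain |
| genome | 5 chromosomes × 100 Mb | desk-scale genome preserving cis/trans geometry |
| SNPs | 1,000 in 2-Mb LD blocks, copy-prob 0.9, MAF ≥ 0.10 | LD-block structure; testable allele splits at n = 75 |
| proteins/genes | 300 / 300, gene i hosts protein i | desk-scale proteome |
| cis effects | 10% of proteins, VE ~ U(0.2, 0.6) within ±10 Mb | spread across the detectability boundary |
| trans hotspot | 1 SNP × 30 targets at VE 0.5 | strong co-regulation; weaker trans effects cannot clear global adjusted p < 5e-8 at n = 75 |
| polygenic | σᵤ² = 0.1, σₑ² = 0.15 (h² = 0.4) on the realized IBS kinship | mapping with estimated K is exactly well-specified, making calibration tests sharp |
| replicate SD | 0.13 (log2) | reproduces ≈ 9% linear intra-strain CV, typical of TMT panels |
| traits | 5, each 3 proteins + 35% noise variance; trait 1 = causal chain (weight 1 on a VE-0.5 cis protein) | one fully planted SNP→protein→trait chain among distractors |
| missingness | per-protein strain coverage ~ U(0.7, 1.0), whole strains dropped | strain-wise unit mirrors a "quantified in > k mice" filter |

Dosages are homozygous {0, 2}: each LD block carries a latent founder
allele per strain at a block frequency drawn in [MAF floor, 1 − floor];
each SNP copies the founder with the block-correlation probability and
is otherwise redrawn, so copy-prob 1 makes a block identical and 0
independent.  Optional two-subpopulation structure shifts block
frequencies per subpopulation (used by the calibration checks).  Planted
effect sizes are parameterized as the fraction of strain-level variance
explained and converted to β through the realized dosage variance, which
makes them portable across panels.  Traits are built from the noiseless
strain × protein matrix carried in the truth ledger, not from realized
strain means, so trait truth is independent of the missingness
realization.  Everything is deterministic under the master seed, with
independent substreams for genotypes, proteome and traits.

What the generator does **not** emulate: pedigree/coalescent realism of
the strain genealogy, TMT batch effects and ratio compression,
non-Gaussian abundance distributions, missingness that depends on
abundance (censoring), or sex and environment covariates.  Passing
recovery tests on these panels therefore demonstrates correctness of
the statistical machinery under a well-specified generative model, not
robustness to those real-data pathologies.

Heritability at n = 75 is weakly identified: a single REML estimate has
a sampling SD near 0.3, so the recovery property (within ±0.15 of the
generative value) refers to the median over ~20 independent
realizations, and that median itself still fluctuates by roughly ±0.1
across panel draws.

The measured median intra-strain CV (~7%) sits below the 9% implied by
the replicate SD because the sample SD of 2–4 replicates is biased low;
the inter-strain CV (~32%) is dominated by genetic variation, as
intended.

## Scaling choices

The default test and acceptance runs use the problem sizes above (the
full pipeline takes a few seconds per seed); multi-seed properties use
6–20 seeds depending on the cost of each realization.  The
50-non-missing-strain feature floor scales with panel size as
min(50, ⌈2n/3⌉), keeping the 50-of-75 proportion on smaller panels.

## Known limitations

* One variance component only: no dominance, epistasis, interaction
  scans or multi-component models.
* The null-reuse δ approximation slightly misestimates per-SNP variance
  ratios for very large single-SNP effects (conservative in practice).
* Shared-SNP matching is by exact id; panels genotyped on different
  arrays would need the LD-window mode before integration.
* Hotspot detection assumes a homogeneous Poisson background; clustered
  gene dense regions could inflate bin counts.
* OPLS complete-case columns discard partially quantified proteins
  entirely rather than modelling them.
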