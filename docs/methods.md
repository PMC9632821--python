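# Methods

This note records the statistical models implemented in `xtrait`, the
conventions and defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Conventions

Positions are 1-based (GRCh37 in the motivating datasets); genomic
intervals are half-open `[start, end)` except the extended MHC exclusion
(chr6: 24,000,000–36,000,000), which is quoted only to Mb precision and is
therefore applied inclusively at both endpoints. Effects are log-odds for
case-control traits; a 95% CI maps to the standard error as
`se = (ln hi − ln lo) / (2 × 1.959964)`. All two-sided normal p-values
are computed and compared in log10 space (printed p-values in the
motivating tables go down to 10⁻³¹, far below where naive `sf` chains
would underflow through intermediate steps). Wherever a single "N" is
needed for a binary trait, the effective sample size
`4 / (1/n_cases + 1/n_controls)` is used.

## Harmonization

Two tables are matched on (chrom, pos) with an snp_id fallback, then each
shared SNP's allele pair is reconciled by exact match, swap (beta negated,
frequency complemented), reverse complement, or swapped reverse
complement; anything else is dropped. Palindromic SNPs (A/T, C/G) carry no
strand information in their labels, so they are oriented by allele
frequency — flipped when the other table's frequency is closer to the
complement — and dropped as ambiguous when `min(f, 1−f)` exceeds the
ambiguity bound in either table. The bound defaults to 0.40 because
frequency-based orientation is unreliable near 0.5; it is a declared
default of this package, not an inference about any published analysis.
Harmonization is idempotent and sign-equivariant (both properties are
tested).

## Meta-analysis and locus discovery

Fixed-effect inverse-variance pooling is the single engine for both
study-level and cross-trait meta-analysis. The opposing mode negates the
second trait's harmonized effects before pooling; the pooled effect is
reported on the first trait's aligned scale, so the orientation of a
printed opposing-mode OR depends only on which trait is passed first.
The retention filter (p < 0.01 in both traits, direction concordance
matching the mode) is applied before candidate discovery; retained SNPs
at p < 5×10⁻⁸ are clustered greedily: the smallest-p SNP (ties broken by
smaller position) leads a ±1 Mb half-open window, absorbed SNPs are
removed, and the process repeats. Published-locus checking flags a ±1 Mb
window when any other-trait SNP reaches p < 1×10⁻⁵.

## LD score regression

LD scores are `ℓⱼ = Σₖ r²ⱼₖ` over a 1 Mb window, with the small-sample
adjustment `r² − (1−r²)/(n_ref−2)` when the reference is a finite cohort.
Heritability and genetic covariance come from weighted regressions of
χ²ⱼ (or z₁ⱼz₂ⱼ) on `N ℓⱼ/M` (or `√(N₁N₂) ℓⱼ/M`); the intercept is free
and absorbs confounding or sample overlap. Weights follow the canonical
two-step scheme: a 1/ℓ-weighted fit supplies fitted means μ, then one
refit with weights `1/(ℓ·2μ²)` (χ² regression) or
`1/(ℓ·(μ₁μ₂ + μ₁₂²))` (product regression). χ² values above
`max(80, 0.001N)` are excluded. Standard errors are delete-one block
jackknives over 200 contiguous blocks, scaled down proportionally
(n/100, minimum 2) below 20,000 SNPs; `rg = ρg/√(h²₁h²₂)` is jackknifed
as a whole ratio, with delete-block denominators floored at 10% of the
full-data heritabilities to keep a rare near-zero denominator from
dominating the variance. As a ratio estimator rg carries a small upward
Jensen bias when the heritabilities are noisy; at the simulation sizes
used here it is a few percent and well inside the jackknife CI. rg is
reported as undefined (NaN, flagged) when either heritability estimate is
non-positive.

## Local heritability and genetic covariance

At a locus with LD matrix R and standardized effects `b = z/√N`
(the z/√N convention removes the allele-frequency scale), the quadratic
form over the top-k eigencomponents gives
`ĥ²_local = (N·bᵀUₖΛₖ⁻¹Uₖᵀb − k)/(N − k)`; the bilinear analogue gives
the local genetic covariance, minus `k·ρ·Nₛ/(N₁N₂)` when the cohorts
share Nₛ samples with phenotypic correlation ρ (zero by default — the
motivating cohorts are disjoint). k defaults to the smallest count of
eigenvalues explaining 99.5% of the trace, capped at 50: truncation
regularizes the inverse of a rank-deficient R. The covariance Wald test
uses the plug-in asymptotic variance
`h²₁/N₂ + h²₂/N₁ + k/(N₁N₂)`, which is exact under normality at the null.
Estimates may be negative at null loci (the bias correction is unbiased,
not positive); the correlation is reported only when both local
heritabilities are positive. With degenerate eigenvalues (e.g. identity
R) the top-k subspace is arbitrary, so exact-k closed-form checks must
use the full rank.

## Colocalization

Wakefield's log approximate Bayes factor
`½[log(1−r) + r·z²]`, `r = W/(W+se²)`, scores each SNP; configuration
sums for the five hypotheses are accumulated by log-sum-exp, with H3's
"distinct variants" sum computed as the stable log-difference
`S₁+S₂ + log1p(−exp(S₁₂−S₁−S₂))` (exactly zero configurations remain for
a single-SNP locus). Prior effect variance defaults to W = 0.2² on the
log-odds scale (0.15² is the usual quantitative-trait choice); per-SNP
priors default to p₁ = p₂ = 10⁻⁴ and p₁₂ = 10⁻⁵. Two decision rules are
exposed: the composite rule — PP_H4 > 0.5 under p₁₂ = 5×10⁻⁵ *and*
PP_H3 < 0.5 under p₁₂ = 10⁻⁵ — and the strict PP_H4 > 0.9 rule used for
published-locus follow-up; both inequalities are strict at their
boundaries. At multi-signal loci each trait's signals are represented by
their conditioned marginals (below) and every signal pair is colocalized;
the per-pair PP_H4 matrix and its maximum are reported.

## Conditional and joint analysis

The summary-statistics normal equations use per-SNP genotype-variance
weights `Dⱼ = 2fⱼ(1−fⱼ)Nⱼ`, off-diagonals `rⱼₖ√(DⱼDₖ)` from reference LD
(zeroed beyond a 10 Mb window), and right-hand side `Dⱼβ̂ⱼ`. The
phenotypic variance is inferred per SNP from the marginal identity
`y'y = D·se²(N−1) + D·β̂²` and median-aggregated, as the algebra requires
and the canonical summary-data derivation prescribes. Forward selection
adds the candidate with the smallest conditional p (partitioned-regression
form of the joint solve, vectorized over candidates; ties break on
position), skipping candidates with r² > 0.9 to the model or condition
number above 10⁸; each addition is followed by backward elimination of
any SNP whose joint p rises above the threshold. A candidate whose
conditional denominator collapses (a near-perfect proxy of the model) has
its signal fully absorbed: conditional beta 0, p 1. SNPs whose
summary-statistics frequency differs from the reference frequency by
more than 0.2 are dropped (panel-mismatch guard). Joint effects are on
the same scale as the input betas under the standardized-phenotype
convention; published joint effects from other variance conventions are
contract references, not numeric targets.

## Synthetic data

The generator emulates the *structure* of a two-trait cross-trait study:
block-diagonal LD with AR(1) blocks `r(i,j) = ρ^|i−j|`, allele
frequencies Uniform(0.05, 0.5), and per-SNP causal labels
(none / shared-aligned / shared-opposing / trait-specific). Causal effects
have fixed magnitude and random sign, with signs shared or reversed at
shared SNPs, so the planted genetic correlation is exactly
`(n_aligned − n_opposing)/n_causal` per trait; default study conditions
mirror the motivating cohorts (effective sizes 15,354 for the SLE
meta-analysis and 5,587 for the severe-COVID-19 GWAS; h² = 0.3 spread over
1,000 causal SNPs of 20,000; rg = 0.56 via 560 shared causal variants;
disjoint cohorts, so no overlap term). Summary statistics are drawn
per block from `z ~ MVN(√N·Rβ, R)`, with cross-trait noise covariance
`(Nₛ·ρ/√(N₁N₂))·R` when overlap is configured; betas and SEs are
back-computed under the standardized-genotype, unit-variance-phenotype
convention, and case-control traits are treated as quantitative on the
liability/log-odds scale because every downstream computation consumes
only (β̂, se) pairs.

The individual-level route discretizes Gaussian-copula latents into
{0,1,2} dosages at Hardy-Weinberg cut points. Discretization attenuates
correlation, so each pairwise latent correlation is calibrated from the
two-term Hermite expansion of the dosage covariance
(`cov ≈ a₁a₂ρ + b₁b₂ρ²/2`), with an eigenvalue clip back to positive
semi-definiteness; the resulting dosage LD tracks the target R to within
sampling error at the sizes tested. Phenotypes are `y = X_std·β + ε` with
residual variance topping total variance up to 1, followed by per-SNP
marginal regression. For fine-mapping oracles, the LD reference is
estimated from the cohort's own genotypes — mirroring the real practice
of using study controls as the LD panel, and necessary because a
population-truth R is a *mismatched* panel for a finite cohort (the
mismatch manifests as spurious conditional signals, exactly as in real
COJO analyses with inadequate reference panels).

What the generator does not emulate — and what passing tests therefore do
not establish about real data: realistic minor-allele-frequency spectra
and frequency-dependent architecture, recombination-map LD (AR(1) blocks
have no long-range structure beyond the block), population stratification
or confounding (intercepts are only exercised through configured sample
overlap), imputation error beyond a constant INFO column, and binary-trait
ascertainment effects on the observed scale.

All randomness flows from one integer seed through fixed-offset
substreams (frequencies, effect signs, z-noise, genotypes), so every
route is byte-reproducible.

## Problem sizes

The bundled validation runs use sizes chosen to exercise every code path
at desk scale: 20,000-SNP genomes with 400 mixed-ρ blocks and 50
replicates for genetic-correlation recovery and its null; 50 two-signal
loci (m = 50, n = 2,000, causal pair at r² ≈ 0.08) for conditional/joint
fine-mapping against individual-level regression; 200 replicates per sign
for local covariance; 300 enumeration instances (≤ 12 SNPs) and 1,000
normalization instances for colocalization. Mixed-ρ blocks matter for LD
score regression: near-uniform LD gives the slope almost no leverage, and
placing causal SNPs systematically (e.g. at block edges) violates the
random-polygenicity assumption and biases the slope — causal placement is
therefore always random.

## Known limitations

- Genome-wide results at real-cohort scale (the published rg of 0.56 with
  s.e. 0.16, the 15 genome-wide loci, printed PP_H4 values) require the
  original cohort data; the package validates the estimators on synthetic
  architectures that plant those quantities instead, and anchors the
  pooling arithmetic to the published worked-example table.
- Fixed effects only: no random-effects or heterogeneity (Cochran's Q)
  modeling.
- Single-causal-variant colocalization only (multi-signal loci are
  handled through conditioning, not through multi-causal priors).
- No genome-build liftover, imputation, or external-resource retrieval.
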