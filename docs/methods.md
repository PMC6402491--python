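# Methods

## Setting and estimand

`mrkit` implements two-sample summary-data Mendelian randomization for
binary exposure and outcome. The exposure GWAS supplies per-SNP effects
γ̂ᵢ with standard errors σ_{γᵢ}; the outcome GWAS supplies β̂ᵢ with
σ_{βᵢ}; both are log odds ratios per copy of the effect allele. The
estimand α is the effect of a 1-unit increase in the log odds of the
exposure on the log odds of the outcome; results are reported as
OR = e^α. Validity rests on the usual instrumental-variable
assumptions: each instrument is associated with the exposure,
independent of confounders, and affects the outcome only through the
exposure. The package's diagnostics (Cochran's Q, I², MR-PRESSO) probe
violations of the third assumption (horizontal pleiotropy).

## Harmonization

Exposure records are reoriented so every instrument effect is positive
(the effect allele is the exposure-increasing allele); the Wald ratio
is invariant under this joint flip, and the estimator tests assert that
invariance. Outcome records are aligned to the exposure alleles,
negating β̂ on an allele swap and attempting an A↔T/C↔G strand flip
before declaring a mismatch. Palindromic variants (A/T, C/G) cannot be
strand-resolved from labels; the default policy infers orientation from
allele frequency and drops the variant when either frequency is missing
or within 0.08 of 0.5 (policies `drop_ambiguous` and `keep` are also
available). The window 0.08 is the common practice for two-sample MR
toolchains; nothing in the package is sensitive to it except which
palindromic SNPs survive. Indels and multi-allelic records are rejected
at read time.

## Instrument selection

Three idempotent filters, each logged per SNP:

- **significance**: keep p < 5×10⁻⁸ (strict inequality).
- **LD pruning**: greedy by p-value — repeatedly keep the most
  significant remaining SNP and drop everything with pairwise r² above
  0.1 against it; ties on p broken by lexicographic snp_id so results
  are platform-independent. The r² matrix is either supplied or
  computed as squared Pearson correlation of allele-dosage columns.
  Position-windowed clumping is deliberately not implemented; with one
  index SNP per locus, greedy-by-p and windowed clumping coincide.
- **imputation quality**: drop info < 0.8 by default (the boundary
  value 0.8 is retained; configurable), used as a sensitivity re-run
  rather than an upfront filter.

## Estimators

With wᵢ = (γ̂ᵢ/σ_{βᵢ})², the IVW estimate is α̂ = Σwᵢα̂ᵢ/Σwᵢ and the
fixed-effect SE is (Σwᵢ)^(−1/2). The *multiplicative random-effects*
SE multiplies this by max(1, √(Q/(n−1))): the point estimate and the
relative weights are unchanged, and the SE is never deflated below the
fixed-effect value. This is the convention of the standard two-sample
MR toolchain; an additive (DerSimonian–Laird) random-effects flavour
would re-weight and is intentionally not offered, to keep one
unambiguous "random-effects" meaning. Confidence intervals use the
normal 1.96 multiplier (at n ≈ 170 instruments the t correction is
negligible) and p-values come from the standard normal.

The first-order Wald variance vᵢ = (σ_{βᵢ}/γ̂ᵢ)² ignores σ_{γᵢ}; this
is the standard NOME approximation, adequate when instruments are
strong (here per-SNP F ≈ (γ/σ_γ)² ≈ 100 under the generator defaults).

The weighted median orders the Wald ratios, standardizes cumulative
weights as s_j = (Σ_{k≤j} w_k − w_j/2)/Σw, and linearly interpolates to
s = 0.5; with equal weights this is the interpolated ordinary median.
Its SE is the standard deviation of the estimate over a parametric
bootstrap (default 1000 replicates) redrawing γ̂ᵢ and β̂ᵢ from
normal(observed, SE); the bootstrap seed is a required argument —
there is no silent global-RNG path anywhere in the package.

Heterogeneity: Q = Σwᵢ(α̂ᵢ − α̂_fixed)², referred to χ²(n−1), with
I² = max(0, (Q − df)/Q) reported as a percentage.

## MR-PRESSO

The observed statistic is RSS = Σᵢ (β̂ᵢ − α̂₋ᵢ γ̂ᵢ)²/σ_{βᵢ}², where
α̂₋ᵢ is the leave-one-out *fixed-effect* IVW estimate (leave-one-out
keeps SNP i's own pleiotropy out of its prediction). The null is
simulated parametrically: γ*ᵢ ~ N(γ̂ᵢ, σ_{γᵢ}), β*ᵢ ~ N(α̂₋ᵢγ̂ᵢ,
σ_{βᵢ}), with the RSS recomputed on each simulated dataset (including
re-estimating the leave-one-out slopes). Empirical p-values use the
add-one correction, p = (1 + #{RSS* ≥ RSS})/(n_sim + 1), so they are
never 0 and never below 1/(n_sim+1). The per-SNP outlier test applies
the same comparison to each SNP's residual, flagging at the
Bonferroni-corrected level 0.05/n. The distortion test compares the
IVW shift from removing the flagged set against the shift from
removing random subsets of the same size.

Default n_sim = 5000: the Bonferroni cutoff at n ≈ 170 instruments is
0.05/170 ≈ 2.9×10⁻⁴, and stable empirical p-values near that cutoff
need n_sim ≫ 1/cutoff. In a multi-stratum analysis the outlier list is
computed once on the first (overall) stratum and applied to all strata,
so every stratum uses the same instrument set; per-stratum screening is
available behind a flag.

A quantified caveat: when a strong outlier (say +10 outcome-SEs) is
present among n instruments, every *clean* SNP's leave-one-out
prediction is shifted by roughly 10/n outcome-SEs, because the outlier
sits inside the other SNPs' leave-one-out sets. This inflates the
family-wise false-flag rate somewhat above the nominal Bonferroni 5%
(measured ≈ 6–9% at n = 51 in this implementation's simulations). The
single-pass construction is kept because it matches the published
method; removing flagged SNPs and re-screening is the practical remedy
and is what the pipeline's exclusion-then-re-estimate flow amounts to.

## Synthetic data generator

The generator draws true instrument effects γᵢ ~ |N(0.10, 0.025)| and
produces observed summary statistics directly on the log-odds scale:

    γ̂ᵢ = γᵢ + N(0, σ_γ),   β̂ᵢ = α·γᵢ + pᵢ + N(0, σ_β)

with σ_γ = 0.010, σ_β = 0.0095, α = 0.04 by default. These defaults
were chosen once to match the regime of a well-powered psychiatric
exposure GWAS (~10⁵ samples) against a large case-control outcome
consortium (~2.3×10⁵ samples): per-SNP Wald-ratio SEs ≈ 0.1, pooled
IVW SE ≈ 0.007–0.01 at 170 instruments, instrument F ≈ 100. Pleiotropy
pᵢ is zero (`none`), N(0, 0.009) (`balanced`, the default, sized to
give mid-range heterogeneity I² ≈ 45% via E[Q]/df ≈ 1 + σ_p²·n/(df·σ_β²)),
or N(0.009, 0.009) (`directional`). A configurable contamination
fraction of SNPs instead receives a fixed shift of `outlier_shift`
(default 10) outcome-SEs — the planted outliers used to exercise
MR-PRESSO. Allele labels are drawn from non-palindromic pairs, allele
frequencies and info scores uniformly within configured ranges.
`add_noise=False` disables the measurement noise (observed = expected),
which is what makes exact truth-recovery assertions possible.
`simulate_ld_block` builds dosage matrices from paired haplotype Markov
chains whose adjacent-column r² equals the target in expectation, for
testing LD pruning.

What the generator does **not** emulate: case-control sampling and the
logistic link (summary statistics are generated directly on the
log-odds scale, so the known bias of IVW for binary exposures is out of
scope), winner's curse in the discovery GWAS (instrument selection can
be emulated by oversampling and thresholding, as the acceptance script
does, but discovery and use of instruments in the same sample is not
modelled), LD between instruments in the association statistics, and
sample overlap between the two GWAS. Passing tests on synthetic data
therefore validate the estimators and the workflow under the stated
generative model, not the epidemiological correctness of any particular
real-data analysis.

Under balanced pleiotropy the instrument-strength-independent-effects
(InSIDE) condition holds by construction, so IVW stays unbiased in
expectation while its heterogeneity grows; under directional pleiotropy
IVW is biased with the sign of the pleiotropy mean, while the weighted
median resists up to 50% invalid weight. Both behaviours are asserted
over hundreds of seeded replicates in the test suite.

Known numerical bias: because γ̂ᵢ appears in the denominator of the
Wald ratio and in the weights, exposure measurement noise causes a
regression-dilution shrinkage of the IVW estimate by a factor
≈ E[γ²]/(E[γ²] + σ_γ²) — about 1% under the defaults, visibly smaller
in simulation (the weighting partially offsets it). This is inherent to
first-order two-sample MR, not to this implementation.

## Numerical and design choices

- Empirical p-values: add-one correction everywhere; never 0.
- Division by zero: γ̂ᵢ = 0 raises rather than silently dropping the
  SNP; upstream significance filtering makes it unreachable on real
  data.
- LD-prune ties: lexicographic snp_id, for cross-platform determinism.
- Single instrument: IVW random-effects mode falls back to fixed (Q
  undefined); weighted median requires ≥ 3 instruments; Cochran's Q
  requires ≥ 2; MR-PRESSO requires ≥ 4.
- Reporting: ORs rounded to 2 decimals, p-values to 2 significant
  figures; full-precision values are always available in
  `report.json`, and the TSV writers use `repr` so harmonized tables
  round-trip bit-exactly.
- Determinism: every stochastic component (weighted-median bootstrap,
  MR-PRESSO simulations, synthetic generation) takes an explicit seed;
  identical configuration yields byte-identical output files.

## Problem sizes used by the automated checks

The test suite and acceptance script run entirely on generated data:
estimator calibration uses 1000 replicates of 170 instruments;
weighted-median robustness 500 replicates with 30% contamination;
outlier detection 100 runs of 51 instruments at n_sim = 5000; the
end-to-end study emulation uses 179 candidate instruments. These sizes
keep the whole suite in the tens of seconds on a single core while
leaving Monte-Carlo error well below the asserted margins.
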