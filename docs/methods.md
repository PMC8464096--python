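# Methods

This note records the statistical model, the conventions chosen where the
field admits more than one, and what the synthetic-data experiments do and
do not demonstrate.

## Model and estimators

All effects are per-allele log odds ratios. For instrument *j*, the observed
summary statistics are modelled as

    β̂_Xj ~ N(β_Xj, σ_Xj²),    β̂_Yj ~ N(θ·β_Xj + α_j, σ_Yj²),

with α_j the direct (pleiotropic) effect of the variant on the outcome. The
two samples are assumed non-overlapping, so the errors are independent.

**Wald ratio.** θ̂_j = β̂_Yj/β̂_Xj with first-order delta SE σ_Yj/|β̂_Xj|.
The first-order form ignores exposure-side uncertainty; this is the standard
reporting convention and is accurate for strong instruments (the relative
SE understatement is √(1+θ²σ_X²/σ_Y²) − 1, under 5% whenever the instrument
has σ_X/|β̂_X| < 0.1 and the outcome association is within a few SEs of
zero). A `second_order=True` option adds the β̂_Y²σ_X²/β̂_X⁴ term.

**IVW.** Weighted regression of β̂_Y on β̂_X through the origin, weights
1/σ_Y²; algebraically the β̂_X²/σ_Y²-weighted mean of the Wald ratios.
*Random-effects flavor:* the SE √(1/Σwβ̂_X²) is multiplied by the residual
standard deviation when it exceeds 1 and left alone otherwise
("multiplicative random effects with a floor at 1"). This reduces to the
fixed-effect SE for under-dispersed data and matches the dominant
convention in two-sample MR tooling. Consequence: under a clean null the
test is mildly conservative (empirical type-I ≈ 0.04 at J = 50 instead of
0.05), which the calibration suite checks as a band, not a point.
P-values are normal-theory throughout.

**MR-Egger.** The same regression with a free intercept, after orienting
every instrument so β̂_X ≥ 0 (flipping β̂_Y in step). Orientation is
required for the intercept — mean directional pleiotropy — to be a
well-defined quantity; the convention is "effect allele = exposure-
increasing allele". SEs use the same multiplicative-residual-scale rule
with J−2 df. The I²_GX statistic, (Q_GX − (J−1))/Q_GX with Q_GX the
1/σ_X²-weighted dispersion of the oriented β̂_X, floored at 0, quantifies
regression-dilution violation of the no-measurement-error (NOME)
assumption; values below 0.9 set a warning flag.

**Weighted median.** Wald ratios ordered, cumulative normalized weights
w_j = β̂_Xj²/σ_Yj² with the midpoint convention p_j = (cum_j − w_j/2)/Σw,
linear interpolation at p = 0.5. SE by parametric bootstrap: redraw
(β̂_X*, β̂_Y*) from their normals, recompute, take the SD (default 1000
draws, explicit seed; at 5000 draws the SE is stable to a few percent
across seeds).

**Simple/weighted mode.** Gaussian-kernel density of the ratios, weights
equal (simple) or β̂_X²/σ_Y² (weighted); bandwidth by the modified Silverman
rule 0.9·min(sd, 1.4826·MAD)·J^(−1/5), scaled by a user-visible
`bandwidth_factor` (default 1). The estimate is the argmax on a 2048-point
grid spanning the ratio range ±3 bandwidths; bootstrap SE as for the
median. Degenerate spreads (all ratios equal) return the common ratio.

**MR-PRESSO.** Observed statistic: Σ_j w_j(β̂_Yj − θ̂_(−j)β̂_Xj)² with
θ̂_(−j) the leave-one-out fixed-effect IVW slope and w_j = 1/σ_Yj². Null
distribution: n_sim parametric replicates drawn around the leave-one-out
fits, with leave-one-out slopes re-estimated inside each replicate; global
and per-SNP p-values are exceedance fractions with the +1/(n_sim+1)
continuity correction, per-SNP values Bonferroni-multiplied by J. When
outliers are flagged at α = 0.05 the corrected estimate is IVW on the
retained set, and the distortion p-value compares the raw-minus-corrected
shift against removal of random subsets of the same size (a documented
simplification of the original distortion coefficient that keeps the same
decision rule). Requires J ≥ 4.

**Cochran Q** uses the same first-order ratio weights as IVW, so Q equals
the IVW residual sum of squares exactly (asserted to 1e-10 in tests).

## Selection, harmonization, reporting conventions

- Instrument screen: p < 5e-8 (strict) and MAF > 0.01; records with missing
  allele frequency pass the MAF screen but are flagged, and are dropped
  later if palindromic.
- Greedy clumping: ascending p (ties by chromosome, position, id); an
  accepted SNP prunes same-chromosome neighbors within 1000 kb whose r² is
  known to exceed 0.05 **or unknown**. The conservative unknown rule exists
  because the local LD table replaces a remote LD service: absence of an
  entry is not evidence of independence. Cross-chromosome pairs are never
  pruned.
- Proxies: an instrument absent from the outcome is replaced by the
  outcome-present SNP with the highest known r² ≥ 0.8 (ties by id). The
  proxy's outcome record is oriented against the instrument by allele
  frequency (positive-LD assumption); if the two orientations differ by
  less than 0.02 in frequency the pair is dropped as phase-unknown.
- Palindromic SNPs (A/T, C/G): oriented by allele frequency; dropped when
  the MAF exceeds 0.42 in *either* study (the stricter reading of an
  "either/unspecified" rule) or when a frequency is missing.
  Non-palindromic pairs try orientation match, then orientation swap
  (negating β̂_Y), then strand complementation, then are dropped as
  mismatches.
- Odds ratios: exp(θ̂) with exp(θ̂ ± 1.96σ) CIs; display rounding 3
  decimals, machine outputs full precision. `se_from_or_pval` inverts a
  published (OR, P) pair to its implied SE, for internal-consistency
  reconstruction of published tables.
- BH-FDR: applied to the primary estimate (Wald for J = 1, IVW otherwise)
  across the exposures sharing an outcome — m = number of exposures, 4 in
  the motivating design. Sensitivity-method p-values are reported
  unadjusted. Raw p < 0.05 without FDR survival is labelled "suggestive".
  The step-up computation is delegated to statsmodels and cross-checked in
  tests against a brute-force oracle.
- Method gating in the pipeline: J = 1 → Wald; J = 2 → IVW; J ≥ 3 adds
  weighted median, both modes, and Egger; J ≥ 4 adds MR-PRESSO.
- F and R² from summary data: F = (β̂/σ)², R² = F/(F+n−2), total R² the sum
  over the clumped (≈ independent) set. These need no prevalence or
  liability-scale assumptions.
- Power: the closed-form normal approximation for binary outcomes given in
  the README; monotone in n, R², and |ln OR|. Note that as α → 1 the
  formula tends to Φ(ncp), not 1; α is restricted to (0, 1).

## The synthetic-data generator

The generator emulates a self-reported-infection exposure GWAS paired with
a case–control (or family-history) outcome GWAS:

- SEs follow the binary-trait approximation
  σ = 1/√(2·maf·(1−maf)·n·φ(1−φ)); doubling n shrinks σ by √2 by
  construction.
- Instrument true effects are sized to a per-SNP F drawn uniformly from
  `f_range` (default 60–1000, which reproduces the I²_GX ≈ 0.98 regime of
  well-powered instrument sets), and the observed exposure effect is
  redrawn until p < 5e-8. The redraw guarantees that selection recovers
  exactly the planted instruments; at F ≥ 60 the redraw probability is
  ~1% for the weakest draws, so the induced winner's-curse bias is orders
  of magnitude below sampling noise (measured IVW bias < 0.001 at θ = 0.2).
- Each instrument sits in an LD block with `ld_block_size − 1` satellite
  SNPs at r² = `ld_within_r2`, whose association scales as √r² of the
  lead's z-score; blocks are 5 Mb apart and cross-block r² is deliberately
  *absent* from the LD table, exercising the conservative clumping rule.
  Standalone null SNPs fill out the panel.
- Pleiotropy: a `pleiotropy_frac` subset of instruments receives
  α_j ~ N(μ_α, σ_α²), independent of instrument strength (InSIDE holds by
  construction; InSIDE-violating scenarios are deliberately out of scope so
  the estimator guarantees remain testable). Outlier instruments scale an
  existing α_j by `outlier_scale`, or plant one of `outlier_scale` outcome
  SEs when background pleiotropy is zero.
- Harmonization stressors: a configurable fraction of palindromic allele
  pairs, a 50% chance of swapped allele order in the outcome record, and a
  configurable strand-flip fraction, all recorded in the truth table.
  Effect alleles are exposure-risk-increasing, making directional
  pleiotropy sign-definite for Egger.
- Default cohort sizes mirror the motivating design (exposure 16,711 /
  118,152; outcome 21,982 / 41,944); the `paper_shaped` preset builds four
  exposures with 1, 2, 2, and 15 instruments at their respective cohort
  scales, one discovery outcome and one family-history validation outcome
  (314,278 participants), with true θ equal to the log odds ratios such a
  screen would report.

**What passing tests show — and don't.** The generator draws exact normal
summary statistics with known SEs, non-overlapping samples, InSIDE-valid
pleiotropy, and block-diagonal LD. Calibration results (type-I error,
coverage, Egger recovery, median robustness, PRESSO detection) therefore
validate the *estimators and pipeline plumbing*, not robustness to
sample overlap, weak instruments (F < 10), correlated pleiotropy, allele-
frequency mismatch between ancestries, or mis-specified SEs — none of
which the generator produces.

## Problem sizes and numerical choices

- Calibration suites run at J = 50 (10,000 null replicates for type-I;
  1,000 for bias/coverage), robustness at J = 50 with 40% invalid weight,
  and PRESSO at J = 15 with n_sim = 1000 over 30–40 seeded runs; the
  "large-n" weighted-median consistency check uses an outcome study of
  1.6 M (consistency is asymptotic in the outcome sample; at the default
  63,926 the finite-sample bias is ≈ 0.037, shrinking to ≈ 0.011 at
  1.6 M — the test pins the asymptotic claim, the methods note records the
  finite-sample behavior).
- All stochastic procedures take explicit integer seeds; the pipeline
  derives per-stage streams from one root seed via `SeedSequence`, so
  reruns are hash-identical.
- Ties in clumping break lexicographically on (p, chromosome, position,
  id), making selection independent of input row order.
- Degenerate inputs: zero exposure effect → Wald refuses; no spread in
  β̂_X → Egger refuses; identical ratios → median/mode return the common
  value; unknown LD → conservative pruning; empty selection → stage-named
  pipeline abort with partial outputs removed.

## Known limitations

- No sample-overlap correction, no Steiger directionality filtering, no
  multivariable MR, no liability-scale conversion of R² for binary traits
  (the F/(F+n−2) form is a summary-data approximation).
- MR-PRESSO's distortion null uses random same-size subset removal rather
  than the original parametric distortion coefficient.
- The LD table is pairwise and local; clumping with it cannot reproduce
  reference-panel haplotype structure, only the independence decisions the
  pipeline actually needs.
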