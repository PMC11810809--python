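# Methods

## Model and estimands

The package implements two-sample summary-data Mendelian randomization for a
three-trait causal chain X → M → Y (exposure, mediator, binary outcome).
All arithmetic is on the scale the source GWAS report: per-SD units for
continuous traits (taxon abundances, cytokine concentrations) and log-odds
for the outcome. For a genetic instrument *j* with exposure association
`(beta_x_j, se_x_j)` and outcome association `(beta_y_j, se_y_j)`, the
structural assumption is `E[beta_y_j] = theta * beta_x_j` where `theta` is
the causal effect; the estimators differ in how they pool the per-SNP
evidence and in which violations of the exclusion restriction they tolerate.

The mediation estimands are defined by the product-of-coefficients
decomposition:

- total effect `theta_total`: univariable IVW of X on Y;
- `alpha`: univariable IVW of X on M;
- `b`: multivariable IVW coefficient of M on Y conditional on X, fitted over
  the pooled X- and M-instrument set — conditioning guarantees the
  mediator's effect is net of the exposure's own path;
- indirect effect `alpha * b`, first-order delta-method SE
  `sqrt(b^2 se_alpha^2 + alpha^2 se_b^2)` (an optional second-order term
  `se_alpha^2 se_b^2` is off by default, matching common applied practice);
- proportion mediated `100 * alpha * b / theta_total`.

Because the outcome is binary, the decomposition lives on the log-odds
scale, where odds-ratio non-collapsibility means the "total" and
"direct + indirect" quantities agree only approximately in real data; the
synthetic generator, which works directly on the log-odds scale, satisfies
the identity exactly and the noiseless test verifies it to 1e-8.

A candidate (exposure, mediator) pair is screened before a mediation result
is assembled: both the step-1 path and the conditional mediator→outcome path
must reach p < 0.05. This is a deterministic reading of "selecting exposures
and mediators with true effects"; the screen threshold is configurable and
the raw (unsuppressed) proportion is always recoverable from the result
object.

### Proportion suppression

A mediation proportion is only interpretable when the indirect and total
effects point the same way and the indirect effect is distinguishable from
zero. The result therefore reports `None` (rendered as an em dash in
tables) with a `suppression_reason` of `sign_discordant` or
`indirect_ci_spans_zero` in the other cases. The rule is switchable off
(`suppress=False`).

## Instrument selection

1. **Harmonization.** Outcome records are aligned to the exposure's effect
   allele; swapped alleles flip the outcome beta and complement its
   frequency; strand-complemented pairs are resolved via A↔T/C↔G; A/T and
   G/C (palindromic) SNPs are dropped by default because allele codes alone
   cannot distinguish a strand flip from an allele swap. An opt-in `infer`
   policy keeps palindromic SNPs whose allele frequency is concordantly far
   from 0.5 (MAF < 0.42 on both sides), oriented by frequency. Indels and
   non-ACGT codes drop as allele mismatches. Duplicate snp_ids keep the
   smallest-p record. Harmonization precedes clumping so that clumping only
   sees usable SNPs.
2. **Association threshold.** Strictly `p < 1e-5` on the exposure side by
   default (the lenient threshold customary for microbiome GWAS, where
   genome-wide-significant hits are scarce). The reverse direction defaults
   to `5e-8` — disease GWAS are well powered — and is prominently
   configurable, as this choice is an assumption rather than a convention.
3. **LD clumping.** Greedy: repeatedly take the remaining SNP with the
   smallest exposure p (ties broken lexicographically by snp_id, for
   determinism) as index and eliminate all others on the same chromosome
   within 1000 kb whose r² with the index is ≥ 0.001 (boundary equality
   eliminates — the retention criterion is read as an independence
   requirement r² < 0.001). SNP pairs missing from the LD matrix are
   treated as unlinked with a warning, since the package ships no reference
   panel; synthetic block-diagonal matrices are the test surface.
4. **Confounder exclusion.** An offline two-column (snp_id, reason) list
   replaces a live variant-annotation lookup; removals are logged per
   reason, absent ids as `not_found`.
5. **Strength metrics.** Per SNP, `R² = 2·MAF·(1-MAF)·beta_x²` and
   `F = beta_x²/se_x²`. Instruments with F < 10 are flagged in the run
   report but never dropped — no F cutoff is imposed.
6. **MR-PRESSO.** Observed statistic: inverse-variance-weighted sum of
   squared residuals of each SNP against the IVW slope fitted without it.
   The null is built from seeded parametric draws resampling both sides
   (`beta_x* ~ N(beta_x, se_x)`, `beta_y* ~ N(slope_loo * beta_x, se_y)`);
   all Monte-Carlo p-values use the (r+1)/(n+1) estimator, so the global p
   is never exactly zero. Per-SNP p-values are Bonferroni-multiplied by k;
   SNPs below 0.05 are removed and estimation re-run, with both pre- and
   post-removal estimates retained and the pre/post difference reported
   descriptively (no distortion significance test). Outlier removal runs
   before the primary estimate, consistent with its placement among the
   instrument quality-control steps.

## Estimators and inference

- **IVW**: `beta = sum(w bx by) / sum(w bx^2)` with `w = 1/se_y^2`; fixed
  SE `(sum w bx^2)^(-1/2)`. The multiplicative random-effects flavour
  scales the SE by `max(1, sqrt(Q/(k-1)))` and is triggered automatically
  when Cochran's Q p < 0.05 (additive DerSimonian–Laird is deliberately not
  implemented). Normal reference for p and 1.96-based CIs, as applied MR
  tables use. A single instrument degrades to the Wald ratio with a notice.
- **Wald ratio** SE is first-order `se_y/|bx|`, which makes IVW-over-ratios
  and the origin regression agree exactly (verified algebraically in
  tests); a second-order option exists.
- **MR-Egger**: instruments oriented to non-negative exposure effects;
  weighted fit with intercept; multiplicative residual scaling floored at
  1; t inference with k-2 df for slope and intercept (the intercept triple
  is the directional-pleiotropy test).
- **Weighted median**: inverse-variance weights of the ratios, cumulative
  weights `s_i = sum_{j<=i} w_j - w_i/2`, linear interpolation at 0.5.
- **Weighted mode**: weighted normal-kernel density over ratios with the
  modified Silverman bandwidth `0.9 min(sd, IQR/1.34) k^(-1/5)` times a
  bandwidth factor, argmax on a 512-point grid spanning the ratios ± 3
  bandwidths; identical ratios short-circuit to the common value. The
  weighted variant is the default; equal weights give the simple mode.
- Median and mode SEs come from a seeded parametric bootstrap (default 1000
  replicates) drawing both beta sides; the bootstrap consumes fixed
  standard-normal draws so estimates are exactly equivariant under outcome
  rescaling and bit-reproducible given a seed.

Every stochastic routine takes an explicit seed; identical seeds give
identical results (asserted in tests).

## Synthetic-data generator

Summary-level only — no genotypes are simulated, which keeps a full
triplet at desk scale (milliseconds). Per SNP: MAF ~ Uniform(0.05, 0.5),
genotype variance `v = 2p(1-p)`, and the GWAS of size n observes each true
effect with SE exactly `1/sqrt(v n)`. The panel splits into three sparse
instrument classes — exposure (true effects `gamma ~ N(0, sigma_gamma^2)`),
mediator-direct (`eta ~ N(0, sigma_eta^2)`), outcome-direct
(`omega ~ N(0, sigma_omega^2)`) — because that is both how real
architectures behave and what identifies the multivariable fit: with no
mediator-direct effects the MVMR design is rank-1 in truth and `b` is not
estimable from any amount of data.

Defaults are the study conditions the package is calibrated under:

| parameter | default | rationale |
|---|---|---|
| n_exp | 18,340 | microbiome-GWAS meta-analysis scale |
| n_med | 15,000 | typical circulating-cytokine GWAS scale |
| n_out | 1,030,836 | AF GWAS scale (60,620 cases + 970,216 controls) |
| sigma_gamma | 0.066 | mean exposure-instrument F ≈ 30 at n_exp |
| sigma_eta | 0.073 | mean mediator-instrument F ≈ 30 at n_med |
| sigma_omega | 0.0088 | mean outcome-instrument F ≈ 30 at n_out |
| alpha, b, c_direct | 0.2, 0.3, 0.1 | mediation proportion 37.5% |
| class fractions | 0.5 / 0.3 / 0.2 | exposure / mediator / outcome SNPs |
| palindrome_fraction | 0.15 | approximate share of A/T + G/C SNPs |
| maf_range | 0.05–0.5 | common variants, as GWAS panels use |

(The F ≈ 30 calibration follows from E[F] ≈ 1 + sigma²·E[2p(1-p)]·n with
E[2p(1-p)] ≈ 0.365 over the MAF range.)

Horizontal pleiotropy is a per-SNP term added to the outcome beta:
`balanced` (zero mean) or `directional` (mean mu), carried with a given
probability, with an optional correlation with the instrument effect (an
InSIDE violation). Directional pleiotropy is applied in the
exposure-increasing-allele orientation — the frame in which the MR-Egger
intercept is defined; injected in the raw random allele frame it would
cancel and be undetectable by construction.

Block LD is realized as equicorrelated effect noise within blocks
(correlation r² between members) plus a matching block-diagonal r² matrix;
block members are placed 10 kb apart (inside the clumping window) and
blocks 10 Mb apart on cycling chromosomes (outside it), so clumping a
block fixture retains exactly one SNP per block. The default is no LD:
independent instruments are the base condition for the calibration suites.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sample overlap between the two GWAS (two-sample
independence is assumed; no overlap-correlation knob), liability-scale
versus log-odds subtleties for the binary outcome, realistic human LD maps,
allele-frequency differences between cohorts (an optional EAF-noise knob
exists for harmonization stress tests, default off), and winner's-curse
effects of discovery-based instrument selection beyond what the p-threshold
itself induces.

Known behaviour worth stating: at mean F ≈ 30, measurement error in the
exposure betas attenuates the univariable estimates by roughly F/(F+1)
(~3%); the attenuation largely cancels in the mediation proportion (a
ratio), and the 200-replicate recovery check lands near 35–36% against the
true 37.5%. When the forward path is non-null, the outcome GWAS top hits
include the exposure's instruments, so a naive reverse-direction analysis
is contaminated — with real data exactly as here; reverse-direction
calibration therefore uses a null forward path, which isolates the
machinery being tested.

## Pipeline conventions

- Per-rank multiple testing: `p < 0.05/n` with effective taxon counts
  phylum 9, class 15, order 19, family 30, genus 117 (defaults,
  overridable). The registry separately records raw per-rank totals (e.g.
  131 genera of which 117 have a known group) without attempting to
  reconcile pre- and post-filter counts across ranks.
- IVW is the primary estimator; discordant secondary estimators set a
  `sensitivity_discordant` flag rather than suppressing the row.
- Per-exposure failures (no overlap, no instruments) are logged and
  skipped; only a fully empty run errors. A `manifest.json` (thresholds,
  seeds, SHA-256 input digests) fully determines the output tables.
- All four estimators run uniformly for every exposure.
- Problem sizes used by the calibration suites: 200 replicates of 50- or
  100-SNP panels for coverage/recovery, 100 replicates for outlier
  detection and intercept recovery, 1000-draw MR-PRESSO nulls and
  1000-draw bootstraps — sizes at which each suite completes in seconds
  while keeping Monte-Carlo error well inside the asserted bands.

## Numerical choices and degenerate inputs

- Ties in clumping break lexicographically; the retained set is invariant
  to input order.
- p-values from the generator are clamped to ≥ 1e-300 so the (0, 1]
  invariant survives extreme z-scores.
- Bootstrap resamples guard zero denominators by nudging resampled exposure
  betas away from exact zero at the smallest positive float.
- `mvmr_ivw` drops an exactly-zero effect column (coefficient 0, SE NaN)
  and fits the remaining trait univariably; any other rank deficiency
  raises a collinearity error naming the traits.
- Zero kernel bandwidth (all ratios identical) returns the common ratio.
- Empty result sets: writing an empty table is an error (no file created);
  an empty mediation run (nothing passed screening) is a success with an
  explanatory log.

## Limitations

No Steiger directionality filtering, proxy-SNP search, MR-RAPS or other
modern robust estimators, no additive random-effects IVW, no
counterfactual (natural direct/indirect) mediation framework, single
mediator per decomposition, no genotype-level simulation, and no LD
estimation from reference panels — LD must be supplied, or absent SNP
pairs are treated as unlinked.
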