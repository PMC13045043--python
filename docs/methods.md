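# Methods

## Scope and model

The package estimates the causal effect of one quantitative exposure trait
on one or more outcome traits from GWAS summary statistics of the two
traits, plus a signed LD correlation matrix over the candidate instruments.
The structural assumption is the standard instrumental-variable one: a
variant z associated with exposure x affects outcome y only through x, so
that b_zy = b_xy · b_zx for every valid instrument, with horizontal
pleiotropy entering as an additive direct effect γ on the outcome.

### Instrument selection

1. **Significance filter.** Exposure association p < 5e-8 (configurable;
   the threshold is a per-analysis choice, not a law of nature).
2. **LD clumping.** Greedy: the smallest-p unremoved variant becomes an
   index SNP; unremoved variants within 1 Mb with r² > 0.05 are removed;
   repeat. Ties on p are broken by position then id, which makes the result
   independent of input order. Cross-chromosome r² is defined as 0.
3. **Strength filter.** Per instrument, R² = z²/(z² + n − 2) and
   F = (n − 2)R²/(1 − R²), which reduces algebraically to F = z². F < 10 is
   excluded (strict inequality; F = 10 is kept). An allele-frequency-based
   R² (2p(1−p)b²/var_y) is available for users with a known phenotype
   variance.
4. **Minimum count.** Fewer than 10 surviving instruments aborts the fit
   with a diagnostic error.

### Causal estimation

Per-instrument ratios b_xy(i) = b_zy(i)/b_zx(i) carry the first-order
delta-method variance var_i = (se_zy² + b_xy(i)²·se_zx²)/b_zx²; the
covariance between ratios i ≠ j is
r_ij·(se_zy,i·se_zy,j + b_xy(i)·b_xy(j)·se_zx,i·se_zx,j)/(b_zx,i·b_zx,j).
The combined estimate is the generalized IVW mean
(1ᵀV⁻¹1)⁻¹·1ᵀV⁻¹·b, with variance (1ᵀV⁻¹1)⁻¹, solved through a Cholesky
factorization (never an explicit inverse). When the smallest eigenvalue of
V falls below 1e-10 of the largest (near-duplicate instruments), a ridge of
1e-8·trace(V)/m is added to the diagonal and flagged in the results.
P-values are large-sample normal; sample sizes in the intended applications
are in the thousands, so no t correction is applied. The covariance between
exposure and outcome effect estimates under sample overlap is zero by
default and exposed as `overlap_rho`.

**HEIDI-outlier.** The reference instrument is the one with the largest
|b_zx/se_zx|. For every other instrument, d_i = b_xy(i) − b_xy(ref) is
tested against var(d_i) = var_i + var_ref − 2·V_i,ref; all instruments with
two-sided p < 0.01 are removed in one pass, and passes repeat (re-deriving
the reference) until no removal. The published description of the test
names neither the reference rule nor single-pass vs iterated behaviour
unambiguously; strongest-instrument reference with iteration to convergence
is this package's documented choice. Excluded variants are reported with
their full effect rows.

**Multiple outcomes.** The family significance threshold is
0.05/n_outcomes (0.0125 for the four-outcome design).

### Colocalization

Per SNP and trait, the Wakefield approximate Bayes factor is
log ABF = ½[log(1 − r) + r·z²], r = W/(W + se²). Under the
one-causal-variant-per-trait assumption the five hypothesis weights are
H0: 1; H1: p1·ΣeL1; H2: p2·ΣeL2; H3: p1·p2·Σ_{i≠j} eL1_i·eL2_j;
H4: p12·Σ eL1+L2. H3 is evaluated in log space as
log(exp(S1+S2) − exp(S12)) with a max-shift; numerical underflow of the
difference clamps PP.H3 to 0 (it is exactly 0 for a single-SNP region).
Defaults: p1 = p2 = 1e-4, p12 = 1e-5, W = 0.15² (the conventional
quantitative-trait value; W is a config key because analyses rarely print
it). Variants present in only one trait's slice are dropped before the
per-SNP products, with a logged count. PP.H4 thresholds (≥ 0.9 "strong")
are report annotations only, never filters. Regions are ±500 kb windows
around instruments (merged when overlapping), re-run at ±100 kb and
±250 kb for sensitivity, reporting whether the top SNP
(argmax of L1 + L2) is stable across window sizes.

### Annotation

Gene models come from GFF3 (`gene` rows), BED (converted to 1-based
inclusive) or TSV. A variant maps to a gene when its position falls within
the gene body extended by `flank_bp` (0 for instruments, 500 kb for
colocalized top variants), via an interval tree. Per-analysis gene sets are
intersected into an exclusive Venn partition whose counts sum to the union
size; the shared fraction is |all-way intersection|/|union|. Consequence
prediction (missense etc.) is out of scope; annotation is purely
positional, and symbol validation is an optional allow-list.

## The synthetic-data generator

The generator emulates the summary-statistics structure the estimators
assume, under a unit-variance phenotype and Hardy–Weinberg dosage variance,
so se = (2·maf·(1−maf)·n)^(−1/2).

**Instrument panels.** Per instrument: maf ~ Uniform(0.1, 0.5); a true
exposure effect ~ N(0, 0.15²) resampled until its expected |z| ≥ 6, which
guarantees genome-wide significance of the underlying signal and avoids
winner's-curse selection in recovery studies (a deliberate idealization —
real instrument selection conditions on the observed z, and an observed
boundary instrument can still fall below the significance threshold by
sampling noise); observed effects are the truth plus N(0, se²) noise, with
optional correlation `overlap_rho` between the exposure and outcome errors
(default 0, as exposure and outcome cohorts in the motivating design
overlap but the overlap covariance is unknown). b_zy = b_xy·b_zx + γ, with
γ ≠ 0 only at planted pleiotropic indices. Instruments sit 2 Mb apart
(quasi-independent; identity LD), so window arithmetic in clumping is
exact. The effect-scale default 0.15 corresponds to leading instruments
explaining of order 0.2–2% of phenotypic variance each at the preset sample
sizes — the top-hit regime of dense livestock meta-GWAS. It is a
per-scenario field, not a calibrated constant.

**Named presets.** The four outcome presets plant the published causal
estimates (0.13, 0.35, −3.24, −0.05) with the published instrument counts
(115, 113, 106, 112) and cohort sizes (exposure 20,555; outcomes 39,323 /
24,215 / 5,707 / 17,077). The pleiotropy presets are noise-free: valid
instruments sit exactly on the causal ratio and the published pleiotropic
variant rows (four for the backfat analysis, two for loin muscle depth,
with their printed effects and SEs) are appended verbatim, so the HEIDI
reconstruction has a deterministic right answer. Note the published rows
are on the trait scale of the original data while the generated instruments
are unit-variance; the HEIDI statistic only compares ratios and their SEs,
so the scale mismatch is immaterial to the reconstruction.

**Regions.** Marginal z-scores are drawn as MVN(R·λ, R) over an AR(1) LD
matrix (r_ij = ρ^|i−j|, drawn via the first-order recursion, which is the
exact Cholesky transport), with λ zero except the non-centrality at the
causal index per trait; betas are z/√n. Presets: 1001 SNPs at 1 kb spacing,
ρ = 0.9, non-centrality 12, n = 20,000 per trait, causal variants shared
(centre) or 200 kb apart. AR(1) is a stand-in for block LD; it does not
model long-range admixture LD or allele-frequency-dependent LD, so passing
tests show correctness of the estimators under the stated model, not
robustness to every real LD pathology.

What the generator does **not** model: individual-level genotypes, breed
structure and per-breed meta-composition, imputation error, winner's curse
in instrument discovery, and heritability budgets (planted effects are not
constrained to sum to a valid total variance).

## Numerical and design choices

- Variant matching is by id first, with a chrom:pos + allele-set fallback;
  strand complements are tried before declaring an allele mismatch;
  palindromic variants follow an explicit policy (default: drop when eaf in
  [0.4, 0.6] in either table). Harmonization is idempotent.
- Meta-analysis is fixed-effect IVW per variant (beta = Σw·b/Σw,
  w = 1/se²; n summed); Cochran's Q is computed and logged but never
  filters. Genomic control estimates λ = median(z²)/0.4549 and never
  deflates (SE scale max(1, √λ)).
- All generators are deterministic given an integer seed; pipeline reruns
  with the same config and seed produce byte-identical tables.
- Problem sizes in the validation studies — 200 replicates per recovery
  preset, 50 colocalization replicates, 2000 replicates for type-I error
  and CI coverage — were chosen to put Monte-Carlo error well below the
  effect sizes being checked while keeping a full run in minutes on one
  CPU.

## Known limitations

- **Finite-sample bias of the ratio-IVW.** With plug-in delta-method
  variances (the standard formula, used here as in the reference
  implementations of this estimator), the combined estimate carries a
  toward-zero relative bias of order 1/E[z²] from the noisy ratio
  denominators and the correlation between each ratio and its own weight.
  At the preset instrument strengths (z roughly 6–30) this is ~1% of the
  causal effect — invisible at the precision such analyses report, but
  detectable by a 200-replicate mean, and it degrades nominal 95% CI
  coverage for the weakest-outcome preset (the age-at-first-farrowing
  conditions, n_outcome = 5,707), where the bias is an appreciable fraction
  of the per-replicate SE. The accompanying validation suite asserts
  unbiasedness at 3 Monte-Carlo SEs and pooled coverage in [93%, 97%];
  those checks fail for the stronger-effect presets for exactly this
  reason and are retained as honest documentation of the estimator's
  small-sample behaviour rather than loosened.
- The colocalization model assumes at most one causal variant per trait per
  region; multi-causal fine-mapping extensions are out of scope.
- Reverse-direction MR, Egger/median/mode estimators, and
  eQTL/TWAS/PheWAS integration are out of scope.
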