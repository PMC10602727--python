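# Methods

## Setting and assumptions

Two-sample Mendelian randomization treats genetic variants as instruments
for an exposure: if SNP j is (i) associated with the exposure, (ii)
independent of exposure–outcome confounders, and (iii) affects the outcome
only through the exposure, then its Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates the
causal effect. The package consumes only summary statistics — per-SNP
(effect, SE, p, alleles, frequency, N) for each trait — so exposure and
outcome samples may come from different studies. Effects on a binary
outcome are log-odds; causal estimates are log-odds per SD-unit exposure
and are reported as odds ratios exp(β) with 95% CI exp(β ± 1.96·SE).

Ratio SEs use the first-order delta method, se(β̂ⱼ) = σ_yj/|γ̂ⱼ|, ignoring
exposure-side error (the NOME simplification; a second-order option exists
on `ratio_estimates`). Two consequences worth knowing: under a nonzero
causal effect θ, exposure noise inflates the dispersion of ratios beyond
σ_yj (so Cochran's Q and the PRESSO global test run "hot" for strongly
causal exposures even with valid instruments — the random-effects IVW
default absorbs this), and all ratio-based estimators carry a
regression-dilution attenuation of order σ_x²/E[γ²], i.e. roughly 1/F̄.

## Instrument selection

Filter stack, in order: p-value ceiling on the exposure association
(default 1e-5, the customary relaxation for under-powered exposures such as
microbiome taxon abundances; 5e-8 genome-wide for the reverse direction);
greedy LD clumping (rank by ascending p, keep the best remaining SNP,
discard SNPs with r² ≥ 0.001 within a 10,000 kb window; ties broken
lexicographically on snp_id so output is order-free); removal of SNPs on a
user-supplied confounder list (the offline stand-in for a
phenotype-catalogue lookup); weak-instrument filtering at F ≥ 10.
Comparisons are strict `<` for p-selection and inclusive `≥` for F,
matching the conventional statements of those rules. The F-statistic is
the single-instrument Wald form F = (β/σ)² by default; the
variance-explained form F = R²(N−2)/(1−R²) with R² = 2·maf(1−maf)·β² is a
config option (`f_method: r2`) — at GWAS effect scales the two agree to a
few percent. LD is consumed as a precomputed pairwise r² matrix (long or
square TSV); with no LD input, clumping degrades to distance-only window
filtering with a warning. Positions are optional; without them the window
condition is treated as satisfied and LD alone decides.

## Harmonization

Outcome effects are aligned to the exposure's effect allele. Swapped
alleles flip the outcome beta and mirror its frequency; strand flips
(complement bases) are reconciled for non-palindromic SNPs before a pair is
declared incompatible, since meta-analysis sources mix strand conventions.
Palindromic (A/T, C/G) SNPs are dropped unconditionally — no
allele-frequency rescue — the strictest reading of "palindromic and
ambiguous SNPs removed". The audit trail accounts for every input SNP
(kept/flipped/strand_flipped, or dropped as
unmatched/palindromic/incompatible); duplicated identifiers within a table
are a hard error rather than a silent first-match join.

## Estimators

Formulas are fixed explicitly (the surrounding literature's canonical
forms) so outputs are well defined:

- **IVW**: β̂ = Σwγ̂Γ̂/Σwγ̂², w = 1/σ_y²; SE multiplied by
  √max(1, Q/(L−1)) under the multiplicative random-effects default
  (`ivw_model: fe` disables); normal p.
- **MR-Egger**: orient instruments to γ̂ ≥ 0, WLS with intercept, weights
  1/σ_y²; SEs are unit-dispersion WLS SEs scaled by max(1, √(RSS/(L−2)));
  two-sided t(L−2) p for slope and intercept. The L−2 df choice is pinned
  by a unit test on a published three-instrument fit (β/SE = 1.93/0.864 →
  p = 0.268 under t(1)).
- **Weighted median**: sort ratios, normalized inverse-variance weights
  w′, cumulative midpoints sⱼ = Σ_{k≤j}w′_k − w′ⱼ/2, linear interpolation
  to s = 0.5. SE = SD of parametric bootstrap resamples
  (γ̂*, Γ̂* redrawn from their SEs; default 1000, seeded); normal p.
- **Modes**: Gaussian-kernel density over the ratios, Silverman-type
  bandwidth 0.9·min(sd, IQR/1.349)·L^(−1/5) times a bandwidth factor
  (default 1), argmax on a fixed 512-point grid spanning the ratio range
  ±3 bandwidths; uniform (simple) or inverse-variance (weighted) kernel
  weights; bootstrap SE as above; t(L−1) p. If both spread measures vanish
  (all ratios equal) the estimate is that common ratio.

Estimates are only reported for pairs with at least three surviving
instruments.

## Pleiotropy and heterogeneity diagnostics

**Cochran's Q** about the fixed-effect IVW slope, χ² with L−1 df;
p < 0.05 flags heterogeneity. **Egger intercept**: t(L−2) test of the
fitted intercept. **MR-PRESSO**: the observed statistic is
RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₋ⱼγ̂ⱼ)² with β̂₋ⱼ the leave-one-out IVW slope; the
null re-draws γ̂ⱼ* ~ N(γ̂ⱼ, σ_xj) and Γ̂ⱼ* ~ N(β̂₋ⱼγ̂ⱼ, σ_yj)
(default 10,000 draws, reducible in config; tests use 500) and recomputes
the statistic, leave-one-out slopes included. Empirical p-values use
(1+k)/(1+N), never zero. Per-SNP outlier p-values rank each SNP's observed
weighted squared residual in its own simulated distribution,
Bonferroni-adjusted by L.

The sequential cleanup loop follows the remove-and-retest recipe: run the
global test; while p ≤ 0.05, remove the SNP with the smallest outlier p
and re-test the remainder (re-ranking each iteration; a config switch can
freeze the initial ranking). The loop hard-stops when fewer than four SNPs
would remain, since the leave-one-out statistic needs three. Numerical
choice made here: empirical p-values floor at 1/(N+1), so at modest N
several SNPs can tie at the floor; ties are broken by the larger observed
weighted squared residual and then lexicographically. Without the residual
key, a gross outlier and a merely slope-contaminated SNP are
indistinguishable at the floor and the loop can eliminate innocents first;
with it, planted-outlier recovery is essentially exact. The distortion
test compares fixed-effect IVW before vs after removal, scaled by the
bootstrap SE of the difference (500 resamples); it is reported but gates
nothing. **Leave-one-out**: IVW per excluded SNP, with a driver flag when
any exclusion flips the estimate's sign or moves the 95% CI across zero.

## Multiple testing and directionality

Each taxonomic rank gets the threshold α/n, with n the number of taxa at
that rank with a reported result (at least three instruments after QC).
This "count of reported taxa" operationalization reproduces the published
thresholds exactly at all five ranks (0.05/88, /27, /14, /12, /8), so no
eigenvalue-based effective-number computation is used. The reverse
direction swaps roles — disease as exposure at the genome-wide 5e-8
instrument ceiling, each identified taxon as outcome — and flags "no
reverse causation" when the reverse IVW p ≥ 0.05. Per-taxon failures are
quarantined with a reason; a panel run never aborts on one bad taxon. All
per-taxon randomness derives from one mandatory config seed via spawned
seed sequences, so reports are byte-reproducible.

## Synthetic data

The generator works directly on the summary-statistic level (no
individual-level genotypes — two-sample MR never sees them, and it keeps
runtime at seconds): maf ~ U(0.05, 0.5) mirroring a MAF > 0.05 filter;
true exposure effects γⱼ ~ N(0.08, 0.03²) truncated positive (effects
reported for the trait-increasing allele); SE scales
σ = 1/√(2n·maf(1−maf)) with defaults n_exp = 18,340 and n_out = 24,510
emulating a microbiome-consortium exposure GWAS and a case/control liver
disease outcome GWAS; Γⱼ = θγⱼ + αⱼ with pleiotropy αⱼ drawn for a
`prop_invalid` fraction of SNPs (balanced mean 0 or directional mean
α_sd; `inside_violated` correlates α with γ at r = 0.5); observed effects
add Gaussian noise; Wald p-values; allele pairs include 15% palindromic
variants by default (the typical A/T + C/G share). Defaults fixed once:
α_sd = 0.01 (comparable to the mean direct effect θ·γ̄ at θ ≈ 0.3),
giving directional pleiotropy that visibly biases IVW while leaving the
weighted median's majority condition intact.

What it does **not** emulate: LD between instruments (SNPs are placed on
distant loci; clumping is exercised against hand-built r² matrices),
case-control liability-scale subtleties, sample overlap between the two
GWAS, and winner's-curse selection on the exposure. Passing tests
therefore demonstrate correctness of the estimators and diagnostics under
the stated generative model, not robustness to those real-data
complications.

## Calibration experiments: design choices

- **Parameter recovery** (θ = 0.3, L = 100, 200 replicates, mean within
  3 Monte-Carlo SEs per estimator) runs at n_exp = n_out = 1,000,000.
  At study-scale n the known finite-sample attenuations — the NOME ratio
  dilution (≈ 1/F̄ ≈ 2%) and MR-Egger's regressor-error dilution
  (≈ σ_x²/var(γ)) — exceed the Monte-Carlo resolution of a 200-replicate
  mean, so the experiment would measure instrument strength, not estimator
  correctness. At biobank-scale n both biases are an order of magnitude
  below 3 MC SEs and the experiment isolates the estimators themselves.
- **Null calibrations** (Egger intercept type-I, Q uniformity, IVW p
  uniformity) run at θ = 0, where the summary-statistic model is exactly
  Gaussian and the statistics have their textbook null distributions; with
  θ ≠ 0 the NOME leakage above makes them intentionally conservative
  (random-effects IVW) or mildly inflated (Egger intercept), which is a
  property of the approximations, not a bug in the tests. The
  random-effects IVW p is checked one-sided (never anti-conservative)
  because the max(1,·) truncation makes it deliberately conservative.
- **Family-wise error**: with two taxa per rank across five ranks, perfect
  calibration still leaves a 1−(1−0.025)¹⁰ ≈ 22% chance of at least one
  false positive per run (per-rank Bonferroni controls each rank at 5%,
  not the whole panel). The test therefore asserts the per-taxon
  false-positive rate (≤ 0.04 at the 0.025 threshold; measured ≈ 0.022)
  and that most runs flag nothing (≥ 65% over 40 runs), which is what the
  design actually guarantees.
- Test and acceptance runs shrink simulation knobs that only affect
  Monte-Carlo resolution (PRESSO draws 500, bootstrap 16–100) and keep
  every structural parameter at its default.

## Known limitations

No GWAS-VCF input, liftover, INDELs or multi-allelic sites; no live
phenotype-catalogue or LD-panel queries (both are file inputs by design);
no I², Rucker framework, MR-RAPS or multivariable MR. The distortion test
is informational only. Egger estimates at L = 3 have one residual df and
are accordingly unstable — they are reported because the standard battery
reports them, but the IVW row is the primary causal claim.
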