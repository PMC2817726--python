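# Methods

`strokemeta` implements an evidence-synthesis pipeline for candidate-gene
case-control studies of ischemic stroke: per-study odds ratios under a chosen
genetic model, inverse-variance pooling with DerSimonian–Laird random effects,
heterogeneity and small-study-bias diagnostics, population attributable risk
(PAR) and temporal trends, cross-disease effect comparison with power
back-calculation, and a mendelian-randomization triangulation that compares
the genotype risk observed directly with the risk predicted from independent
genotype→biomarker and biomarker→disease data.

## Effect estimates

A study's genotype counts (hom-risk, het, hom-wild) for cases and controls are
collapsed to a 2×2 exposure table under one of four genetic models: dominant
(carriers vs non-carriers), recessive (hom-risk vs rest), allelic (risk vs
wild alleles, two per genotype) and hom-vs-hom (het column dropped). The
log odds ratio is ln(ad/bc) with se = √(1/a+1/b+1/c+1/d). Zero cells receive
the Haldane–Anscombe correction: +0.5 to **all four cells of the affected
table only**; a zero cell with the correction disabled is a hard error rather
than an infinite estimate. The first count slot is always the risk (variant)
genotype; orientation is the caller's responsibility and is carried through
so sign flips cannot pass silently. Studies that publish only allele counts
are accepted (blank het columns in the table dialect) and are compatible with
the allelic model only. Per-allele ORs can therefore be obtained either by
genotype collapsing or from allele counts; both paths are exposed because
the convention differs between published meta-analyses.

All 95% intervals are plain Wald intervals, estimate ± 1.96·se (exponentiated
on the OR scale). No Knapp–Hartung adjustment is applied, matching the
classical software conventions this engine mirrors.

## Pooling, heterogeneity, bias

Fixed-effect pooling is the inverse-variance weighted mean (w = 1/se²).
Between-study variance τ² is the DerSimonian–Laird method-of-moments
estimate, max(0, (Q − (k−1))/C) with C = Σw − Σw²/Σw, and random-effects
weights are 1/(se² + τ²). Heterogeneity is Cochran's Q with a χ²(k−1)
p-value; I² is derived from Q as a descriptive convenience only — reporting
decisions use the Q p-value at 0.05. Publication bias uses Egger's
regression in its published formulation: OLS of the standardized effect
y/se on precision 1/se, two-sided t-test on the intercept with k−2 df,
screened at p < 0.1. (The funnel *plot* exports effect against se; the
regression is not run on the plot's coordinates.) A design in which all
precisions are equal is singular and rejected. No confidence interval is
computed for τ² because none is used downstream.

Continuous outcomes (biomarker levels by genotype) pool the difference of
group means with se = √(sd₁²/n₁ + sd₂²/n₂) through the same random-effects
machinery.

## PAR and trends

PAR(%) = 100·p(OR−1)/(p(OR−1)+1), with p the risk-genotype frequency among
pooled controls under the same genetic model used for the OR. Summed PARs
across polymorphisms are a first-order total that ignores overlap between
exposures; the sum of per-gene values rounded to one decimal can therefore
differ slightly from a total computed on unrounded inputs (27.7 vs 27.5 for
the published per-gene values), and the package sums exactly what it is
given. The trend series counts, per publication year, cases recruited to
polymorphisms judged associated (random-effects CI excluding 1 and
heterogeneity p ≥ 0.05; configurable) versus unassociated, with both
per-year and cumulative series emitted because either accumulation
convention is defensible.

## Cross-disease comparison

Two pooled log-OR results for the same contrast are classified as:
concordant-positive (both CIs exclude 1 on the same side and overlap),
dissociated (disjoint CIs — which subsumes significance in opposite
directions), underpowered-overlap (exactly one significant, CIs overlap) or
concordant-null. For underpowered-overlap the minimum case count for 90%
power at α = 0.05 is back-calculated from the significant disease's OR via
the two-proportion normal-approximation sample size on exposure frequency,

n = (z₁₋α/₂·√((1+1/r)·p̄q̄) + z₁₋β·√(p₁q₁ + p₀q₀/r))² / (p₁−p₀)²,

with p₁ = OR·p₀/(1+p₀(OR−1)) and r controls per case (default 1:1, per-allele
or genotype contrast at the caller's discretion). The formula is validated
against Monte-Carlo power of the uncorrected Pearson chi-square test (the
matching asymptotic test; a Yates-corrected test would sit ~1–2 points
lower at these sizes). Restricting comparisons to population subsets
(e.g. one ethnicity) is done by filtering the study table and re-running,
not by a dedicated operation.

## Triangulation

For a genotype contrast (rarer vs commoner), the pooled biomarker shift
ΔX is estimated from disease-free cohorts, either in shared absolute units
or as percent change 100·(mean_a − mean_b)/mean_b with a delta-method se
(for analytes reported in incommensurable units; subgroup pooling by assay
type is supported by filtering the study list). Published ORs of stroke per
increment δ of the biomarker are converted to the genotype's shift assuming
log-linearity: ln OR_scaled = (ΔX/δ)·ln OR, se scaled by |ΔX/δ|; se is
recovered from published CIs by the symmetric log-scale formula, with a
warning and the wider half-width when the CI is asymmetric beyond 5%. The
rescaled estimates are pooled by generic inverse-variance random effects and
exponentiated; a single external summary estimate passes through as k = 1.

The expected-OR CI propagates only the IP-risk OR uncertainty, treating ΔX
as fixed at its pooled value: the pooled shift is typically an order of
magnitude more precise than the risk estimates it scales (its relative se
contributes < 1% of the expected log-OR variance in the reference
scenarios), and treating it as a plug-in constant keeps the estimator a
linear pooling of published quantities. ORs must be oriented per positive
unit of the biomarker; the applied scale factor f is reported per study in
the audit trail so sign conventions can be checked.

**Verdict.** The headline concordance criterion is whether the expected
point estimate lies inside the observed 95% CI — the criterion under which
a biomarker-predicted risk is judged consistent with directly observed
genotype risk. The reverse containment (observed point inside expected CI)
is evaluated and reported alongside as a diagnostic. A symmetric "both
containments" rule was considered and rejected: for independent, calibrated
estimates the probability that both hold is bounded by 2Φ(1.96/√2)−1 ≈ 0.83
even when expected and observed risk are identical in truth, i.e. the
symmetric rule misclassifies a sixth of genuinely concordant pairs at best,
with the bound attained when the two uncertainties are equal.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
a single seed feeding a splittable stream per stage (bit-identical,
call-order independent output):

* genotype studies: per-study log-OR ~ N(ln OR, τ²); controls multinomial
  under Hardy–Weinberg proportions; case genotypes from genotype-conditional
  odds that reproduce the target exposure OR exactly for the 2×2 models
  (dominant, recessive, hom-vs-hom — the het class tilted by half the
  log-OR); the allelic model tilts the allele frequency and re-forms
  genotypes under HWE, an approximation adequate for HWE populations;
  publication years uniform on 1993–2009 to exercise the trend analysis;
* biomarker studies: group means drawn around fixed population means with
  sd/√n noise and χ²-distributed sample SDs, cohort split by genotype
  frequency (floor 20 per group);
* IP-risk studies: with Gaussian biomarker levels and logistic risk of slope
  β per unit, case levels are exactly N(μ + βσ², σ²) against control levels
  N(μ, σ²); each study is analysed by logistic regression (statsmodels) and
  reported per an increment drawn from a configurable set, so rescaling is
  exercised with heterogeneous increments.

Not emulated: covariate confounding, linkage structure, non-Gaussian
(e.g. skewed) biomarker distributions, genotyping error, and selective
publication. Passing calibration tests therefore demonstrates internal
statistical correctness of the pipeline under its own model, not robustness
to those real-data features.

Reference scenarios (sizes follow the ranges printed for the corresponding
literatures: ~26 genotype studies of hundreds of cases each, IP-risk studies
of 800–1688 cases and up to ~30.5k controls):

* `fvl_like` — fully mediated thrombophilia chain: carrier frequency ~4.9%
  (allele 2.5%), APC-resistance ratio shift −0.74 against a reference mean
  3.0 (SD 0.40), risk slope ln(1.30)/−0.74 per unit, no direct effect;
  marginal carrier OR 1.30. τ² = 0, matching the absence of significant
  heterogeneity reported for the positive gene–stroke associations.
* `pai1_like` — pleiotropy: the rarer homozygote lowers the biomarker ~25%
  (15 vs 20 units, SD 8, percent-change mode) while higher levels carry risk
  (slope 0.047 per unit), plus a direct genotype effect bringing the
  marginal hom-vs-hom OR to 1.30; biomarker-predicted OR ≈ 0.79, so the
  chain is discordant by construction.
* `null` — no effect anywhere.

## Numerical choices and edge cases

* Degenerate single-study "pools" pass through unchanged with τ² = 0.
* τ² truncation at zero; C ≤ 0 (pathological weights) returns τ² = 0.
* Egger requires k ≥ 3 and non-constant precisions; Q requires k ≥ 2.
* The report renders ORs/CIs to 2 decimals; JSON audit files keep full
  precision. Duplicate study ids within a polymorphism are a hard error
  (overlapping publications are a curation decision, not auto-resolved).
* Monte-Carlo checks in the test-suite use sizes chosen so their own
  sampling error is small against the tolerance being asserted (e.g.
  CI coverage estimated over 5000 replicate meta-analyses, power over 10⁴
  simulated tables); the whole suite runs in well under a minute.

## Known limitations

Sums of PARs ignore exposure overlap. The triangulation assumes the
published IP-risk ORs are causally transportable and log-linear over the
rescaling range; it is a consistency check, not a formal instrumental-
variable estimator (no Wald-ratio/IVW machinery, no MR-Egger pleiotropy
test). DerSimonian–Laird Wald intervals run slightly below nominal coverage
(~94% at I² ≈ 55%), a well-documented property of the estimator rather than
an implementation artefact.
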