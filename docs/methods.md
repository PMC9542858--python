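# Methods

## The model

A species sensitivity distribution (SSD) treats the acute effect
concentration of a chemical as a random variable across species. We fit
the log-normal form: if `x_s` is the log10 effect concentration
(µg/L) of species `s`, the SSD is Normal(mean, SD) on the log10 scale,
with the mean estimated by the arithmetic average and the SD by the
sample SD with the n−1 denominator. (The denominator matters: it
propagates into every SD ratio and HC5 downstream, so it is fixed here
rather than left to convention.)

The hazardous concentration for 5% of species is the plug-in 5th
percentile,

    HC5 = mean − 1.645 × SD        (log10 µg/L)

using the rounded constant 1.645 rather than the exact quantile
1.64485…, so that reported HC5 values agree digit-for-digit with the
standard formula as used in regulatory practice; `hcx` generalizes to
any fraction with the exact quantile. No sample-size-dependent
extrapolation factors (Aldenberg–Jaworska tolerance limits) and no
HC5 confidence limits are computed: the comparison is between plug-in
point estimates. Alternative SSD shapes (log-logistic, Burr III) are
out of scope.

## Curation rules and their edge cases

* **Effect measures.** Acute EC50/LC50 only (the allowed set is a
  config field). Chronic records are removed regardless of measure.
* **Solubility cap.** A record is removed only when its concentration
  *strictly exceeds* 5× the chemical's water solubility: the boundary
  value is retained. Records with unknown solubility are retained and
  tallied separately in the audit trail, since solubility coverage in
  real exports is incomplete and silently dropping those records would
  bias chemicals with poor physicochemical annotation. The cap is
  applied at the record level, before aggregation, so a species'
  geometric mean never includes an implausible concentration but the
  species survives if any of its records do.
* **Amphibians** are excluded entirely; saltwater amphibian data do not
  exist in the target databases, so they could never pair.
* **Aggregation.** Replicate tests of one (chemical, habitat, species)
  collapse to the geometric mean (arithmetic mean on the log10 scale).
  Duplicate rows are deliberately *not* deduplicated first: repeated
  tests are legitimate replicates and belong in the mean.
* **Eligibility.** Both habitats independently need ≥ 5 species from
  ≥ 2 of {algae, invertebrates, fish}; the taxa requirement is
  enforced per SSD, not per chemical. A species occurring in both
  habitats counts once in each.
* **Normality screen.** Shapiro–Wilk per fitted SSD; Holm's step-down
  adjustment over the *whole family* of 2 × (candidate chemicals)
  tests at α = 0.05 (a per-habitat family is available as a config
  switch). The screen runs after eligibility, so the family is exactly
  the candidate set. A chemical failing in either habitat is excluded
  whole — the comparison needs both habitats anyway.

Filter order between the record-level criteria is immaterial (each is a
row-local predicate); the pipeline fixes the order effect-measure →
solubility → amphibian → aggregate → eligibility → fit → screen purely
so audit counts are reproducible.

## SMA regression

Both axes of every parameter comparison are estimates, so ordinary
least squares would attenuate the slope; we use standardized major
axis (model II) regression:

    b = sign(r) · SD(y)/SD(x),   a = mean(y) − b · mean(x)

with the F-based slope interval `b·(√(B+1) ± √B)`,
`B = F(1−α; 1, n−2)·(1−r²)/(n−2)`, and a t interval for the elevation
with `SE(a)² = Var(y − b·x)/n + mean(x)²·Var(b)`,
`Var(b) = b²(1−r²)/(n−2)`. The elevation-interval form is validated
against a case-resampling percentile bootstrap (2000 replicates) in the
acceptance suite; a simulation there also confirms nominal 95% slope
coverage (observed 93–97% over 1000 bivariate-normal datasets of
n = 50). The default orientation puts saltwater on x and freshwater on
y; both orientations are written to `sma_results.csv` (SMA reciprocity
means the slope simply inverts). The SD comparison is run on log10(SD)
so all three parameter comparisons are log-log. Major-axis and ranged
variants, and multi-group common-slope tests, are not implemented.

## Ratio analyses

Fold ratios are reported in concentration units: `10^(Δ log10)` for
means and HC5, the direct quotient for SDs (which are already log10-
scale quantities). Range membership (0.1–10 for means/HC5, 0.25–4 for
SDs) uses closed intervals; these ranges are reciprocal-symmetric, so
the summaries are invariant to swapping the habitat labels. The
operational logic linking the two ranges: with equal SDs a 10-fold mean
difference is exactly a 10-fold HC5 difference, and a 4-fold SD ratio
is a 0.6 log10-unit difference, which Eq.-of-HC5 arithmetic turns into
roughly one order of magnitude at the 5th percentile.

The species-number analysis correlates the *lower* of the two species
counts with |log10 ratio| (Pearson, two-sided p from the t transform).
The mode-of-action analysis runs a one-sample t-test of the log10
saltwater-to-freshwater ratios against 0 within each label {narcotic,
specific, unclassified}; no multiplicity correction is applied across
the three groups. Both are repeated in an `n_min ≥ 10` stratum.

## The synthetic-data generator

The generator emulates the statistical structure of a curated acute
ecotoxicity database, not its taxonomy: per chemical, the pair of true
SSD means is bivariate normal on log10 µg/L (defaults: location 2.5,
scale 1.2 in both habitats, ρ = 0.95) and the pair of true SSD SDs is
bivariate lognormal (median 0.6 log10 units, spread 0.15 on log10(SD),
ρ = 0.5). The high mean-correlation and weaker SD-correlation defaults
mirror the qualitative contrast observed in real freshwater/saltwater
corpora (tight mean coupling, loose SD coupling); equal marginal scales
make the corpus-level true SMA slope exactly 1 for means and SDs, which
is what the recovery tests exploit. Defaults of 104 chemicals, species
pools of 854 freshwater / 296 saltwater species, per-chemical species
counts uniform on 5–60 (freshwater) and 5–25 (saltwater), and
mode-of-action weights 20/39/45 over 104 reproduce the scale of a
realistic curated corpus. Each species receives 1 + Poisson(0.5) test
records with Normal(0, 0.2) within-species log10 noise; solubility is
set 8 log10 units above the SSD mean so that no clean record ever
trips the solubility cap by chance.

Planted violations are appended as *extra* rows or *extra* chemicals
(never replacing clean data), with their row ids and chemical ids
recorded in the ground truth, so "the filters removed exactly the
planted set" is a well-defined assertion. Non-normal chemicals draw
sensitivities from a standardized exponential (mean 0, SD 1, strong
right skew) at 50 species per habitat, where the Shapiro–Wilk test has
essentially full power even after Holm adjustment.

Each chemical consumes its own counter-based substream
(`SeedSequence(seed, spawn_key=(index,))`): enlarging the corpus never
perturbs chemicals already drawn, and identical config + seed yields a
byte-identical record CSV.

What the generator does **not** emulate: real species lists and
chemical inventories, non-normal-but-retained sensitivity shapes,
unit heterogeneity, censored records ("greater than" concentrations),
correlated taxonomic composition across habitats, and solubility that
actually binds for hydrophobic chemicals. Passing tests therefore
demonstrate the *pipeline's* correctness under the stated laws, not
that real freshwater/saltwater SSDs agree.

## Numerical and design notes

* Attenuation under unequal sampling noise: with the default
  asymmetric species counts (saltwater SSDs average ~3× fewer species)
  the saltwater axis carries more estimation variance, which inflates
  SD(x) and pulls the SMA mean-slope a few percent below the true
  slope — visible in the worked example (0.93 vs. a true 1). The
  end-to-end recovery test uses 100 species in both habitats so both
  axes carry equal noise and the slope interval covers the truth; at
  desk scale that run uses 500 chemicals, large enough that the
  slope's Monte-Carlo error is well inside the interval.
* The bootstrap-vs-analytic interval gate allows endpoint differences
  up to half the interval width (one fifth on average over 100
  datasets): percentile bootstrap intervals at n = 15–40 differ from
  the F/t forms by a small-sample shift of that order, on top of
  Monte-Carlo noise from 2000 replicates.
* Degenerate inputs fail loudly: < 2 species or zero variance in a fit,
  zero variance on either SMA axis, constant ratios in the correlation
  or t-test, and a fraction outside (0, 1) in `hcx` all raise typed
  errors rather than returning NaN.
* Ties and boundaries: the solubility cap keeps the boundary record;
  range membership is closed; Holm uses a stable sort so tied p-values
  adjust identically regardless of input order.
* Empty inputs are legal throughout the pipeline (header-only outputs,
  zero-count audit stages); downstream statistics raise
  insufficient-data errors instead of crashing when a stratum is empty.

## Problem sizes

The default test suite and the reproduction script run on synthetic
corpora of 25–500 chemicals (up to ~150,000 records in the recovery
test), 1000-replicate coverage simulations, and 100 × 2000-replicate
bootstrap comparisons; these sizes give Monte-Carlo error comfortably
below every asserted tolerance.
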