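# Methods

## Model and assumptions

The simulator projects annual hatchling cohorts of a theoretical neritic
loggerhead assemblage through three survival stages. The survivorship
recurrence is

    p(0) = A0S
    p(a) = p(a−1) · OS   for 1 ≤ a ≤ NR−1      (oceanic stage)
    p(a) = p(a−1) · NS   for a ≥ NR            (neritic; first NS in the NR year)

with all rates fixed across years: A0S = 0.4, OS = 0.713, NS = 0.854,
maximum age 77. These are stable-population values; no density dependence,
no growth trend, no interannual survival variability. An equivalent closed
form for the equilibrium neritic total of one sex,
`H · A0S · OS^(NR−1) · Σ_{k=1..78−NR} NS^k`, is kept as an internal oracle:
note the NS exponent runs from 1 (the recruitment year itself) through
78−NR, which is what the recurrence implies. Writing the final-age survival
as NS^(77−NR) would drop the recruitment-year application of NS and fails
to reproduce the baseline total.

Every member of a cohort recruits at the cohort's NR in the same year — an
intentionally coarse "grand gesture" assumption that maximizes cohort
resonance and is the point of the exercise, not a realism claim.

Counts are integerized by a single floor per (cohort, age, sex) cell after
all double-precision multiplication. Floor (not round) is the convention
throughout: it reproduces the baseline assemblage total (288,232), the
female lookup tables (e.g. 2,134,687 = ⌊0.825 · 2,587,500⌋) and the
sinusoid production extrema (1,725,000; 3,449,942), where rounding does
not.

242 cohorts are projected; the first 77 are burn-in so that every reported
year (1856–2020, 165 years) carries a full 0–77 age structure. Burn-in
cohorts predate the driver series, so they take the schedule's default
NR = 10 and, under M5, the fixed mean production. Sinusoid order `o`
corresponds to cohort year 1855 + o.

## Climate driver

The monthly index is averaged over April–November (nesting and hatching
season); years missing any season month are dropped, not imputed (the real
record is complete, so this only affects synthetic edge cases). Annual
means are z-scored against the grand mean and grand standard deviation of
a reference span — the sample (n−1) SD convention, matching the default of
the spreadsheet tools this analysis style originates in. Each cohort's
window statistic is the sum of z over its ages 0–7; windows truncated by
either end of the series are dropped and those cohorts fall back to the
default NR (they cannot reach the neritic stage inside the reported span
anyway).

The five NR bands are exact 20-percentile bands, so they are implemented
as rank quintiles: sums sorted ascending, ties broken by earlier cohort
year, cut into five contiguous groups whose sizes differ by at most one.
This avoids choosing among percentile-interpolation conventions and makes
the assignment deterministic and monotone in the window sum.

## Sex-ratio variants

M1/M2 fix the split at 2,199,375 F / 388,125 M (0.85 female). M3/M4 take
the female count from lookup tables keyed by NR spanning ±5% / ±10% around
0.85 (males by subtraction); every entry equals ⌊proportion · 2,587,500⌋.
One printed M4 entry (NR = 8) is internally inconsistent with that rule by
a digit transposition and is used here as 1,940,625 = ⌊0.75 · 2,587,500⌋.
M5 applies the M4 fractions to its sinusoid-driven variable total. Cooler
phases (low NR) carry the lower female proportions, per the historical
soil-temperature association that motivates the coupling.

## Age-group summaries

Neritic animals are grouped NR–19, 20–29, 30–77 per calendar year; the
first group's lower bound is each cohort's own NR because pre-NR ages are
oceanic by construction. Printed percentage breakdowns are produced with
largest-remainder rounding so shares sum to 100 — the baseline shares
79.38/16.38/4.24 print as 80/16/4 (nearest-integer rounding of each share
independently would give 79/16/4, summing to 99).

Because counts are floored per cell, a group's realised female proportion
can deviate from the exact mixture of cohort input fractions by up to
roughly (number of cells)/(group total) — about 10⁻⁴ for the full
assemblage and up to ~10⁻² for the small adult group. Tests of the mixture
bounds and of the fixed-split variants use this integerization tolerance;
the underlying real-valued proportions obey the bounds exactly.

## Sexing and growth

Sex classification uses strict inequalities for female and male and an
inclusive band for undetermined, so values exactly at a threshold are
undetermined. Thresholds are per assay era: 200/300 pg ml⁻¹ before 2004,
400/500 from 2004 (the 2019 ELISA retains the 2004+ range). Males at
≥ 75.1 cm SCLmin are flagged (log message + boolean column) because
pubescent females can show elevated testosterone; no quantitative
correction exists, so the flag never changes the label.

The growth curve SCL = 18.705 · age^0.4403 is shipped as the canonical
default; a generic log–log least-squares fitter is provided for
re-deriving coefficients from size-at-age pairs. Age-group size ceilings
are the curve evaluated at half-ages 19.5 and 29.5 — this reproduces all
six published 1-dp ceilings (69.2/83.0, 65.7/78.9, 72.6/87.2) where
integer boundary ages do not. Classification compares measured size
against the ceilings at the same 0.1 cm reported precision, so an animal
exactly at a ceiling falls in the lower group. Two related published
inconsistencies are noted and not reconciled: the curve yields ~126.6 cm
at age 77 (not the stated 110.6), and the +5% group-2 floor is printed
0.3 cm below that variant's group-1 ceiling; the half-age construction is
used as stated above.

## Statistics

Correlations are scipy's Pearson/Spearman with two-sided p-values
(t-approximation, n−2 df; midranks for ties). The chi-square comparison of
observed age structure against the baseline model appends the expected
distribution (baseline shares scaled to the mean observed total) as a
fourth column of a 3×4 contingency table, giving df = 6. Quartiles use the
linear-interpolation (type-7) convention. The survey-block trend tests
correlate each age group's observed female proportion with sample size
(Pearson) and with the ordinal growth-equation code and chronological
block order (Spearman); groups with fewer than three blocks are skipped.

## Synthetic data

The driver generator is one sinusoid (default period 65 y, amplitude
0.2 °C) plus monthly AR(1) noise (φ = 0.5, innovation SD 0.1 °C,
stationary start) — enough to mimic a multidecadal signal under unsmoothed
monthly noise, with no attempt to match the real index's full spectrum.
The capture generator draws each animal's true sex Bernoulli(female
fraction), size lognormal (median 68 cm, σ_log 0.14, clipped to
45–110 cm), and testosterone lognormal per sex. Default hormone medians
(50 pg ml⁻¹ female, 2000 male) and spreads (σ_log 0.6 and 0.5) represent
clearly separated sexes, consistent with thresholds that were chosen
because they discriminate reliably; classifier misclassification under the
defaults is below half a percent. Overlap is a configuration dial: the
test suite uses a wider-overlap configuration (medians 120/1000, σ_log
1.2) to emulate a survey-like ~5% undetermined rate, checked against the
lognormal-CDF analytic value.

What passing these tests shows — and does not. The synthetic driver
demonstrates the resonance mechanism (adult abundance vs. female
proportion r ≤ −0.9; male:female ratio vs. female abundance r ≥ +0.9) and
the recovery tests show the classifier is unbiased when the sexes'
hormone distributions are separated. They do not validate survival values
against field data, nor the assumption that all cohort members recruit
simultaneously, nor behaviour under assay distributions with heavy
overlap.

## Problem sizes and determinism

The full projection (242 cohorts × 78 ages × 2 sexes) runs in well under a
second, so all simulator tests use the full configuration. The classifier
recovery test uses 500 seeded replicates of 2330 captures. The simulator
has no stochastic elements at all; every stochastic component takes an
explicit seed fanned out to per-component substreams, and regeneration is
byte-identical under a fixed seed.

## Known limitations

- NR quintiles are computed over cohorts with complete 8-year windows
  only; whether burn-in cohorts entered the original percentile
  computation is unknowable from the published description.
- The empirical capture data are available only on request, so the
  observed correlation coefficients and chi-square statistic of the
  original survey are structural templates for synthetic tests, not
  reproduction targets.
- Reproducing the climate-driven assemblage extrema requires the real
  NOAA AMO file (user-supplied path); index product revisions can shift
  quintile boundaries and hence those extrema.
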