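# Methods

## The instrument and its scores

The Odor Hedonic Profile asks a respondent to rate 14 everyday odor
situations on a dashed line from −9 ("extremely unpleasant") through 0
("neutral") to +9 ("extremely pleasant").  Dashes mark whole numbers;
the space between two dashes counts as half a number, so the response
grid is the 37 half-integers in [−9, +9].  A mark in the space between
the neutral dash and the first dash of a valence is read as ±0.5: the
grid admits it, and only with it do valid marks map one-to-one onto the
37 legal scores (a bare cross on the neutral dash is the neutral
response).  Half-integers are dyadic rationals, exactly representable in
binary floating point, so all score identities below hold bit-exactly
without a rational-number type.

Per respondent, with item scores `x₁..x₁₄`:

| quantity | definition | range |
|---|---|---|
| `T⁺` | Σ max(xᵢ, 0) | [0, 126] |
| `T⁻` | Σ min(xᵢ, 0) | [−126, 0] |
| `TS` | Σ \|xᵢ\| = T⁺ − T⁻ | [0, 126] |
| `Δ`  | Σ xᵢ = T⁺ + T⁻ | [−126, 126] |

A response set is valid only when all 14 items are present and on the
grid; there is no imputation — the TS range presumes 14 answers, and a
partial questionnaire is a data-collection problem, not a scoring one.

## Cohort-normed banding and profiles

Each total is banded against a reference cohort's mean ± SD.  "High"
and "low" are strict inequalities (`value > mean + SD`,
`value < mean − SD`); the closed interval between the cutoffs is
"medium", so a value exactly on a cutoff is medium.  For `T⁻` the same
rule is applied on the negated axis: "high T⁻" means *more negative*
(the respondent rated the unpleasant items strongly).  The sample
(n−1) SD is the default; a population-SD switch exists because the
convention is rarely reported with published summary statistics, and
with the reference cohort's printed means and SDs both conventions give
the same cutoffs to two decimals.

Five of the 27 band triples are named — liberal (high, high, high),
conservative (low, low, low), neutral (medium³), positive alliesthesia
(medium TS, high T⁺, low T⁻), negative alliesthesia (medium TS, low
T⁺, high T⁻) — and the remaining 22 are "other".  "Other" is defined
as the complement, not enumerated, because the named patterns are the
only ones with a behavioural interpretation.  Norms are derived from
the whole cohort by default (per-sex norming is available behind a
flag), and threshold files carry provenance because a profile is only
meaningful relative to the reference group that produced the norms.

## Statistical battery

* **Spearman correlations** use mid-ranks for ties; the two-sided
  p-value comes from the t approximation
  `t = ρ√((n−2)/(1−ρ²))` with n−2 df (an exact permutation p is
  available for small n).
* **Sex comparisons** use the pooled-variance (Student) independent
  two-sample t-test; Welch is available behind a flag since equal
  variances are an assumption, not a finding.
* **Bonferroni adjustment** is applied within each reported battery —
  42 item-total correlations, 18 sex comparisons (14 items + TS, T⁺,
  T⁻, Δ), 18 self-smell correlations — with the family size explicit
  and overridable.  Adjusted p-values never decrease and cap at 1;
  significance is declared at adjusted p < 0.05.
* **Item screening** (pre-test): an item is dropped when Shapiro–Wilk
  rejects normality of its scores at α = 0.05, or when more than two of
  30 respondents (proportion > 2/30, configurable) report never having
  experienced the situation.  The count-based cutoff is the
  instrument's original rule; a literal 5%-proportion rule would
  exclude an item at exactly 2/30, which the original screening
  tolerated.

## Synthetic cohort generator

The generator exists so every pipeline stage is testable without
collecting data.  Each item score is drawn from a normal distribution
truncated to [−9, 9] and rounded to the nearest half-step (ties away
from zero).  Defaults:

* **Item means** — the published per-sex means of the 14 items; the
  pooled means are their unweighted average (the reference cohort was
  balanced 50/50).
* **Item SDs** — a linear spread model `sd = a − b·|mean|`, clipped to
  [0.8, 6.0], anchored so the strongest items (|mean| ≈ 7.2) get
  sd ≈ 2.0 and the weakest (|mean| ≈ 1.7) get sd ≈ 5.6, the two
  published extremes.  This reproduces the instrument's signature
  across-item anticorrelation between |mean| and SD without assuming
  unpublished per-item values; per-item overrides are accepted.
* **Self-rated smell** — a Gaussian-copula rank blend with TS at a
  target Spearman ρ of 0.23 (the published association), mapped to a
  mildly positive half-step scale (location 3, scale 3).
* **Demographics** — sex assigned by a deterministic count from the sex
  ratio (default 0.5) and shuffled; age normal(22.9, 1.4) clipped to
  19–26, the reference cohort's frame.

Everything is driven by one `numpy` Generator seeded from the cohort
specification, so identical specifications give byte-identical cohorts.

### Planted profiles

For recovery experiments, `plant_profile` shifts a model set so sampled
respondents express a named profile at a given `intensity` (1 =
unchanged).  Mean magnitudes are scaled per valence group — never
flipping sign, capped at 9 — and all SDs are divided by the intensity,
because a profile is a *consistent* response style: liberal scales both
valences up, conservative down.  For the alliesthesia profiles the
enhanced valence scales up by the intensity and the opposite valence is
shrunk by the factor, found numerically (Brent's method on the exact
truncated-and-quantized score pmf), that keeps the expected TS at the
base cohort's expected TS — alliesthesia shifts the hedonic balance,
not the total hedonic output, which is exactly what places TS mid-band
while T⁺ and T⁻ move apart.  Neutral planting rescales both valence
groups so the expected T⁺ and T⁻ sit at the base cohort's expected
totals, compensating for the tighter planted spread.  The recovery
experiment used in validation plants 40 respondents per label at
intensity 5 and classifies them against norms from an unplanted
200-respondent reference cohort.

### What the generator does and does not emulate

Items are sampled independently within a respondent.  Real cohorts show
correlated response styles across items — that correlation is precisely
what the profiles measure — so the unplanted generator produces
narrower between-respondent spread of the totals than a real cohort
(simulated TS SD ≈ 9 vs the published 14.6), and a simulated cohort's
mean TS (≈ 65) sits below the published 76.1: with independent items,
truncation at ±9 and the anchored spread model, Σ E|xᵢ| is smaller than
the real cohort's.  Passing distributional tests therefore shows that
the pipeline recovers the structure the generator encodes (the
|mean|–SD anticorrelation, the sex direction in T⁻, planted classes) —
not that the generator reproduces every published cohort-level moment.
Norms derived from synthetic cohorts are accordingly tighter than the
published ones; analyses of real data should derive norms from real
cohorts or load the published ones from a thresholds file.

## Numerical choices and degenerate inputs

* Scores are validated against the half-step grid exactly
  (`2x == round(2x)`), not with a tolerance: the grid is the data model.
* A cohort of fewer than 2 respondents has no SD and is rejected;
  an all-identical cohort yields sd = 0 and hi = lo = mean (every
  respondent then bands "medium" on that axis).
* Constant vectors make rank correlations undefined and raise a
  dedicated error rather than returning NaN.
* Threshold symmetry (`hi + lo = 2·mean`) is exact because cutoffs are
  stored as mean and SD and derived as properties, not stored twice.
* Truncated-normal sampling uses rejection (acceptance ≥ 0.5 for all
  default models); rounding ties go away from zero so ±9 remain
  reachable from their half-open outer cells.
* The recovery experiment and replicate counts (200 cohorts of n = 100
  for distributional structure; 200 reference + 200 planted respondents
  for recovery) are sized so each check runs in seconds while leaving
  the Monte-Carlo margins far from the asserted bounds.

## Known limitations

* No within-respondent item correlation in the unplanted generator (see
  above); planted classes reintroduce it only as a mean shift.
* The instrument's qualitative item-selection criteria (sui generis
  odor, prominence between near-duplicate items) are editorial and out
  of scope; only the two quantitative screening rules are implemented.
* Test–retest machinery is out of scope: the construct is state-like
  and the original instrument was not retested.
* Smoking habits are carried nowhere: they were collected historically
  but never analyzed.
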