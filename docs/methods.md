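# Methods

## Problem setting

Spontaneous-report databases collect suspected drug–event pairs with no
denominator of exposed patients, so safety screening rests on
*disproportionality*: is event *e* reported relatively more often with the
target drug than with everything else? The package implements the four
standard screening statistics (ROR, PRR, the BCPNN information component, and
the MGPS empirical-Bayes ratio in its shrinkage-free reduction), the report
preprocessing they presuppose (deduplication, drug matching, MedDRA-style
PT→SOC standardization), and the descriptive analyses that usually accompany
them (demographic tables, sex/age/reporter subgroups, a sex-difference
volcano statistic, time-to-onset binning). Because real quarterly extracts
and the licensed MedDRA dictionary cannot be bundled, a synthetic generator
emits structurally faithful data with known ground truth; all statistical
guarantees quoted for the package are statements about that generator.

## Counting unit and contingency tables

The unit of the 2×2 tables is the **report–event pair**: a report
contributes one pair per distinct preferred term (PT) it mentions. For event
*e*, `a` counts target-drug reports mentioning *e*, `b` the remaining
target-drug pairs, `c`/`d` the same for non-target reports, so
N = a+b+c+d equals the total pair count of the corpus — constant across
events and larger than the number of reports. This matches how REAC lists
each PT once per report version and makes the `a ≥ 3` criteria report
counts. At SOC level a report counts once per SOC by default (several PTs of
one report sharing a SOC do not double-count; `soc_counting="per_pair"`
switches this off).

## Estimators and numerical conventions

Formulas as in the README table. Conventions:

- **Zero cells.** When any of b, c, d is zero, δ = 0.5 is added to all four
  cells (Haldane–Anscombe) before points and bounds. a = 0 is never rescued:
  the row is reported with NaN metrics (EBGM 0), all flags false — explicit,
  never silently dropped.
- **Formula modes.** `standard` uses the observed/expected numerator a·N in
  IC and EBGM and a normal-theory IC025 on the log₂ scale,
  IC025 = IC − 1.96·√(1/a+1/b+1/c+1/d)/ln 2. `paper-literal` reproduces a
  published variant verbatim: the IC/EBGM numerators drop the factor `a`
  (giving log₂(N/((a+c)(a+b))) and N/((a+c)(a+b))) and IC025 is
  exp(ln IC − 1.96·√·), which exists only for IC > 0; rows where it does not
  are marked not-evaluable for the bound and cannot flag. The literal mode
  exists so the discrepancy between the two readings is inspectable on the
  same data; every output row records the mode that produced it.
- **MGPS reduction.** The EBGM reported is the relative reporting ratio
  (observed/expected) paired with the closed-form one-sided 95% bound
  EBGM·exp(−1.64·√(1/a+1/b+1/c+1/d)). The full gamma-Poisson mixture fit
  (hyperparameter estimation, posterior shrinkage) is deliberately out of
  scope; with the table sizes the screen operates on, shrinkage would mainly
  affect small-`a` rows that the criteria already gate.
- **Monotonicity caveat.** ROR and PRR are strictly increasing in `a` with
  b, c, d fixed. The observed/expected ratio (IC, EBGM) is only monotone
  when the event is rare relative to both margins
  (1/a > 1/(a+b) + 1/(a+c)); at `a` comparable to the margins it can dip
  over an integer step. The property tests assert monotonicity in the
  rare-event regime the screen operates in.

## Deduplication

Submissions are grouped by case key; the version with the latest receipt
date survives, ties broken by the larger report id. Partial receipt dates
(YYYYMM, YYYY) are padded to their earliest day for ordering only;
unparseable dates sort first, so any dated version beats them. The operation
is idempotent and every discard is logged with a reason. Grouping by case
key alone subsumes report-id versioning and is directly checkable against
the generator ledger's intended survivors.

## Demographic normalization

Ages convert to years from units {year, decade, month, week, day}; weights
to kg from {kg, lbs, g}. Unknown units make the value unusable (missing)
rather than guessing. Age groups follow the printed labels `<18, 18–64.9,
65–85, >85`, i.e. bins [0,18), [18,65), [65,85], (85,∞) — 65 and 85 both
fall in the third bin; weight groups [0,50), [50,100], (100,∞). Outcome
codes map DE→death, LT→life-threatening, HO→hospitalization, DS→disability,
anything else →other, counted once per category per report. Percentages in
all emitted tables are count/total rounded half-up to one decimal.

## Sex-difference volcano

Among target-drug reports of known sex, each PT with ≥ 3 reports in at
least one sex gets the 2×2 (female, male) × (PT present, PT absent), an odds
ratio (δ = 0.5 when any cell is zero), a two-sided Fisher exact p-value, and
x = log₂(OR). Labels (female/male) are assigned at unadjusted p < 0.05 by
the sign of x — the unadjusted scale matches the familiar −log₁₀ p volcano
axis — and a Benjamini–Hochberg column is always emitted alongside so the
multiplicity-aware reading is available. The within-exposed contrast
(event profile conditional on exposure) is the default because it compares
the ADE spectra of treated women and men directly; the alternative — the
ratio of sex-stratified RORs against the background, with a normal-theory
p-value from the summed log-ROR variances — is available via
`contrast="ror_ratio"`. Both are implemented; neither is claimed to be the
one used in any particular published figure.

## Time to onset

Onset = event date − earliest therapy-start date of a target-drug entry,
requiring full YYYYMMDD precision on both; partial dates, missing dates and
negative differences are excluded and counted by reason. Bins (days):
[0–30], [31–60], [61–90], [91–180], [181–360], >360; day 0 and day 30 both
fall in the first bin. The two intermediate bins are configurable
(`onset_bin_edges`). The event-date anchor is the default; receipt date is a
switch (`onset_anchor="fda_dt"`) because extracts do not always carry event
dates.

## The synthetic generator

One configuration describes a reporting universe: `n_background_reports`
drawn over a 12-drug background universe and `n_target_reports` for the
target drug (brand synonyms rotated through DRUG, a fraction with dose
suffixes, a small fraction with blank names but a filled active-ingredient
field, and ~30% combination regimens with a second drug row).

**Event model.** Each report mentions PT *j* independently with probability
p_j = mean_pts_per_report · q_j, where q is the baseline multinomial event
profile (so background pair shares converge to q). An injected effect θ acts
on the *pair-level reporting odds*: with m = Σp the expected pairs per
report, background odds are w_j = p_j/(m−p_j), and target-report inclusion
probabilities are solved by fixed-point iteration so that the target-arm
odds are exactly θ·w_j under the perturbed margin m′. The pair-based ROR of
the downstream 2×2 therefore estimates θ directly — measured over 200
replicates at 200,000/2,000 reports the estimator is unbiased to within
~1% with ~95% CI coverage. Two consequences are built in rather than bugs:
non-injected PTs drift slightly below ROR 1 when effects are injected (pair
shares sum to one on both arms — the competition/masking effect of real
databases), and pooling sexes when *other* PTs carry sex-specific
multipliers mixes two margins, so a pooled ROR can deviate from θ by a
percent-level non-collapsibility term. Sex-specific multipliers rescale θ
within the stated sex before solving, which makes the volcano ground truth
explicit.

**Everything else.** Strata (sex, age group, weight, reporter, country,
outcome) are categorical draws with defaults matching a published
demographic table of a 1,632-report corpus; missingness is
missing-completely-at-random per field with defaults mirroring that table
(weight 81.1% missing, age 49.6%, sex 7%, reporter 24.8%) and event/start
dates 50% each so that roughly a quarter of target reports carry a complete
onset — real spontaneous-report missingness may be informative, which this
deliberately does not model. Onset days are exponential with mean 27.7 days
by default, chosen so that P(onset ≤ 30 d) ≈ 66%; dates are YYYYMMDD with a
configurable fraction degraded to YYYYMM/YYYY to exercise partial-date
handling. Duplicates: each case is, with probability `duplicate_rate`
(default 0.05), emitted a second time with a distinct report id and an
earlier receipt date — the only duplicate dialect generated, matching the
rule the dedup stage resolves; the ledger records every group and its
intended survivor. Identical (config, seed) reproduces byte-identical
files; report ids are int64 in memory and plain digits in the
"$"-delimited files.

**What passing tests do and do not show.** The generator validates the
pipeline's arithmetic, bookkeeping and statistical calibration under a
clean, known model. It does not model free-text drug-name noise, informative
missingness, reporting cascades, case-version demographic conflicts, or
secular reporting trends, so green tests are not evidence about those
failure modes in real extracts.

## Problem sizes and seeds used by the shipped checks

Effect recovery: θ ∈ {2, 8, 16} on three designated PTs at baseline
probability 0.005, 200,000 background/2,000 target reports, 200 seeds
(suite) or 40 seeds (acceptance script). Null calibration: 500 PTs,
100,000/4,000 reports, 6 pooled seeds (suite) / 3 (script); the ROR flag
rate and volcano label rate stay under the 7.5% bound (measured ~2–4%).
Chi-square uniformity of the null contingency tables is checked at one
fixed seed without Yates correction (Kolmogorov–Smirnov α = 0.01).
Formula-oracle equivalence uses 10,000 random tables with cells up to 10⁵
against an independent scalar recomputation at relative error 10⁻¹⁰. These
sizes were chosen as the smallest at which the stochastic assertions are
stable across seeds.

## Known limitations

- No gamma-Poisson MGPS fit and no MCMC BCPNN posterior; the closed-form
  bounds above are the implemented, documented behavior.
- No multiple-comparison correction in the disproportionality screen (by
  design; the volcano emits BH alongside).
- Background = all non-target reports in the loaded window; no masking-bias
  correction, no drug–drug interaction tables.
- The exclusion of "incomplete or ambiguous" reports in published analyses
  has no recoverable rule; the pipeline excludes only reports with no PT
  (and, optionally, outside the receipt-date window), counting everything it
  drops.
- PT→SOC mapping is flat (no HLT/HLGT/SMQ levels); the map is always
  user-supplied or generator-emitted.
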