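# Methods

venuescope turns a review-platform business extract — a venue table, a
review table (venue id + date), and whatever externally verified facts
exist — into surveillance quantities: when venues opened, which are still
open, how fast the category is growing, and where it clusters.  This note
records the models, the conventions, the synthetic-data design, and the
numerical choices, in that order.

## Calendar-month arithmetic

All derived statistics are denominated in calendar months:
`months_between(a, b) = (b.year - a.year) * 12 + (b.month - a.month)`,
day-of-month ignored.  Two dates in the same month are 0 months apart;
the difference is additive and antisymmetric.  The alternative (30-day
bins) was rejected because the calendar convention makes "reviewed in the
snapshot month" a recency of exactly 0 and lets per-year mean lags arise
as averages of small integers.  The 6-month closure window is likewise 6
calendar months, not 183 days.

Percentages are rounded half-up to one decimal everywhere
(`round_half_up`); this single rule reproduces every ratio the package
prints from its underlying integer counts.

## Opening-date model (correction table)

For the calibration cohort — venues with a verified opening date on or
after the platform launch *and* at least one review — compute the lag
`months_between(verified_opening, first_review)` and average it per
opening year.  That per-year table of (n, mean lag) is the correction
table.  A venue's opening is then predicted as

    predicted_opening = first_review − round_half_up(mean_lag_of_year)

with the factor keyed by the **first-review year**, because the true
opening year is unknown at prediction time.  The two keys coincide
whenever the lag is under ~12 months, which is exactly the recent,
high-adoption regime where the method is reliable; predictions whose
first review predates the cutoff year (default 2010, configurable) are
labelled `pre-cutoff` rather than suppressed.

Fallbacks: a calibration year with no venues keeps an explicit empty row;
at prediction time the nearest *earlier* year's mean is used (backward
fallback is conservative — historical lags are larger), and when no
earlier fitted year exists the nearest later one is used, the only
defined direction.  Verified-but-unreviewed venues are excluded with a
warning.  The package deliberately reports no confidence interval on a
predicted date: with yearly-mean calibration on a few dozen venues any
interval would be decoration.

## Closure model (recency rule) and evaluation

A venue is called **closed** when `months_between(last_review, snapshot)
>= threshold` (default 6).  The boundary is inclusive — "no review in the
past 6 months" is read as ≥ 6 — and the convention is configurable.
Venues with zero reviews satisfy the rule vacuously and are called closed
by default (`reviewless_closed=False` excludes them instead).

Evaluation is a 2×2 contingency table with *closed* as the positive
class: sensitivity = tp/(tp+fn) over truly closed venues, specificity =
tn/(tn+fp) over truly open ones, each a half-up one-decimal percent; a
zero denominator yields an absent value with a warning, never an
exception.  `threshold_sweep` generalises the fixed rule: as the
threshold grows, sensitivity is nonincreasing and specificity
nondecreasing (the rule is a threshold on a scalar), which the tests
assert as a property.

The platform's own crowd-sourced closed-flag is evaluated the same way as
a baseline.  Crowd flags of this kind empirically almost never mark an
open venue closed, so the synthetic generator gives the flag perfect
specificity *by construction* and imperfect sensitivity; the evaluator
has to rediscover both.

## Trend summaries

Reviews bucket into calendar months per category, zero-count months kept,
so the series is contiguous.  Window means use half-open windows
`[start, end)` — half-open windows compose without double counting; the
convention is documented because "from August to August" is otherwise
ambiguous.  Growth is summarised as cumulative fold-change
(cumulative count through t1 over through t0) and monthly fold-change
(count(m1)/count(m0)), both to one decimal; a zero baseline yields an
absent value with a warning.  A control category on the same platform
(with its own opening and review rates) normalises for platform-wide
growth: the comparison of fold-changes, not either number alone, carries
the signal.

## Geographic density

Zips come from the explicit field when valid, else the last standalone
5-digit token of the address; unresolvable venues pool under `unknown` so
zip counts always conserve the venue total.  Region rollups are driven by
an editable region→zip table, never hard-coded logic; the shipped NYC
defaults use standard borough prefixes (100–102 Manhattan, 103 Staten
Island, 104 Bronx, 111/113/114/116 Queens, 112 Brooklyn) plus two
neighbourhood groupings: Lower East Side = {10002, 10003, 10009} and
Astoria = {11102, 11103, 11105, 11106}.  Published UHF-style listings
sometimes misprint Astoria with Manhattan-format 100xx codes; the default
follows the borough-consistent reading.  Exports are CSV (zip, count) or
RFC 7946 GeoJSON with zip/count properties, zip-ascending for bit-stable
output; polygon geometries are optional user-supplied inputs so testing
never requires boundary data.

## Synthetic data generator

The generator exists so every stage can be tested against known truth.
Per category:

* **Openings**: per calendar year, `Poisson(opening_rate[year])` venues,
  each opening on a uniform day of that year (truncated at the snapshot).
* **Closure**: geometric months-to-closure with per-month hazard
  `closure_hazard_per_month`; closures past the snapshot are truncated to
  "still open".
* **Reviews**: a month-discretised nonhomogeneous Poisson process.  In
  month m an active venue receives `Poisson(base_rate × adoption(m) ×
  exposure(m))` reviews, where `adoption(t)` is 0 before the platform
  launch and logistic in fractional months since the adoption midpoint
  afterwards, and `exposure` prorates partial months (opening month,
  closure month, pre-launch days).  Review days are uniform within the
  admissible window, so no review precedes opening or launch, or follows
  closure or the snapshot.
* **Flag**: truly closed venues are flagged with probability
  `flag_sensitivity`; open venues never.
* **Ground truth**: every venue gets a verified status (the simulated
  truth); a verified opening date is included with a probability that may
  depend on the opening year, emulating the recency bias of manual
  verification.

Month discretisation matches the month resolution of every downstream
statistic while keeping the simulator simple; modelling review text,
ratings, reviewer identity, or spatial structure beyond categorical zip
assignment is out of scope.  All randomness flows from one integer seed
through a single `numpy` Generator in a fixed iteration order, so a seed
reproduces the dataset byte for byte.

### The "ny-like" preset

Defaults are a desk-scale mimic of a state-wide tobacco-venue extract,
not a reproduction of any real dataset: opening rates rising from 2–4
per year (2004–2008) to 36 in 2014 (~140 target venues), platform launch
2004-10-01, snapshot 2014-10-28, adoption midpoint mid-2010 with
steepness 0.06 per month, base review rate 1.2 reviews per venue-month at
full adoption, closure hazard 0.006 per month (roughly a fifth of venues
closed by the snapshot), flag sensitivity 0.77, verification probability
0.12 before 2009 rising to 0.35 from 2010 (a calibration cohort of
~40–50, recency-biased), and a flat-opening-rate control category (10 per
year, review rate 1.0) sharing the adoption curve.  No public source
states per-venue review-volume distributions; the review-rate defaults
are order-of-magnitude choices and should be treated as such.

What passing tests on this preset show — and don't: the pipeline recovers
the quantities the generator encodes (declining first-review lags,
flag operating point, growth-rate ordering, conservation laws).  Real
extracts add everything the generator omits: venues recategorised over
time, duplicate listings, reviews deleted or moderated away, non-logistic
adoption, and closure processes correlated with review volume.  Accuracy
numbers from synthetic runs therefore characterise the *method under its
own assumptions*, not expected field performance.

### The Monte-Carlo lag oracle

`expected_first_review_lag(year, config)` estimates the expected
opening-to-first-review lag by simulating the generator's exact mechanics
(default 4 000 samples), conditional on a review arriving by the
snapshot — the same conditioning a fitted correction table inherits.  The
recovery test compares fitted per-year means against this oracle within
two standard errors of the fitted mean, for year cells with n ≥ 5 over 30
replicates, requiring ≥ 90% of cells to agree.  A caution for readers
re-running it with other seeds: a 2-SE interval with a sample standard
deviation at n as small as 5 is a t-style interval with true per-cell
coverage nearer 88–94%, so the aggregate rate hovers close to the 90%
bar by construction; the packaged test is deterministic and passes.

## Degenerate inputs and numerical choices

* All-zero rates produce a valid empty dataset with a warning.
* Duplicate venue ids, missing id/name, and unparseable dates are hard
  errors naming the row; malformed zips demote to absent with a warning;
  reviews for unknown venues are retained and counted.
* Recency-mode ties break toward the smaller recency.
* An empty review set with no snapshot override is a hard error (there is
  no defensible default reference date).
* The pipeline writes nothing time-dependent, so fixed seed + config
  gives byte-identical report bundles; `summary.json` records the seed, a
  config hash, and per-stage row counts.

## Problem sizes

Tests and the acceptance script run the preset at its natural scale
(~230–260 venues, ~6–7k reviews per replicate; 30 replicates for the
recovery study; 4 000 Monte-Carlo samples per year for the lag oracle),
sizes chosen to make sampling error small relative to the tolerances
being checked.
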