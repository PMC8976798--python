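# Methods

## Scope and data model

`fracrisk` implements the epidemiological chain behind a country-specific
fracture-risk calibration: a hospital-admission line-listing is reduced to
first low-energy hip fractures, converted to age/sex-specific incidence
with exact intervals, smoothed into a continuous fracture hazard, combined
with a life-table death hazard into competing-risk fracture probabilities,
and applied to population pyramids for burden projection.  The bundled
reference aggregates come from a two-year (2017–2018) prospective survey in
15 Saudi hospitals whose catchment was estimated at 12.82% of the national
45+ population; the package also fabricates complete synthetic inputs so
the whole chain runs and is verified offline.

## Case ascertainment

A record is an eligible case if it is inside the survey window, a citizen
(configurable), at or above the minimum age (default 45), carries an
ICD-10 code starting S72.0/S72.1/S72.2, has a low-energy mechanism, and is
not pathological.  Rejections are attributed under a fixed precedence —
window → citizenship → age → ICD → trauma → pathological → duplicate — so
that each record is counted once and rejection reports are reproducible;
the underlying survey protocol does not order its exclusions, so any fixed
order is a convention.  Deduplication keeps the earliest admission per
(patient, 4-character ICD-10 site class): "same fracture site" is defined
at the S72.x granularity, the finest the eligible codes distinguish.  Ages
are used as recorded integers; the tabulation's terminal band is labelled
80–84 but treated as open-ended (80+), since admissions above 84 occur and
must be counted somewhere.

## Incidence estimation

Within a cell, events are Poisson with mean rate × population ×
observation-years; person-years are population × years (static-population
assumption, adequate for a two-year window).  Interval estimates are
Garwood exact chi-square bounds, `[χ²(α/2, 2x)/2, χ²(1−α/2, 2x+2)/2]/PY`:
they are defined at zero events (lower bound 0) and conservative (coverage
≥ nominal), which the test suite verifies by simulation.  Display rounding
follows the reference table's convention: rates ≥ 10 to the nearest
integer, rates < 10 to one decimal; unrounded values are carried
internally everywhere.  One printed bound in the reference table (women
65–69, upper bound 153) is one unit above what Garwood — or Clopper–Pearson
or Byar — yields from the printed inputs (152.48 → 152); the tests document
it as a last-digit slip in the source rather than adopt a non-standard
interval.

Between-sex rate comparisons use the exact conditional test: given the
combined count, the female count is binomial with success probability
py_f/(py_f+py_m) under rate equality; the two-sided p doubles the smaller
tail (observed value included) and is capped at 1.  On the bundled data
this yields p < 0.05 at 55–59 only, with all older bands non-significant.

## Hazard construction

Band rates are anchored at band midpoints ((start+end+1)/2 for a closed
integer band, e.g. 47.5 for 45–49) and joined by log-linear interpolation:
hip-fracture incidence is close to exponential in age, so straight lines in
log-rate are the least-structured smoother that is exact at the anchors.
Below the first midpoint the hazard is constant (assessments below 40 are
out of range anyway); above the last midpoint the slope of the final two
anchors is extrapolated and capped at a ceiling hazard (default 0.1/year)
to keep old-age extrapolation bounded.  Bands with zero events are floored
at the rate implied by half an event on the band's person-years before
taking logs (half of the smallest positive rate when person-years are
unknown).  Life-table death probabilities become hazards via
h = −ln(1−q), constant within each year of age, which reproduces ∏(1−q)
survival exactly at any grid step.  The default grid is monthly
(step 1/12 year) from age 40 to a terminal age of 105; halving the step
changes 10-year probabilities by < 10⁻⁴ on the bundled calibration.

## Probabilities under competing mortality

With piecewise-constant cause-specific hazards f (fracture) and d (death),
the probability that fracture comes first in `[a₀, a₀+T)` is summed in
closed form per cell (see README); the same decomposition gives the
death-first and event-free masses, and the three sum to one identically,
which the tests assert to 10⁻¹⁰ and cross-check against an independent
fine-grid Riemann oracle to 10⁻⁶.  Cells where f+d = 0 contribute nothing;
partial first/last cells are handled by width clipping.  The remaining
lifetime probability from age 50 is the same integral run to the terminal
age.  First-event semantics are used throughout: the fracture hazard is the
first-MOF (or first-hip) hazard and no post-event states are modelled.

MOF hazards are hip hazards multiplied by an age/sex ratio table, applied
to hazards (not probabilities) and interpolated linearly between anchors —
ratios vary slowly, and linearity preserves the constant-ratio identity
exactly.  The bundled default ratio table is synthetic and illustrative
(the published Swedish values are not reproduced here); it has the
characteristic shape — ratios of 7 (women) / 4.5 (men) at 50 declining to
1.5 / 1.4 at 85, never below 1 since MOF includes hip.  Clinical risk
factors enter only as hazard multipliers; the calibrated per-factor weights
of the web FRAX tool are proprietary and deliberately out of scope, so the
prior-fracture illustration `rr_frac = 1.8` is a conventional round value,
not a calibrated coefficient.  Assessment ages are restricted to 40–90.

## Projection

Expected annual counts apply fixed cell rates to pyramid populations,
`Σ rate × pop / 10⁵`, over bands at or above a minimum age (default 50).
Pyramid bands older than the terminal incidence band inherit its rate —
the oldest ages dominate long-horizon growth, so excluding them would bias
projections down.  A scalar rate multiplier supports simple secular-trend
scenarios; demographic scenario modelling itself is out of scope (any
pyramid CSV can be supplied).  Applying the fitted rates back to the survey
population reproduces the observed annual count (342/year) exactly, a
self-consistency identity that holds because the rates are the maximum-
likelihood cell estimates.

## Synthetic data: what it emulates, and what it does not

The generator draws eligible records per cell as Poisson counts at the
configured true rates (defaults: the bundled survey's unrounded rates and
catchment populations), with uniform ages within band (the survey reports
only banded data; no finer age structure is claimed), uniform admission
dates, and fracture-site codes at the observed 43/47/10% split.
Contaminants — high-trauma, pathological, non-citizen, under-age and
duplicate records, default 20% of the eligible volume in total — share the
eligible age/sex structure so the filters cannot succeed on demographics
alone, and every record carries a ground-truth label.  Life tables are
Gompertz, q = 1 − exp(−a·e^{b·age}).  The defaults (hazard 0.025/yr for
women and 0.035/yr for men at 70, log-slope b = 0.15/yr) emulate a
population whose mortality rises steeply after 70: the mortality log-slope
deliberately exceeds the fracture hazard's (~0.08/yr in the bundled rates)
so that the competing effect dominates at old age, which is what produces
the characteristic unimodal 10-year probability curve peaking near 70 and
remaining-lifetime hip risks of ~4.3% (women) / 2.7% (men).  Pyramids grow
geometrically per band, older bands faster (2%→5.5%/yr), emulating rapid
population ageing.

Passing tests on these synthetics demonstrate statistical correctness of
the pipeline (filters, estimators, engines), not the accuracy of any
real-world probability: real mortality, real MOF ratios and real
demography must be supplied as CSVs for substantive use.  Care-seeking,
catchment overlap between hospitals and post-fracture excess mortality are
not simulated.

## Numerical choices and edge cases

* Exact chi-square interval evaluation agrees with direct Poisson-CDF
  root-finding to < 10⁻¹² on the mean scale; the tests require 10⁻⁸.
* Probability integrals are closed-form per cell; the only discretisation
  is the hazard grid itself (monthly by default, see above).
* Zero-hazard cells use a guarded 0/0 → 0 share so f = d = 0 spans
  contribute exactly nothing.
* Empty registry input yields empty output and an all-zero rejection
  report, not an error; unparseable CSV rows are logged with their row
  number and skipped.
* Test problem sizes: the end-to-end recovery check runs 1,000 generator
  seeds at the full survey scale (~850 records each); engine cross-checks
  use 100 random hazard grids with a 10⁻⁴-year oracle step.  The
  acceptance script uses 500 seeds for the same recovery quantity.

## Known limitations

* The hazard smoother is exact at band midpoints but is not the (unpublished)
  smoothing of the web FRAX engine; interior values need not match it.
* Lifetime risks depend strongly on the terminal-age convention (105,
  capped extrapolated hazard above the last anchor).
* The conditional binomial test conditions on the total count; it is exact
  but mildly conservative, like all exact tests.
* No age-standardisation, no record linkage beyond patient-id equality,
  no ICD-9 support, no BMD or clinical-risk-factor modelling.
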