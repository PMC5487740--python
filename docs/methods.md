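# Methods

This note records the models, numerical conventions and design choices
behind `routinesense`, and what the synthetic validation does and does not
establish.

## Data model

The pipeline's currency is the event log: one row per motion firing (value
1, empty channel) or per 5-minute appliance power sample (kWh, named
channel), for a single residence. Timestamps enter in UTC and are converted
to local wall clock by an explicit schedule of (start instant, UTC offset)
segments; segments are half-open and an event exactly on a boundary belongs
to the later segment. We deliberately avoid tz-database lookups: monitored
deployments publish their standard/daylight offsets, and an explicit offset
table makes the "local time" state auditable. A *day* is local
midnight-to-midnight after localization, because routines are wall-clock
phenomena. The CSV writer emits canonical formatting (second-resolution
ISO-8601, `Z` suffix only for UTC files, shortest-round-trip floats) so
write → read → write is byte-identical.

## Cleaning

**Binarization.** A power sample counts as appliance use iff its value
*strictly* exceeds the per-channel standby threshold (default 0.005 kWh per
5-minute sample); threshold 0 therefore keeps every strictly positive
sample. Each qualifying sample becomes one "firing" at its own timestamp.

**Gap classification.** Silences strictly over `min_absence` (default 24 h)
are classified: every sensor quiet → whole-home *absence*; one sensor quiet
while at least one other fires → *battery failure* for that sensor (this
also captures "sensor not installed until later"). Battery-failure
intervals exclude any overlap with absence intervals, since silence during
an empty house proves nothing about a sensor. The threshold is strict
("over 24 hours") so that a daily firing spaced exactly 24 h apart is not a
gap. Which sensors are screened is the caller's choice via the inventory
argument; the analysis drivers screen only the battery-powered motion
sensors, treating appliance-channel silence as behavior.

**Outlier repair.** Daily-count values above Q3 + k·IQR (k = 3) are
replaced by the arithmetic mean of the *non-outlier* values; quartiles use
linear interpolation of order statistics (the numpy default, "type 7"),
the inequality is strict at the fence, and low values are never altered — a
quiet day is signal. Including the outliers in the replacement mean would
defeat the repair, so they are excluded. Pre-battery-failure firing spikes
and visitor days are handled by this same mechanism, not a bespoke
detector. Series shorter than 4 values are returned unchanged with a
warning. Days fully inside an absence gap are dropped from daily series
(an empty-house zero is not a behavioral zero); partial-day absences keep
the day.

## Cyclical profiles

Events are grouped by hour ± 30 minutes: bin *h* covers
[h:00 − 30 min, h:00 + 30 min), the half-hour before midnight wrapping into
bin 0; the 24 bins tile the clock circle so bin sums equal event counts
exactly. Profiles are cumulative raw counts by default (per-day
normalization is an option; radar plots of cumulative frequency are the
convention followed). The absence view maps each bin to
`scale_max − count`, putting zero-movement hours at the outer edge; an
all-zero profile is flagged degenerate. Radar rendering places 00:00 at the
top with hours clockwise, matching a 24-hour clock face.

## Adherence to schedule

For a routine window (label, clock window, target sensor, tolerance;
default kettle 05:00–09:00 ± 30 min), each day of the observation span gets
exactly one label: *absent* (fully inside an absence gap), else
*unobserved* (target sensor in a battery-failure gap), else *with data*
(≥ 1 in-window target firing), else *not taken*. The four counts sum to the
span length by construction.

The median time of use is computed over the *pooled* in-window firings of
all with-data days (not per-day first firings — offered as an option),
using linear-interpolated order statistics on minutes-since-midnight.
A with-data day is adherent iff at least one firing lies in the closed
interval median ± tolerance; "± 30 minutes" reads inclusive, and closed
boundaries are deterministic. Adherence % = 100 · adherent / with-data,
rounded **half away from zero** to one decimal (or to integer on request);
the same rounding scores the 8-item routinization questionnaire
(5/8 → 63%). Timing dispersion (IQR, population SD) is reported on the
same pooled times.

## Change detection

* **Trend.** OLS of a daily metric on [1, day index, daily maximum
  temperature], classical normal-theory p-values (via statsmodels). A
  zero-variance temperature column is dropped; a collinear design raises.
  The night metric defaults to the 23:00–06:00 window attributed to the
  night's starting date; the per-night median inter-firing interval is also
  available.
* **Seasonal.** Cold/hot day sets are the q and 1−q temperature tails
  (default q = 0.25, consistent with roughly quartile groups of about half
  a year of days); the comparison is the pooled-variance two-sample t test
  with df = n₁ + n₂ − 2. Degenerate cases: identical zero-variance samples
  give t = 0, p = 1; zero variance with unequal means signals an infinite
  statistic.
* **Cyclical.** Scheduled outings are detected as whole-home *motion*
  silence inside the window (power is ignored — appliances on standby
  report regardless of presence); the attendance series carries a rolling
  rate (default window 6 occasions ≈ 2 weeks for a thrice-weekly outing).
* **Irregular.** A day's 24-bin profile is compared against the mean ± SD
  of the same weekday's profiles over a trailing 4–6-week window (the day
  under test never contributes; absences and DST-shift days are excluded;
  fewer than 2 contributing days is a cold start). Per-bin deviation is
  (count − mean)/(sd + ε) with ε = 0.5 counts to stabilize zero-variance
  bins of sparse count data; the day's score is the mean absolute
  deviation, mapped to levels by θ_low = 1.5 and θ_high = 3.0 (two levels
  are prescribed; the values are package defaults, user-adjustable as alert
  sensitivity).

## Alerts

Missed-routine alerts require *both* the primary appliance channel silent
around the historical median and the corroborating room-motion sensor
silent in the window — corroboration is a veto, not a conjunction for
normality, because its purpose is protection against false positives and
dead appliance sensors. Level is high only when the corroborating room
shows no motion all morning (taken as 00:00–12:00). A stay in a room runs
from the first firing there following activity elsewhere to the next firing
outside the room — motion sensors cannot classify motion, so only
room-transition logic is defensible — and overlong stays alert unless the
surrounding silence is a classified absence. No alert of any kind is
emitted for an absent day. The engine is batch (end-of-day) and a pure
function of its inputs.

## Synthetic residents

The simulator emits what the pipeline must survive, with ground truth:

* Background motion per room: inhomogeneous Poisson with piecewise-constant
  hour-of-day intensity (24 values/room — the same resolution as the
  profiles, keeping the generator analyzable), modulated multiplicatively
  by temperature and, for night bedroom bins, a linearly growing
  restlessness factor.
* Activities: on eligible weekdays, with adherence probability p, at clock
  time μ + N(0, σ); one power sample on the 5-minute grid plus a Poisson
  motion burst. Published magnitudes for background rates do not exist;
  the archetype defaults are plausibility choices (e.g. ~8 lounge
  firings/hour for a sedentary resident's waking hours) and are documented
  as such.
* Artifacts: constant standby draw on every grid slot *below* the cleaning
  threshold (so binarization is genuinely exercised), battery failures with
  optional pre-failure firing spikes.
* Whole-home silences: attended outings and multi-day travel blocks (travel
  removes all events and records the exact silent interval in truth).
* Illness injection: kitchen/bedroom motion thinned by 0.7·severity,
  morning appliance usage suppressed, scheduled outings cancelled, and
  lounge movement scaled up by a factor 2·severity of the day's own
  afternoon count with a later (17:30-centered), prolonged peak — matching
  the qualitative description of an unwell resident camped in the lounge
  with visitors. Severity 0 is the identity.
* Randomness: one master seed; per-stream sub-seeds derived from stable
  stream names, so adding a sensor never perturbs other streams. Identical
  (config, seed) gives byte-identical CSV. Timestamps are emitted directly
  in local wall clock (behavior is wall-clock); `delocalize` produces UTC
  input for exercising localization.

**What a green test establishes.** Parameter recovery on this generator
shows the estimators are consistent with their own stated models: the
adherence statistic recovers a known daily-routine probability (estimated
as adherent days over *present* days, since a skipped routine must count
against the estimate), OLS recovers a known slope with nominal 99% CI
coverage over 100 replicates, gap classification returns injected travel
silences verbatim, and the deviation detector flags a 2-day illness while
holding a 10% false-positive budget over 90 null days (measured rate ≈ 3–4%
at the default thresholds). It does **not** establish performance on real
homes: multi-occupancy, visitors, pets, sensor placement quirks and
correlated behavioral drift are outside the generator, and the published
regression/t statistics of the motivating trial derive from raw data that
are not public, so they are not reproduction targets.

## Known limitations

* Battery-failure screening of an appliance channel cannot distinguish a
  dead transmitter from an appliance simply unused for a day-plus; the
  inventory argument leaves that judgement to the caller.
* The deviation score treats bins independently; a routine shifted by one
  hour scores similarly to one abolished.
* Attendance detection assumes single occupancy — any in-window motion is
  taken as "home".
* DST handling excludes transition days from baselines but does not model
  sunset-linked behavior; schedule shifts must be configured explicitly.
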