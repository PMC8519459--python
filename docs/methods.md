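# Methods

`terrapin` analyses deployments of small multi-sensor tags glued to the
carapace of freshwater turtles: a 1 Hz environmental stream (temperature,
pressure, light) and a 10 Hz tri-axial acceleration stream per animal, plus
site-level reference temperatures (air, water surface, water at 20 cm, pond
bottom at 10-min cadence), 3-h weather records and a sunrise/sunset table.
This note records the models, the defaults and why, and what the synthetic
test bed does and does not establish.

## Time base and clock drift

All analysis runs in seconds since a per-deployment epoch in UTC (local
time is display-only, avoiding DST ambiguity). Tag clocks drift by tens of
minutes over a season (order 20 min per 140 days); timestamps are remapped
through the GPS-anchored (logger time, true time) pairs taken at attachment
and retrieval by piecewise-linear interpolation — exactly linear with two
anchors, exact at every anchor, extrapolated with the edge slopes. Gaps
longer than 5 s in the 1 Hz stream are recorded, never interpolated; windowed
statistics overlapping a gap are flagged invalid.

## Signal decomposition

Acceleration is split into a *static* (gravity/posture) and a *dynamic*
(movement) component with a zero-phase low-pass filter: a 4th-order
Butterworth at cutoff 1/window (default window 2 s, i.e. 0.5 Hz) applied
forward–backward, so features are not time-shifted; a centred 2 s moving
average is available as a config alternative. Dynamic = raw − static, so
reconstruction is exact by construction. One filter window at each stream
end is flagged as edge transient and excluded from event detection.

VeDBA is the Euclidean norm of the dynamic vector (m s⁻²); the Manhattan
variant (ODBA) is provided but off by default. Time-integrated VeDBA
(trapezoidal, with interpolated interval endpoints so integrals are exactly
additive) is the activity index in m s⁻¹; a constant 0.16 m s⁻² over an
hour integrates to 576 m s⁻¹, which is why per-phase "hourly VeDBA" values
land in the hundreds.

Posture: with the tag on top of the carapace the heave axis reads +g when
level; pitch = atan2(surge, hypot(sway, heave)) (positive nose-up, bounded
in ±90°) and roll = atan2(sway, heave) (full circle). Samples whose static
norm falls below 0.1 g have undefined posture and are flagged, not raised.
Which logger axis is surge is a config field — it is hardware-dependent.

Pressure is surface-referenced; depth_cm = 1000 × P_bar (0.1 bar per
metre). Negative readings are sensor noise and are clipped to zero with a
flag.

## Daily phase segmentation

Statistics are computed over consecutive, non-overlapping 60 s epochs of
the 1 Hz stream (an epoch needs ≥ 50 valid samples): median and mean light,
sample standard deviations (n−1) of temperature and pressure, mean
temperature and its running 24-h minimum. The rules:

* **Night**: median light < 1000 lux AND sd(T) < 1 °C AND sd(P) < 5×10⁻³
  bar. An epoch matching both rules is Night (the more specific
  conjunction).
* **Midday**: mean light > 20 000 lux AND mean temperature ≥ 2 °C above the
  running 24-h minimum. "Several degrees above the daily minimum" has no
  published number; 2 °C is the package default and configurable.

Raw labels flicker at dawn/dusk, so each label mask is smoothed by
morphological closing (gaps ≤ 5 min) then opening (runs ≥ 10 min). Cycles
run from one Night onset to the next (phases are defined relative to
Night, so calendar midnight is the wrong anchor). Within a cycle, Midday is
the longest surviving midday run; Morning fills Night-end → Midday-start
and Evening fills Midday-end → next Night onset. When no midday epoch
survives (overcast days), the whole inter-Night interval is Morning and no
Evening is emitted. The trailing Night run of a record is emitted as a bout
but anchors no cycle. Cycles are dated by the day at Night end — the dawn
day whose daylight the cycle contains — which keeps individual-day keys
unique when a record begins mid-night and aligns each cycle with the
weather it experienced.

## Event detection

**Breathing.** During nocturnal rest just below the surface each inhalation
is a transient pressure decrease. The baseline is a centred 120 s running
median; an inhalation is a peak of (baseline − P) of ≥ 2 cm depth
equivalent, with a 5 s refractory interval (mean inhalation spacing in the
field is ~17 s, so one surfacing is never double-counted). Inhalations with
gaps ≤ 60 s form one breathing bout: at that setting a typical bout (~9.6
inhalations over ~160 s) stays whole while typical inter-bout pauses
(~22 min) never merge. The 2 cm threshold is a tunable derived from the
observed 4.4 ± 3.1 cm surfacing rises, not a published constant. Note a
conditioning effect the tests make visible: because sub-threshold rises are
undetectable, the mean over detected inhalations (~5 cm) and especially the
per-bout baseline-minus-minimum statistic (a maximum over ~10 draws, ~8–9 cm
under iid rises) both exceed the generating mean.

**Basking and dives.** Within Midday, temperature is smoothed over 60 s and
maximal non-decreasing runs lasting ≥ 300 s with run-average slope
≥ 0.2 °C/min are basking events (ΔT = total rise). Dives open on either a
temperature drop ≥ 2 °C per 60 s or a pressure rise ≥ 0.01 bar per 30 s;
triggers within 60 s merge into one event that records its first trigger.
All "sudden change" magnitudes are package defaults (configurable); none is
published.

**Nest digging.** Rear-leg digging oscillates the body in pitch while roll
stays stable. Sliding 2-min windows (30 s stride) over the 10 Hz angle
series are flagged when (var[roll] < 50 AND var[pitch] > 120) OR
(var[roll] < 10 AND var[pitch] > 40), variances in deg² with the n−1
denominator (the thresholds are only plausible in degrees²). Flagged
windows merge across gaps ≤ 10 min; merged spans ≥ 5 min become events with
their mean VeDBA. Acceleration alone cannot distinguish successful laying
from an attempt, so events count as attempts unless they match an observed
nesting time from the metadata (within one day).

**Validation.** Detections are matched to truth intervals by any overlap;
FP% = FP/(TP+FP)×100 and FN% = FN/(TP+FN)×100, rounded to one decimal.

## Stratum inference from temperature

Outside quiet Night rest the pressure channel is erratic (knocks,
vegetation), so the animal's vertical stratum is inferred by OLS of tag
temperature on each reference series, linearly interpolated from the 10-min
cadence to the tag timestamps. The informal criterion "intercept ≈ 0,
slope ≈ 1, R² ≈ 1" is operationalised as the score
(1 − R²) + |slope − 1| + |intercept|/10 (so 1 °C of intercept error trades
against 0.1 of R²; the weight is configurable); the minimum-score stratum
wins, with ties < 10⁻⁶ flagged ambiguous. Both per-bout and pooled fits are
exposed because it is unknown which the original analysis used outside
Night. A reference stratum whose gaps cover more than half a bout is
skipped with a warning.

## Budgets and the activity–temperature relation

Per cycle: phase durations; per-phase hourly VeDBA = VeDBA integral over
the bout ÷ bout duration in hours (stated prominently because the quantity
is reported in the field literature without its formula); the 24-h integral
(daily VeDBA); basking hours; breathing/nesting counts. When bouts tile the
cycle, per-phase integrals sum to the daily integral to machine precision —
an invariant the tests assert at 10⁻⁶ relative. A cycle is complete when
≥ 95% of samples are present at nominal cadence (partial below 80%).

Budgets are aligned on the first successful laying (offset 0), with
pre/peri/post tags bracketing first attempt to last nesting event. Daily
VeDBA is regressed on daily mean field air temperature separately per
period (slope, SE, R²); the non-linear hourly relation is summarised by
binning hourly VeDBA into 2 °C temperature bins and reporting the bin with
maximal upper-decile VeDBA (activity rises with temperature up to the peak
bin, then falls).

## Basking-occurrence model

The response is Midday presence per individual-day; candidate predictors
are daily mean air temperature, daily mean of 3-h cloud fractions, daily
rainfall sum and day length, each centred and reduced (mean 0, variance 1,
sample sd). Fitting is a binomial GLM (statsmodels IRLS; convergence at
deviance tolerance 10⁻⁸ within 100 iterations) with fixed per-individual
intercepts — a deterministic approximation of a random-intercept mixed
model, chosen as the default because it is reproducible and
dependency-free; the approximation is good when each individual contributes
many days, as here. Perfect separation is detected per term and reported by
name. Backward elimination drops, at each step, the term whose removal
lowers AIC most (ties broken by term name) and stops when no removal
lowers AIC; removing a null term lowers AIC iff its likelihood-ratio
statistic is below 2, which happens with probability P(χ²₁ < 2) ≈ 0.843 —
so roughly one pure-noise predictor in six survives selection by design of
AIC, a property the recovery simulations reproduce.

## The synthetic test bed

No public raw dataset of this kind exists, so every stage is validated
against a forward model whose defaults are the field regime: 8 individuals
(the published roster biometrics; tag 7 g, under 1% of mean body mass),
night from sunset+1h to sunrise−1h at 47.6° N, nocturnal resting pressure
0.037 ± 0.016 bar with breathing bouts ~22.5 min apart (9.6 inhalations per
bout ~17 s apart, rises N(4.4, 3.1) cm, clipped positive), basking scheduled
by a logistic model of standardized daily weather (slopes −2.5 cloud, +0.75
day length, −0.35 rain; hard suppression above 90% cloud), bask bouts of
ramps (≈ 0.45 °C/min), slightly cooling plateaus and short dives, evening
activity until night, and 1–6 nest-digging bouts (~73 ± 38 min, pitch
oscillation 12–19° at 0.25 Hz, roll quiet) in a mid-season window, the last
one successful. State VeDBA means are the field regime (rest 0.117, forage
0.173, bask 0.151, evening 0.160, digging 0.31 m s⁻²): per-axis dynamic
noise sd = target mean ÷ 2√(2/π) (the mean of a 3-dof chi distribution,
verified numerically in the tests), high-passed above the decomposition
cutoff so the analysis recovers the targets within 5%. Gravity follows a
slow orientation random walk plus a 0.25–0.3 Hz swimming sway, band-limited
below the cutoff. Active-phase pressure is a strongly erratic reflected
random walk (step 0.01 bar/s), matching the field description; nights carry
small AR(1) sensor noise (the 2 cm inhalation threshold is ≈ 3σ of that
noise). The default deployment length is 20 days (field season: 137), which
keeps the full recovery suite within minutes while exercising every
detector; the full-season schedule is generated (cheaply, without streams)
for bookkeeping checks.

What the generator does *not* emulate — hence what passing tests do not
show about real data: biophysical heat transfer (water/carapace lags are
simple exponential smoothers), real sensor failure modes and fouling,
behavioural idiosyncrasy beyond independent schedules over shared weather,
moonlight, rain-driven light noise, and any coupling between activity and
temperature within a state. Detector thresholds transfer to real data only
to the extent those simplifications are harmless; the package therefore
treats every threshold as configuration, with the defaults documented
here.

Recovery summaries over synthetic deployments exclude nights truncated by
the record boundaries (they are censored observations of night duration);
their breathing bouts still count in the detection confusion.

## Numerical and degenerate-input choices

Sample statistics use the n−1 denominator throughout. Epochs are
non-overlapping (stride = window) for the 1-min statistics; nesting windows
overlap (stride 30 s) and are merged before event extraction. OLS with a
zero-variance regressor raises a degenerate-fit error; a stratum fit where
all references are degenerate propagates that error. Angle computation on a
near-zero static vector flags rather than raises. Determinism: all
generator randomness derives from numpy SeedSequence children of
(seed, individual, purpose), so streams are identical across calls and call
orders; model fits are deterministic given data.
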