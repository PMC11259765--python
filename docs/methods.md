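# Methods

## The estimation model

The estimator treats nocturnal heat flow as one-dimensional steady-state
conduction: flux from core to skin through the body's thermal resistance
equals flux from skin through the sensor package to room air. Equating
the two Fourier terms `q = λ1(CBT − Ts) = λ2(Ts − Ta)` and writing
`K = λ2/λ1` gives the working equation `CBT = Ts + K(Ts − Ta)` and its
inverse `Ts = (K·Ta + CBT)/(1+K)`. The slope of skin on ambient
temperature is therefore `α = K/(1+K)`, and calibration recovers
`K = α/(1−α)` by ordinary least squares. (Some presentations of this
derivation circulate with the algebra of the intermediate forms garbled —
`Ts = (K/(1+K))Ta + CBT(1+K)` and `α = K(1+K)` — which are dimensionally
inconsistent with the working equation; the package implements the
self-consistent forms, which exactly invert `CBT = Ts + K(Ts − Ta)` and
`K = α/(1−α)`.)

Assumptions worth stating: `K` is constant within a person over weeks
(sensor geometry fixed; fat/muscle composition stable), core temperature
is approximately constant over the aggregation window, and heat flow is
quasi-static at the 1-minute sampling scale. Absolute accuracy is not the
goal — the estimate sits systematically below ingestible-capsule
temperature — but day-to-day *fluctuations* track it, which is what shift
detection needs.

Calibration pools valid minutes across nights/participants into one
global `K` (per-subject fits are possible by passing per-subject pairs).
A single night usually spans under 2 °C of ambient range, which makes the
slope ill-conditioned and sensitive to any residual warm-up transient;
pooling nights across different room temperatures conditions the
regression properly. Fitted `α < 0` (physically implausible, noise- or
confound-driven) is clamped to 0 and flagged; `α ≥ 1` is refused as a
model violation.

## Night preprocessing

* **Warm-up discard**: the first 60 minutes after the recording starts
  are dropped (the sensor equilibrates after application; the recording
  start stands in for the donning event, which is not separately logged).
* **Analysis window**: the following 240 minutes. Recordings covering the
  discard period but not the full window are processed on the truncated
  window and flagged; recordings shorter than the discard period are
  unusable (`too_short`).
* **Plausibility**: readings outside 15–45 °C (skin) or −10–45 °C
  (ambient) are flagged invalid, never silently dropped.
* **Ambient exclusion**: minutes with `Ta > Ts` are excluded — the model
  direction of heat flow is violated and external heat is suspected.
* **Artifact rule**: the estimated CBT cannot physiologically move faster
  than `max_step` (default 0.3 °C/min), and ambient should not jump more
  than `max_ambient_step` (default 2 °C/min); a violating minute opens an
  artifact run that stays excluded until the estimate returns within
  `max_step` of the last pre-artifact valid value. Both thresholds are
  configuration, not physiology-derived constants; they are deliberately
  loose so that genuine circadian drift never triggers them.
* **Nightly reduction**: the representative temperature is the arithmetic
  mean of the estimated CBT over valid minutes; nights with under
  `min_valid_fraction` (default 0.5) of the window valid report no value.
  The 0.5 default is a package choice — the tradition in temperature
  charting is to drop doubtful days entirely, and half a window is where
  the mean's stability visibly degrades in simulation.

Temperatures are carried at full float precision; CSV output and rule
evaluation round to 0.01 °C (thermometer display resolution).

## Cycle assembly and inclusion

A cycle spans one menses onset to the day before the next; the trailing
span after the final onset is not a cycle. A night belongs to the cycle
day of the evening it began; oral BBT taken on waking belongs to that
same calendar day. Cycles are labelled from LH tests (any positive →
ovulatory; recorded but all negative → anovulatory; none → unlabelled).
Exclusions mirror the study design: unlabelled cycles (`missing_lh`), and
cycles where *any* available temperature channel exceeds 30% missing days
(`missing_temps`) — excluding the whole cycle rather than one channel
keeps the paired McNemar comparison on a common cycle set.

## The shift rule, precisely

Candidates are scanned in increasing onset day `d` (from day 7). The
reference window is the six calendar days `d−6 … d−1`; it is evaluable
with ≥ 4 recorded values, whose max and mean are the rule's anchors. The
rising sequence is days `d, d+1, d+2`, all recorded — a missing day
breaks the run (the missing-data allowance applies only to the reference
window). Comparisons are on values rounded to 0.01 °C with a 1e−9 float
guard; "at least 0.2 °C higher" is `≥ max + 0.2`, "exceeds" is strict
`>`.

* **Base**: all three rising values ≥ max + 0.2.
* **Fourth-measurement exception**: first two ≥ max + 0.2, third strictly
  above max but by < 0.2; the next recorded measurement confirms by
  exceeding max by any margin. If this pattern matches, the disregard
  exception is never attempted (the exceptions are mutually exclusive;
  first match wins), and a failed fourth measurement fails the candidate.
* **Disregard exception**: exactly one of the three rising values is at
  or below the reference *mean*; it is disregarded — it may be any of the
  three, including the first — and the next recorded measurement
  completes the triple. The two retained values must still clear
  max + 0.2, and the completed third value must be ≥ mean + 0.2 (the
  rule's own switch from "highest" to "average" here is implemented
  literally).

All confirmed detections are reported; classification accepts the
earliest detection whose onset lies in the last 14 calendar days of the
cycle (`length−13 … length`; configurable to latest). Earlier shifts stay
visible in `all_detections` but never flip the cycle to biphasic — they
are treated as pre-ovulatory noise or disturbance. Shifts caused by
illness or other annotated disturbances are handled by an explicit
per-day exclusion mask supplied by the caller; the package does not
attempt fever detection. Series under 10 days, or candidates with an
unevaluable reference window, yield no detections (not errors). The
detector is deterministic and translation-invariant, and it is verified
against an independent brute-force restatement of the rule over
exhaustive small-grid series in the test suite.

## Diagnostics

Standard 2×2 definitions (sensitivity `tp/(tp+fn)`, specificity
`tn/(tn+fp)`, PPV `tp/(tp+fp)`, NPV `tn/(tn+fn)`, F1
`2tp/(2tp+fp+fn)`), each reported only when its denominator is positive.
Published tables of this design sometimes carry the two predictive-value
labels transposed (a PPV of `51/52 = 98.08%` printed as NPV and vice
versa); the package always computes the standard definitions, so check
labels against the generating ratios when comparing.

McNemar's test runs on correctness-discordance of two methods over the
same cycles: exact two-sided binomial for `b+c < 25`, else χ² with
continuity correction `(|b−c|−1)²/(b+c)`; either variant can be forced.
The biphasic-proportion comparison is a 2×2 χ² without continuity
correction (configurable in spirit — pass the corrected variant through
scipy directly if wanted). Tests are two-sided at α = 0.05.

`r_rm` is implemented from its ANCOVA definition: within-subject centring
removes per-subject intercepts, the common slope is fit on the centred
data, and `r_rm = sign(slope)·sqrt(SS_x/(SS_x+SS_err))` on
`df = n_pairs − n_subjects − 1`, p-value from the t distribution on `df`,
95% CI by Fisher z with standard error `1/sqrt(df−1)` (the convention of
the reference R implementation). It equals the Pearson correlation of the
centred pairs and is invariant to per-subject offsets in either variable;
both properties are tested, along with numerical agreement with an
independent library implementation.

## The synthetic generator

The generator's job is to exercise every pipeline decision, not to be a
physiological simulator.

**Nights**: ambient follows a linear drift (default −0.3 °C/h around
24 °C) plus smooth wander (white noise through a 21-minute window, sd
0.3 °C); skin temperature follows the inverse heat-flux relation at the
generating `K` (default 0.2) plus iid sensor noise (sd 0.05 °C); a
warm-up deficit of 1–2 °C decays over the first ~45–75 minutes; optional
displacement artifacts drop skin temperature by 1–3 °C for 5–15 minutes.
Defaults were chosen once as representative of a bedroom recording; the
estimator recovers the generating core temperature to within a few
hundredths of a °C and the generating `K` to a few percent under them.

**Cycles**: daily temperature is a follicular baseline (population mean
36.48 °C, between-subject SD 0.22 °C) plus, for ovulatory cycles, a
smoothstep luteal rise of magnitude drawn N(0.41, 0.20) °C truncated at
0.05 (population mean and SD of the between-phase change) ramping over 2
days at the ovulation day, which sits 14 days before the next menses with
±2 days of uniform jitter (a 12–16-day luteal phase); iid daily noise (sd
0.10 °C) and 10% missing days. The LH surge is placed one day before
ovulation; anovulatory cycles are flat-plus-noise (no established
anovulatory temperature model exists; this is the null the rule assumes)
and test negative throughout. The oral-BBT channel shares each cycle's
latent profile with larger noise (0.15 °C), more missingness (15%) and a
level offset, encoding the looser measurement protocol of waking oral
readings.

**What passing does and does not show.** Under these defaults end-to-end
sensitivity is far below values reported for real cohorts (≈30–40% vs
≈85%): truncated-normal shift draws put ~15% of ovulatory cycles below
the 0.2 °C threshold entirely; iid daily noise inflates the running
6-day maximum that the rise must clear by a further ~0.13 °C; and the
±2-day luteal jitter pushes some true onsets outside the last-14-days
acceptance window. Real daily temperature series are smoother
(autocorrelated) and real luteal plateaus more sustained, both of which
favour the rule. The synthetic study therefore validates the *machinery*
— ordering of channels, monotonicity of sensitivity in effect size and
noise, inclusion bookkeeping — not the absolute accuracy figures, which
are properties of real physiology the generator deliberately does not
claim. Specificity, by contrast, is near 1 in simulation because
flat-plus-noise rarely defeats the rule; real anovulatory cycles with
disturbances produce more false biphasic calls.

**Problem sizes.** Tests and the acceptance script use 74–200 cycles per
condition and 10,000 random series for the brute-force equivalence
check; these sizes give stable Monte-Carlo estimates (binomial se ≈ 3
percentage points at n=200) while keeping the whole suite around ten
seconds.

## Known limitations

* The 4-hour window is anchored to recording start, not sleep onset; no
  donning event or sleep staging is modelled.
* The artifact rule is a step detector; slow sensor creep that stays
  under `max_step` passes through.
* No fertile-window forecasting: the method is retrospective by
  construction, detecting a shift only after three post-rise days.
* Confidence intervals for sensitivity/specificity do not adjust for the
  nested design (multiple cycles per subject).
* The generator omits circadian harmonics, stress/illness covariates and
  autocorrelated daily noise; see above for the consequences.
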