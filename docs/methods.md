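# Methods

## Scope and design

`sipcage` models a home-cage apparatus in which an RFID-identified rat
licking a capacitive spout activates a stepper-driven peristaltic pump,
and every drinking bout is logged to CSV with a timestamp, lick count
and dispensed volume. The package has three layers: a pure domain
model (`core`), serialisation and validation of the device's logs
(`logio`), a stochastic digital twin of the behaviour + firmware
(`simulator`), and the metric library (`microstructure`). The
command-line layer (`cli`) only wires these together. Inferential
statistics (ANOVA, post-hoc tests) on the metric tables are
deliberately out of scope: the package ends at tidy per-subject tables
that any statistics environment can consume.

## Time conventions

* **Zeitgeber time.** ZT0 is the lights-on instant (the standard
  chronobiology convention). With lights off at 08:00 and 12 h of
  dark, lights-on is 20:00 and dark spans ZT12–24. The dark phase is
  half-open `[lights_off, lights_on)`, hourly bins are half-open
  `[h, h+1)`: every instant belongs to exactly one phase and one bin.
* **Days** are 24 h windows counted from `experiment_start`, not
  calendar midnights, matching continuous-access designs that start
  mid-day. Zero-bout days are enumerated as observed zeros, never
  dropped.
* **Timestamps** are absolute datetimes at microsecond resolution; all
  arithmetic is in seconds since `experiment_start`. Time zones and
  daylight-saving shifts are not modelled — the light cycle is a fixed
  clock anchor.

## Dose and preference

Ethanol dose uses volume x v/v fraction x 0.789 g/mL (density of pure
ethanol at room temperature, configurable) divided by body mass. Body
mass is a single per-subject value for the analysis window; whether a
real experiment should use per-day masses is a design decision of that
experiment — re-running the analysis with an updated registry covers
it. Preference is volume-based (ethanol mL over total mL); a
dose-based variant can be derived from the same tables. 0/0 preference
is emitted as NaN flagged `undefined`, never as 0: an animal that did
not drink expressed no preference.

## Behavioural model

Per rat, bout initiations are an inhomogeneous Poisson process with a
dark-phase and a light-phase rate (defaults 2.0 and 0.2 bouts/h: rats
do nearly all drinking in the dark), generated by thinning at the
larger rate. After each accepted bout the process is suspended for the
bout duration plus the bout gap, so a rat never overlaps itself and
consecutive logged rows are distinct drinking events. This dead time
(~20 s against inter-bout times of minutes to hours) deflates both
phase rates by the same factor of order 1%, so phase-ratio and
preference recoveries are unaffected to well within Monte-Carlo error.

Each bout picks the ethanol spout with probability `ethanol_choice_p`,
else the water spout (single-fluid setups send every bout to the one
spout class present). Lick counts are lognormal (defaults: log-mean
4.0, log-sd 0.5 → median ≈ 55 licks) rounded to an integer ≥ 1;
inter-lick intervals are gamma with mean 0.15 s and shape 20 — the
fairly regular 6–7 Hz rhythmic licking of rats. These are documented,
configurable defaults, not claims about any particular dataset.

## Firmware model

* **Single occupancy.** The spout housing admits one head. A rat
  arriving at a busy spout retries after an exponential delay (mean
  30 s) up to 3 times, then abandons the bout; every deferral and drop
  is recorded in the ground truth. Logged bouts on one device
  therefore never overlap, and `validate_session` checks this with a
  running-max-end sweep (one violation per offending bout).
* **Pump.** While the tag is present and the animal licks, the pump
  advances `steps_per_lick` motor steps per lick (default 5) at
  `uL_per_step` (default 0.5 µL). Per-step delivered volume has
  coefficient of variation `noise_cv` (default 1%); the per-bout
  aggregate is drawn as one Normal(S·uL, uL·cv·√S) variate — the exact
  distribution of the sum of S i.i.d. per-step factors — truncated at
  zero. Logged volume is rounded to 3 decimals (µL resolution).
  With the default calibration a bout delivers 2.5 µL per lick.
* **Access policy.** Deny rules by (RFID, device, time window) zero
  the delivered volume but keep the lick count — the extinction-probe
  semantics of a lickometer that stays live while delivery is off.
  Occupancy bookkeeping uses the millisecond-rounded duration that is
  logged, so the written file can never show a rounding-induced
  overlap.
* **Logging threshold.** The firmware logs every drinking event; the
  ≥ 20-lick bout criterion is applied at analysis time, where it
  belongs with the other statistical choices. `filter_bouts` reports
  how many events it removed.
* **Determinism.** One seeded `numpy` generator drives everything, in
  a documented order (per-rat schedules first, then event-queue draws
  chronologically); identical parameters and seed give byte-identical
  logs.

## Dispense-accuracy protocol

The bench protocol repeatedly meters a target volume (default
20 repeats of 1.00 mL) **without resetting** between trials: trial *i*
runs until the cumulative metered display first reaches *i* x target,
so step-quantisation error cannot accumulate across trials. Delivered
volume carries the per-step noise; the result table has per-trial
signed and absolute % errors plus a mean and 95% t-interval. With
`noise_cv = 0` every |error| is bounded by one step's volume over the
target (0.05% at the defaults), which the tests assert exactly.

## Metric definitions and numerical choices

* **Volume per lick** is total volume / total licks per subject-fluid
  (a pooled per-lick estimate), not the mean of per-bout ratios; the
  two differ when bout sizes vary and the pooled form weights licks
  equally.
* **Bout frequency** is bouts per day over the full analysis window,
  including zero-bout days in the denominator.
* **Bout-range bins**: half-open lick-count bins with default edges
  20, 45, 70, 95, 120, 145, 170, 195 and an open last bin (8 ranges).
  Normalised fractions are computed within subject x fluid and sum to
  1 whenever that fluid's total is positive. The first edge must not
  exceed the bout threshold.
* **Bout size** is reported in mL, with labelled lick-count variants
  (`mean_bout_licks`, `max_bout_licks`) alongside.
* **Lick-level metrics**: bouts are segmented per (animal, device) by
  the bout gap; inter-lick intervals are computed only within bouts
  (pairs spanning a boundary are excluded); bout duration is
  first-to-last lick; lick rate is (n−1)/duration, undefined (flagged)
  for single-lick bouts; the inter-bout interval is last lick of one
  bout to first lick of the next at the same device.
* **Conservation.** Hourly-ZT, light/dark, daily and bout-range tables
  all partition the same filtered bouts, so their per-subject-fluid
  sums agree to float-association error (asserted at 1e-9 mL over
  hundreds of seeded sessions).
* **Validation thresholds.** A bout whose lick count implies a
  within-bout rate above 50 Hz (or several licks in zero duration) is
  flagged implausible; rats lick at 6–7 Hz, so 50 Hz is a conservative
  hardware-glitch bound.

## What the simulator does and does not emulate

It emulates the features the metrics are sensitive to: circadian rate
modulation, per-rat fluid preference, heavy-tailed bout sizes, rhythmic
licking, single-occupancy contention, step quantisation and pump noise,
access restriction, and logging resolution. It does **not** emulate
spatial behaviour, social rank dynamics, calibration drift or sensor
waveforms, postural false triggers, or correlations between bout size
and time of day beyond what the rate model induces. Passing
parameter-recovery tests therefore shows the analysis is correct for
data of this structure, not that any particular biological effect size
is realistic; defaults were chosen once as plausible for adult female
rats in a two-bottle ethanol paradigm.

## Problem sizes

The reference scenario is 4 rats x 9 days x 2 devices (~1,000 bouts,
~60,000 licks). Property suites run 100 seeded 9-day sessions for
conservation, 20 seeds x 3 parameter values for circadian and
preference recovery (agreement asserted within 3 Monte-Carlo standard
errors of the seed means), 100 randomised sessions for round-trip
identity, and 200 seeds for the no-drift regression check of the
dispense protocol. These sizes make the Monte-Carlo error bars small
relative to the effects being recovered while keeping the full suite
fast.

## Known limitations

* One bottle per fluid class: with several ethanol concentrations the
  choice model would need a per-device probability vector.
* The retry policy (exponential, mean 30 s, 3 attempts) is a modelling
  choice; real contention behaviour is unmeasured. Its parameters are
  module constants rather than config.
* The bout-level log is the source of truth for volumes; lick-level
  logs carry no volume and are only used for timing microstructure.
* `validate_session` checks pairwise occupancy per device, not
  cross-device simultaneity of one animal (physically impossible in
  the simulator by construction, but not asserted for external logs).
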