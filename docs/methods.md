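# Methods

## Scope and data model

The package analyzes time-domain recordings of an electrochemical ethylene
sensor in two experimental designs: (i) repeated response/recovery cycles at
a fixed nominal concentration (repeatability/stability characterization) and
(ii) day-scale continuous monitoring of ethylene emitted by climacteric
fruit during postharvest ripening, paired with texture-analyzer measurements
of the fruit.  All signals are uniformly sampled concentration series
(`SensorTrace`) carrying gas-in/gas-out event markers and a declared time
unit — seconds for cycles, minutes for ripening trajectories.  No raw
recordings of the original characterization study were deposited, so the
synthetic generators below stand in for them; the printed summary tables
(repeatability statistics, correlation matrices, avocado hardness) ship with
the package as reference data.

## Six-stage cycle model

A cycle is modeled piecewise:

* S1 — constant air baseline X<sub>a</sub>;
* S2 — first-order exponential rise toward the maximum X<sub>m</sub>,
  normalized so the curve attains X<sub>m</sub> exactly at the S2/S3
  boundary.  A first-order law is the standard lumped approximation for
  electrochemical cells; the normalization gives the generator an exact,
  testable maximum;
* S3 — the overshoot X<sub>m</sub> − X<sub>g</sub> relaxes exponentially to
  the steady plateau X<sub>g</sub> (settling constant defaults to one fifth
  of the stage duration, so the plateau is reached well before gas-out);
* S4–S6 — double-exponential recovery
  (1−w)·e^(−u/τ_decay) + w·e^(−u/τ_tail) toward the baseline: a fast
  electrochemical decay plus a slow tail (weight w ≈ 0.12) representing
  residual gas around the sensing element.

Additive Gaussian noise, linear drift, an optional sinusoidal disturbance
and sparse spikes are superimposed.  The demonstration configuration
(`demo_cycle_config`) is calibrated so the noise-free curve peaks at
20.4 ppm, settles at 20.15 ppm and crosses 70% of the excursion 25 s after
gas-in — the textbook numbers quoted for this sensor class — by solving the
rise constant from the closed form (brentq).

Ground truth returned with every cycle includes the generating levels, the
analytic 70%/30% crossing times, the analytic maximum slope, the noise-free
curve and the injected spike positions, enabling parameter-recovery tests.

## Stage segmentation and feature extraction

Operational boundaries (all intervals half-open, times measured from the
relevant marker):

* S2 ends at the first attainment of 95% of the in-gas maximum;
* S4 ends at recovery to baseline + 30% of the excursion, S5 at 5%;
* a cycle whose 95% crossing falls within the last 10% of the gas window
  has no stable stage and raises a segmentation error; recovery thresholds
  never reached clamp the boundary to the trace end and are flagged.

The 23 parameters follow fixed definitions: X<sub>a</sub> is the S1 mean;
X<sub>g</sub> the mean of the final 20% of S3 (robust to the overshoot);
X<sub>m</sub> the in-gas maximum; X<sub>res</sub>/X<sub>rec</sub> the
values 60 s after gas-in and 180 s after gas-out; X<sub>recair</sub> the
mean of the final 10% of S6.  t<sub>res</sub> is the rise to 70% of the
excursion; t<sub>rec</sub> the fall to 30% (the recovery threshold is not
standardized; the 30% mirror of the 70% rise convention is used and is
recorded in the report defaults).  Derivatives use central differences
(one-sided at the ends); D<sub>res</sub>/D<sub>rec</sub> are reported as
absolute values of the extreme first derivative in the response
([gas-in, gas-out]) and recovery ([gas-out, end]) windows, while the
second-derivative extrema keep their sign.  Integrals are trapezoidal.
Marker offsets that fall outside the trace yield NaN for that field plus a
missing-value flag rather than an error.

Note X<sub>res</sub> is defined at 1 min even though typical response times
are below 30 s — both are implemented as defined, since the 1-min value
probes plateau stability rather than rise speed.

## Preprocessing

Gross errors are removed with a Hampel filter: samples deviating from a
7-sample rolling median by more than 3 robust scales (1.4826·rolling MAD)
are replaced by that median.  Noise and periodic disturbances are suppressed
with a centred moving average (default 5 samples, which on default synthetic
cycles displaces the 70% crossing by at most one sample); edge windows
shrink instead of padding so no boundary values are fabricated.  Both steps
preserve grid, markers and length; day-scale trajectories use a wider
31-min window, matching their slower dynamics.

## Repeatability statistics

Per parameter over n cycles: mean, sample (n−1) variance and SD, and
CV = 100·SD/mean.  The CV carries the sign of the mean (repeatability
tables conventionally print negative CVs for negative-mean parameters);
stability rankings use |CV| with alphabetical tie-breaks.  Whether the
original tables used n or n−1 cannot be determined (they differ by < 6% at
n = 10); n−1 is used and recorded in the report defaults.

## Feature-subset selection

Four rules, applied in order, combine repeatability with Pearson
correlation structure (pairwise product-moment, constant columns flagged):

1. response levels: the most repeatable in-air parameter and the most
   repeatable in-gas parameter (smallest |CV| each);
2. time parameters: among those with |CV| below the threshold (default 5%),
   the two sharing the most information with the other time parameters
   (largest mean |off-diagonal r|);
3. derivatives: the first-order pair when the first-order family's mean
   |CV| is at most the second-order family's;
4. integrals: the integral least correlated (|r|) with the steady-state
   response X<sub>g</sub>; ties pick the lexicographically first and are
   flagged.

The published description of the selection is partly outcome-driven; this
rule set is one explicit operationalization that reproduces the published
outcome {X<sub>a</sub>, X<sub>g</sub>, t<sub>res</sub>, t<sub>rec</sub>,
D<sub>res</sub>, D<sub>rec</sub>, intT} on the packaged tables.  The 5%
threshold covers every selected parameter there while excluding the
late-recovery levels (CV 16–58%) and the derivative-extremum times
(CV 6.5–17.3%).  All thresholds are configurable and logged in the report.

## Ensemble dispersion model

`generate_cycle_ensemble` jitters the cycle configuration per cycle with
independent Gaussian relative perturbations, seeded deterministically from
the ensemble seed.  The level CV (baseline, plateau) is the user-facing
`between_cycle_cv` (default 2.4%); the remaining jitters scale with it,
calibrated a priori to the dispersion structure of the packaged
repeatability tables: rise time constant 1.4×, recovery time constants 1×,
gas-exposure (plateau-stage) duration 6× (the exposure was timed manually,
and this dominates intT, decorrelating it from X<sub>g</sub>), overshoot
20× (the maximum is visibly less repeatable than the plateau), slow-tail
weight 5× and a baseline drift draw (dominating the late-recovery readings
X<sub>rec</sub>/X<sub>recair</sub>, the least repeatable levels).  Zero CV
with zero noise reproduces bit-identical cycles.

With a first-order rise the maximum slope occurs at gas-in, so the
derivative-extremum times t<sub>D·</sub> sit near the markers and are
noise-dominated — unlike a real sensor's sigmoidal onset, which places them
seconds later.  Their high CVs still exclude them from the subset, which is
the behaviour that matters downstream; absolute means of the t<sub>D·</sub>
and second-derivative parameters are therefore not comparable to published
values.  This is the main respect in which passing tests do not certify
real-data behaviour; levels, times, first derivatives and integrals are
faithful.

## Ripening trajectory model

The noise-free emission curve rises first-order to a climacteric peak and
then declines monotonically with two accelerated-decline phases: smooth
logistic steps centred in the configured windows (default 600–700 min and
2200–2400 min) drop the current level by configured fractions, and the
baseline slope steps between pre/mid/tail values through matching smooth
ramps.  The first-derivative minima of the noise-free curve fall inside the
windows by construction.  Default sampling is 1 min; noise SD 0.05 ppm.

Defaults are calibrated (bounded least squares on the closed form) so the
segment mean levels before window 1, between windows and after window 2 are
18.5 → 1.85 → 0.555 ppm — a strong climacteric burst whose decline
parallels the softening trajectory, which is the phenomenon the analysis is
designed to detect.  A second calibrated fixture (18 → 13 → 8.77 ppm)
reproduces response change amplitudes of 27.78% / 32.53%, the values
reported for the original (unpublished) ripening recording; since that
recording cannot be obtained, the fixture reproduces its printed summary by
construction and is documented as such.

## Change amplitude vectors and difference ratio

Ripening tables use per-(group, day) means; the pre-ripening pool is shared
between groups.  For synthetic tables with zero spread, Change I/II equal
100·(1−f) of the configured decay factors exactly.  Kinetic phase summaries
per family:

* response — segment means (before window 1 / between / after window 2);
* first and second derivative — the fastest decline (signed minimum of the
  derivative) in the decline window adjacent to each segment: window 1,
  window 2, and the residual tail segment;
* integral — segment means of the cumulative emission integral.  A
  per-unit-time segment area would be numerically identical to the response
  summary and could never be ranked apart from it; the cumulative curve is
  what an emission-integral record shows, and since it is monotone
  increasing the integral family fails the decline trend, as observed for
  real emission integrals.

The difference ratio of a kinetic family against the ripening reference
(mean change of the strongly responding texture parameters — hardness,
adhesiveness, chewiness; color is ordinal-only and excluded) is the mean
over the two phases of |Δk − Δr| / |Δr|.  Any monotone transform yields the
same ranking, which is all the selection uses.  Declining in both phases
(Change I > 0 and Change II > 0) is a hard eligibility prerequisite;
ineligible families keep their score for inspection.  On the default
scenario this makes the ranking structural: the second-derivative summary
does not decline consistently and the integral grows, so the response and
first-derivative families lead — the optimal-parameter outcome the method
is designed to produce.  Group comparison uses Welch's unequal-variance
t-test, reported descriptively (no test was named in the original
comparison, and n = 3 per cell).

## Numerical choices and problem sizes

Trapezoidal integration throughout; threshold crossings use the first grid
sample at/after the threshold (half-open intervals, ±1e-12 guards);
calibrations solve closed forms with brentq / bounded least squares to
1e-12.  The test suite and the acceptance script size their simulations at
200-cycle ensembles (10–20 reseeded replicates) and 3000-min trajectories
(20–40 replicates), which estimate the stochastic outcomes to well under
the asserted margins while the whole suite runs in seconds.

## Known limitations

* First-order rise kinetics: no onset delay, so derivative-extremum timing
  statistics are not comparable to sigmoidal real sensors (see above).
* No electrochemical cell physics, temperature/humidity compensation or
  hardware emulation; concentration is taken as calibrated input.
* Color is carried only as an ordinal ripeness stage; no image analysis.
* The selection rule set reproduces the published outcome but is not the
  only rule set consistent with its verbal description.
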