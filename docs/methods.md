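# Methods

This note records the models implemented by `sonarcee`, the assumptions
and parameter choices behind them, and what the synthetic-data tests do
and do not establish.

## Transmission schedules

Sessions last 10 minutes with one pulse every 20 s. The ramp-up scheme
holds 15 pulses in [0, 300) s with source level (SL) interpolated linearly
in dB from 152 to 214 dB re. 1 µPa m (shortened pulses, effective duration
T = 0.47 s) and 15 pulses in [300, 600) s at 214 dB (T = 0.93 s). The
full-power scheme transmits only the second half. The exact per-pulse SL
steps of a fielded ramp-up are an operational detail; the linear-in-dB rule
is the default and `build_ramp_up_scheme(step_rule=...)` accepts
alternatives. Because the fielded step sequence is not reproduced exactly,
the 0.43 dB total-energy surplus of ramp-up over full-power sessions is
applied as a fixed SEL_cum adjustment constant rather than re-derived from
the schedule.

Energy bookkeeping is exact: `SL_E = SL + 10·log10(T / 1 s)`, and scheme
totals sum single-pulse energies in the linear domain, so a doubled pulse
count raises the total by 3.010 dB.

## Exposure model

Received levels are `SPL = SL − PL` and `SEL = SL_E − PL` with PL evaluated
over the three-dimensional slant range between the towed source (50 m depth
by default) and the whale, both linearly interpolated to pulse times.
Propagation loss is a pluggable callable; the shipped default is spherical
spreading `20·log10(r)` with optional linear absorption, and a
range-by-depth CSV grid with bilinear interpolation accepts externally
ray-traced fields. No surface-image interference or vertical directivity is
modelled. R_min is a proximity metric, not a dose metric, so it is taken
over the full tracks at 1 s resolution rather than at pulse times.

Bias correction adds the mean measured-minus-modelled difference (or a
fixed offset, e.g. +5.8 dB for SPL_max, +2.2 dB for SEL_cum from the
reference tag calibration) to modelled levels; after paired correction the
mean residual is zero by construction. Position uncertainty is propagated
by re-evaluating the indicators under isotropic horizontal and 1 m-s.d.
depth perturbations of the whale track (the depth figure reflects tag
pressure-sensor precision).

## Avoidance detection

Tracks are downsampled to the 20 s pulse grid; headings come from
consecutive positions (clockwise from north). Turns are maximal runs of
same-sign wrapped heading increments; their magnitude is the cumulative
unsigned change. A candidate avoidance response must (i) reach 90°,
(ii) end inside a session window, and (iii) be followed by persistent
movement away from the ship's trackline — mean post-turn heading within
[0, 100)° of the ship's course, evaluated from turn end to session end
with a 3-step (60 s) minimum. The significance of a candidate is its
add-one empirical tail probability `p = (1 + #{baseline ≥ m}) / (1 + n)`
against turns from the 4 h of baseline preceding the session (session
windows excluded); the add-one form avoids p = 0 under finite baselines.
By default the null uses baseline turns of the candidate's rotational
direction; `pooled_one_direction` restricts to clockwise turns only, the
variant that minimises serial correlation in the null sample. Decisions
use a Bonferroni level of 0.05 divided by the number of candidate turns
tested across the experiment. We require the turn to *end* inside the
session (its start time is reported as the response onset); feeding state
is assigned from lunges between 10 min before session start and the onset
(or session end without a response).

Note one structural property of this detector: because candidacy already
requires a 90° turn, its realised false-positive rate depends on how common
large turns are in baseline behaviour, not only on the nominal alpha. With
the default synthetic baseline (below), the session-level false-positive
rate is ~3% at alpha = 0.05.

## Full-power avoidance Monte Carlo

Each of 100,000 draws samples a whale state at the first full-power pulse
(t = 300 s): range to the source from a truncated normal (µ = 456 m,
σ = 185 m, bound 0 — the observed scatter of intercept accuracy), bearing
from a von Mises (µ = 20°, κ = 0.89), depth from a gamma (a = 0.5,
b = 37 m) and avoidance speed from a truncated normal (µ = 1.3 m s⁻¹,
σ = 0.5 m s⁻¹, bound 0). Truncated normals are sampled exactly via the
inverse CDF. SPL per pulse assumes spherical spreading; the source sails
straight at 4.1 m s⁻¹ at 50 m depth, one 214 dB pulse every 20 s for five
minutes. Each draw is evaluated **paired**: the same whale once held
stationary and once moving perpendicular to the source track, away from
it, from the first transmission onward; the reduction is the difference in
SPL_max. Pairing makes a 75th percentile of exactly zero meaningful: a
draw's reduction is zero precisely when the stationary whale's closest
pulse is already the first one.

Two conventions were genuinely open and are exposed in `SimConfig`:

* **Bearing reference.** The fitted von Mises angle is read as the
  *whale-to-source* bearing relative to the ship's course (default
  `bearing_convention="whale_to_source"`). Under the navigational
  protocol the ship reaches the predicted intercept at t ≈ 305 s, so at
  the first pulse the source has typically passed the whale and is
  receding; this convention reproduces the reference reduction
  percentiles (0 / ~3.6 / ~5.9 dB, zero fraction 0.77). The opposite
  reading (`"source_to_whale"`, whale ahead of the source) yields far
  fewer zeros (~0.30) and much larger tail percentiles, inconsistent
  with the reference values, and is retained only as an option.
* **Onset delay.** Avoidance is instantaneous: motion starts at t = 300 s
  (`onset_delay_s = 0`). A one-step delay lowers the tail percentiles by
  ~0.8 dB and is available as a sensitivity knob.

## Risk statistics

The factor models used for inference (risk indicator ~ session, and
~ avoidance × ramp-up session) are saturated, so the independence
working-correlation point estimates are the per-cell sample means for any
family; the gamma family (used for R_min, a positive quantity) carries a
log link, and coefficients are log cell means. Uncertainty comes from the
delete-one-cluster jackknife over the blocking unit (whale group),

V = (G−1)/G · Σ_g (b₍g₎ − b̄)(b₍g₎ − b̄)ᵀ,

which is preferred over the sandwich estimator at G ≈ 10 clusters. If
removing a cluster empties a factor cell, that replicate is skipped with a
warning — with very few clusters per cell the jackknife is not estimable
and the fit raises instead. Contrasts between cells use a parametric
bootstrap on N(coef, V) (5000 draws); the 2.5th/97.5th percentiles give
the interval and significance follows the CI-sign rule. For saturated
Gaussian fits these intervals converge to normal-theory intervals from V.
Two-sided Wald tests report the signed `Z = estimate/√variance`; the
equivalent 1-d.f. chi-square is Z².

Barnard's unconditional test uses the pooled-variance score statistic and
maximises, over a uniform grid (1001 points) of the common success
probability, the probability of `|Z| ≥ |Z_obs|` under independent
binomials. Outcomes whose statistic ties the observed one within 1e-12 are
included in the rejection region; this keeps analytically tied tables that
strict floating-point comparison would drop, and makes the p-value
(slightly) conservative rather than anti-conservative. Hearing risk
classifies weighted SEL_cum against 179 dB (TTS onset) and 199 dB (PTS)
re. 1 µPa² s for low-frequency cetaceans, with a value exactly at a
threshold falling in the higher-risk class; in the 1.3–2.0 kHz sonar band
the low-frequency auditory weighting is 0 dB, so unweighted values compare
directly.

## Synthetic-data generator

Baseline whale movement is a correlated random walk on the 20 s analysis
grid: wrapped-normal heading increments (s.d. 12° per step by default),
truncated-normal per-step speeds (1.0 ± 0.3 m s⁻¹, a typical undisturbed
humpback transit speed), a sinusoidal dive cycle (30 m × 300 s) with 2 m
noise clipped at the surface, and Poisson feeding lunges (10 h⁻¹) kept
only at depths > 0.5 m, matching the constraint of lunge detection.

The default heading concentration deserves a note. Turn *segments*
accumulate runs of same-sign increments, so their magnitudes are
heavier-tailed than a single increment: at 12°/step the segmented baseline
turn magnitudes have s.d. ≈ 17° and spontaneous ≥ 120° turns occur in
≈ 0.1% of turns. This directional regime is what makes the detector's
joint operating characteristics hold simultaneously — a false-positive
rate below alpha *and* reliable recovery of injected ≥ 120° responses.
Markedly more tortuous baselines (e.g. 30°/step, segmented turn s.d.
≈ 42°) produce frequent large spontaneous turns against which a 120°
response is statistically indistinguishable; real analyses face the same
trade-off through the animal's actual behaviour.

Injected avoidance rotates the heading at onset by the requested
magnitude in the rotation direction whose held heading satisfies the
detector's away criterion, holds it at the response speed (1.3 m s⁻¹
observed average) to session end, then resumes the original relative
displacements. A whale already heading along the ship's course cannot be
made away-compliant by any fixed-magnitude turn; the experiment records a
compliance flag instead of forcing geometry (≈ 10% of random headings).

Ship approaches solve the constant-velocity pursuit quadratic for the
intercept of the whale's recent least-squares velocity (last 3 fixes) and
schedule the session start 1250 m short of it at 4.1 m s⁻¹ — five minutes
of sailing to intercept, placing closest approach near the first
full-power pulse. Infeasible pursuits (whale as fast and diverging) fall
back to a flagged closest-point-of-approach course. Experiments are a
control followed by two sonar sessions (RampUp1+RampUp2 or
RampUp1+FullPower), ≥ 1 h apart, control first.

What the generator does **not** emulate: position-estimation error in the
whale track (tracks are exact), surfacing gaps, behavioural-state switches
in baseline movement, dose-dependent response onset (injection times are
drawn uniformly in the ramp phase), and group (mother–calf) co-movement.
Green tests therefore establish the correctness and calibration of the
*pipeline* on a well-specified movement model, not the field realism of
any particular parameter value.

## Numerical conventions

Angles are degrees clockwise from north at all interfaces (radians
internal); times are seconds from session start; positions are local
flat-earth east/north metres, depth positive down. Heading-increment
dead-band: increments below 1e-9° (atan2 rounding on held-heading
segments) are treated as zero in turn segmentation. Empirical p-values use
the add-one convention; reductions in the Monte Carlo count as zero below
1e-12 dB. All random draws flow from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give byte-identical generator
output and identical simulation summaries.

## Known limitations

* Ray-traced propagation with environmental profiles is out of scope; the
  spherical default under-predicts loss in downward-refracting conditions
  (hence the bias-correction hook).
* The jackknife requires every factor cell to survive cluster deletion;
  very unbalanced designs degrade to fewer replicates.
* The avoidance detector's realised error rates depend on the baseline
  turn climate (see above); alpha is nominal, not exact.
* Lunge *detection* and tag sensor simulation are not modelled; lunges are
  event times supplied to, not derived by, the pipeline.
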