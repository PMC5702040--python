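# sonarcee

Tools for analysing controlled-exposure experiments that test **sonar
ramp-up** ("soft start") as a mitigation measure for baleen whales. A
research vessel towing a low-frequency active sonar approaches a tagged
whale on a straight intercept course; the question is whether gradually
increasing the source level before full-power operation lets the whale
move away and lowers its received dose, compared with switching the sonar
on at full power nearby.

The package implements the computational core of such an experiment,
end-to-end runnable on synthetic whale tracks:

* **Transmission schedules** (`sonarcee.schedule`) — ramp-up (source level
  rising 152 → 214 dB re. 1 µPa m over 5 min, then 5 min at 214 dB),
  full-power (5 min silence, 5 min at 214 dB) and no-sonar control
  schemes on a 20 s pulse grid, with energy source levels
  `SL_E = SL + 10·log10(T/t0)` for effective pulse durations T.
* **Exposure and risk indicators** (`sonarcee.exposure`) — per-pulse
  received levels `SPL = SL − PL`, `SEL = SL_E − PL` over the
  source–whale slant range, with pluggable propagation loss (spherical
  spreading default, CSV grid reader for externally modelled fields), and
  the three session risk indicators: maximum sound pressure level
  SPL_max, cumulative sound exposure level
  `SEL_cum = 10·log10(Σ 10^(SEL_i/10))`, and minimum source–whale range
  R_min. Includes measurement-bias correction, the 0.43 dB ramp-up
  SEL_cum protocol adjustment, and Monte Carlo propagation of
  whale-position uncertainty.
* **Avoidance detection** (`sonarcee.avoidance`) — tracks downsampled to
  20 s, headings segmented into maximal same-sign turns; a turn is a
  potential avoidance response if ≥ 90°, in-session, and followed by
  persistent movement away from the ship's trackline (mean heading within
  100° of the ship's course); significance is the add-one empirical tail
  probability against 4 h of baseline turns, Bonferroni-corrected by the
  number of tests on the experiment. Feeding state is assigned from lunge
  times.
* **Full-power avoidance Monte Carlo** (`sonarcee.fullpower_sim`) — how
  much could an instantaneous, perpendicular avoidance response reduce
  SPL_max under the full-power protocol? 100,000 paired draws of whale
  range (truncated normal, µ = 456 m, σ = 185 m), bearing (von Mises,
  µ = 20°, κ = 0.89), depth (gamma, a = 0.5, b = 37 m) and speed
  (truncated normal, µ = 1.3 m s⁻¹, σ = 0.5 m s⁻¹).
* **Risk statistics** (`sonarcee.risk_stats`) — saturated factor models
  under an independence working correlation with leave-one-cluster-out
  jackknife covariance (Gaussian for levels, gamma/log for range),
  parametric-bootstrap contrasts (5000 draws, CI-sign significance rule),
  Wald tests, Barnard's unconditional 2×2 test, Pearson correlations, and
  classification of SEL_cum against TTS (179 dB re. 1 µPa² s) and PTS
  (199 dB) hearing-risk thresholds.
* **Synthetic data** (`sonarcee.tracks`) — baseline whale movement as a
  correlated random walk with dive cycles and Poisson feeding lunges,
  injected avoidance responses, constant-velocity intercept planning for
  the ship (session start 1.25 km from predicted intercept, 4.1 m s⁻¹),
  and whole experiments (control + two sonar sessions, ≥ 1 h apart).

## Worked example

```python
from sonarcee import SimConfig, run_simulation

summary = run_simulation(SimConfig(seed=1))
print(summary.percentiles, summary.zero_fraction)
```

```
{'p75': 0.0, 'p95': 3.63, 'p97.5': 5.86} 0.771
```

77% of simulated whales gain *nothing* by fleeing — their peak received
level is fixed by the very first full-power pulse, transmitted when the
source (sailing at 4.1 m s⁻¹, three times faster than an avoiding whale)
has typically already passed its closest point. Even the 97.5th percentile
of the achievable SPL_max reduction is only ~6 dB, which is why full-power
exposure outcomes can be modelled from no-sonar control sessions without
assuming any behavioural response.

A full synthetic experiment, from tracks to indicators:

```python
from sonarcee import make_experiment, detect_experiment
from sonarcee.cli import indicators_for_experiment

exp = make_experiment(11, respond_flags=(True, False))   # respond in RampUp1
calls = detect_experiment(exp)
print(indicators_for_experiment(exp, calls))
```

```
session_type  avoided  SPL_max_dB  SEL_cum_dB  R_min_m
     Control    False         NaN         NaN    150.6
   FullPower    False       170.4       177.5    150.6
     RampUp1     True       164.1       170.5    312.5
     RampUp2    False       181.1       182.9     40.8
```

The injected 146° turn in RampUp1 is detected (empirical p = 0.011 against
the whale's own 4 h baseline turn distribution) and the avoidance shows up
exactly where it should: lower SPL_max and SEL_cum and a larger minimum
range than the modelled FullPower outcome for the same whale. The control
session has no received levels (no transmissions) but still yields R_min;
applying the full-power scheme to its observed tracks produces the modelled
FullPower record.

The same pipeline is scriptable from the shell:

```sh
sonarcee generate --out data/ --seed 11 --n-experiments 4
sonarcee expose   --data data/ --out indicators.csv --seed 11
sonarcee detect   --data data/ --out calls.csv      --seed 11
sonarcee stats    --indicators indicators.csv --calls calls.csv \
                  --out report.json --seed 11
sonarcee simulate-fullpower --seed 1 --out sim.json
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch: it runs the
100,000-draw full-power avoidance Monte Carlo at the default configuration
and a small synthetic pipeline pass (generation → detection → indicators),
logging the summary to stderr and writing the results JSON to `--out`.
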