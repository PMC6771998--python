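# gaitcoord

Quantitative analysis of bilateral gait coordination and gait asymmetry
from gait-event time series.

Clinicians and movement scientists use two temporal measures to describe
how well the left and right legs cooperate during walking. Given the
heel-strike (HS) and toe-off (TO) timestamps of both legs — e.g. from a
shoe-mounted IMU system on a treadmill — this package computes:

* **Phase coordination index (PCI).** With the reference leg chosen as
  the one with the larger mean swing time, the stride phase of cycle *i*
  is φᵢ = 360° · (t_Si − t_Li) / (t_L(i+1) − t_Li), where t_Li and t_Si
  are the reference and contralateral heel strikes; 180° is perfect
  anti-phase stepping. Accuracy is φ_ABS = mean |φᵢ − 180°| (as a
  percentage, Pφ_ABS = 100 · φ_ABS / 180) and consistency is
  φ_CV = 100 · SD(φ) / mean(φ). Then **PCI = φ_CV + Pφ_ABS** (percent;
  lower = better coordination). PCI estimates are flagged as unreliable
  below 23 strides.
* **Gait asymmetry (GA).** From the shorter and longer of the two legs'
  mean swing times, **GA = 100 · |ln(SSWT / LSWT)|** (percent; 0 =
  perfect symmetry).

Around these, the package provides the full study workflow: stride
segmentation and spatiotemporal parameters (stride/step/swing/stance and
double-support times, cadence, step length), a calibrated stochastic
simulator of 80-subject × 3-speed-condition treadmill cohorts (80% /
100% / 120% of preferred speed), and the group-statistics pipeline
(Shapiro–Wilk screen, one-way ANOVA with Bonferroni post hocs, Pearson
correlation screen of PCI/GA against gait speed, height, BMI, cadence,
swing time and step length).

## Worked example

```python
import numpy as np
from gaitcoord import (SimulationParams, simulate_trial, analyze_trial,
                       pci, gait_asymmetry, expected_pci)

# exact formula checks
print(pci(np.array([170.0, 190.0])).pci)   # 13.412297568739417
print(gait_asymmetry(0.40, 0.48))          # 18.232155679395458

# a simulated 1-minute trial with 5 deg of phase noise
trial = simulate_trial(SimulationParams(n_strides=1000, phase_sd=5.0, seed=1))
result = analyze_trial(trial)
print(round(result.pci, 3), round(expected_pci(180.0, 5.0), 3))
# 4.888 4.994   -> the analysis recovers the analytic expectation
print(result.reference_leg, round(result.ga, 3))
# L 1.207       -> slight swing-time asymmetry, left leg is the reference
```

The same pipeline runs from the shell:

```sh
gaitcoord simulate --out run/ --seed 1            # events.csv + metadata.csv
gaitcoord analyze --events run/events.csv --metadata run/metadata.csv \
                  --out run/results.csv           # one row per trial
gaitcoord stats --results run/results.csv --out run/tables/
gaitcoord reproduce --out run/repro/              # summary/correlation tables
```

`gaitcoord simulate` prints one line per condition, e.g.
`usual: n=80 trials, mean PCI 2.80%, mean GA 1.20%`, and `gaitcoord
stats` reports the three-condition ANOVA verdicts for PCI and GA.
`gaitcoord reproduce` accepts a per-subject spreadsheet via `--s1` and a
user-configurable `--column-map` YAML; without one it falls back to a
bundled *synthetic* moment-matched stand-in cohort and says so loudly.

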