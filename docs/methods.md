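# Methods

## The measures

Walking is modelled purely through its event times: per leg, an ordered,
alternating sequence of heel strikes (HS) and toe offs (TO) on a common
clock. A stride is an ipsilateral HS→HS cycle; within it, stance runs
HS→TO and swing TO→next HS, so stride = stance + swing holds to
round-off by construction. A step runs from a contralateral HS to the
next ipsilateral HS; double support is the time both feet are on the
ground, computed as the overlap between the reference leg's stance
interval and the contralateral leg's ground-contact set within each
cycle (the paper-standard "two bilateral-contact intervals per stride").

The phase of cycle *i* is φᵢ = 360°·(t_Si − t_Li)/(t_L(i+1) − t_Li),
where t_L are heel strikes of the reference leg — the leg with the
larger mean swing time (left on an exact tie; the tie rule is arbitrary
but deterministic) — and t_Si is the single contralateral heel strike in
the half-open cycle [t_Li, t_L(i+1)). Cycles with zero or multiple
contralateral strikes are skipped and counted, not fatal; with in-cycle
pairing, φ is always in (0°, 360°), so no circular wrapping is needed.
PCI = φ_CV + Pφ_ABS with Pφ_ABS = 100·mean|φᵢ−180°|/180 and
φ_CV = 100·SD(φ)/mean(φ). φ_CV uses the sample SD (n−1): the trials are
small samples of an ongoing process. φ_ABS is the *mean* of |φᵢ−180°|,
the only reading that yields a scalar. PCI estimates from fewer than 23
phases carry a reliability warning flag, never an error: the threshold
is a published reliability guideline, not a validity bound.

GA = 100·|ln(SSWT/LSWT)| from the two legs' mean swing times. It is
invariant to leg labels, to the PCI reference choice, and to uniform
time scaling; PCI is invariant to time translation and scaling.

## Units and conventions

Times in seconds, speeds in m/s, cadence in steps/min (60 / mean step
time over both legs), φ in degrees, PCI/GA in percent. Step length is a
measured channel when supplied; otherwise it is derived as belt speed ×
mean step time and flagged `step_length_derived`, because the identity
only holds if the belt speed equals the mean progression speed — the
published group table's speed/cadence/step-length triple is in fact not
mutually consistent under that identity (1.11 m/s at 111.6 steps/min
implies ≈0.60 m, not 0.63 m), so the two sources are never silently
reconciled.

## The synthetic generator

A trial draws reference-leg heel strikes from cumulative
Normal(stride mean, stride SD) increments (default 1.075 ± 0.02 s,
≈56 strides ≈ 1 min of walking); places the contralateral strike of
cycle *i* at t_Li + (φᵢ/360)(t_L(i+1) − t_Li) with
φᵢ ~ Normal(180°, σ) truncated to (5°, 355°); and places toe offs so
swing times are Normal(swing mean, swing SD) truncated to [0.05 s, 95%
of the cycle]. Gaussian-with-truncation is the minimal model for data
reported only as means ± SD; the truncation bounds exist to keep event
orderings physically possible. The default per-role swing means are
0.433/0.427 s: a ~1.3% swing asymmetry is the healthy-cohort norm and
makes the reference-leg choice deterministic. (With exactly equal swing
means the sample reference is a coin flip, and phases measured *against*
the generated direction have slightly lower dispersion — a directional
artifact of conditioning the contralateral strike on the reference
cycle; real gait has no such privileged direction. This is a known
generator limitation, not a property of the analysis.)

The closed-form oracle: for φ ~ Normal(μ, σ),
E[PCI] ≈ 100·σ/μ + 100·E|φ−180°|/180 with the folded-normal mean
E|φ−180°| = σ√(2/π)·exp(−δ²/2σ²) + δ(1−2Φ(−δ/σ)), δ = μ−180. At μ=180
this is (100σ/180)(1+√(2/π)) ≈ 0.9988·σ, i.e. 4.994 at σ=5°. The φ_CV
term uses the first-order 100·σ/μ approximation; its finite-sample bias
is below 1% for the ≥50-stride trials used throughout.

A cohort draws 80 subjects × 3 conditions (belt speed at 0.8/1.0/1.2 ×
each subject's preferred speed, preferred ≈ N(1.11, 0.05) m/s), with
per-condition cadence, step-length and swing distributions set to the
published group table, covariates height ~ N(1.66, 0.091) m and
BMI ~ N(22.8, 3.1) kg/m², and ≈60 s of strides per trial. Condition
effects enter as per-condition phase-noise levels chosen by inverting
the closed form so cohort PCI means land on 2.87/2.65/3.57% (usual/
fast/slow), and as half-normal swing-asymmetry magnitudes matched to GA
means 1.27/0.97/1.74% after deducting the finite-trial estimation
noise. Two modelling choices go beyond anything the study reports and
are documented as such: subject-level random effects (log-normal
coordination multiplier, CV 0.25, to give the observed between-subject
PCI spread) are correlated across conditions with ρ = 0.7, since the
study gives no within-subject correlation; and the subject's
coordination multiplier is negatively linked (ρ = 0.5) to their
step-length random effect, reproducing the reported shorter-steps →
worse-coordination association. One integer seed drives a hierarchical
`SeedSequence` (cohort → subject → trial), so runs are byte-identical
and any sub-stream is independently reproducible.

What the generator does *not* emulate: raw IMU waveforms and event-
detection error, fatigue or learning across trials, non-Gaussian or
autocorrelated stride-time dynamics, and any speed–asymmetry coupling
beyond the calibrated condition means. Passing tests therefore show the
estimators and statistics behave correctly under the stated stochastic
model, not that the measures are valid for any particular sensor.

## Statistics

The screening and comparison pipeline mirrors the study design:
Shapiro–Wilk per variable per condition (reported only, never gating);
one-way ANOVA across the three conditions treating them as independent
groups — as the study states — followed by pooled-variance two-sample
t-tests with Bonferroni adjustment p_adj = min(1, 3p); two-sided
Pearson r for PCI and GA against the six covariates within each
condition. All tests two-sided at α = 0.05. Because the design is
actually repeated measures, a within-subject variant (repeated-measures
ANOVA + paired t-tests) is available behind `repeated=True`, explicitly
non-default; it is also the only reading under which the published
pairwise p-values (e.g. PCI usual-vs-fast p = 0.005) are attainable,
since independent-groups t-tests on the published summaries give far
larger p. Degenerate inputs are marked NaN (constant vectors in the
normality screen and correlation grid) or rejected with a message
(missing condition groups, < 2 values per group).

## Reference-data stand-in

The study's per-subject spreadsheet is not redistributed with this
package. `synthetic_reference.py` builds a *synthetic* 80-subject
cohort whose per-condition sample means/SDs and PCI/GA-covariate
correlations equal the published values exactly, via an orthonormal
zero-mean basis (QR of centered Gaussians): covariate directions are
exactly uncorrelated, outcomes are linear combinations with
coefficients equal to the target correlations plus an orthogonal
residual, and every column is affinely mapped to its target mean/SD.
Recomputing the summary and correlation tables from these rows verifies
the pipeline's arithmetic end to end; it does not re-derive the
published numbers from measurements. The construction matches moments,
not marginal shapes — a few GA values can be negative, which real
trials cannot produce. Users holding the real spreadsheet can run the
true reproduction through `read_supplementary` / `gaitcoord reproduce
--s1`, whose column map is user-configurable because the sheet's layout
is not standardized.

## Numerical and scale choices

Interchange CSVs round event timestamps to the microsecond grid (write→
read→write is byte-stable; 1 µs is far below any gait-relevant scale);
results CSVs keep full float precision; only the human-facing formatted
tables use fixed decimals. Monte-Carlo problem sizes — 20 seeds ×
1000 strides for the closed-form check, 500 replicates × 240 records
for the Type-I error, 20 seeds × 80-subject cohorts for the speed
findings — were chosen so sampling error is a small fraction of each
check's tolerance while a full run stays in the tens of seconds.

## Known limitations

Event streams are assumed clean (detection is out of scope); dropped-
event robustness is limited to skipping unpaired cycles with a count.
GA uses swing times only, as in the source study. The independent-
groups default ANOVA understates within-subject power by design
(fidelity first). The generator's conditional phase construction has
the directional artifact noted above, negligible once swing asymmetry
fixes the reference leg.
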