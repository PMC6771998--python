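"""Stochastic gait-event simulator for single trials and full cohorts.

The generator emulates treadmill walking trials of roughly one minute:
reference-leg heel strikes accumulate Gaussian stride-time increments,
the contralateral heel strike falls at a phase phi_i ~ Normal(180, sd)
degrees within each cycle (truncated to (5, 355) so it stays inside the
cycle), and toe-offs are placed so per-leg swing times are Gaussian
(truncated to [0.05 s, 95% of the cycle]).  A cohort draws 80 subjects x
3 speed conditions (80% / 100% / 120% of each subject's preferred belt
speed) with per-subject random effects, calibrated so the default cohort
means of PCI and GA per condition land on the published group means
(PCI 2.87 / 2.65 / 3.57 %, GA 1.27 / 0.97 / 1.74 % at usual/fast/slow).

Everything is driven by one integer seed through a hierarchical
``numpy.random.SeedSequence``, so identical seeds give byte-identical
output and any subject's stream can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coordination import analyze_trial
from .events import GaitEventSeries, build_stride_table, summarize


class SimulationError(ValueError):
    """Simulation parameters cannot satisfy the truncation bounds."""


# --------------------------------------------------------------------------
# single trial
# --------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Generative settings for one trial.

    Swing means are given per role (long/short swing leg); which physical
    leg plays the long role is a ``simulate_trial`` argument.
    """

    n_strides: int = 56
    stride_time_mean: float = 1.075  # s; ~111.6 steps/min
    stride_time_sd: float = 0.02  # s
    phase_mean: float = 180.0  # degrees; anti-phase stepping
    phase_sd: float = 2.9  # degrees
    swing_mean_long: float = 0.433  # s; slight asymmetry (GA ~1.3%) is the
    swing_mean_short: float = 0.427  # healthy-cohort norm and fixes the reference leg
    swing_sd: float = 0.01  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise SimulationError("n_strides must be >= 2")
        if not (self.swing_mean_long >= self.swing_mean_short > 0):
            raise SimulationError("need swing_mean_long >= swing_mean_short > 0")
        if not self.stride_time_mean > self.swing_mean_long:
            raise SimulationError("stride_time_mean must exceed swing_mean_long")
        if self.phase_sd < 0 or self.swing_sd < 0 or self.stride_time_sd < 0:
            raise SimulationError("standard deviations must be >= 0")
        if not (5.0 < self.phase_mean < 355.0):
            raise SimulationError("phase_mean must lie inside the (5, 355) bounds")
        if self.swing_mean_short <= 0.05:
            raise SimulationError("swing means must exceed the 0.05 s floor")
        if self.swing_mean_long >= 0.95 * self.stride_time_mean:
            raise SimulationError("swing_mean_long must be < 95% of the stride time")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws; degenerates to the mean when sd == 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), size)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), size)
    if np.any(lo >= hi):
        raise SimulationError("empty truncation interval")
    if sd == 0:
        if np.any(mean <= lo) or np.any(mean >= hi):
            raise SimulationError("degenerate mean outside truncation bounds")
        return mean.copy()
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_trial(
    params: SimulationParams,
    subject_id: str = "sim",
    condition: str = "usual",
    belt_speed: float = 1.11,
    long_leg: str = "L",
) -> GaitEventSeries:
    """Generate one trial's bilateral gait-event stream.

    Reference-leg heel strikes are cumulative Normal(stride_time_mean,
    stride_time_sd) increments; the contralateral strike of cycle i is at
    t_Li + (phi_i/360)(t_L(i+1) - t_Li); toe-offs precede the next
    ipsilateral heel strike by the drawn swing time.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_strides

    stride = _trunc_normal(
        rng, params.stride_time_mean, params.stride_time_sd, 0.06, np.inf, n
    )
    t_long = np.concatenate([[0.0], np.cumsum(stride)])

    phi = _trunc_normal(rng, params.phase_mean, params.phase_sd, 5.0, 355.0, n)
    t_short = t_long[:-1] + (phi / 360.0) * stride

    swing_long = _trunc_normal(
        rng, params.swing_mean_long, params.swing_sd, 0.05, 0.95 * stride, n
    )
    to_long = t_long[1:] - swing_long

    d_short = np.diff(t_short)
    swing_short = _trunc_normal(
        rng, params.swing_mean_short, params.swing_sd, 0.05, 0.95 * d_short, n - 1
    )
    to_short = t_short[1:] - swing_short

    if long_leg == "L":
        left_hs, left_to, right_hs, right_to = t_long, to_long, t_short, to_short
    else:
        left_hs, left_to, right_hs, right_to = t_short, to_short, t_long, to_long
    return GaitEventSeries(
        subject_id=subject_id,
        condition=condition,
        belt_speed=belt_speed,
        left_hs=left_hs,
        left_to=left_to,
        right_hs=right_hs,
        right_to=right_to,
    )


def expected_pci(phase_mean: float, phase_sd: float) -> float:
    """Analytic expectation of the PCI for phi ~ Normal(phase_mean, phase_sd).

    E[P_phi_ABS] = 100 * E|phi - 180| / 180 with E|phi - 180| the folded-
    normal mean, and E[phi_CV] ~= 100 * sd / mean; at phase_mean = 180 the
    sum reduces to (100 * sd / 180) * (1 + sqrt(2/pi)).
    """
    if not phase_mean > 0:
        raise SimulationError("phase_mean must be > 0")
    delta = phase_mean - 180.0
    if phase_sd == 0:
        folded = abs(delta)
    else:
        folded = phase_sd * math.sqrt(2.0 / math.pi) * math.exp(
            -(delta**2) / (2.0 * phase_sd**2)
        ) + delta * (1.0 - 2.0 * sps.norm.cdf(-delta / phase_sd))
    return 100.0 * phase_sd / phase_mean + 100.0 * folded / 180.0


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def _cond_dict(usual, fast, slow):
    return {"usual": usual, "fast": fast, "slow": slow}


@dataclass
class CohortParams:
    """Generative settings for a multi-subject, three-condition study.

    Defaults encode the study conditions: 80 subjects, belt speeds at
    0.8/1.0/1.2 x preferred, ~1 min of strides per trial, and condition-
    level cadence/step-length/swing/PCI/GA distributions matching the
    published group table.  ``pci_step_length_corr`` links shorter steps
    to worse coordination; ``subject_consistency`` correlates a subject's
    random effects across conditions.
    """

    n_subjects: int = 80
    speed_multipliers: dict = field(
        default_factory=lambda: {"slow": 0.8, "usual": 1.0, "fast": 1.2}
    )
    preferred_speed_mean: float = 1.11  # m/s
    preferred_speed_sd: float = 0.05
    cadence_mean: dict = field(default_factory=lambda: _cond_dict(111.6, 120.3, 99.7))
    cadence_sd: dict = field(default_factory=lambda: _cond_dict(6.5, 6.9, 9.8))
    step_length_mean: dict = field(default_factory=lambda: _cond_dict(0.63, 0.71, 0.56))
    step_length_sd: dict = field(default_factory=lambda: _cond_dict(0.08, 0.09, 0.09))
    swing_time_mean: dict = field(default_factory=lambda: _cond_dict(0.43, 0.40, 0.48))
    swing_between_sd: dict = field(default_factory=lambda: _cond_dict(0.02, 0.02, 0.04))
    pci_mean_target: dict = field(default_factory=lambda: _cond_dict(2.87, 2.65, 3.57))
    ga_mean_target: dict = field(default_factory=lambda: _cond_dict(1.27, 0.97, 1.74))
    pci_subject_sd_log: float = 0.25  # between-subject CV of coordination noise
    pci_step_length_corr: float = 0.5
    subject_consistency: float = 0.7
    swing_sd: float = 0.01  # s, within-trial
    stride_time_sd: float = 0.02  # s, within-trial
    height_mean: float = 1.66  # m
    height_sd: float = 0.091
    bmi_mean: float = 22.8  # kg/m^2
    bmi_sd: float = 3.1
    trial_seconds: float = 60.0
    seed: int = 0


@dataclass
class SubjectTrialRecord:
    """One row of the study's analysis table: covariates + outcomes."""

    subject_id: str
    condition: str
    gait_speed: float  # m/s, belt speed
    height: float  # m
    bmi: float  # kg/m^2
    preferred_speed: float  # m/s
    cadence: float  # steps/min
    step_length: float  # m
    swing_time: float  # s, mean of both legs
    sswt: float
    lswt: float
    pci: float  # percent
    ga: float  # percent
    phi_abs: float
    p_phi_abs: float
    phi_cv: float
    n_phases: int
    reference_leg: str
    reliability_flag: bool


def records_to_frame(records: Iterable[SubjectTrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def simulate_cohort(
    params: CohortParams | None = None, return_events: bool = False
):
    """Simulate the full cohort and analyze every trial.

    Returns a list of ``SubjectTrialRecord`` (n_subjects x 3 conditions),
    or ``(records, events)`` with the raw event series when
    ``return_events`` is true.
    """
    p = params or CohortParams()
    k_per_degree = expected_pci(180.0, 1.0)  # PCI percent per degree of phase SD
    rho = p.subject_consistency
    rho_sl = p.pci_step_length_corr

    root = np.random.SeedSequence(p.seed)
    records: list[SubjectTrialRecord] = []
    events_out: list[GaitEventSeries] = []
    for s, subj_ss in enumerate(root.spawn(p.n_subjects)):
        own, *cond_ss = subj_ss.spawn(4)
        rng = np.random.default_rng(own)
        subject_id = f"S{s + 1:03d}"
        height = rng.normal(p.height_mean, p.height_sd)
        bmi = rng.normal(p.bmi_mean, p.bmi_sd)
        preferred = max(0.5, rng.normal(p.preferred_speed_mean, p.preferred_speed_sd))
        # subject-level random effects shared across conditions
        z_sl, z_m, z_g, z_sw = rng.standard_normal(4)
        log_m = (
            p.pci_subject_sd_log
            * (-rho_sl * z_sl + math.sqrt(1.0 - rho_sl**2) * z_m)
            - 0.5 * p.pci_subject_sd_log**2
        )

        for cond, css in zip(("usual", "fast", "slow"), cond_ss):
            cadence = float(np.clip(rng.normal(p.cadence_mean[cond], p.cadence_sd[cond]), 60.0, 200.0))
            stride_mean = 120.0 / cadence
            n_strides = max(2, round(p.trial_seconds / stride_mean))
            step_length = p.step_length_mean[cond] + p.step_length_sd[cond] * (
                rho * z_sl + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            )
            phase_sd = (p.pci_mean_target[cond] / k_per_degree) * math.exp(log_m)
            swing_base = max(
                0.15,
                p.swing_time_mean[cond]
                + p.swing_between_sd[cond]
                * (rho * z_sw + math.sqrt(1.0 - rho**2) * rng.standard_normal()),
            )
            # swing asymmetry: half-normal |d| with mean matched to the GA
            # target after deducting the finite-trial estimation noise
            s_ln = p.ga_mean_target[cond] / (100.0 * math.sqrt(2.0 / math.pi))
            se = p.swing_sd * math.sqrt(2.0 / n_strides) / swing_base
            s_eff = math.sqrt(max(s_ln**2 - se**2, 1e-12))
            d = s_eff * (rho * z_g + math.sqrt(1.0 - rho**2) * rng.standard_normal())
            swing_left = swing_base * math.exp(d / 2.0)
            swing_right = swing_base * math.exp(-d / 2.0)

            trial = SimulationParams(
                n_strides=n_strides,
                stride_time_mean=stride_mean,
                stride_time_sd=p.stride_time_sd,
                phase_mean=180.0,
                phase_sd=phase_sd,
                swing_mean_long=max(swing_left, swing_right),
                swing_mean_short=min(swing_left, swing_right),
                swing_sd=p.swing_sd,
                seed=int(css.generate_state(1)[0]),
            )
            events = simulate_trial(
                trial,
                subject_id=subject_id,
                condition=cond,
                belt_speed=preferred * p.speed_multipliers[cond],
                long_leg="L" if swing_left >= swing_right else "R",
            )
            table = build_stride_table(events)
            result = analyze_trial(events, stride_table=table)
            summary = summarize(table, events.belt_speed, step_lengths=[step_length])
            records.append(
                SubjectTrialRecord(
                    subject_id=subject_id,
                    condition=cond,
                    gait_speed=events.belt_speed,
                    height=height,
                    bmi=bmi,
                    preferred_speed=preferred,
                    cadence=summary.cadence,
                    step_length=summary.mean_step_length,
                    swing_time=0.5 * (result.sswt + result.lswt),
                    sswt=result.sswt,
                    lswt=result.lswt,
                    pci=result.pci,
                    ga=result.ga,
                    phi_abs=result.phi_abs,
                    p_phi_abs=result.p_phi_abs,
                    phi_cv=result.phi_cv,
                    n_phases=result.n_phases,
                    reference_leg=result.reference_leg,
                    reliability_flag=result.reliability_flag,
                )
            )
            if return_events:
                events_out.append(events)
    if return_events:
        return records, events_out
    return records
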