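"""Phase coordination index (PCI) and swing-time gait asymmetry (GA).

Bilateral walking coordination is quantified from the relative timing of
the two legs' heel strikes.  With the reference ("long") leg chosen as
the one with the larger mean swing time, the stride phase of cycle i is

    phi_i = 360 * (t_Si - t_Li) / (t_L(i+1) - t_Li)   [degrees]

where t_Li are reference-leg heel strikes and t_Si the contralateral
("short" swing) leg's.  Perfect anti-phase stepping gives phi = 180.
Accuracy of phase generation is phi_ABS = mean |phi_i - 180| and, as a
percentage, P_phi_ABS = 100 * phi_ABS / 180; consistency is the
coefficient of variation phi_CV = 100 * SD(phi) / mean(phi).  Their sum,

    PCI = phi_CV + P_phi_ABS   [percent],

is lower for more accurate and more consistent left-right coordination.

Gait asymmetry compares the two legs' mean swing times (SSWT <= LSWT):

    GA = 100 * |ln(SSWT / LSWT)|   [percent],

with 0 meaning perfect symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import GaitEventError, GaitEventSeries, StrideTable, build_stride_table

#: Minimum number of phases for a reliable, characteristic PCI estimate.
RELIABLE_MIN_PHASES = 23


@dataclass
class PhaseStats:
    """Accuracy/consistency decomposition of a phase series."""

    phi_abs: float  # degrees
    p_phi_abs: float  # percent
    phi_cv: float  # percent
    pci: float  # percent
    n_phases: int
    reliability_flag: bool  # True when n_phases < RELIABLE_MIN_PHASES


@dataclass
class CoordinationResult:
    """Full per-trial coordination outcome (one row of the study table)."""

    reference_leg: str  # {"L", "R"}: leg with the larger mean swing time
    phi: np.ndarray  # per-stride phases, degrees
    phi_abs: float
    p_phi_abs: float
    phi_cv: float
    pci: float
    sswt: float  # shorter mean swing time, s
    lswt: float  # longer mean swing time, s
    ga: float  # percent
    n_phases: int
    n_skipped_cycles: int
    reliability_flag: bool


def select_reference_leg(stride_table: StrideTable) -> str:
    """Leg with the larger mean swing time ("L" on an exact tie)."""
    if stride_table.left.empty or stride_table.right.empty:
        raise GaitEventError("need at least one complete stride per leg")
    return "L" if stride_table.mean_swing("L") >= stride_table.mean_swing("R") else "R"


def phase_series(hs_long, hs_short) -> tuple[np.ndarray, int]:
    """Per-cycle phases and the number of skipped cycles.

    For each reference-leg cycle [t_Li, t_L(i+1)) containing exactly one
    contralateral heel strike t_Si, the phase is
    360 * (t_Si - t_Li) / (t_L(i+1) - t_Li); cycles with zero or several
    contralateral strikes are skipped and counted, not fatal.
    """
    hs_long = np.asarray(hs_long, dtype=float)
    hs_short = np.asarray(hs_short, dtype=float)
    if len(hs_long) < 2:
        raise GaitEventError("need at least 2 reference-leg heel strikes")
    for name, arr in (("hs_long", hs_long), ("hs_short", hs_short)):
        if len(arr) > 1 and not np.all(np.diff(arr) > 0):
            raise GaitEventError(f"{name} must be strictly increasing")

    starts, ends = hs_long[:-1], hs_long[1:]
    lo = np.searchsorted(hs_short, starts, side="left")
    hi = np.searchsorted(hs_short, ends, side="left")
    ok = (hi - lo) == 1
    phi = 360.0 * (hs_short[lo[ok]] - starts[ok]) / (ends[ok] - starts[ok])
    return phi, int((~ok).sum())


def phase_accuracy(phi) -> tuple[float, float]:
    """(phi_ABS, P_phi_ABS): mean |phi - 180| in degrees and as % of 180."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise GaitEventError("empty phase series")
    phi_abs = float(np.mean(np.abs(phi - 180.0)))
    return phi_abs, 100.0 * phi_abs / 180.0


def phase_consistency(phi) -> float:
    """phi_CV: 100 * sample SD / mean of the phase series, percent."""
    phi = np.asarray(phi, dtype=float)
    if phi.size < 2:
        raise GaitEventError("phi_CV needs at least 2 phases")
    mean = float(np.mean(phi))
    if mean <= 0:
        raise GaitEventError("phi_CV undefined for non-positive mean phase")
    return 100.0 * float(np.std(phi, ddof=1)) / mean


def pci(phi) -> PhaseStats:
    """PCI = phi_CV + P_phi_ABS, with the <23-phase reliability warning."""
    phi = np.asarray(phi, dtype=float)
    phi_abs, p_phi_abs = phase_accuracy(phi)
    phi_cv = phase_consistency(phi)
    return PhaseStats(
        phi_abs=phi_abs,
        p_phi_abs=p_phi_abs,
        phi_cv=phi_cv,
        pci=phi_cv + p_phi_abs,
        n_phases=int(phi.size),
        reliability_flag=phi.size < RELIABLE_MIN_PHASES,
    )


def gait_asymmetry(mean_swing_a: float, mean_swing_b: float) -> float:
    """GA = 100 * |ln(SSWT/LSWT)| from the two legs' mean swing times."""
    if not (mean_swing_a > 0 and mean_swing_b > 0):
        raise GaitEventError("swing times must be positive")
    return 100.0 * abs(np.log(mean_swing_a / mean_swing_b))


def analyze_trial(
    events: GaitEventSeries, stride_table: StrideTable | None = None
) -> CoordinationResult:
    """Full pipeline for one trial: stride table -> reference leg ->
    phase series -> PCI, plus swing-time GA."""
    for leg in ("L", "R"):
        if len(events.hs(leg)) < 3:
            raise GaitEventError("need at least 3 heel strikes per leg")
    if stride_table is None:
        stride_table = build_stride_table(events)

    ref = select_reference_leg(stride_table)
    other = "R" if ref == "L" else "L"
    phi, skipped = phase_series(events.hs(ref), events.hs(other))
    stats = pci(phi)

    swing_ref = stride_table.mean_swing(ref)
    swing_other = stride_table.mean_swing(other)
    sswt, lswt = min(swing_ref, swing_other), max(swing_ref, swing_other)
    return CoordinationResult(
        reference_leg=ref,
        phi=phi,
        phi_abs=stats.phi_abs,
        p_phi_abs=stats.p_phi_abs,
        phi_cv=stats.phi_cv,
        pci=stats.pci,
        sswt=sswt,
        lswt=lswt,
        ga=gait_asymmetry(sswt, lswt),
        n_phases=stats.n_phases,
        n_skipped_cycles=skipped,
        reliability_flag=stats.reliability_flag,
    )
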