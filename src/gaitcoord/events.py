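"""Bilateral gait-event data model and spatiotemporal parameters.

Gait events are heel strikes (HS, the foot contacts the ground) and toe
offs (TO, the foot leaves the ground) for each leg.  A stride is one full
gait cycle of a leg, ipsilateral HS to the next ipsilateral HS; within it
TO -> next HS is the swing phase and HS -> TO the stance phase.  A step
runs from a contralateral HS to the next ipsilateral HS, so there are two
steps per stride and cadence (steps/min) is 60 over the mean step time.
All times are seconds on a common trial clock; the treadmill belt speed
(m/s) is carried as trial metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Walking-speed conditions: fractions 0.8 / 1.0 / 1.2 of preferred speed.
CONDITIONS = ("slow", "usual", "fast")

#: Stride-table column order; one row per complete ipsilateral HS->HS cycle.
STRIDE_COLUMNS = (
    "start",
    "stride_time",
    "step_time",
    "swing_time",
    "stance_time",
    "double_support",
)


class GaitEventError(ValueError):
    """An event stream violates the gait-event invariants."""


def _as_times(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise GaitEventError("timestamp arrays must be one-dimensional")
    return arr


@dataclass
class GaitEventSeries:
    """Heel-strike and toe-off timestamps for both legs of one trial.

    Invariants (checked at construction): every timestamp list is strictly
    increasing; per leg, exactly one toe-off lies strictly between each
    pair of consecutive heel strikes; ``belt_speed > 0``.
    """

    subject_id: str
    condition: str
    belt_speed: float
    left_hs: np.ndarray
    left_to: np.ndarray
    right_hs: np.ndarray
    right_to: np.ndarray

    def __post_init__(self) -> None:
        for name in ("left_hs", "left_to", "right_hs", "right_to"):
            setattr(self, name, _as_times(getattr(self, name)))
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise GaitEventError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not self.belt_speed > 0:
            raise GaitEventError(f"belt_speed must be > 0, got {self.belt_speed}")
        for leg in ("left", "right"):
            hs = getattr(self, f"{leg}_hs")
            to = getattr(self, f"{leg}_to")
            for label, arr in ((f"{leg}_hs", hs), (f"{leg}_to", to)):
                if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                    bad = int(np.argmin(np.diff(arr) > 0)) + 1
                    raise GaitEventError(
                        f"{label} is not strictly increasing at index {bad}"
                    )
            if len(hs) >= 2:
                # exactly one TO strictly inside every consecutive HS pair
                n_inside = np.searchsorted(to, hs[1:], side="left") - np.searchsorted(
                    to, hs[:-1], side="right"
                )
                bad = np.nonzero(n_inside != 1)[0]
                if bad.size:
                    i = int(bad[0])
                    raise GaitEventError(
                        f"{leg} heel strike index {i + 1}: expected exactly one "
                        f"toe-off between consecutive heel strikes, found "
                        f"{int(n_inside[i])}"
                    )

    # -- convenience transforms (used heavily by property tests) -------
    def hs(self, leg: str) -> np.ndarray:
        return self.left_hs if leg == "L" else self.right_hs

    def shifted(self, dt: float) -> "GaitEventSeries":
        """Translate every timestamp by ``dt`` seconds."""
        return replace(
            self,
            left_hs=self.left_hs + dt,
            left_to=self.left_to + dt,
            right_hs=self.right_hs + dt,
            right_to=self.right_to + dt,
        )

    def scaled(self, k: float) -> "GaitEventSeries":
        """Multiply every timestamp by ``k > 0`` (uniform time dilation)."""
        if not k > 0:
            raise GaitEventError("scale factor must be > 0")
        return replace(
            self,
            left_hs=self.left_hs * k,
            left_to=self.left_to * k,
            right_hs=self.right_hs * k,
            right_to=self.right_to * k,
        )

    def mirrored(self) -> "GaitEventSeries":
        """Swap the left and right leg labels."""
        return replace(
            self,
            left_hs=self.right_hs.copy(),
            left_to=self.right_to.copy(),
            right_hs=self.left_hs.copy(),
            right_to=self.left_to.copy(),
        )


@dataclass
class StrideTable:
    """Per-stride intervals for each leg, one row per complete cycle.

    ``dropped`` counts events and intervals that could not be used: leading
    or trailing events outside a complete cycle, and step / double-support
    entries whose contralateral event was missing (left as NaN in the
    table).
    """

    left: pd.DataFrame
    right: pd.DataFrame
    dropped: dict

    @property
    def n_strides_left(self) -> int:
        return len(self.left)

    @property
    def n_strides_right(self) -> int:
        return len(self.right)

    def leg(self, leg: str) -> pd.DataFrame:
        return self.left if leg == "L" else self.right

    def mean_swing(self, leg: str) -> float:
        frame = self.leg(leg)
        if frame.empty:
            raise GaitEventError(f"no complete strides on leg {leg}")
        return float(frame["swing_time"].mean())


@dataclass
class SpatiotemporalSummary:
    """Trial-level means of the classic spatiotemporal gait parameters."""

    cadence: float  # steps/min
    mean_step_length: float  # m
    step_length_derived: bool  # True when derived as belt_speed * step time
    gait_speed: float  # m/s (echoes the belt speed)
    mean_stride_time: float  # s
    mean_step_time: float  # s
    mean_stance_time: float  # s
    mean_double_support: float  # s
    mean_swing_left: float  # s
    mean_swing_right: float  # s
    mean_swing_time: float  # s, both legs pooled


def _contact_intervals(
    hs: np.ndarray, to: np.ndarray, t_start: float, t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-contact intervals of one foot: each HS to the next TO.

    A toe-off before the first heel strike closes a contact that was open
    at trial start; a final heel strike with no later toe-off leaves the
    foot on the ground until trial end.
    """
    starts, ends = [], []
    if len(to) and (len(hs) == 0 or to[0] < hs[0]):
        starts.append(t_start)
        ends.append(to[0])
    for h in hs:
        later = to[np.searchsorted(to, h, side="right"):]
        if len(later):
            starts.append(h)
            ends.append(later[0])
        else:
            starts.append(h)
            ends.append(t_end)
    return np.asarray(starts), np.asarray(ends)


def _overlap(a: np.ndarray, b: np.ndarray, ls: np.ndarray, rs: np.ndarray) -> np.ndarray:
    """Total overlap of each [a_i, b_i] with the interval set {[ls_j, rs_j]}."""
    if len(ls) == 0:
        return np.full(len(a), np.nan)
    lo = np.maximum(a[:, None], ls[None, :])
    hi = np.minimum(b[:, None], rs[None, :])
    return np.clip(hi - lo, 0.0, None).sum(axis=1)


def _leg_table(
    hs: np.ndarray,
    to: np.ndarray,
    contra_hs: np.ndarray,
    contra_contacts: tuple[np.ndarray, np.ndarray],
    dropped: dict,
    prefix: str,
) -> pd.DataFrame:
    if len(hs) < 2:
        dropped[f"{prefix}_events_trimmed"] = len(hs) + len(to)
        return pd.DataFrame(columns=list(STRIDE_COLUMNS)).astype(float)

    starts, ends = hs[:-1], hs[1:]
    stride = ends - starts
    # exactly one TO per cycle is guaranteed by the alternation invariant
    to_in = to[np.searchsorted(to, starts, side="right")]
    stance = to_in - starts
    swing = ends - to_in

    # step time: the single contralateral HS strictly inside the cycle
    lo = np.searchsorted(contra_hs, starts, side="right")
    hi = np.searchsorted(contra_hs, ends, side="left")
    step = np.full(len(starts), np.nan)
    ok = (hi - lo) == 1
    step[ok] = ends[ok] - contra_hs[lo[ok]]
    dropped[f"{prefix}_steps"] = int((~ok).sum())

    # double support: while this foot is in stance ([start, to_in]), the
    # time the contralateral foot is also on the ground, summed per cycle
    ds = _overlap(starts, to_in, *contra_contacts)
    dropped[f"{prefix}_double_support"] = int(np.isnan(ds).sum())

    # events outside the complete cycles (leading TOs, trailing TOs)
    n_to_used = len(starts)
    dropped[f"{prefix}_events_trimmed"] = len(to) - n_to_used

    return pd.DataFrame(
        {
            "start": starts,
            "stride_time": stride,
            "step_time": step,
            "swing_time": swing,
            "stance_time": stance,
            "double_support": ds,
        }
    )


def build_stride_table(events: GaitEventSeries) -> StrideTable:
    """Segment an event stream into complete strides per leg.

    A stride is delimited by consecutive ipsilateral heel strikes; rows
    exist only for complete cycles, and intervals whose defining
    contralateral event is absent from the cycle are NaN with a dropped
    count.  Malformed alternation is rejected by the ``GaitEventSeries``
    invariants with the offending index.
    """
    events.validate()
    all_times = np.concatenate(
        [events.left_hs, events.left_to, events.right_hs, events.right_to]
    )
    if all_times.size == 0:
        raise GaitEventError("empty event stream")
    t_start, t_end = float(all_times.min()), float(all_times.max())

    left_contacts = _contact_intervals(events.left_hs, events.left_to, t_start, t_end)
    right_contacts = _contact_intervals(events.right_hs, events.right_to, t_start, t_end)

    dropped: dict = {}
    left = _leg_table(
        events.left_hs, events.left_to, events.right_hs, right_contacts, dropped, "left"
    )
    right = _leg_table(
        events.right_hs, events.right_to, events.left_hs, left_contacts, dropped, "right"
    )
    return StrideTable(left=left, right=right, dropped=dropped)


def summarize(
    stride_table: StrideTable,
    belt_speed: float,
    step_lengths: Sequence[float] | None = None,
) -> SpatiotemporalSummary:
    """Trial-level spatiotemporal summary from a stride table.

    Step length is a measured channel when ``step_lengths`` is given;
    otherwise it is derived as belt_speed x mean step time and flagged,
    because the derivation assumes the belt speed is exactly the mean
    progression speed.
    """
    left, right = stride_table.left, stride_table.right
    if left.empty and right.empty:
        raise GaitEventError("empty stride table")
    both = pd.concat([left, right], ignore_index=True)
    step_times = both["step_time"].dropna()
    if step_times.empty:
        raise GaitEventError("no complete step intervals in stride table")

    mean_step_time = float(step_times.mean())
    cadence = 60.0 / mean_step_time
    if step_lengths is not None and len(step_lengths) > 0:
        mean_step_length = float(np.mean(step_lengths))
        derived = False
    else:
        mean_step_length = belt_speed * mean_step_time
        derived = True

    mean_swing_left = float(left["swing_time"].mean()) if not left.empty else np.nan
    mean_swing_right = float(right["swing_time"].mean()) if not right.empty else np.nan
    return SpatiotemporalSummary(
        cadence=cadence,
        mean_step_length=mean_step_length,
        step_length_derived=derived,
        gait_speed=float(belt_speed),
        mean_stride_time=float(both["stride_time"].mean()),
        mean_step_time=mean_step_time,
        mean_stance_time=float(both["stance_time"].mean()),
        mean_double_support=float(both["double_support"].dropna().mean()),
        mean_swing_left=mean_swing_left,
        mean_swing_right=mean_swing_right,
        mean_swing_time=float(both["swing_time"].mean()),
    )
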