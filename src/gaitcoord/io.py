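"""CSV interchange formats and provenance records.

Canonical formats (UTF-8, '.' decimal, header mandatory):

* event CSV — one row per gait event:
  ``subject_id, condition, leg (L/R), event (HS/TO), time_s``;
  timestamps are written on a microsecond grid so write -> read -> write
  is byte-stable.
* cohort metadata CSV — one row per (subject, condition):
  ``subject_id, height_m, bmi, preferred_speed, condition, belt_speed``
  plus optionally ``mean_step_length_m`` (the measured channel).
* results CSV — one row per analyzed trial, full float precision.

Every CLI run also writes ``provenance.json`` (config + seed + package
version); no timestamps, so identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .events import CONDITIONS, GaitEventError, GaitEventSeries

EVENT_COLUMNS = ("subject_id", "condition", "leg", "event", "time_s")


class FormatError(ValueError):
    """Malformed interchange file."""


def events_to_frame(series: Iterable[GaitEventSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for leg, hs, to in (("L", s.left_hs, s.left_to), ("R", s.right_hs, s.right_to)):
            for ev, times in (("HS", hs), ("TO", to)):
                for t in times:
                    rows.append((s.subject_id, s.condition, leg, ev, round(float(t), 6)))
    frame = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return frame.sort_values(
        ["subject_id", "condition", "time_s", "leg"], kind="stable"
    ).reset_index(drop=True)


def write_events_csv(series: Iterable[GaitEventSeries], path) -> None:
    events_to_frame(series).to_csv(path, index=False, float_format="%.6f")


def read_events_csv(
    path, belt_speeds: Mapping[tuple[str, str], float] | None = None
) -> list[GaitEventSeries]:
    """Parse an event CSV into one ``GaitEventSeries`` per (subject, condition).

    ``belt_speeds`` maps (subject_id, condition) to the belt speed in m/s;
    trials without an entry default to 1.0 m/s.  Malformed rows are
    reported with their line number (header = line 1).
    """
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        if row.leg not in ("L", "R"):
            raise FormatError(f"{path}: line {i}: leg must be L or R, got {row.leg!r}")
        if row.event not in ("HS", "TO"):
            raise FormatError(f"{path}: line {i}: event must be HS or TO, got {row.event!r}")
        if row.condition not in CONDITIONS:
            raise FormatError(
                f"{path}: line {i}: condition must be one of {CONDITIONS}, got {row.condition!r}"
            )
        if not np.isfinite(row.time_s):
            raise FormatError(f"{path}: line {i}: non-finite time_s")

    out = []
    for (subject, cond), block in frame.groupby(["subject_id", "condition"], sort=True):
        def times(leg: str, ev: str) -> np.ndarray:
            sel = block[(block["leg"] == leg) & (block["event"] == ev)]
            return np.sort(sel["time_s"].to_numpy(dtype=float))

        speed = 1.0 if belt_speeds is None else belt_speeds.get((subject, cond), 1.0)
        try:
            out.append(
                GaitEventSeries(
                    subject_id=subject,
                    condition=cond,
                    belt_speed=speed,
                    left_hs=times("L", "HS"),
                    left_to=times("L", "TO"),
                    right_hs=times("R", "HS"),
                    right_to=times("R", "TO"),
                )
            )
        except GaitEventError as exc:
            raise FormatError(f"{path}: trial ({subject}, {cond}): {exc}") from exc
    return out


def write_metadata_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "condition", "belt_speed"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_results_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    if frame.empty:
        raise FormatError(f"{path}: empty results file")
    return frame


def write_provenance(out_dir, config: dict) -> Path:
    """Machine-readable run record: config + seed + package version."""
    from . import __version__

    record = {"package": "gaitcoord", "version": __version__, **config}
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path
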