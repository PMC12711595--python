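"""Ingestion of behavioral event logs and trial metadata.

Playback trials are video-coded as timed behavior bouts (BORIS-style exports:
one row per bout with onset/offset in seconds from playback onset).  This
module parses those logs, applies the study's trial inclusion rules, and
rasterizes each trial onto the one-zero 1-s sampling grid over the 180-s
analysis window (120 s playback + 60 s post-playback) that all downstream
scoring operates on.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorEvent",
    "TrialRecord",
    "OneZeroMatrix",
    "ExcludedTrial",
    "IngestError",
    "STIMULI",
    "ANTHROPOGENIC_STIMULI",
    "SITES",
    "DEFAULT_WINDOW_S",
    "read_events",
    "read_trials",
    "one_zero_sample",
    "apply_trial_filters",
]

DEFAULT_WINDOW_S = 180

STIMULI = ("dove", "drone", "vehicle", "talking")
ANTHROPOGENIC_STIMULI = ("drone", "vehicle", "talking")
#: Human-exposure gradient; field sites APGR (limited), WGL (moderate), FGR (high).
SITES = ("low_exposure", "moderate_exposure", "high_exposure")

SEXES = ("female", "male")
AGE_CLASSES = ("subadult", "adult")

# Trial inclusion window: playbacks closer than 30 m risk startle artifacts
# (local amplification), beyond 100 m attenuation/masking dominate.
MIN_DISTANCE_M = 30.0
MAX_DISTANCE_M = 100.0
# A look toward an external disturbance of >= 10 s (or moving away from it)
# terminates the trial; looks of <= 5 s are ordinary scanning and retained.
DISTURBANCE_EXCLUDE_S = 10.0
SCANNING_RETAIN_S = 5.0


class IngestError(ValueError):
    """Raised when an event log or metadata table violates its contract."""


@dataclass(frozen=True)
class BehaviorEvent:
    """One annotated behavior bout within a trial."""

    trial_id: str
    behavior_code: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise IngestError(
                f"trial {self.trial_id!r}: onset {self.onset_s} < 0; onsets are "
                "defined from playback start"
            )
        if self.offset_s < self.onset_s:
            raise IngestError(
                f"trial {self.trial_id!r}: offset {self.offset_s} < onset {self.onset_s}"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation with its full experimental context."""

    trial_id: str
    giraffe_id: str
    playback_event_id: str
    exemplar_id: str
    stimulus: str
    site: str
    date: _dt.date
    speaker_distance_m: float
    wind_speed_kmh: float
    group_size: int
    sex: str
    age_class: str
    order_in_session: str = "first"
    disturbance_look_s: float = 0.0
    moved_from_disturbance: bool = False

    def __post_init__(self) -> None:
        if self.stimulus not in STIMULI:
            raise IngestError(f"trial {self.trial_id!r}: unknown stimulus {self.stimulus!r}")
        if self.site not in SITES:
            raise IngestError(f"trial {self.trial_id!r}: unknown site {self.site!r}")
        if self.sex not in SEXES:
            raise IngestError(f"trial {self.trial_id!r}: unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise IngestError(f"trial {self.trial_id!r}: unknown age class {self.age_class!r}")
        if self.group_size < 1:
            raise IngestError(
                f"trial {self.trial_id!r}: group size {self.group_size} < 1 "
                "(the focal animal is a group member)"
            )
        if not self.exemplar_id.startswith(self.stimulus):
            raise IngestError(
                f"trial {self.trial_id!r}: exemplar {self.exemplar_id!r} does not "
                f"belong to stimulus type {self.stimulus!r}"
            )


@dataclass
class OneZeroMatrix:
    """Per-second presence/absence of each behavior over the analysis window.

    Second ``i`` represents the half-open interval ``[i, i+1)`` from playback
    onset; a cell is 1 iff a bout overlaps that interval with positive measure.
    """

    trial_id: str
    window_s: int
    codes: tuple[str, ...]
    data: np.ndarray  # (len(codes), window_s), uint8

    def row(self, code: str) -> np.ndarray:
        return self.data[self.codes.index(code)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.codes))


@dataclass(frozen=True)
class ExcludedTrial:
    trial: TrialRecord
    reason: str


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    # sep=None sniffs comma vs tab from the header line
    return pd.read_csv(path, sep=None, engine="python")


def read_events(path: str | Path, known_codes=None) -> list[BehaviorEvent]:
    """Parse a delimited event log into sorted :class:`BehaviorEvent` records.

    Parameters
    ----------
    path
        CSV/TSV with header columns ``trial_id, behavior, onset_s, offset_s``.
    known_codes
        Iterable of valid ethogram codes.  ``None`` loads the packaged
        ethogram.  Any row whose behavior is not in this set is a hard error:
        a typo in a behavior label must never silently drop a bout.
    """
    if known_codes is None:
        from .scoring import load_ethogram

        known_codes = load_ethogram().entries.keys()
    known = set(known_codes)

    df = _read_table(path)
    required = {"trial_id", "behavior", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"{path}: missing columns {sorted(missing)}")

    events: list[BehaviorEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        code = str(row.behavior)
        if code not in known:
            raise IngestError(f"{path} row {i + 2}: unknown behavior code {code!r}")
        onset, offset = float(row.onset_s), float(row.offset_s)
        if offset < onset:
            raise IngestError(
                f"{path} row {i + 2}: offset {offset} precedes onset {onset}"
            )
        events.append(BehaviorEvent(str(row.trial_id), code, onset, offset))
    events.sort(key=lambda e: (e.trial_id, e.onset_s, e.offset_s, e.behavior_code))
    return events


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Parse the trial metadata CSV (dates ISO-8601)."""
    df = _read_table(path)
    trials = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            date = _dt.date.fromisoformat(str(d["date"]))
        except ValueError as exc:
            raise IngestError(f"{path} row {i + 2}: bad date {d['date']!r}: {exc}") from None
        moved = d.get("moved_from_disturbance", False)
        if isinstance(moved, str):
            moved = _BOOL[moved.strip().lower()]
        trials.append(
            TrialRecord(
                trial_id=str(d["trial_id"]),
                giraffe_id=str(d["giraffe_id"]),
                playback_event_id=str(d["playback_event_id"]),
                exemplar_id=str(d["exemplar_id"]),
                stimulus=str(d["stimulus"]),
                site=str(d["site"]),
                date=date,
                speaker_distance_m=float(d["speaker_distance_m"]),
                wind_speed_kmh=float(d["wind_speed_kmh"]),
                group_size=int(d["group_size"]),
                sex=str(d["sex"]),
                age_class=str(d["age_class"]),
                order_in_session=str(d.get("order_in_session", "first")),
                disturbance_look_s=float(d.get("disturbance_look_s", 0.0)),
                moved_from_disturbance=bool(moved),
            )
        )
    return trials


def one_zero_sample(
    events: list[BehaviorEvent],
    window_s: int = DEFAULT_WINDOW_S,
    codes=None,
) -> OneZeroMatrix:
    """Rasterize one trial's bouts onto the 1-s presence/absence grid.

    A bout registers in second ``i`` iff ``[onset, offset]`` overlaps
    ``[i, i+1)`` with positive measure — a zero-length touch at a boundary
    (e.g. offset exactly at ``i``) does not count.  Bouts are truncated at the
    window end; bouts entirely past it contribute nothing.
    """
    trial_ids = {e.trial_id for e in events}
    if len(trial_ids) > 1:
        raise IngestError(f"events from multiple trials passed: {sorted(trial_ids)}")
    trial_id = next(iter(trial_ids)) if trial_ids else ""

    if codes is None:
        codes = tuple(sorted({e.behavior_code for e in events}))
    else:
        codes = tuple(codes)
    data = np.zeros((len(codes), window_s), dtype=np.uint8)
    index = {c: i for i, c in enumerate(codes)}
    for ev in events:
        if ev.onset_s >= window_s:
            continue
        if ev.behavior_code not in index:
            raise IngestError(f"behavior {ev.behavior_code!r} not in requested code list")
        # seconds whose unit interval [i, i+1) gets positive-measure overlap
        first = int(math.floor(ev.onset_s))
        end = min(ev.offset_s, float(window_s))
        if end <= ev.onset_s:  # zero-length (point) bout: zero measure everywhere
            continue
        last = int(math.ceil(end)) - 1  # overlap with [last, last+1) is end - last > 0
        if end == math.floor(end):
            last = int(end) - 1  # touching the boundary from the left is zero measure
        data[index[ev.behavior_code], first : last + 1] = 1
    return OneZeroMatrix(trial_id=trial_id, window_s=window_s, codes=codes, data=data)


# Exclusion reason codes (machine-readable)
REASON_DISTANCE_BELOW = "distance_below_30m"
REASON_DISTANCE_ABOVE = "distance_above_100m"
REASON_DISTURBANCE = "external_disturbance"
REASON_MOVED = "moved_from_disturbance"


def apply_trial_filters(
    trials: list[TrialRecord],
) -> tuple[list[TrialRecord], list[ExcludedTrial]]:
    """Partition trials into included / excluded per the study's field rules.

    Excluded iff speaker distance is outside [30, 100] m, the focal animal
    looked toward an external disturbance for >= 10 s, or it moved away from
    the disturbance.  Looks of <= 5 s are ordinary scanning.  Looks of 6-9 s
    fall between the two anchor rules; they are retained with a warning so the
    choice is auditable rather than silent.
    """
    included: list[TrialRecord] = []
    excluded: list[ExcludedTrial] = []
    for t in trials:
        if t.speaker_distance_m is None or (
            isinstance(t.speaker_distance_m, float) and math.isnan(t.speaker_distance_m)
        ):
            raise IngestError(
                f"trial {t.trial_id!r}: missing speaker distance; inclusion "
                "cannot be adjudicated"
            )
        if t.speaker_distance_m < MIN_DISTANCE_M:
            excluded.append(ExcludedTrial(t, REASON_DISTANCE_BELOW))
        elif t.speaker_distance_m > MAX_DISTANCE_M:
            excluded.append(ExcludedTrial(t, REASON_DISTANCE_ABOVE))
        elif t.moved_from_disturbance:
            excluded.append(ExcludedTrial(t, REASON_MOVED))
        elif t.disturbance_look_s >= DISTURBANCE_EXCLUDE_S:
            excluded.append(ExcludedTrial(t, REASON_DISTURBANCE))
        else:
            if t.disturbance_look_s > SCANNING_RETAIN_S:
                warnings.warn(
                    f"trial {t.trial_id!r}: disturbance look of "
                    f"{t.disturbance_look_s:.1f} s is between the 5-s scanning "
                    "and 10-s exclusion anchors; retained",
                    stacklevel=2,
                )
            included.append(t)
    return included, excluded
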