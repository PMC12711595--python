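"""Reaction-intensity scoring: the 0-12 index and its logistic time-weighting.

Each coded behavior maps to an integer reaction intensity on a 0-12 scale
(0 = continues feeding/ruminating, 12 = flight), grouped into categories
A (0-5, minimal), B (6-9, cessation of natural behavior and sustained
attention) and C (10-12, full vigilance including relocation).  To emphasize
acute, stimulus-evoked responses over delayed ones, intensities are weighted
by a decreasing logistic of latency centered at 12 s — near-full weight
within ~9 s, near-zero after ~15 s — and the trial's primary response is the
maximum weighted score among the first three distinct reacting behaviors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import BehaviorEvent, OneZeroMatrix, one_zero_sample, DEFAULT_WINDOW_S

__all__ = [
    "EthogramMap",
    "WeightParams",
    "ScoredBehavior",
    "TrialFeatures",
    "load_ethogram",
    "score_behavior",
    "categorize",
    "logistic_weight",
    "latency_first_response",
    "first_three_behaviors",
    "time_weighted_score",
    "reaction_duration",
    "compute_trial_features",
]

MAX_SCORE = 12

#: Default steepness ln(19)/3 per second: the tightest smooth logistic with
#: w(9) = 0.95 and w(15) = 0.05 around the 12-s center.
DEFAULT_STEEPNESS = math.log(19.0) / 3.0


@dataclass(frozen=True)
class EthogramMap:
    """Total map from behavior code to reaction intensity (0-12)."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        bad = {c: s for c, s in self.entries.items() if not 0 <= int(s) <= MAX_SCORE}
        if bad:
            raise ValueError(f"ethogram intensities outside 0..12: {bad}")

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> int:
        return score_behavior(code, self)

    def codes_with_intensity(self, minimum: int) -> set[str]:
        return {c for c, s in self.entries.items() if s >= minimum}

    def code_for(self, intensity: int) -> str:
        """Some code carrying exactly this intensity (used by the simulator)."""
        for c, s in sorted(self.entries.items()):
            if s == intensity:
                return c
        raise KeyError(f"no behavior with intensity {intensity}")


def load_ethogram(path: str | Path | None = None) -> EthogramMap:
    """Load the behavior -> intensity table (packaged editable CSV by default)."""
    if path is None:
        with resources.as_file(
            resources.files("vigiplay").joinpath("data/ethogram.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return EthogramMap(dict(zip(df["behavior_code"].astype(str), df["intensity"].astype(int))))


def score_behavior(code: str, ethogram: EthogramMap) -> int:
    if code not in ethogram.entries:
        raise KeyError(f"behavior code {code!r} not in ethogram")
    return int(ethogram.entries[code])


def categorize(score: int) -> str:
    """Intensity category: A = 0-5, B = 6-9, C = 10-12."""
    if not 0 <= score <= MAX_SCORE:
        raise ValueError(f"score {score} outside 0..{MAX_SCORE}")
    if score <= 5:
        return "A"
    if score <= 9:
        return "B"
    return "C"


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the decreasing logistic latency weight w(t).

    ``w(t) = 1 / (1 + exp(steepness * (t - center_s)))``; w(center_s) = 0.5.
    The bounds record the narrative anchors ("full weight within ~9 s",
    "minimal weight after ~15 s") and are validated against the curve.
    """

    center_s: float = 12.0
    steepness: float = DEFAULT_STEEPNESS
    full_weight_bound_s: float = 9.0
    zero_weight_bound_s: float = 15.0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0 (weight must decrease)")
        # the default steepness ln(19)/3 hits both bounds exactly; tolerate
        # float rounding at the boundary
        if logistic_weight(self.full_weight_bound_s, self) < 0.95 - 1e-9:
            raise ValueError(f"w({self.full_weight_bound_s}) < 0.95 with these parameters")
        if logistic_weight(self.zero_weight_bound_s, self) > 0.05 + 1e-9:
            raise ValueError(f"w({self.zero_weight_bound_s}) > 0.05 with these parameters")


def logistic_weight(t: float, params: WeightParams | None = None) -> float:
    """Decreasing logistic latency weight in (0, 1), w(center) = 0.5 exactly."""
    if params is None:
        params = WeightParams()
    # scipy.special.expit of the negative argument, written out to keep this
    # hot one-liner dependency-light
    x = params.steepness * (t - params.center_s)
    if x >= 0:
        return math.exp(-x) / (1.0 + math.exp(-x))
    return 1.0 / (1.0 + math.exp(x))


@dataclass(frozen=True)
class ScoredBehavior:
    behavior_code: str
    intensity: int
    latency_s: float
    weight: float
    weighted_score: float


@dataclass(frozen=True)
class TrialFeatures:
    """Derived per-trial response measures (model inputs)."""

    trial_id: str
    latency_first_s: float | None
    duration_s: float
    reaction_intensity: float
    category: str


def latency_first_response(matrix: OneZeroMatrix, ethogram: EthogramMap) -> int | None:
    """First second with any reacting (intensity >= 1) behavior active, else None.

    Latency is reported on the one-zero grid, i.e. at whole-second resolution.
    """
    reacting = [i for i, c in enumerate(matrix.codes) if score_behavior(c, ethogram) >= 1]
    if not reacting:
        return None
    any_active = matrix.data[reacting].max(axis=0)
    hits = np.flatnonzero(any_active)
    return int(hits[0]) if hits.size else None


def first_three_behaviors(
    events: list[BehaviorEvent],
    ethogram: EthogramMap,
    params: WeightParams | None = None,
) -> list[ScoredBehavior]:
    """First up to three *distinct* reacting behaviors, in onset order.

    Distinctness is by ethogram code (repeat bouts of the same behavior do not
    consume a slot); "reacting" means intensity >= 1.  Each behavior carries
    the whole-second latency of its first onset.
    """
    if params is None:
        params = WeightParams()
    seen: set[str] = set()
    out: list[ScoredBehavior] = []
    for ev in sorted(events, key=lambda e: (e.onset_s, e.behavior_code)):
        intensity = score_behavior(ev.behavior_code, ethogram)
        if intensity < 1 or ev.behavior_code in seen:
            continue
        seen.add(ev.behavior_code)
        latency = float(math.floor(ev.onset_s))
        w = logistic_weight(latency, params)
        out.append(
            ScoredBehavior(ev.behavior_code, intensity, latency, w, intensity * w)
        )
        if len(out) == 3:
            break
    return out


def time_weighted_score(
    first3: list[ScoredBehavior], params: WeightParams | None = None
) -> float:
    """Primary response: max of intensity x w(latency); 0 when no reaction."""
    if len(first3) > 3:
        raise ValueError("time_weighted_score takes at most three behaviors")
    if params is None:
        params = WeightParams()
    if not first3:
        return 0.0
    return max(b.intensity * logistic_weight(b.latency_s, params) for b in first3)


def reaction_duration(
    matrix: OneZeroMatrix, ethogram: EthogramMap, min_intensity: int = 6
) -> float:
    """Seconds in the window with any behavior of intensity >= ``min_intensity``.

    The >= 6 default counts seconds of interrupted natural behavior (the B/C
    category boundary: cessation of feeding/ruminating with sustained
    attention); total vigilant time, not first-bout length.
    """
    rows = [i for i, c in enumerate(matrix.codes) if score_behavior(c, ethogram) >= min_intensity]
    if not rows:
        return 0.0
    return float(matrix.data[rows].max(axis=0).sum())


def compute_trial_features(
    events: list[BehaviorEvent],
    ethogram: EthogramMap,
    params: WeightParams | None = None,
    window_s: int = DEFAULT_WINDOW_S,
    duration_min_intensity: int = 6,
) -> TrialFeatures:
    """Full per-trial feature extraction from one trial's event stream."""
    if params is None:
        params = WeightParams()
    trial_id = events[0].trial_id if events else ""
    codes = tuple(sorted({e.behavior_code for e in events}))
    matrix = one_zero_sample(events, window_s=window_s, codes=codes)
    latency = latency_first_response(matrix, ethogram)
    duration = reaction_duration(matrix, ethogram, min_intensity=duration_min_intensity)
    first3 = first_three_behaviors(events, ethogram, params)
    intensity = time_weighted_score(first3, params)
    return TrialFeatures(
        trial_id=trial_id,
        latency_first_s=None if latency is None else float(latency),
        duration_s=duration,
        reaction_intensity=intensity,
        category=categorize(int(round(intensity))),
    )


def features_to_frame(features: list[TrialFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [f.trial_id for f in features],
            "latency_first_s": [f.latency_first_s for f in features],
            "duration_s": [f.duration_s for f in features],
            "reaction_intensity": [f.reaction_intensity for f in features],
            "category": [f.category for f in features],
        }
    )
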