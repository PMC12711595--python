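"""Fixed-effect design construction for the mixed models.

Continuous covariates (group size, wind speed, speaker distance) are
standardized to mean 0, SD 1 (population SD; configurable).  Speaker distance
enters as a raw degree-2 polynomial on the standardized scale, since sound
attenuation with distance is non-linear.  Date is mapped to integer day
offsets and standardized *within* each site x stimulus stratum, absorbing
systematic temporal drift in the data-collection period.  Sex and age combine
into a 4-level factor.  The design is treatment-coded with a full
sound x site interaction; contrasts downstream are coding-invariant, so the
reference levels (dove, low_exposure, adult_female by default) are a
convention, not a contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import SITES, STIMULI, TrialRecord
from .scoring import TrialFeatures

__all__ = [
    "FactorCoding",
    "DesignInfo",
    "DesignMatrices",
    "zscore",
    "standardize_date_within",
    "encode_sexage",
    "build_design",
]

SEXAGE_LEVELS = ("adult_female", "adult_male", "subadult_female", "subadult_male")


def zscore(values, ddof: int = 0) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD by default).

    Constant or singleton input returns all zeros with a warning: a stratum
    with no spread carries no usable contrast, and zeros keep it neutral.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("zscore of empty input")
    sd = x.std(ddof=ddof) if x.size > ddof else 0.0
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn(
            f"zscore: degenerate input (n={x.size}, sd={sd}); returning zeros",
            stacklevel=2,
        )
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _day_numbers(trials: list[TrialRecord]) -> np.ndarray:
    """Integer day offsets from the earliest trial date."""
    origin = min(t.date for t in trials)
    return np.array([(t.date - origin).days for t in trials], dtype=float)


def standardize_date_within(trials: list[TrialRecord], ddof: int = 0) -> pd.Series:
    """Date z-scores computed separately within each (site, stimulus) stratum."""
    days = _day_numbers(trials)
    out = np.empty(len(trials))
    strata = pd.DataFrame(
        {"site": [t.site for t in trials], "stimulus": [t.stimulus for t in trials]}
    )
    for _, idx in strata.groupby(["site", "stimulus"], sort=False).groups.items():
        idx = np.asarray(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton strata are expected
            out[idx] = zscore(days[idx], ddof=ddof)
    return pd.Series(out, index=[t.trial_id for t in trials], name="date_z")


def encode_sexage(sex: str, age_class: str) -> str:
    """Combine sex and age class into the 4-level demographic factor."""
    level = f"{age_class}_{sex}"
    if level not in SEXAGE_LEVELS:
        raise ValueError(f"invalid sex/age combination: {sex!r}, {age_class!r}")
    return level


@dataclass(frozen=True)
class FactorCoding:
    """Reference levels for treatment coding (conventions; contrasts are invariant)."""

    sound_ref: str = "dove"
    site_ref: str = "low_exposure"
    sexage_ref: str = "adult_female"

    def __post_init__(self) -> None:
        if self.sound_ref not in STIMULI:
            raise ValueError(f"unknown sound reference {self.sound_ref!r}")
        if self.site_ref not in SITES:
            raise ValueError(f"unknown site reference {self.site_ref!r}")
        if self.sexage_ref not in SEXAGE_LEVELS:
            raise ValueError(f"unknown sexage reference {self.sexage_ref!r}")


@dataclass(frozen=True)
class DesignInfo:
    """Column layout of the fixed-effect design, with condition-row algebra."""

    columns: tuple[str, ...]
    coding: FactorCoding

    def condition_row(
        self, site: str, sound: str, sexage: str | None = None
    ) -> np.ndarray:
        """Fixed-effect row for a (site, sound) cell with covariates at their means.

        Standardized covariates are 0 at their means.  ``sexage=None``
        averages the four demographic levels with equal weights (reference-
        grid convention).
        """
        if site not in SITES:
            raise ValueError(f"unknown site {site!r}")
        if sound not in STIMULI:
            raise ValueError(f"unknown sound {sound!r}")
        if sexage is None:
            rows = [self.condition_row(site, sound, sa) for sa in SEXAGE_LEVELS]
            return np.mean(rows, axis=0)
        if sexage not in SEXAGE_LEVELS:
            raise ValueError(f"unknown sexage level {sexage!r}")
        row = np.zeros(len(self.columns))
        cols = {c: i for i, c in enumerate(self.columns)}
        row[cols["Intercept"]] = 1.0
        for name in (
            f"sound[{sound}]",
            f"site[{site}]",
            f"sound[{sound}]:site[{site}]",
            f"sexage[{sexage}]",
        ):
            if name in cols:  # absent for reference levels
                row[cols[name]] = 1.0
        return row


@dataclass
class DesignMatrices:
    """Everything the sampler consumes: X, y, random-factor codes, metadata."""

    X: pd.DataFrame
    y: np.ndarray
    groups: dict[str, np.ndarray]  # factor name -> integer codes per row
    group_levels: dict[str, list[str]]
    info: DesignInfo
    trial_ids: list[str]


def build_design(
    trials: list[TrialRecord],
    features: list[TrialFeatures] | pd.DataFrame,
    response: str = "reaction_intensity",
    coding: FactorCoding | None = None,
    ddof: int = 0,
) -> DesignMatrices:
    """Assemble the treatment-coded fixed-effect design and response vector."""
    if coding is None:
        coding = FactorCoding()
    if not trials:
        raise ValueError("no trials")
    if not isinstance(features, pd.DataFrame):
        from .scoring import features_to_frame

        features = features_to_frame(features)
    feat = features.set_index("trial_id")
    missing = [t.trial_id for t in trials if t.trial_id not in feat.index]
    if missing:
        raise ValueError(f"trials without features: {missing}")
    if response not in feat.columns:
        raise ValueError(f"unknown response {response!r}")
    y = feat.loc[[t.trial_id for t in trials], response].to_numpy(dtype=float)
    if np.isnan(y).any():
        bad = [t.trial_id for t, v in zip(trials, y) if np.isnan(v)]
        raise ValueError(f"missing response values for trials: {bad}")

    n = len(trials)
    sounds = [t.stimulus for t in trials]
    sites = [t.site for t in trials]
    sexage = [encode_sexage(t.sex, t.age_class) for t in trials]

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    sound_levels = [s for s in STIMULI if s != coding.sound_ref]
    site_levels = [s for s in SITES if s != coding.site_ref]
    for s in sound_levels:
        cols[f"sound[{s}]"] = np.array([v == s for v in sounds], dtype=float)
    for s in site_levels:
        cols[f"site[{s}]"] = np.array([v == s for v in sites], dtype=float)
    for so in sound_levels:
        for si in site_levels:
            cols[f"sound[{so}]:site[{si}]"] = cols[f"sound[{so}]"] * cols[f"site[{si}]"]

    cols["group_size_z"] = zscore([t.group_size for t in trials], ddof=ddof)
    cols["wind_z"] = zscore([t.wind_speed_kmh for t in trials], ddof=ddof)
    dist_z = zscore([t.speaker_distance_m for t in trials], ddof=ddof)
    cols["dist_z"] = dist_z
    cols["dist_z2"] = dist_z**2
    cols["date_z"] = standardize_date_within(trials, ddof=ddof).to_numpy()
    for level in SEXAGE_LEVELS:
        if level != coding.sexage_ref:
            cols[f"sexage[{level}]"] = np.array(
                [v == level for v in sexage], dtype=float
            )

    X = pd.DataFrame(cols, index=[t.trial_id for t in trials])

    groups: dict[str, np.ndarray] = {}
    group_levels: dict[str, list[str]] = {}
    for name, getter in (
        ("giraffe_id", lambda t: t.giraffe_id),
        ("playback_event_id", lambda t: t.playback_event_id),
        ("exemplar_id", lambda t: t.exemplar_id),
    ):
        values = [getter(t) for t in trials]
        levels = sorted(set(values))
        lut = {v: i for i, v in enumerate(levels)}
        groups[name] = np.array([lut[v] for v in values], dtype=np.int64)
        group_levels[name] = levels

    info = DesignInfo(columns=tuple(X.columns), coding=coding)
    return DesignMatrices(
        X=X,
        y=y,
        groups=groups,
        group_levels=group_levels,
        info=info,
        trial_ids=[t.trial_id for t in trials],
    )
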