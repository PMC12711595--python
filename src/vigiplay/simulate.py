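"""Synthetic study-like data with known ground truth.

Two generation levels:

* :func:`simulate_trials` draws a full trial/feature table mirroring the
  field design — three sites on a human-exposure gradient with 19/10/4
  individuals, four stimulus types with 8 exemplars each, repeated measures
  per individual in dove + anthropogenic session pairs, crossed random
  intercepts (individual, playback event, exemplar), and Gaussian residual
  noise, clamped to the 0-12 response scale.
* :func:`simulate_event_stream` emits a per-second behavior event log whose
  pipeline-recovered time-weighted score returns a requested latent
  intensity, enabling end-to-end round-trip tests of ingest + scoring.

The default site x stimulus effect pattern encodes the habituation gradient:
strong anthropogenic effects at the low-exposure site (drone +4.3, vehicle
+5.3, talking +1.9 relative to dove), moderate effects (~+1) at the
moderate-exposure site, and small effects (~+0.3) at the high-exposure site.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ANTHROPOGENIC_STIMULI, SITES, STIMULI, BehaviorEvent, TrialRecord
from .scoring import EthogramMap, WeightParams, load_ethogram

__all__ = ["SimConfig", "GroundTruth", "simulate_trials", "simulate_event_stream", "write_fixture"]

#: Per-site demographic composition (sexage level -> count), echoing the
#: field populations: low-exposure 19 (8 adult F, 4 adult M, 7 subadult M),
#: moderate 10, high 4.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, int]] = {
    "low_exposure": {"adult_female": 8, "adult_male": 4, "subadult_male": 7},
    "moderate_exposure": {"adult_female": 4, "adult_male": 4, "subadult_female": 2},
    "high_exposure": {"adult_female": 1, "adult_male": 2, "subadult_female": 1},
}

DEFAULT_EFFECTS: dict[tuple[str, str], float] = {
    ("low_exposure", "drone"): 4.3,
    ("low_exposure", "vehicle"): 5.3,
    ("low_exposure", "talking"): 1.9,
    ("moderate_exposure", "drone"): 1.1,
    ("moderate_exposure", "vehicle"): 0.9,
    ("moderate_exposure", "talking"): 1.3,
    ("high_exposure", "drone"): 0.4,
    ("high_exposure", "vehicle"): 0.2,
    ("high_exposure", "talking"): 0.2,
}


def _default_effects():
    return dict(DEFAULT_EFFECTS)


def _default_demographics():
    return {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    demographics: dict[str, dict[str, int]] = field(default_factory=_default_demographics)
    n_exemplars: int = 8
    #: dove + anthropogenic session pairs per individual (2 trials each)
    sessions_per_individual: int = 7
    effects: dict[tuple[str, str], float] = field(default_factory=_default_effects)
    intercept: float = 3.0  # mean dove response, kept off the clamp floor
    site_effects: dict[str, float] = field(default_factory=dict)
    beta_dist: float = -0.8  # stronger reactions at closer range, per SD
    beta_dist2: float = 0.0
    beta_group: float = -0.17
    beta_wind: float = 0.05
    beta_date: float = 0.0
    sexage_effects: dict[str, float] = field(default_factory=dict)
    sd_giraffe: float = 0.3
    sd_event: float = 0.5
    sd_exemplar: float = 0.3
    sd_resid: float = 1.3
    distance_range_m: tuple[float, float] = (30.0, 100.0)
    wind_range_kmh: tuple[float, float] = (0.0, 25.0)
    max_group_size: int = 15
    study_days: int = 335  # July 2023 - June 2024
    start_date: _dt.date = _dt.date(2023, 7, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_giraffe", "sd_event", "sd_exemplar", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.distance_range_m
        if not (30.0 <= lo <= hi <= 100.0):
            raise ValueError("distance support must lie within the 30-100 m inclusion window")
        if not any(sum(d.values()) > 0 for d in self.demographics.values()):
            raise ValueError("infeasible design: no individuals")


@dataclass
class GroundTruth:
    """Exact generating quantities for a simulated dataset."""

    intercept: float
    cell_effects: dict[str, float]  # "site:sound" -> effect vs dove at that site
    site_effects: dict[str, float]
    covariate_betas: dict[str, float]
    sexage_effects: dict[str, float]
    giraffe_intercepts: dict[str, float]
    event_intercepts: dict[str, float]
    exemplar_intercepts: dict[str, float]
    linear_predictor: dict[str, float]  # per trial, before noise
    latent: dict[str, float]  # per trial, after noise, before clamping
    clamp_fraction: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _split_sexage(level: str) -> tuple[str, str]:
    age, sex = level.rsplit("_", 1)
    return sex, age


def simulate_trials(
    config: SimConfig | None = None,
) -> tuple[list[TrialRecord], pd.DataFrame, GroundTruth]:
    """Draw a study-like trial table, feature table and its ground truth.

    Every individual participates in ``sessions_per_individual`` sessions of
    one dove and one anthropogenic playback (so same-individual dove controls
    always exist for matching).  Within a site, individuals are grouped 1-3
    per session round and co-observed group members share the playback event
    (and its random intercept), wind and date; speaker distance is redrawn
    per individual and per stimulus.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)

    # individuals
    giraffes: list[tuple[str, str, str]] = []  # (id, site, sexage)
    for site in SITES:
        comp = config.demographics.get(site, {})
        i = 0
        for sexage, count in comp.items():
            for _ in range(count):
                giraffes.append((f"G_{site[:3]}_{i:02d}", site, sexage))
                i += 1
    if not giraffes:
        raise ValueError("infeasible design: no individuals")

    u_giraffe = {g: rng.normal(0, config.sd_giraffe) for g, _, _ in giraffes}
    exemplar_ids = [f"{s}_{k + 1}" for s in STIMULI for k in range(config.n_exemplars)]
    u_exemplar = {e: rng.normal(0, config.sd_exemplar) for e in exemplar_ids}
    u_event: dict[str, float] = {}

    trials: list[TrialRecord] = []
    raw_rows: list[dict] = []
    event_counter = 0
    trial_counter = 0

    by_site: dict[str, list[tuple[str, str, str]]] = {s: [] for s in SITES}
    for g in giraffes:
        by_site[g[1]].append(g)

    # stratified randomization of the anthropogenic stimulus: a shuffled
    # per-site deck cycles through the three types, so every site hears every
    # type even in small designs (mirroring the field rotation of playback
    # packages)
    decks: dict[str, list[str]] = {s: [] for s in SITES}

    def draw_anthro(site: str) -> str:
        if not decks[site]:
            decks[site] = list(rng.permutation(ANTHROPOGENIC_STIMULI))
        return decks[site].pop()

    for site in SITES:
        members = by_site[site]
        if not members:
            continue
        for _round in range(config.sessions_per_individual):
            order = rng.permutation(len(members))
            pos = 0
            while pos < len(order):
                gsize = int(rng.integers(1, 4))
                group = [members[i] for i in order[pos : pos + gsize]]
                pos += gsize
                anthro = draw_anthro(site)
                day = int(rng.integers(0, config.study_days))
                wind = float(rng.uniform(*config.wind_range_kmh))
                first_is_dove = bool(rng.integers(0, 2))
                stim_order = ["dove", anthro] if first_is_dove else [anthro, "dove"]
                for which, stim in enumerate(stim_order):
                    event_counter += 1
                    event_id = f"V{event_counter:04d}"
                    u_event[event_id] = rng.normal(0, config.sd_event)
                    exemplar = f"{stim}_{int(rng.integers(1, config.n_exemplars + 1))}"
                    for gid, gsite, sexage in group:
                        trial_counter += 1
                        sex, age = _split_sexage(sexage)
                        extra = int(rng.integers(0, 4))
                        trials.append(
                            TrialRecord(
                                trial_id=f"T{trial_counter:04d}",
                                giraffe_id=gid,
                                playback_event_id=event_id,
                                exemplar_id=exemplar,
                                stimulus=stim,
                                site=gsite,
                                date=config.start_date + _dt.timedelta(days=day),
                                speaker_distance_m=float(
                                    rng.uniform(*config.distance_range_m)
                                ),
                                wind_speed_kmh=wind,
                                group_size=min(len(group) + extra, config.max_group_size),
                                sex=sex,
                                age_class=age,
                                order_in_session="first" if which == 0 else "second",
                            )
                        )

    # standardized covariates on the realized sample (population SD), matching
    # the design module's convention so the generating betas live on the same
    # scale the model estimates
    dist = np.array([t.speaker_distance_m for t in trials])
    wind = np.array([t.wind_speed_kmh for t in trials])
    gs = np.array([t.group_size for t in trials], dtype=float)
    days = np.array([(t.date - config.start_date).days for t in trials], dtype=float)

    def z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    dist_z, wind_z, gs_z, date_z = z(dist), z(wind), z(gs), z(days)

    lp = np.full(len(trials), config.intercept)
    for i, t in enumerate(trials):
        lp[i] += config.site_effects.get(t.site, 0.0)
        if t.stimulus != "dove":
            lp[i] += config.effects[(t.site, t.stimulus)]
        sexage = f"{t.age_class}_{t.sex}"
        lp[i] += config.sexage_effects.get(sexage, 0.0)
        lp[i] += u_giraffe[t.giraffe_id] + u_event[t.playback_event_id]
        lp[i] += u_exemplar[t.exemplar_id]
    lp = (
        lp
        + config.beta_dist * dist_z
        + config.beta_dist2 * dist_z**2
        + config.beta_group * gs_z
        + config.beta_wind * wind_z
        + config.beta_date * date_z
    )
    # lp above includes the random-effect realizations; keep the pure fixed
    # part separately for ground truth
    fixed_lp = lp - np.array(
        [
            u_giraffe[t.giraffe_id] + u_event[t.playback_event_id] + u_exemplar[t.exemplar_id]
            for t in trials
        ]
    )

    latent = lp + rng.normal(0, config.sd_resid, size=len(trials))
    response = np.clip(latent, 0.0, 12.0)
    clamp_fraction = float(np.mean((latent < 0) | (latent > 12)))

    # companion descriptive features: duration loosely tracks intensity,
    # latency shortens with intensity (plausible, not fitted quantities)
    duration = np.where(
        response >= 1.0,
        np.clip(response * rng.uniform(1.0, 6.0, len(trials)), 0, 180),
        0.0,
    )
    latency = np.where(
        response >= 1.0,
        np.clip(rng.exponential(6.0, len(trials)) / np.maximum(response / 4.0, 0.5), 0, 179).round(),
        np.nan,
    )
    cat = pd.cut(
        np.round(response).astype(int),
        bins=[-1, 5, 9, 12],
        labels=["A", "B", "C"],
    )
    features = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "latency_first_s": latency,
            "duration_s": duration,
            "reaction_intensity": response,
            "category": cat.astype(str),
        }
    )

    truth = GroundTruth(
        intercept=config.intercept,
        cell_effects={f"{si}:{so}": v for (si, so), v in config.effects.items()},
        site_effects={s: config.site_effects.get(s, 0.0) for s in SITES},
        covariate_betas={
            "dist_z": config.beta_dist,
            "dist_z2": config.beta_dist2,
            "group_size_z": config.beta_group,
            "wind_z": config.beta_wind,
            "date_z": config.beta_date,
        },
        sexage_effects=dict(config.sexage_effects),
        giraffe_intercepts=u_giraffe,
        event_intercepts=u_event,
        exemplar_intercepts=u_exemplar,
        linear_predictor={t.trial_id: float(v) for t, v in zip(trials, fixed_lp)},
        latent={t.trial_id: float(v) for t, v in zip(trials, latent)},
        clamp_fraction=clamp_fraction,
        seed=config.seed,
    )
    return trials, features, truth


def simulate_event_stream(
    latent_intensity: float,
    ethogram: EthogramMap | None = None,
    params: WeightParams | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "sim",
) -> list[BehaviorEvent]:
    """Emit a behavior event log whose pipeline score recovers the latent.

    The score-carrying behavior has intensity ``round(latent)`` and an onset
    well inside the full-weight region (< 7 s), so the recovered
    time-weighted score differs from the latent by at most the rounding gap
    of 0.5.  Up to two strictly weaker distinct distractor behaviors and a
    background maintenance (score-0) bout are added for realism.
    """
    if not 0.0 <= latent_intensity <= 12.0:
        raise ValueError("latent intensity must be within 0..12")
    if ethogram is None:
        ethogram = load_ethogram()
    if params is None:
        params = WeightParams()
    if rng is None:
        rng = np.random.default_rng()

    events: list[BehaviorEvent] = []
    # background maintenance behavior from onset
    events.append(BehaviorEvent(trial_id, "continues feeding/ruminating", 0.0, 180.0))

    main = int(round(latent_intensity))
    if main < 1:
        return events

    # flight-grade reactions are effectively immediate
    hi = 2.0 if main >= 12 else 6.9
    onset = float(rng.uniform(0.3, hi))
    code = ethogram.code_for(main)
    events.append(BehaviorEvent(trial_id, code, onset, onset + float(rng.uniform(2, 10))))

    weaker = list(range(1, main))
    n_distract = min(int(rng.integers(0, 3)), len(weaker)) if weaker else 0
    picks = (
        rng.choice(weaker, size=n_distract, replace=False) if n_distract else np.array([])
    )
    for intensity in np.atleast_1d(picks):
        t0 = float(rng.uniform(0.3, 30.0))
        events.append(
            BehaviorEvent(
                trial_id,
                ethogram.code_for(int(intensity)),
                t0,
                t0 + float(rng.uniform(1, 5)),
            )
        )
    events.sort(key=lambda e: e.onset_s)
    return events


def write_fixture(
    outdir: str | Path, config: SimConfig | None = None
) -> tuple[Path, Path]:
    """Write a simulated dataset in the CSV formats the ingest module reads.

    Event logs are generated from each trial's latent feature intensity, so
    re-scoring the events reproduces the feature table (within rounding).
    Returns (events_path, trials_path).
    """
    if config is None:
        config = SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, features, truth = simulate_trials(config)
    rng = np.random.default_rng(config.seed + 1)
    ethogram = load_ethogram()

    rows = []
    for t, intensity in zip(trials, features["reaction_intensity"]):
        for ev in simulate_event_stream(
            float(intensity), ethogram, rng=rng, trial_id=t.trial_id
        ):
            rows.append(
                {
                    "trial_id": ev.trial_id,
                    "behavior": ev.behavior_code,
                    "onset_s": round(ev.onset_s, 3),
                    "offset_s": round(ev.offset_s, 3),
                }
            )
    events_path = outdir / "events.csv"
    pd.DataFrame(rows).to_csv(events_path, index=False)

    trials_path = outdir / "trials.csv"
    pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "giraffe_id": [t.giraffe_id for t in trials],
            "playback_event_id": [t.playback_event_id for t in trials],
            "exemplar_id": [t.exemplar_id for t in trials],
            "stimulus": [t.stimulus for t in trials],
            "site": [t.site for t in trials],
            "date": [t.date.isoformat() for t in trials],
            "speaker_distance_m": [t.speaker_distance_m for t in trials],
            "wind_speed_kmh": [t.wind_speed_kmh for t in trials],
            "group_size": [t.group_size for t in trials],
            "sex": [t.sex for t in trials],
            "age_class": [t.age_class for t in trials],
            "order_in_session": [t.order_in_session for t in trials],
            "disturbance_look_s": [t.disturbance_look_s for t in trials],
            "moved_from_disturbance": [t.moved_from_disturbance for t in trials],
        }
    ).to_csv(trials_path, index=False)
    truth.to_json(outdir / "ground_truth.json")
    return events_path, trials_path
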