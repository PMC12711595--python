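"""End-to-end orchestration: ingest -> scoring -> design -> models -> reports.

Every stage output is written as CSV into the run's output directory together
with a manifest (input hashes, seed, package version), so a run is a pure
function of (inputs, config, seed): non-MCMC outputs are bit-identical across
re-runs and MCMC summaries are identical given the fixed sampler seed.

Also houses small stimulus-metadata utilities (playback SPL midpoints) and
the descriptive duration summary.  Duration analyses are run alongside
intensity but flagged "secondary" in the report: duration is highly variable
across trials and intensity is the more reliable behavioral metric.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import FactorCoding, build_design
from .ingest import (
    ANTHROPOGENIC_STIMULI,
    SITES,
    apply_trial_filters,
    read_events,
    read_trials,
)
from .matching import (
    MatchConfig,
    difference_scores,
    fit_matched_model,
    match_controls,
    pairs_to_frame,
)
from .model import (
    ModelSpec,
    between_site_contrast,
    fit_lmm,
    partial_dependence,
    within_site_contrast,
)
from .scoring import WeightParams, compute_trial_features, features_to_frame, load_ethogram

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "spl_midpoint", "summarize_durations"]

log = logging.getLogger("vigiplay")


@dataclass
class RunConfig:
    events_path: str
    trials_path: str
    output_dir: str
    response: str = "reaction_intensity"
    seed: int = 20230701
    weight: WeightParams = field(default_factory=WeightParams)
    match: MatchConfig = field(default_factory=MatchConfig)
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    ethogram_path: str | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        weight = WeightParams(**raw.pop("weight", {}))
        match = MatchConfig(**raw.pop("match", {}))
        return cls(weight=weight, match=match, **raw)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.seed,
        )

    def validate(self) -> None:
        for name in ("events_path", "trials_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")


@dataclass
class PipelineResult:
    outputs: dict[str, Path]
    manifest: dict


def spl_midpoint(range_low_db: float, range_high_db: float) -> int:
    """Mean playback SPL: midpoint of the calibrated range, nearest integer."""
    if range_low_db > range_high_db:
        raise ValueError(f"SPL range inverted: {range_low_db} > {range_high_db}")
    return int(math.floor((range_low_db + range_high_db) / 2.0 + 0.5))


#: Calibrated within-exemplar playback SPL ranges (dB) per stimulus type.
PLAYBACK_SPL_RANGES_DB: dict[str, tuple[float, float]] = {
    "drone": (68.0, 78.0),
    "vehicle": (55.0, 64.0),
    "talking": (58.0, 68.0),
    "dove": (65.0, 73.0),
}


def summarize_durations(
    features: pd.DataFrame, trials, group_by: tuple[str, str] = ("site", "stimulus")
) -> pd.DataFrame:
    """Per site x stimulus cell: mean, sample SD (n-1) and n of duration_s.

    Empty cells get n = 0 with absent mean/SD; singleton cells get SD 0 with
    a warning.
    """
    meta = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "site": [t.site for t in trials],
            "stimulus": [t.stimulus for t in trials],
        }
    )
    df = meta.merge(features[["trial_id", "duration_s"]], on="trial_id", how="left")
    rows = []
    for site in SITES:
        for stim in ("dove",) + ANTHROPOGENIC_STIMULI:
            vals = df.loc[(df["site"] == site) & (df["stimulus"] == stim), "duration_s"]
            vals = vals.dropna()
            n = len(vals)
            if n == 0:
                rows.append({"site": site, "stimulus": stim, "mean": np.nan, "sd": np.nan, "n": 0})
            elif n == 1:
                warnings.warn(
                    f"duration cell ({site}, {stim}) has a single trial; SD set to 0",
                    stacklevel=2,
                )
                rows.append(
                    {"site": site, "stimulus": stim, "mean": float(vals.iloc[0]), "sd": 0.0, "n": 1}
                )
            else:
                rows.append(
                    {
                        "site": site,
                        "stimulus": stim,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write all stage outputs plus a manifest."""
    logging.basicConfig(level=config.verbosity)
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    ethogram = load_ethogram(config.ethogram_path)

    log.info("stage ingest: reading %s", config.events_path)
    events = read_events(config.events_path, ethogram.entries.keys())
    trials = read_trials(config.trials_path)
    included, excluded = apply_trial_filters(trials)
    log.info("stage filter: %d included, %d excluded", len(included), len(excluded))
    pd.DataFrame(
        {
            "trial_id": [e.trial.trial_id for e in excluded],
            "reason": [e.reason for e in excluded],
        }
    ).to_csv(outdir / "excluded_trials.csv", index=False)
    outputs["excluded_trials"] = outdir / "excluded_trials.csv"

    log.info("stage scoring: %d trials", len(included))
    by_trial: dict[str, list] = {}
    for ev in events:
        by_trial.setdefault(ev.trial_id, []).append(ev)
    feats = [
        compute_trial_features(by_trial.get(t.trial_id, []), ethogram, config.weight)
        for t in included
    ]
    # compute_trial_features leaves trial_id empty for event-less trials
    feats = [
        f if f.trial_id else type(f)(t.trial_id, None, 0.0, 0.0, "A")
        for f, t in zip(feats, included)
    ]
    features = features_to_frame(feats)
    features.to_csv(outdir / "features.csv", index=False)
    outputs["features"] = outdir / "features.csv"

    log.info("stage design + raw model")
    design = build_design(included, features, response=config.response)
    fit = fit_lmm(design, config.model_spec())
    fit.summary.to_csv(outdir / "posterior_summary.csv")
    outputs["posterior_summary"] = outdir / "posterior_summary.csv"

    log.info("stage contrasts")
    rows = []
    for site in SITES:
        for sound in ANTHROPOGENIC_STIMULI:
            c = within_site_contrast(fit, site, sound, "dove")
            rows.append(
                {
                    "label": c.label,
                    "mu_diff": c.mu_diff,
                    "cri_low": c.cri_low,
                    "cri_high": c.cri_high,
                    "supported": c.supported,
                }
            )
    for sound in ANTHROPOGENIC_STIMULI:
        for site_a, site_b in (
            ("low_exposure", "moderate_exposure"),
            ("low_exposure", "high_exposure"),
            ("moderate_exposure", "high_exposure"),
        ):
            c = between_site_contrast(fit, sound, site_a, site_b)
            rows.append(
                {
                    "label": c.label,
                    "mu_diff": c.mu_diff,
                    "cri_low": c.cri_low,
                    "cri_high": c.cri_high,
                    "supported": c.supported,
                }
            )
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    outputs["contrasts"] = outdir / "contrasts.csv"

    partial_dependence(fit).to_csv(outdir / "partial_dependence.csv", index=False)
    outputs["partial_dependence"] = outdir / "partial_dependence.csv"

    log.info("stage matching")
    tests = [t for t in included if t.stimulus in ANTHROPOGENIC_STIMULI]
    doves = [t for t in included if t.stimulus == "dove"]
    pairs, unmatched = match_controls(tests, doves, config.match)
    pairs = difference_scores(pairs, features)
    pairs_to_frame(pairs).to_csv(outdir / "matched_pairs.csv", index=False)
    unmatched.to_csv(outdir / "unmatched.csv", index=False)
    outputs["matched_pairs"] = outdir / "matched_pairs.csv"
    outputs["unmatched"] = outdir / "unmatched.csv"

    log.info("stage matched model")
    matched_spec = ModelSpec(
        response="diff_score",
        chains=config.chains,
        iterations=config.iterations,
        warmup=config.warmup,
        seed=config.seed + 1,
    )
    matched = fit_matched_model(pairs, included, matched_spec)
    matched.to_csv(outdir / "matched_model.csv", index=False)
    outputs["matched_model"] = outdir / "matched_model.csv"

    log.info("stage report")
    durations = summarize_durations(features, included)
    durations.to_csv(outdir / "duration_summary.csv", index=False)
    outputs["duration_summary"] = outdir / "duration_summary.csv"

    spl = pd.DataFrame(
        {
            "stimulus": list(PLAYBACK_SPL_RANGES_DB),
            "range_low_db": [v[0] for v in PLAYBACK_SPL_RANGES_DB.values()],
            "range_high_db": [v[1] for v in PLAYBACK_SPL_RANGES_DB.values()],
            "mean_spl_db": [spl_midpoint(*v) for v in PLAYBACK_SPL_RANGES_DB.values()],
        }
    )
    spl.to_csv(outdir / "spl_midpoints.csv", index=False)
    outputs["spl_midpoints"] = outdir / "spl_midpoints.csv"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "response": config.response,
        "note": "duration analyses are secondary; intensity is the primary response",
        "inputs": {
            "events": _sha256(Path(config.events_path)),
            "trials": _sha256(Path(config.trials_path)),
        },
        "outputs": {k: _sha256(p) for k, p in outputs.items()},
        "n_included": len(included),
        "n_excluded": len(excluded),
        "n_pairs": len(pairs),
        "max_rhat": float(fit.summary["rhat"].max()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = outdir / "manifest.json"
    return PipelineResult(outputs=outputs, manifest=manifest)
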