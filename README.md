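# vigiplay

Analysis pipeline for acoustic playback experiments on wildlife vigilance —
built around a multisite study of free-ranging giraffes presented with
anthropogenic noise (drone, vehicle engine, people talking) and a natural
control (ring-necked dove) across three reserves differing in human
exposure. It takes BORIS-style behavioral event logs and trial metadata and
produces the study's statistical results end to end: the time-weighted
reaction-intensity statistic, Bayesian linear mixed models with crossed
random intercepts and site × stimulus contrasts, and a Mahalanobis-matched
within-individual pseudo-control comparison. A synthetic-data generator with
exact ground truth makes every stage testable without field data.

Intended users: behavioral ecologists and biostatisticians running or
re-analyzing playback experiments with repeated measures, shared playback
events, and reused stimulus exemplars.

## The statistics at the core

**Response.** Each trial's behavior bouts are rasterized to one-zero 1-s
samples over a 180-s window. Behaviors map to a 0–12 reaction index
(0 = continues feeding, 12 = flight; categories A = 0–5, B = 6–9,
C = 10–12). The primary response down-weights late reactions with a
decreasing logistic of latency centered at t₀ = 12 s,

    w(t) = 1 / (1 + exp(k (t − t₀))),   k = ln(19)/3  (w(9) = 0.95, w(15) = 0.05)

and takes, over the first three distinct reacting behaviors, the maximum of
intensity × w(latency).

**Raw model.** y = Xβ + u_giraffe + u_event + u_exemplar + ε with crossed
random intercepts and fixed effects sound × site, standardized group size,
wind, a degree-2 speaker-distance polynomial, date standardized within
site × sound, and a 4-level sex-age factor; weakly informative priors;
blocked Gibbs sampling with collapsed variance-component updates (split-Rhat
checked against 1.01). Contrasts μ_diff = E[Y | site, sound_a] −
E[Y | site, sound_b] are computed from the posterior draws at covariate
means, sex-age averaged with equal weights; an effect is supported when the
95% credible interval excludes zero.

**Matched analysis.** Each anthropogenic trial is paired with its most
similar same-individual dove trial by Mahalanobis distance over wind,
distance, group size and date (date up-weighted ×3 by default); difference
scores (test − control) are modeled per sound × site cell with a
per-individual random intercept.

## Worked example

```python
import vigiplay as v

ethogram = v.load_ethogram()
params = v.WeightParams()
events = [
    v.BehaviorEvent("T1", "continues feeding/ruminating", 0.0, 180.0),
    v.BehaviorEvent("T1", "one ear moves", 2.4, 3.9),
    v.BehaviorEvent("T1", "stops chewing/ruminating and looks", 4.3, 21.0),
    v.BehaviorEvent("T1", "run away", 25.0, 40.0),
]
print(v.compute_trial_features(events, ethogram, params))
```

prints

```
TrialFeatures(trial_id='T1', latency_first_s=2.0, duration_s=32.0,
              reaction_intensity=5.997666688485197, category='B')
```

Reading: the first reacting behavior (an ear movement, intensity 1) starts
in second 2; intensity ≥ 6 behaviors are active for 32 s (looking 4–20 s,
flight 25–39 s). The score is driven by "stops chewing and looks"
(intensity 6) at 4 s latency: 6 × w(4) = 6 × 0.9996 ≈ 5.998. The flight
(intensity 12) at 25 s is annulled by the weight (w(25) ≈ 3e-6) — a
delayed departure is not treated as a direct reaction to the stimulus.
Category B: cessation of natural behavior with sustained attention.

For a full run — simulate a study, score it, fit both models, match,
report — use the CLI:

```
vigiplay simulate --outdir fixture --seed 1
vigiplay run-all --config run.yaml     # paths + seed + options in YAML
```

or `run_pipeline(RunConfig(...))` from Python. Every run writes features,
posterior summaries, contrast and matched-pair CSVs plus a manifest with
input hashes and the seed; re-runs with the same inputs and seed reproduce
the outputs.

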