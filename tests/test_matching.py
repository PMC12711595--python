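"""Mahalanobis matching, difference scores, and the matched-design model."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from vigiplay.matching import (
    MatchConfig,
    MatchedPair,
    difference_scores,
    fit_matched_model,
    mahalanobis_distance,
    match_controls,
    match_sensitivity,
    matching_covariates,
)
from tests.test_ingest import make_trial


class TestMahalanobisDistance:
    def test_identical_points_zero(self):
        assert mahalanobis_distance([1, 2], [1, 2], np.eye(2)) == 0.0

    def test_identity_covariance_is_euclidean(self):
        got = mahalanobis_distance([0, 0], [3, 4], np.eye(2))
        assert got == pytest.approx(5.0)

    def test_hand_computed_quadratic_form(self):
        # diff (1,1), Sigma = diag(2, 0.5) -> sqrt(1/2 + 2) = sqrt(2.5)
        cov_inv = np.linalg.inv(np.diag([2.0, 0.5]))
        got = mahalanobis_distance([1, 1], [0, 0], cov_inv)
        assert got == pytest.approx(1.5811, abs=1e-4)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            mahalanobis_distance([1, 0], [0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            mahalanobis_distance([1, 0], [0, 0], np.array([[1.0, 0.5], [0.0, 1.0]]))


def _matched_universe(rng, n_tests=50, n_candidates=10, n_giraffes=10):
    """Anthropogenic trials with same-individual dove candidate pools."""
    d0 = dt.date(2023, 7, 1)
    tests, doves = [], []
    i = 0
    for g in range(n_giraffes):
        gid = f"G{g}"
        for _ in range(n_tests // n_giraffes):
            i += 1
            tests.append(
                make_trial(
                    trial_id=f"X{i:03d}",
                    giraffe_id=gid,
                    stimulus="drone",
                    exemplar_id="drone_1",
                    date=d0 + dt.timedelta(days=int(rng.integers(0, 300))),
                    speaker_distance_m=float(rng.uniform(30, 100)),
                    wind_speed_kmh=float(rng.uniform(0, 25)),
                    group_size=int(rng.integers(1, 12)),
                )
            )
        for k in range(int(rng.integers(1, n_candidates + 1))):
            doves.append(
                make_trial(
                    trial_id=f"D{g:02d}{k:02d}",
                    giraffe_id=gid,
                    stimulus="dove",
                    exemplar_id="dove_1",
                    date=d0 + dt.timedelta(days=int(rng.integers(0, 300))),
                    speaker_distance_m=float(rng.uniform(30, 100)),
                    wind_speed_kmh=float(rng.uniform(0, 25)),
                    group_size=int(rng.integers(1, 12)),
                )
            )
    return tests, doves


def brute_force_pairs(tests, doves, config):
    """Independent exhaustive minimizer with the stated tie-breaks."""
    table = matching_covariates(list(tests) + list(doves))
    Z = table[list(config.covariates)].to_numpy()
    cov = np.cov(Z, rowvar=False) + config.ridge * np.eye(len(config.covariates))
    ci = np.linalg.inv(cov)
    w = np.array([config.date_weight if c == "date_z" else 1.0 for c in config.covariates])
    out = {}
    for t in tests:
        best = None
        for c in doves:
            if c.giraffe_id != t.giraffe_id:
                continue
            d = (
                table.loc[t.trial_id, list(config.covariates)].to_numpy(dtype=float)
                - table.loc[c.trial_id, list(config.covariates)].to_numpy(dtype=float)
            ) * w
            dist = float(np.sqrt(d @ ci @ d))
            key = (dist, abs(table.loc[t.trial_id, "day"] - table.loc[c.trial_id, "day"]), c.trial_id)
            if best is None or key < best[0]:
                best = (key, c.trial_id, dist)
        if best is not None:
            out[t.trial_id] = (best[1], best[2])
    return out


class TestMatchControls:
    def test_single_candidate_always_selected(self):
        rng = np.random.default_rng(1)
        tests, _ = _matched_universe(rng, n_tests=1, n_giraffes=1)
        dove = make_trial(
            trial_id="D1", giraffe_id="G0", stimulus="dove", exemplar_id="dove_1",
            speaker_distance_m=99.0, wind_speed_kmh=24.0, group_size=12,
        )
        extra = make_trial(
            trial_id="D2", giraffe_id="OTHER", stimulus="dove", exemplar_id="dove_1"
        )
        pairs, unmatched = match_controls(tests, [dove, extra])
        assert len(pairs) == 1 and pairs[0].control_trial_id == "D1"
        assert unmatched.empty

    def test_brute_force_oracle_equivalence(self):
        pairs_cfg = MatchConfig()
        rng = np.random.default_rng(2)
        tests, doves = _matched_universe(rng, n_tests=50, n_candidates=10)
        pairs, _ = match_controls(tests, doves, pairs_cfg)
        oracle = brute_force_pairs(tests, doves, pairs_cfg)
        assert len(pairs) == len(oracle)
        for p in pairs:
            cid, dist = oracle[p.test_trial_id]
            assert p.control_trial_id == cid
            assert p.distance == pytest.approx(dist)

    def test_tie_break_prefers_temporally_closer(self):
        d0 = dt.date(2023, 7, 1)
        t = make_trial(
            trial_id="X1", giraffe_id="G0", stimulus="drone", exemplar_id="drone_1",
            date=d0 + dt.timedelta(days=100), speaker_distance_m=60, wind_speed_kmh=10,
            group_size=5,
        )
        # two controls symmetric in date (90 vs 120 days), identical otherwise
        near = make_trial(
            trial_id="D_far_id", giraffe_id="G0", stimulus="dove", exemplar_id="dove_1",
            date=d0 + dt.timedelta(days=110), speaker_distance_m=60, wind_speed_kmh=10,
            group_size=5,
        )
        far = make_trial(
            trial_id="D_aaa", giraffe_id="G0", stimulus="dove", exemplar_id="dove_1",
            date=d0 + dt.timedelta(days=80), speaker_distance_m=60, wind_speed_kmh=10,
            group_size=5,
        )
        pairs, _ = match_controls([t], [near, far])
        assert pairs[0].control_trial_id == "D_far_id"  # 10 days beats 20 days

    def test_unmatched_reported_and_excluded(self):
        t = make_trial(trial_id="X1", giraffe_id="LONER", stimulus="drone", exemplar_id="drone_1")
        other_doves = [
            make_trial(trial_id=f"D{i}", giraffe_id="G0", stimulus="dove", exemplar_id="dove_1",
                       speaker_distance_m=30 + i, wind_speed_kmh=float(i), group_size=1 + i)
            for i in range(3)
        ]
        pairs, unmatched = match_controls([t], other_doves)
        assert pairs == []
        assert list(unmatched["test_trial_id"]) == ["X1"]
        assert unmatched["reason"].iloc[0] == "no_same_individual_control"

    def test_extreme_date_weight_degenerates_to_nearest_date(self):
        rng = np.random.default_rng(4)
        tests, doves = _matched_universe(rng, n_tests=10, n_candidates=8)
        cfg = MatchConfig(date_weight=1e6)
        pairs, _ = match_controls(tests, doves, cfg)
        table = matching_covariates(tests + doves)
        for p in pairs:
            t_day = table.loc[p.test_trial_id, "day"]
            cand = [d for d in doves if d.giraffe_id == table.loc[p.test_trial_id, "giraffe_id"]]
            best_gap = min(abs(table.loc[c.trial_id, "day"] - t_day) for c in cand)
            got_gap = abs(table.loc[p.control_trial_id, "day"] - t_day)
            assert got_gap == best_gap

    def test_without_replacement_controls_unique(self):
        rng = np.random.default_rng(5)
        tests, doves = _matched_universe(rng, n_tests=20, n_candidates=4)
        pairs, unmatched = match_controls(tests, doves, MatchConfig(replacement=False))
        controls = [p.control_trial_id for p in pairs]
        assert len(controls) == len(set(controls))
        assert len(pairs) + len(unmatched) == len(tests)

    def test_matching_is_deterministic(self):
        rng = np.random.default_rng(6)
        tests, doves = _matched_universe(rng)
        p1, _ = match_controls(tests, doves)
        p2, _ = match_controls(tests, doves)
        assert p1 == p2

    def test_within_individual_pairs_share_giraffe(self):
        rng = np.random.default_rng(7)
        tests, doves = _matched_universe(rng)
        pairs, _ = match_controls(tests, doves)
        gid = {t.trial_id: t.giraffe_id for t in tests + doves}
        assert all(gid[p.test_trial_id] == gid[p.control_trial_id] for p in pairs)


class TestDifferenceScores:
    @pytest.mark.parametrize(
        "test_y,control_y,expected", [(6.0, 6.0, 0.0), (5.99, 0.0, 5.99), (0.0, 4.0, -4.0)]
    )
    def test_sign_convention(self, test_y, control_y, expected):
        feats = pd.DataFrame(
            {"trial_id": ["X1", "D1"], "reaction_intensity": [test_y, control_y]}
        )
        out = difference_scores([MatchedPair("X1", "D1", 0.5)], feats)
        assert out[0].diff_score == pytest.approx(expected)

    def test_missing_feature_names_pair(self):
        feats = pd.DataFrame({"trial_id": ["X1"], "reaction_intensity": [1.0]})
        with pytest.raises(KeyError, match="D1"):
            difference_scores([MatchedPair("X1", "D1", 0.5)], feats)


class TestMatchedModel:
    def _pairs_and_trials(self, diffs_by_cell, n_per_cell=8, seed=0):
        rng = np.random.default_rng(seed)
        trials, pairs = [], []
        i = 0
        for (snd, site), mu in diffs_by_cell.items():
            for k in range(n_per_cell):
                i += 1
                tid = f"X{i:03d}"
                trials.append(
                    make_trial(
                        trial_id=tid, giraffe_id=f"G{i % 6}", stimulus=snd,
                        exemplar_id=f"{snd}_1", site=site,
                        sex=["female", "male"][i % 2],
                    )
                )
                pairs.append(
                    MatchedPair(tid, f"D{i:03d}", 0.1, mu + float(rng.normal(0, 0.5)))
                )
        return pairs, trials

    def test_null_differences_give_null_effects(self):
        cells = {(s, "low_exposure"): 0.0 for s in ("drone", "vehicle", "talking")}
        pairs, trials = self._pairs_and_trials(cells, seed=1)
        from vigiplay.model import ModelSpec

        out = fit_matched_model(
            pairs, trials, ModelSpec(chains=2, iterations=1000, warmup=500, seed=2)
        )
        assert (~out["supported"]).all()
        assert out["beta"].abs().max() < 0.8

    def test_built_in_effect_detected(self):
        cells = {
            ("drone", "low_exposure"): 4.0,
            ("vehicle", "low_exposure"): 0.0,
        }
        pairs, trials = self._pairs_and_trials(cells, n_per_cell=12, seed=3)
        from vigiplay.model import ModelSpec

        out = fit_matched_model(
            pairs, trials, ModelSpec(chains=2, iterations=1000, warmup=500, seed=4)
        ).set_index(["sound", "site"])
        drone = out.loc[("drone", "low_exposure")]
        assert drone["supported"] and drone["cri_low"] > 0
        assert drone["beta"] == pytest.approx(4.0, abs=1.0)

    def test_empty_cells_absent_not_zero(self):
        cells = {("drone", "low_exposure"): 1.0}
        pairs, trials = self._pairs_and_trials(cells, seed=5)
        from vigiplay.model import ModelSpec

        out = fit_matched_model(
            pairs, trials, ModelSpec(chains=2, iterations=600, warmup=300, seed=6)
        )
        assert len(out) == 1  # only the populated cell is reported


class TestSensitivity:
    def test_weight_grid_report_shape(self):
        rng = np.random.default_rng(8)
        tests, doves = _matched_universe(rng, n_tests=10, n_candidates=5)
        rep = match_sensitivity(tests, doves, weights=(1.0, 3.0, 10.0))
        assert list(rep["date_weight"]) == [1.0, 3.0, 10.0]
        assert (rep["n_pairs"] == len(tests)).all()
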