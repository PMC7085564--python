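from datetime import date

import numpy as np
import pandas as pd
import pytest

from stdd import block1
from stdd.features import extract_features, feature_matrix
from stdd.sensing_io import MS_PER_HOUR, MS_PER_MIN, empty_frame, local_to_ms

DAY = date(2023, 3, 6)
DAY0 = local_to_ms(pd.Timestamp(DAY))


# ---------------------------------------------------------------------------
# Sleep scoring

class TestScoreSleep:
    def test_anchor_durations(self):
        assert block1.score_sleep(3.0) == 1
        assert block1.score_sleep(11.0) == 1
        assert block1.score_sleep(7.0) == 10

    def test_linear_interpolation(self):
        assert block1.score_sleep(5.0) == 6  # round-half-up of 5.5
        assert block1.score_sleep(9.0) == 6
        assert block1.score_sleep(6.0) == 8  # 10 - 2.25

    def test_symmetry_about_baseline(self):
        for d in np.arange(0, 7.01, 0.25):
            assert block1.score_sleep(7 + d) == block1.score_sleep(7 - d)

    def test_monotone_in_deviation(self):
        devs = np.arange(0, 7.01, 0.1)
        scores = [block1.score_sleep(7 + d) for d in devs]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(1 <= s <= 10 for s in scores)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            block1.score_sleep(-1.0)


# ---------------------------------------------------------------------------
# Sleep detection fixtures

def night_light(dark_ranges, lux_dark=5.0, lux_bright=500.0):
    """Per-minute light samples over 22:00-10:00; dark in given hour ranges
    (hours are offsets from the day start, so 23.0 is 11 p.m. and 30.5 is
    6:30 a.m. next day)."""
    rows = []
    t0 = DAY0 + int(22 * MS_PER_HOUR)
    for m in range(12 * 60):
        t = t0 + m * MS_PER_MIN
        h = 22 + m / 60.0
        dark = any(lo <= h < hi for lo, hi in dark_ranges)
        rows.append({"timestamp": t, "lux": lux_dark if dark else lux_bright})
    return pd.DataFrame(rows)


class TestDetectSleep:
    def test_clean_night(self):
        """Dark, static and unused 23:00-06:30 yields 7.5 hours."""
        light = night_light([(23.0, 30.5)])
        dur = block1.detect_sleep(light, empty_frame("events"),
                                  empty_frame("accel"), DAY)
        assert dur == pytest.approx(7.5, abs=0.02)

    def test_screen_burst_splits_runs(self):
        """A 03:00 screen-on splits 23:00-08:00 and the longest run wins."""
        light = night_light([(23.0, 32.0)])
        events = pd.DataFrame({
            "timestamp": [DAY0 + 27 * MS_PER_HOUR],  # 03:00
            "kind": ["screen_on"]})
        dur = block1.detect_sleep(light, events, empty_frame("accel"), DAY)
        assert dur == pytest.approx(5.0, abs=0.05)  # the 03:01-08:00 run

    def test_fully_bright_night(self):
        light = night_light([])
        assert block1.detect_sleep(light, empty_frame("events"),
                                   empty_frame("accel"), DAY) == 0.0

    def test_motion_breaks_eligibility(self):
        light = night_light([(23.0, 31.0)])
        # vigorous phone movement around 02:00 for 5 minutes
        t0 = DAY0 + 26 * MS_PER_HOUR
        n = 5 * 60 * 10
        rng = np.random.default_rng(0)
        accel = pd.DataFrame({
            "timestamp": t0 + np.arange(n) * 100,
            "x": rng.normal(0, 2.0, n), "y": rng.normal(0, 2.0, n),
            "z": 9.81 + rng.normal(0, 2.0, n)})
        dur = block1.detect_sleep(light, empty_frame("events"), accel, DAY)
        # longest run is 02:05-07:00 (about 4.9 h), not the full 8 h
        assert dur == pytest.approx(4.92, abs=0.1)

    def test_duration_bounded_by_night_window(self):
        light = night_light([(22.0, 34.0)], lux_dark=0.0)
        dur = block1.detect_sleep(light, empty_frame("events"),
                                  empty_frame("accel"), DAY)
        assert dur <= 12.0


# ---------------------------------------------------------------------------
# Social activity

def calls_frame(rows):
    return pd.DataFrame(rows, columns=["start", "direction", "duration_s"])


def apps_frame(rows):
    return pd.DataFrame(rows, columns=["start", "app_id", "is_social",
                                       "duration_s"])


class TestSocial:
    def test_empty_day_scores_zero(self):
        assert block1.social_score(empty_frame("calls"),
                                   empty_frame("apps"), DAY) == 0.0

    def test_weighted_sum_formula(self):
        calls = calls_frame([
            [DAY0 + 10 * MS_PER_HOUR, "incoming", 300.0],
            [DAY0 + 11 * MS_PER_HOUR, "incoming", 300.0]])
        apps = apps_frame([[DAY0 + 12 * MS_PER_HOUR, "a", 1, 300.0]])
        # 10 * (2 calls + 1 session) + (10 + 5) minutes = 45
        assert block1.social_score(calls, apps, DAY) == pytest.approx(45.0)

    def test_non_social_apps_ignored(self):
        apps = apps_frame([[DAY0 + 12 * MS_PER_HOUR, "game", 0, 600.0]])
        assert block1.social_score(empty_frame("calls"), apps, DAY) == 0.0

    def test_homogeneity(self):
        calls = calls_frame([[DAY0 + 9 * MS_PER_HOUR, "outgoing", 120.0],
                             [DAY0 + 10 * MS_PER_HOUR, "incoming", 60.0]])
        apps = apps_frame([[DAY0 + 12 * MS_PER_HOUR, "a", 1, 240.0]])
        single = block1.social_score(calls, apps, DAY)
        doubled = block1.social_score(
            pd.concat([calls, calls.assign(start=calls["start"] + 1000)]),
            pd.concat([apps, apps.assign(start=apps["start"] + 1000)]), DAY)
        assert doubled == pytest.approx(2 * single)

    def test_other_days_excluded(self):
        calls = calls_frame([[DAY0 - 1000, "incoming", 600.0]])
        assert block1.social_score(calls, empty_frame("apps"), DAY) == 0.0

    def test_social_level_minmax(self):
        d1, d2, d3 = DAY, date(2023, 3, 7), date(2023, 3, 8)
        raws = {d1: 0.0, d2: 45.0, d3: 90.0}
        assert block1.social_level(raws, d3) == 10
        assert block1.social_level(raws, d2) == 6  # round-half-up of 5.5
        assert block1.social_level(raws, d1) == 1

    def test_social_level_constant_series(self):
        raws = {DAY: 30.0, date(2023, 3, 7): 30.0}
        assert block1.social_level(raws, DAY) == 5


def test_food_level_pass_through():
    assert block1.food_level(4) == 4
    assert block1.food_level(np.nan) is None
    assert block1.food_level(None) is None
    with pytest.raises(ValueError):
        block1.food_level(12)


# ---------------------------------------------------------------------------
# Personal models

class _FixedPredictor:
    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def predict(self, X):
        return self.preds[:len(X)]


def fixed_model(preds):
    return block1.PersonalModel("physical", "rf", _FixedPredictor(preds), 5)


class TestPredictPeriodLevel:
    def test_unanimous(self):
        model = fixed_model([6] * 10)
        assert block1.predict_period_level(model, np.zeros((10, 5))) == 6

    def test_tie_breaks_low(self):
        model = fixed_model([3] * 10 + [7] * 10)
        assert block1.predict_period_level(model, np.zeros((20, 5))) == 3

    def test_majority(self):
        model = fixed_model([2] * 5 + [8] * 7)
        assert block1.predict_period_level(model, np.zeros((12, 5))) == 8

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            block1.predict_period_level(fixed_model([1]), np.empty((0, 5)))


class TestTrainPersonalModel:
    def test_single_label_constant_model(self, caplog):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with caplog.at_level("WARNING"):
            m = block1.train_personal_model(X, np.full(20, 4), "physical")
        assert isinstance(m.estimator, block1.ConstantModel)
        assert (m.predict(X) == 4).all()
        assert "constant" in caplog.text

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 10))
        y = rng.integers(1, 5, size=100)
        probe = rng.normal(size=(30, 10))
        p1 = block1.train_personal_model(X, y, "mood", seed=9).predict(probe)
        p2 = block1.train_personal_model(X, y, "mood", seed=9).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("algo", ["rf", "svm"])
    def test_separable_synthetic_participant(self, tiny_participant, algo):
        """Strong level -> signal coupling trains to >= 95 % accuracy."""
        feats = extract_features(tiny_participant)
        X, y = feature_matrix(feats, "physical")
        model = block1.train_personal_model(X, y, "physical", algo=algo)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_unknown_algo(self):
        with pytest.raises(KeyError):
            block1.train_personal_model(np.zeros((4, 2)), [1, 2, 1, 2],
                                        "physical", algo="mlp")


class TestComputeLevelVectors:
    def test_vectors_complete_after_day_zero(self, tiny_participant):
        levels = block1.compute_level_vectors(tiny_participant, seed=1)
        assert len(levels) == 18  # 3 days x 6 answered EMAs
        later = levels[levels["date"] > levels["date"].min()]
        for c in ("physical", "mood", "sleep", "social", "food"):
            assert later[c].notna().all()
            assert later[c].between(1, 10).all()
        # day 0 has no detected night, hence no sleep level
        day0 = levels[levels["date"] == levels["date"].min()]
        assert day0["sleep"].isna().all()

    def test_food_matches_ema(self, tiny_participant):
        levels = block1.compute_level_vectors(tiny_participant, seed=1)
        assert (levels["food"] == levels["ema_food"]).all()


class TestEvaluatePersonalModels:
    def test_metrics_on_separable_data(self, tiny_participant):
        feats = {"p01": extract_features(tiny_participant)}
        summary, detail = block1.evaluate_personal_models(feats, seed=0)
        assert set(summary["cluster"]) <= {"physical", "mood"}
        row = summary[summary["cluster"] == "physical"].iloc[0]
        assert row["tp_rate_mean"] >= 60  # informative far above chance
        for metric in ("precision_mean", "recall_mean", "f_measure_mean"):
            assert 0 <= row[metric] <= 100

    def test_shuffled_labels_near_chance(self, tiny_participant):
        feats = extract_features(tiny_participant).copy()
        rng = np.random.default_rng(4)
        feats["label_physical"] = rng.permutation(
            feats["label_physical"].to_numpy())
        feats["label_mood"] = rng.permutation(feats["label_mood"].to_numpy())
        summary, _ = block1.evaluate_personal_models({"p": feats}, seed=0)
        if len(summary):
            n_classes = feats["label_physical"].nunique()
            row = summary[summary["cluster"] == "physical"]
            if len(row):
                assert row.iloc[0]["tp_rate_mean"] <= 100 / n_classes + 35

    def test_repeated_cv_protocol(self, tiny_participant):
        feats = {"p01": extract_features(tiny_participant)}
        holdout, _ = block1.evaluate_personal_models(
            feats, seed=0, clusters=("physical",))
        cv, _ = block1.evaluate_personal_models(
            feats, seed=0, clusters=("physical",), cv=(3, 1))
        # both protocols agree that the coupling is strongly learnable
        assert cv.iloc[0]["tp_rate_mean"] >= 60
        assert holdout.iloc[0]["tp_rate_mean"] >= 60

    def test_tiny_participants_skipped(self, tiny_participant, caplog):
        df = extract_features(tiny_participant).head(3)
        with caplog.at_level("WARNING"):
            summary, detail = block1.evaluate_personal_models(
                {"p": df}, clusters=("physical",))
        assert len(detail) == 0
        assert "skipped" in caplog.text
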