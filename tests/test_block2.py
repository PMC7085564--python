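import numpy as np
import pandas as pd
import pytest

from stdd import block2
from stdd.sensing_io import ParticipantManifest


# ---------------------------------------------------------------------------
# Group assignment

class TestAssignGroup:
    @pytest.mark.parametrize("phq,outcome,expected", [
        (3, "none", "normal"),
        (9, "none", "normal"),
        (10, "remission_or_partial", "mild"),
        (15, "other_depressive_disorder", "moderate"),
        (15, "mdd_confirmed", "severe"),
        (27, "mdd_confirmed", "severe"),
    ])
    def test_rules(self, phq, outcome, expected):
        m = ParticipantManifest("p", phq, outcome)
        assert block2.assign_group(m) == expected

    @pytest.mark.parametrize("phq,outcome", [
        (15, "none"),                      # depressive score, no finding
        (3, "mdd_confirmed"),              # normal score, depressive finding
    ])
    def test_inconsistent_pairs_raise(self, phq, outcome):
        with pytest.raises(block2.GroupAssignmentError):
            block2.assign_group(ParticipantManifest("p", phq, outcome))


def test_nominal_design_count():
    assert block2.nominal_sample_count() == 3600
    assert block2.nominal_sample_count(6, 28, 20) == 3360


# ---------------------------------------------------------------------------
# Dataset assembly

def levels_frame(n_per_pid, groups, rng=None, drop_sleep_rows=0):
    rng = rng or np.random.default_rng(0)
    rows = []
    for pid in groups:
        for i in range(n_per_pid):
            rows.append({
                "participant_id": pid, "checkin_time": i,
                **{c: int(rng.integers(1, 11))
                   for c in block2.FEATURE_ORDER}})
    df = pd.DataFrame(rows)
    if drop_sleep_rows:
        df.loc[df.index[:drop_sleep_rows], "sleep"] = np.nan
    return df


class TestBuildGroupDataset:
    def test_shapes_and_labels(self):
        groups = {"a": "normal", "b": "severe"}
        X, y, dropped = block2.build_group_dataset(
            levels_frame(5, groups), groups)
        assert X.shape == (10, 5) and dropped == 0
        assert list(X.columns) == list(block2.FEATURE_ORDER)
        assert set(y) == {"normal", "severe"}

    def test_incomplete_periods_dropped_with_count(self):
        groups = {"a": "normal", "b": "severe"}
        X, y, dropped = block2.build_group_dataset(
            levels_frame(5, groups, drop_sleep_rows=1), groups)
        assert dropped == 1 and len(X) == 9

    def test_missing_group_assignment(self):
        with pytest.raises(KeyError):
            block2.build_group_dataset(levels_frame(2, {"a": "normal"}), {})


# ---------------------------------------------------------------------------
# Classifier

def separable_samples(n_per_group=120, seed=0, sd=0.7):
    """Group-dependent level vectors with clear separation."""
    rng = np.random.default_rng(seed)
    centers = {"normal": 8, "mild": 6, "moderate": 4, "severe": 2}
    X, y, pids = [], [], []
    for gi, (g, c) in enumerate(centers.items()):
        for i in range(n_per_group):
            X.append(np.clip(np.round(rng.normal(c, sd, 5)), 1, 10))
            y.append(g)
            pids.append(f"{g}{i % 5}")  # 5 pseudo-participants per group
    return np.array(X), np.array(y), np.array(pids)


class TestGroupClassifier:
    def test_train_deterministic_and_introspectable(self):
        X, y, _ = separable_samples()
        cfg = block2.GroupModelConfig(seed=5)
        m1 = block2.train_group_classifier(X, y, cfg)
        m2 = block2.train_group_classifier(X, y, cfg)
        assert m1.n_estimators == 100
        np.testing.assert_array_equal(m1.predict(X[:50]), m2.predict(X[:50]))

    def test_single_group_rejected(self):
        X = np.ones((10, 5))
        with pytest.raises(ValueError):
            block2.train_group_classifier(X, np.array(["mild"] * 10))

    def test_separable_groups_high_accuracy(self):
        X, y, _ = separable_samples()
        cfg = block2.GroupModelConfig(per_group_test_n=None, n_repeats=3)
        report = block2.evaluate_group_classifier(X, y, cfg)
        assert report.accuracy >= 90.0

    def test_permuted_labels_near_chance(self):
        X, y, _ = separable_samples(n_per_group=150)
        cfg = block2.GroupModelConfig(per_group_test_n=None, n_repeats=5,
                                      seed=1)
        report = block2.evaluate_group_classifier(X, y, cfg,
                                                  permute_labels=True)
        n = report.overall_total
        three_sd = 3 * 100 * np.sqrt(0.25 * 0.75 / n)
        assert abs(report.accuracy - 25.0) <= max(three_sd, 5.0)

    def test_report_internal_consistency(self):
        X, y, _ = separable_samples()
        report = block2.evaluate_group_classifier(
            X, y, block2.GroupModelConfig(per_group_test_n=None, n_repeats=2))
        assert report.overall_correct == sum(r.correctly_classified
                                             for r in report.rows)
        for r in report.rows:
            assert r.tp_rate == pytest.approx(
                100 * r.correctly_classified / r.total_instances)
        frame = report.to_frame()
        assert list(frame["group"]) == ["normal", "mild", "moderate",
                                        "severe", "total"]

    def test_participant_level_split(self):
        X, y, pids = separable_samples()
        cfg = block2.GroupModelConfig(per_group_test_n=None, n_repeats=2,
                                      split_by="participant")
        report = block2.evaluate_group_classifier(X, y, cfg,
                                                  participant_ids=pids)
        assert 0 <= report.accuracy <= 100

    def test_per_group_test_n_lowered_when_scarce(self, caplog):
        X, y, _ = separable_samples(n_per_group=40)
        cfg = block2.GroupModelConfig(per_group_test_n=150, n_repeats=1)
        with caplog.at_level("INFO"):
            report = block2.evaluate_group_classifier(X, y, cfg)
        assert report.rows[0].total_instances < 150
        assert "lowered" in caplog.text


class TestGroupReportCounts:
    def test_from_counts_arithmetic(self):
        report = block2.GroupReport.from_counts({
            "normal": (150, 146), "mild": (150, 147),
            "moderate": (150, 138), "severe": (150, 145)})
        assert report.overall_total == 600
        assert report.overall_correct == 576
        assert report.accuracy == pytest.approx(96.00)

    def test_correct_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            block2.GroupReport.from_counts({"normal": (10, 11)})


# ---------------------------------------------------------------------------
# Feature importance

class TestFeatureImportance:
    def test_single_informative_feature(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 11, size=(600, 5))
        y = np.where(X[:, 2] > 5, "high", "low")  # sleep column drives label
        shares = block2.feature_importance(samples=(X, y))
        assert shares.sum() == pytest.approx(100.0, abs=1e-6)
        assert shares.idxmax() == "sleep"
        assert shares["sleep"] > 90

    def test_constant_feature_zero_share(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 11, size=(300, 5))
        X[:, 4] = 7
        y = np.where(X[:, 0] > 5, "a", "b")
        shares = block2.feature_importance(samples=(X, y))
        assert shares["food"] == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_labels_spread_importance(self):
        rng = np.random.default_rng(4)
        X = rng.integers(1, 11, size=(2000, 5))
        y = rng.choice(["a", "b"], size=2000)
        shares = block2.feature_importance(samples=(X, y))
        # no feature dominates when the label is independent of all of them
        assert shares.max() < 60

    def test_model_based_importance(self):
        X, y, _ = separable_samples()
        model = block2.train_group_classifier(X, y)
        shares = block2.feature_importance(model=model,
                                           feature_names=list("abcde"))
        assert shares.sum() == pytest.approx(100.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Response rates and agreement

def ema_log(slot_answered, base_day=19_000 * 86_400_000):
    """slot_answered: mapping hour -> list of 0/1 over days."""
    rows = []
    for hour, answers in slot_answered.items():
        for d, a in enumerate(answers):
            rows.append({"checkin_time": base_day + d * 86_400_000
                         + hour * 3_600_000,
                         "answered": a, "physical": 5 if a else np.nan,
                         "mood": 5 if a else np.nan,
                         "sleep": 5 if a else np.nan,
                         "social": 5 if a else np.nan,
                         "food": 5 if a else np.nan})
    return pd.DataFrame(rows)


class TestResponseRates:
    def test_full_compliance(self):
        log = ema_log({h: [1, 1, 1] for h in (7, 10, 13, 16, 19, 22)})
        rates = block2.response_rates({"p1": log})
        assert (rates["response_rate"] == 1.0).all()
        assert len(rates) == 6

    def test_partial_rates_averaged_over_participants(self):
        a = ema_log({7: [1, 0, 0, 0]})    # 0.25
        b = ema_log({7: [1, 1, 1, 0]})    # 0.75
        rates = block2.response_rates({"a": a, "b": b})
        assert rates.loc[rates["slot_hour"] == 7,
                         "response_rate"].iloc[0] == pytest.approx(0.5)

    def test_empty_participant_excluded(self, caplog):
        log = ema_log({7: [1, 1]})
        with caplog.at_level("WARNING"):
            rates = block2.response_rates(
                {"a": log, "b": log.iloc[:0]})
        assert "no EMA rows" in caplog.text
        assert len(rates) == 1


class TestAgreement:
    def make_levels(self, sensed, reported, cluster="sleep"):
        df = pd.DataFrame({cluster: sensed, f"ema_{cluster}": reported})
        for c in block2.FEATURE_ORDER:
            if c != cluster:
                df[c] = 5
                df[f"ema_{c}"] = 5
        return df

    def test_identical_series(self):
        vals = [1, 3, 5, 7, 9, 2, 4]
        r = block2.evaluate_agreement(self.make_levels(vals, vals),
                                      clusters=("sleep",))
        assert r["sleep"] == pytest.approx(1.0)

    def test_independent_series_small_r(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 11, 1000)
        b = rng.integers(1, 11, 1000)
        r = block2.evaluate_agreement(self.make_levels(a, b),
                                      clusters=("sleep",))
        assert abs(r["sleep"]) < 0.1

    def test_anti_monotone_negative(self):
        a = [1, 2, 3, 4, 5]
        b = [10, 8, 6, 4, 2]
        r = block2.evaluate_agreement(self.make_levels(a, b),
                                      clusters=("sleep",))
        assert r["sleep"] < 0

    def test_zero_variance_reported_absent(self):
        r = block2.evaluate_agreement(self.make_levels([5] * 5, [1, 2, 3, 4,
                                                                 5]),
                                      clusters=("sleep",))
        assert r["sleep"] is None

    def test_too_few_pairs_absent(self):
        r = block2.evaluate_agreement(self.make_levels([1, 2], [1, 2]),
                                      clusters=("sleep",))
        assert r["sleep"] is None
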