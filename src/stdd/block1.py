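"""Block I: per-participant symptom-level classification.

Physical activity and mood levels are learned per participant (random
forest by default, RBF-kernel SVM as the alternative) from the windowed
accelerometer / heart-rate features of :mod:`stdd.features`, labeled by EMA
label duplication.  Sleep is rule based: within the nocturnal window
(22:00-10:00) a minute counts as sleep-eligible when the phone is dark,
static and unused, and the longest eligible run is the night's sleep
duration, scored against a 7-hour baseline.  Social activity is a weighted
sum of call/app counts (weight 10) plus durations in minutes, min-max
scaled to 1-10 within the participant.  Food intake passes straight through
from the EMA answer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date as Date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import (RepeatedStratifiedKFold,
                                     train_test_split)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (MOOD_FEATURES, PHYSICAL_FEATURES, EmaLinkConfig,
                       WindowingConfig, extract_features, feature_matrix)
from .sensing_io import (MS_PER_HOUR, MS_PER_MIN, ParticipantDataset,
                         local_to_ms, to_local)

logger = logging.getLogger("stdd.block1")

LEARNED_CLUSTERS = ("physical", "mood")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class SleepConfig:
    """Rule-based sleep detection and scoring parameters."""

    night_start_hour: float = 22.0    # local clock, evening
    night_end_hour: float = 10.0      # local clock, next morning
    dark_lux_max: float = 10.0
    baseline_h: float = 7.0
    anchor_deviation_h: float = 4.0   # |duration - baseline| that scores 1
    static_threshold: float = 0.3     # per-minute accel magnitude SD, m/s^2

    def __post_init__(self) -> None:
        if self.dark_lux_max < 0:
            raise ValueError("dark_lux_max must be >= 0")
        if self.baseline_h <= 0 or self.anchor_deviation_h <= 0:
            raise ValueError("baseline_h and anchor_deviation_h must be > 0")


@dataclass(frozen=True)
class SocialConfig:
    """Weighted-sum social score: weight x counts + minutes."""

    weight: float = 10.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")


# ---------------------------------------------------------------------------
# Learned personal models (physical activity, mood)

class ConstantModel:
    """Degenerate predictor used when training data has a single label."""

    def __init__(self, level: int):
        self.level = int(level)

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.level, dtype=int)


@dataclass
class PersonalModel:
    """A per-participant classifier for one symptom cluster."""

    cluster: str
    algo: str
    estimator: object
    n_features: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"{self.cluster} model expects {self.n_features} features, "
                f"got shape {X.shape}")
        return np.asarray(self.estimator.predict(X), dtype=int)


def _make_estimator(algo: str, seed: int):
    if algo == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      n_jobs=1)
    if algo == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", gamma="scale",
                                 random_state=seed))
    raise KeyError(f"unknown algorithm {algo!r}; use 'rf' or 'svm'")


def train_personal_model(X, y, cluster: str, algo: str = "rf",
                         seed: int = 42) -> PersonalModel:
    """Fit one participant's level classifier (1-10 treated as classes)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("no labeled windows to train on")
    classes = np.unique(y)
    if len(classes) < 2:
        logger.warning("single-label training data for %s; using a constant "
                       "predictor (level %d)", cluster, classes[0])
        est = ConstantModel(int(classes[0]))
    else:
        est = _make_estimator(algo, seed)
        est.fit(X, y)
    return PersonalModel(cluster, algo, est, X.shape[1])


def predict_period_level(model: PersonalModel, windows) -> int:
    """Aggregate per-window predictions into one period level.

    Majority vote over the window predictions; ties break toward the lower
    level.
    """
    X = np.asarray(windows, dtype=float)
    if len(X) == 0:
        raise ValueError("a period needs at least one window")
    preds = model.predict(X)
    levels, counts = np.unique(preds, return_counts=True)
    return int(levels[np.argmax(counts)])  # unique() is sorted ascending


# ---------------------------------------------------------------------------
# Rule-based sleep

def detect_sleep(light: pd.DataFrame, events: pd.DataFrame,
                 accel: pd.DataFrame, night_start_date: Date,
                 cfg: SleepConfig | None = None, tz: str = "UTC") -> float:
    """Longest dark/static/unused run within one night, in hours.

    ``night_start_date`` names the evening whose night is scanned: the
    window runs from 22:00 local that day to 10:00 the next morning.  A
    minute is sleep-eligible iff no screen-on event falls in it, every light
    sample in it is at or below ``dark_lux_max`` and the phone-accelerometer
    magnitude SD within it is at or below ``static_threshold``; minutes with
    no data for a signal count as eligible for that signal.
    """
    cfg = cfg or SleepConfig()
    t0 = local_to_ms(pd.Timestamp(night_start_date), tz) \
        + int(cfg.night_start_hour * MS_PER_HOUR)
    t1 = local_to_ms(pd.Timestamp(night_start_date + timedelta(days=1)),
                     tz) + int(cfg.night_end_hour * MS_PER_HOUR)
    n_min = int((t1 - t0) // MS_PER_MIN)
    if n_min <= 0:
        return 0.0
    eligible = np.ones(n_min, dtype=bool)

    def _minute_idx(ts: np.ndarray) -> np.ndarray:
        return ((ts - t0) // MS_PER_MIN).astype(np.int64)

    if len(events):
        ets = events["timestamp"].to_numpy(dtype=np.int64)
        mask = (ets >= t0) & (ets < t1) \
            & (events["kind"].to_numpy() == "screen_on")
        eligible[_minute_idx(ets[mask])] = False

    if len(light):
        lts = light["timestamp"].to_numpy(dtype=np.int64)
        mask = (lts >= t0) & (lts < t1)
        bright = light["lux"].to_numpy(dtype=float)[mask] > cfg.dark_lux_max
        eligible[_minute_idx(lts[mask])[bright]] = False

    if len(accel):
        ats = accel["timestamp"].to_numpy(dtype=np.int64)
        mask = (ats >= t0) & (ats < t1)
        if mask.any():
            idx = _minute_idx(ats[mask])
            mag = np.sqrt(np.square(
                accel[["x", "y", "z"]].to_numpy(dtype=float)[mask]
            ).sum(axis=1))
            counts = np.bincount(idx, minlength=n_min)
            sums = np.bincount(idx, weights=mag, minlength=n_min)
            sqs = np.bincount(idx, weights=mag * mag, minlength=n_min)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = sums / counts
                var = np.maximum(sqs / counts - mean * mean, 0.0)
            moving = (counts > 0) & (np.sqrt(var) > cfg.static_threshold)
            eligible[moving] = False

    # longest contiguous eligible run
    best = run = 0
    for e in eligible:
        run = run + 1 if e else 0
        best = max(best, run)
    return best / 60.0


def score_sleep(duration_h: float, cfg: SleepConfig | None = None) -> int:
    """Sleep level from duration: linear in |duration - baseline|.

    Zero deviation from the 7-hour baseline scores 10; a deviation of 4
    hours or more (3 h or 11 h of sleep) scores 1.  The result is rounded
    half-up and clamped to 1..10, symmetric about the baseline.
    """
    cfg = cfg or SleepConfig()
    if duration_h < 0:
        raise ValueError("duration_h must be >= 0")
    dev = abs(duration_h - cfg.baseline_h)
    raw = 10.0 - (9.0 / cfg.anchor_deviation_h) * dev
    return int(min(10, max(1, _round_half_up(raw))))


# ---------------------------------------------------------------------------
# Social activity

def social_score(calls: pd.DataFrame, apps: pd.DataFrame, day: Date,
                 cfg: SocialConfig | None = None, tz: str = "UTC") -> float:
    """Daily weighted-sum social score.

    ``weight x (incoming calls + outgoing calls + social app opens)
    + minutes of incoming + outgoing + social app use``, over one calendar
    day.  Only sessions flagged social count.
    """
    cfg = cfg or SocialConfig()
    t0 = local_to_ms(pd.Timestamp(day), tz)
    t1 = t0 + 24 * MS_PER_HOUR
    n_calls = 0
    call_min = 0.0
    if len(calls):
        ts = calls["start"].to_numpy(dtype=np.int64)
        sel = (ts >= t0) & (ts < t1)
        n_calls = int(sel.sum())
        call_min = float(calls["duration_s"].to_numpy(dtype=float)[sel].sum()
                         / 60.0)
    n_apps = 0
    app_min = 0.0
    if len(apps):
        ts = apps["start"].to_numpy(dtype=np.int64)
        social = apps["is_social"].to_numpy(dtype=int) == 1
        sel = (ts >= t0) & (ts < t1) & social
        n_apps = int(sel.sum())
        app_min = float(apps["duration_s"].to_numpy(dtype=float)[sel].sum()
                        / 60.0)
    return cfg.weight * (n_calls + n_apps) + call_min + app_min


def social_level(daily_raws: Mapping[Date, float] | pd.Series,
                 day: Date) -> int:
    """Per-participant min-max scaling of daily raw scores to 1-10.

    A constant series (no dynamic range) maps every day to the neutral
    level 5.
    """
    if isinstance(daily_raws, pd.Series):
        raws = daily_raws.to_dict()
    else:
        raws = dict(daily_raws)
    if day not in raws:
        raise KeyError(f"no raw social score for day {day}")
    values = np.array(list(raws.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 5
    scaled = 1.0 + 9.0 * (raws[day] - lo) / (hi - lo)
    return int(min(10, max(1, _round_half_up(scaled))))


def food_level(ema_answer) -> int | None:
    """EMA pass-through for food intake; ``None`` for skipped check-ins."""
    if ema_answer is None or (isinstance(ema_answer, float)
                              and np.isnan(ema_answer)):
        return None
    level = int(ema_answer)
    if not 1 <= level <= 10:
        raise ValueError(f"food answer out of range: {ema_answer!r}")
    return level


# ---------------------------------------------------------------------------
# Per-participant level vectors

def compute_level_vectors(dataset: ParticipantDataset,
                          features_df: pd.DataFrame | None = None,
                          windowing: WindowingConfig | None = None,
                          link: EmaLinkConfig | None = None,
                          sleep_cfg: SleepConfig | None = None,
                          social_cfg: SocialConfig | None = None,
                          algo: str = "rf", seed: int = 42) -> pd.DataFrame:
    """One five-element symptom-level vector per answered EMA period.

    Physical and mood come from personal models trained on all of the
    participant's labeled windows and aggregated per period by majority
    vote; sleep scores the night ending that morning; social min-max scales
    the day's weighted sum; food is the EMA answer.  Sensed levels are
    returned next to the corresponding EMA answers (``ema_*`` columns) so
    downstream agreement analysis needs no re-join.  Periods missing an
    element (e.g. day-0 periods with no detected night) carry NaN there.
    """
    tz = dataset.timezone
    sleep_cfg = sleep_cfg or SleepConfig()
    social_cfg = social_cfg or SocialConfig()
    if features_df is None:
        features_df = extract_features(dataset, windowing, link)

    models: dict[str, PersonalModel | None] = {}
    for cluster in LEARNED_CLUSTERS:
        X, y = feature_matrix(features_df, cluster)
        models[cluster] = (train_personal_model(X, y, cluster, algo, seed)
                           if len(X) else None)

    answered = dataset.ema[dataset.ema["answered"] == 1]
    if len(answered) == 0:
        return pd.DataFrame()
    checkins = answered["checkin_time"].to_numpy(dtype=np.int64)
    local = to_local(checkins, tz)
    dates = sorted({d for d in local.date})

    # nightly sleep levels: the night ending on day d started on d-1.
    # A night whose window opens before the first observed sample cannot be
    # detected (the no-data-is-eligible rule would pad it), so it is absent.
    data_start = (int(dataset.light["timestamp"].iloc[0])
                  if len(dataset.light) else int(checkins.min()))
    sleep_by_day: dict[Date, float] = {}
    durations: dict[Date, float] = {}
    for d in dates:
        night_start = d - timedelta(days=1)
        night_t0 = local_to_ms(pd.Timestamp(night_start), tz) \
            + int(sleep_cfg.night_start_hour * MS_PER_HOUR)
        if night_t0 < data_start:
            sleep_by_day[d] = np.nan
            durations[d] = np.nan
            continue
        dur = detect_sleep(dataset.light, dataset.events,
                           dataset.accel_phone, night_start, sleep_cfg, tz)
        durations[d] = dur
        sleep_by_day[d] = score_sleep(dur, sleep_cfg) if dur > 0 else np.nan

    raw_social = {d: social_score(dataset.calls, dataset.apps, d,
                                  social_cfg, tz) for d in dates}

    rows = []
    for (_, ema_row), day, hour in zip(answered.iterrows(), local.date,
                                       local.hour):
        t = int(ema_row["checkin_time"])
        period = features_df[features_df["checkin_time"] == t]
        sensed: dict[str, float] = {}
        phys_cols, mood_cols = list(PHYSICAL_FEATURES), list(MOOD_FEATURES)
        if models["physical"] is not None and len(period):
            sensed["physical"] = predict_period_level(
                models["physical"], period[phys_cols].to_numpy(dtype=float))
        else:
            sensed["physical"] = np.nan
        if models["mood"] is not None and len(period):
            sensed["mood"] = predict_period_level(
                models["mood"], period[mood_cols].to_numpy(dtype=float))
        else:
            sensed["mood"] = np.nan
        rows.append({
            "participant_id": dataset.participant_id,
            "checkin_time": t, "date": day.isoformat(), "slot_hour": int(hour),
            "physical": sensed["physical"], "mood": sensed["mood"],
            "sleep": sleep_by_day.get(day, np.nan),
            "social": social_level(raw_social, day),
            "food": food_level(ema_row["food"]),
            "sleep_duration_h": durations.get(day, np.nan),
            "ema_physical": int(ema_row["physical"]),
            "ema_mood": int(ema_row["mood"]),
            "ema_sleep": int(ema_row["sleep"]),
            "ema_social": int(ema_row["social"]),
            "ema_food": int(ema_row["food"]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation (per-model metrics)

def _repeated_cv_predictions(X, y, cluster, algo, seed, cv):
    folds, repeats = cv
    folds = min(folds, int(np.unique(y, return_counts=True)[1].min()))
    if folds < 2:
        raise ValueError("not enough samples per class for cross-validation")
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                       random_state=seed)
    truths, preds = [], []
    for tr, te in splitter.split(X, y):
        model = train_personal_model(X[tr], y[tr], cluster, algo, seed)
        truths.append(y[te])
        preds.append(model.predict(X[te]))
    return np.concatenate(truths), np.concatenate(preds)

def evaluate_personal_models(features_by_participant: Mapping[str,
                                                              pd.DataFrame],
                             algo: str = "rf", seed: int = 42,
                             clusters: Sequence[str] = LEARNED_CLUSTERS,
                             test_fraction: float = 0.3,
                             min_windows: int = 10,
                             cv: tuple[int, int] | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Held-out evaluation of every personal model.

    For each participant and learned cluster a stratified 70/30 split is
    evaluated; metrics (precision, recall, F-measure, TP rate; all
    macro-averaged over the level classes) are summarised as mean +- SD
    (population SD) across participants.  Returns ``(summary, detail)``.
    Participants with fewer than ``min_windows`` labeled windows are
    skipped with a warning.

    ``cv=(folds, repeats)`` switches to repeated stratified k-fold
    cross-validation (e.g. ``(10, 10)``), pooling the out-of-fold
    predictions per repeat; the default holdout is the cheaper protocol.
    """
    detail_rows = []
    for pid, df in features_by_participant.items():
        for cluster in clusters:
            X, y = feature_matrix(df, cluster)
            if len(X) < min_windows:
                logger.warning("%s/%s: only %d labeled windows; skipped",
                               pid, cluster, len(X))
                continue
            if len(np.unique(y)) < 2:
                logger.warning("%s/%s: single label; skipped", pid, cluster)
                continue
            if cv is not None:
                y_te, pred = _repeated_cv_predictions(X, y, cluster, algo,
                                                      seed, cv)
            else:
                class_counts = np.unique(y, return_counts=True)[1]
                stratify = y if class_counts.min() >= 2 else None
                X_tr, X_te, y_tr, y_te = train_test_split(
                    X, y, test_size=test_fraction, random_state=seed,
                    stratify=stratify)
                model = train_personal_model(X_tr, y_tr, cluster, algo, seed)
                pred = model.predict(X_te)
            prec, rec, f1, _ = precision_recall_fscore_support(
                y_te, pred, average="macro", zero_division=0)
            detail_rows.append({
                "participant_id": pid, "cluster": cluster,
                "n_windows": len(X),
                "precision": 100 * prec, "recall": 100 * rec,
                "f_measure": 100 * f1, "tp_rate": 100 * rec,
            })
    detail = pd.DataFrame(detail_rows)
    if len(detail) == 0:  # nothing evaluable
        return pd.DataFrame(), detail
    summary_rows = []
    for cluster in clusters:
        sub = detail[detail["cluster"] == cluster]
        if len(sub) == 0:
            continue
        row = {"cluster": cluster, "n_models": len(sub)}
        for metric in ("precision", "recall", "f_measure", "tp_rate"):
            row[f"{metric}_mean"] = float(sub[metric].mean())
            row[f"{metric}_sd"] = float(sub[metric].std(ddof=0))
        summary_rows.append(row)
    return pd.DataFrame(summary_rows), detail
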