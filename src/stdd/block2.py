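"""Block II: depression-group assignment, classification and reporting.

Participants are assigned to one of four severity groups from their PHQ-9
screening score and clinical-interview outcome (normal / mild / moderate /
severe).  Each answered-EMA period contributes one five-element sample —
the Block-I levels for physical activity, mood, sleep, social activity and
food intake — labeled with the participant's (stable) group.  A 100-tree
random forest is trained on a 70/30 split and evaluated with equal-sized
per-group test sets; the report mirrors the per-group instance/TP-rate
table shape.  Information-gain feature importance and the Pearson agreement
between passively sensed and self-reported levels complete the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .sensing_io import (EMA_SLOT_HOURS, ParticipantManifest, slot_hour_of)
from .synthetic_data import GROUPS

logger = logging.getLogger("stdd.block2")

FEATURE_ORDER = ("physical", "mood", "sleep", "social", "food")


class GroupAssignmentError(ValueError):
    """PHQ-9 score and interview outcome contradict each other."""


def assign_group(manifest: ParticipantManifest) -> str:
    """Severity group from PHQ-9 cutoff plus interview outcome.

    PHQ-9 of 0-9 with no depressive interview finding is normal; scores of
    10 or more map to mild (remission / partial episode), moderate (other
    depressive disorder) or severe (confirmed MDD) by the interview
    category.  A score of exactly 10 counts as depressive-range, following
    the conventional screening cutoff.  Inconsistent pairs raise
    :class:`GroupAssignmentError`.
    """
    phq = int(manifest.phq9)
    outcome = manifest.interview_outcome
    if phq <= 9:
        if outcome != "none":
            raise GroupAssignmentError(
                f"{manifest.participant_id}: PHQ-9 {phq} (normal range) but "
                f"interview outcome {outcome!r}")
        return "normal"
    if outcome == "none":
        raise GroupAssignmentError(
            f"{manifest.participant_id}: PHQ-9 {phq} (depressive range) but "
            "no interview outcome")
    return {"remission_or_partial": "mild",
            "other_depressive_disorder": "moderate",
            "mdd_confirmed": "severe"}[outcome]


def nominal_sample_count(n_slots: int = 6, n_days: int = 30,
                         n_participants: int = 20) -> int:
    """Design sample count: EMA slots/day x days x participants."""
    return n_slots * n_days * n_participants


# ---------------------------------------------------------------------------
# Dataset assembly

def build_group_dataset(level_vectors: pd.DataFrame,
                        groups: Mapping[str, str],
                        ) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Five-feature samples with group labels, one per complete period.

    Periods with any absent level element are dropped (the count is
    returned and logged).  Returns ``(X, y, n_dropped)`` where X keeps the
    period identifiers as the index.
    """
    for pid in level_vectors["participant_id"].unique():
        if pid not in groups:
            raise KeyError(f"participant {pid!r} has no group assignment")
    feats = level_vectors[list(FEATURE_ORDER)]
    complete = feats.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d periods with incomplete level vectors",
                    n_dropped)
    kept = level_vectors[complete]
    X = kept[list(FEATURE_ORDER)].astype(int)
    X.index = pd.MultiIndex.from_frame(
        kept[["participant_id", "checkin_time"]])
    y = kept["participant_id"].map(groups).to_numpy()
    return X, y, n_dropped


# ---------------------------------------------------------------------------
# Classifier

@dataclass(frozen=True)
class GroupModelConfig:
    n_trees: int = 100
    test_fraction: float = 0.30
    per_group_test_n: int | None = 150
    n_repeats: int = 10
    seed: int = 42
    split_by: str = "sample"   # "sample" (pooled periods) or "participant"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.split_by not in ("sample", "participant"):
            raise ValueError("split_by must be 'sample' or 'participant'")


def train_group_classifier(X, y, cfg: GroupModelConfig | None = None
                           ) -> RandomForestClassifier:
    """Random forest over the five ordinal levels (deterministic in seed)."""
    cfg = cfg or GroupModelConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two groups")
    model = RandomForestClassifier(n_estimators=cfg.n_trees,
                                   random_state=cfg.seed, n_jobs=1)
    model.fit(np.asarray(X, dtype=float), y)
    return model


# ---------------------------------------------------------------------------
# Reports

@dataclass
class GroupRow:
    group: str
    total_instances: int
    correctly_classified: int
    tp_rate: float  # percent


@dataclass
class GroupReport:
    """Per-group instance counts and TP rates plus the overall accuracy."""

    rows: list[GroupRow]
    overall_total: int
    overall_correct: int
    accuracy: float          # percent
    accuracy_sd: float       # percent, across repeated splits (NaN if n/a)

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]],
                    accuracy_sd: float = float("nan")) -> "GroupReport":
        """Build a report from per-group (total, correct) counts."""
        rows = []
        for group, (total, correct) in counts.items():
            if correct > total:
                raise ValueError(f"{group}: correct {correct} > total {total}")
            rows.append(GroupRow(group, int(total), int(correct),
                                 100.0 * correct / total))
        overall_total = sum(r.total_instances for r in rows)
        overall_correct = sum(r.correctly_classified for r in rows)
        return cls(rows, overall_total, overall_correct,
                   100.0 * overall_correct / overall_total, accuracy_sd)

    def to_frame(self) -> pd.DataFrame:
        recs = [{"group": r.group, "total_instances": r.total_instances,
                 "correctly_classified": r.correctly_classified,
                 "tp_rate": round(r.tp_rate, 2)} for r in self.rows]
        recs.append({"group": "total", "total_instances": self.overall_total,
                     "correctly_classified": self.overall_correct,
                     "tp_rate": round(self.accuracy, 2)})
        return pd.DataFrame(recs)


def evaluate_group_classifier(X, y, cfg: GroupModelConfig | None = None,
                              permute_labels: bool = False,
                              participant_ids=None) -> GroupReport:
    """Repeated stratified 70/30 evaluation with equal per-group test sets.

    Each repeat draws a new split (and forest seed), subsamples the test
    partition to the same number of samples per group (``per_group_test_n``,
    lowered to the smallest group's test count when necessary) and counts
    per-group correct classifications.  Counts are accumulated over repeats,
    so the report's internal arithmetic stays exact; the accuracy SD is
    taken across repeats.  ``permute_labels`` shuffles y before every
    repeat — the chance-level control.

    With ``split_by='participant'`` whole participants are held out (the
    stricter generalisation test: no individual contributes to both
    partitions); ``participant_ids`` aligns with the rows of X and is taken
    from X's MultiIndex when X is the frame built by
    :func:`build_group_dataset`.
    """
    cfg = cfg or GroupModelConfig()
    if participant_ids is None and isinstance(X, pd.DataFrame) \
            and isinstance(X.index, pd.MultiIndex):
        participant_ids = X.index.get_level_values(0).to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if cfg.split_by == "participant" and participant_ids is None:
        raise ValueError("participant-level split requires participant ids")
    groups_present = sorted(np.unique(y), key=GROUPS.index)
    totals = {g: 0 for g in groups_present}
    corrects = {g: 0 for g in groups_present}
    accuracies = []
    rng = np.random.default_rng(cfg.seed)
    for r in range(cfg.n_repeats):
        y_r = rng.permutation(y) if permute_labels else y
        if cfg.split_by == "participant":
            te_mask = _participant_test_mask(participant_ids, y_r,
                                             cfg.test_fraction, rng)
            X_tr, X_te = X[~te_mask], X[te_mask]
            y_tr, y_te = y_r[~te_mask], y_r[te_mask]
        else:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y_r, test_size=cfg.test_fraction,
                random_state=cfg.seed + r, stratify=y_r)
        model = RandomForestClassifier(n_estimators=cfg.n_trees,
                                       random_state=cfg.seed + r, n_jobs=1)
        model.fit(X_tr, y_tr)

        test_counts = {g: int(np.sum(y_te == g)) for g in groups_present}
        n_test = min(test_counts.values())
        if cfg.per_group_test_n is not None:
            if cfg.per_group_test_n > n_test:
                logger.info("per-group test n lowered from %d to %d "
                            "(smallest group)", cfg.per_group_test_n, n_test)
            else:
                n_test = cfg.per_group_test_n
        rep_correct = rep_total = 0
        for g in groups_present:
            idx = np.flatnonzero(y_te == g)
            idx = rng.choice(idx, size=n_test, replace=False)
            pred = model.predict(X_te[idx])
            c = int(np.sum(pred == g))
            totals[g] += n_test
            corrects[g] += c
            rep_correct += c
            rep_total += n_test
        accuracies.append(100.0 * rep_correct / rep_total)
    sd = float(np.std(accuracies, ddof=0)) if len(accuracies) > 1 \
        else float("nan")
    return GroupReport.from_counts(
        {g: (totals[g], corrects[g]) for g in groups_present}, sd)


def _participant_test_mask(pids, y, test_fraction: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Hold out ~test_fraction of each group's participants (>= 1)."""
    pids = np.asarray(pids)
    mask = np.zeros(len(pids), dtype=bool)
    group_of = {}
    for pid, g in zip(pids, y):
        group_of.setdefault(pid, g)
    by_group: dict[str, list] = {}
    for pid, g in group_of.items():
        by_group.setdefault(g, []).append(pid)
    for g, members in sorted(by_group.items()):
        members = sorted(members)
        n_test = max(1, int(round(test_fraction * len(members))))
        held = rng.choice(members, size=n_test, replace=False)
        mask |= np.isin(pids, held)
    return mask


# ---------------------------------------------------------------------------
# Feature importance

def _information_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Entropy reduction of the class labels given a discrete feature."""
    def entropy(labels: np.ndarray) -> float:
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    h = entropy(y)
    cond = 0.0
    for v in np.unique(x):
        sel = x == v
        cond += sel.mean() * entropy(y[sel])
    return h - cond


def feature_importance(samples: tuple[np.ndarray, np.ndarray] | None = None,
                       model: RandomForestClassifier | None = None,
                       feature_names: Sequence[str] | None = None
                       ) -> pd.Series:
    """Importance shares (percent, summing to 100) per feature.

    With ``samples`` = (X, y) of discrete level features, the share is the
    information gain of each feature about the group label.  With a fitted
    forest, impurity-based importances are used (the personal-model case).
    Constant features contribute a zero share.
    """
    if samples is not None:
        X, y = samples
        X = np.asarray(X)
        y = np.asarray(y)
        gains = np.array([_information_gain(X[:, j], y)
                          for j in range(X.shape[1])])
        names = feature_names or list(FEATURE_ORDER)[:X.shape[1]]
    elif model is not None:
        gains = np.asarray(model.feature_importances_, dtype=float)
        names = feature_names or [f"f{j}" for j in range(len(gains))]
    else:
        raise ValueError("provide samples or a fitted model")
    gains = np.maximum(gains, 0.0)
    total = gains.sum()
    shares = (gains / total * 100.0 if total > 0
              else np.full(len(gains), 100.0 / len(gains)))
    return pd.Series(shares, index=list(names), name="importance_pct"
                     ).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Response rates and sensing/EMA agreement

def response_rates(ema_logs: Mapping[str, pd.DataFrame],
                   timezones: Mapping[str, str] | None = None
                   ) -> pd.DataFrame:
    """Per-slot EMA response rates averaged over participants.

    ``ema_logs`` maps participant id to an EMA frame; participants with no
    scheduled check-ins are excluded with a warning.
    """
    per_part: list[pd.Series] = []
    for pid, ema in ema_logs.items():
        if len(ema) == 0:
            logger.warning("%s: no EMA rows; excluded from response rates",
                           pid)
            continue
        tz = (timezones or {}).get(pid, "UTC")
        hours = slot_hour_of(ema["checkin_time"].to_numpy(), tz)
        answered = ema["answered"].to_numpy(dtype=int)
        rates = {}
        for h in EMA_SLOT_HOURS:
            sel = hours == h
            if sel.sum():
                rates[h] = answered[sel].mean()
        per_part.append(pd.Series(rates, name=pid))
    if not per_part:
        return pd.DataFrame(columns=["slot_hour", "response_rate"])
    table = pd.DataFrame(per_part)
    out = table.mean(axis=0).rename("response_rate").rename_axis("slot_hour")
    return out.reset_index()


def evaluate_agreement(level_vectors: pd.DataFrame,
                       clusters: Sequence[str] = FEATURE_ORDER,
                       min_periods: int = 3) -> dict[str, float | None]:
    """Pearson r between sensed and EMA levels, per symptom cluster.

    Pairs are the periods of ``level_vectors`` (columns ``<cluster>`` vs
    ``ema_<cluster>``).  Clusters with fewer than ``min_periods`` complete
    pairs or zero variance in either series report ``None``.
    """
    out: dict[str, float | None] = {}
    for cluster in clusters:
        sensed = level_vectors[cluster]
        reported = level_vectors[f"ema_{cluster}"]
        ok = sensed.notna() & reported.notna()
        a = sensed[ok].to_numpy(dtype=float)
        b = reported[ok].to_numpy(dtype=float)
        if len(a) < min_periods or np.std(a) == 0 or np.std(b) == 0:
            out[cluster] = None
            continue
        out[cluster] = float(stats.pearsonr(a, b).statistic)
    return out
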