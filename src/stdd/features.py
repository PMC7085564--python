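"""Sliding-window accelerometer features and EMA label linkage.

The physical-activity / mood feature pipeline mirrors classical
accelerometer-based activity recognition: the raw 50 Hz stream is cut into
fixed-length windows of 50 samples (1 s) with 50 % overlap, and 17
time-domain statistics are computed per axis — 51 per device, 102 for the
phone + watch pair.  Each window inherits, as its label, the 1-10 ordinal
answer of the EMA check-in whose 30-minute look-back interval contains the
window start ("label duplication").  Step and significant-motion counts and
heart-rate mean/SD are computed once per 30-minute pre-EMA period and
broadcast to every window of that period, giving 104-dimensional
physical-activity vectors and 106-dimensional mood vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sensing_io import MS_PER_MIN, ParticipantDataset

logger = logging.getLogger("stdd.features")

#: The 17 per-axis window statistics, in canonical order.
FEATURE_NAMES = (
    "mean", "std", "max", "min", "energy", "kurtosis", "skewness",
    "rms", "rss", "sum", "sum_abs", "mean_abs", "range",
    "median", "upper_quartile", "lower_quartile", "mad",
)
N_AXIS_FEATURES = len(FEATURE_NAMES)          # 17
N_DEVICE_FEATURES = 3 * N_AXIS_FEATURES       # 51
N_ACCEL_FEATURES = 2 * N_DEVICE_FEATURES      # 102

AXES = ("x", "y", "z")

#: Column names of the 102-element accelerometer block, phone block first.
ACCEL_COLUMNS = tuple(
    f"{dev}_{axis}_{feat}"
    for dev in ("p", "w") for axis in AXES for feat in FEATURE_NAMES
)


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry: 50-sample (1 s) windows, 50 % overlap."""

    window_len: int = 50
    overlap: float = 0.5
    rate: float = 50.0

    def __post_init__(self) -> None:
        if self.window_len <= 1:
            raise ValueError("window_len must exceed 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.step < 1:
            raise ValueError("window step must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def step(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap)))

    @property
    def nominal_gap_ms(self) -> float:
        return 1000.0 / self.rate


@dataclass(frozen=True)
class EmaLinkConfig:
    """EMA look-back: windows in [checkin - lookback, checkin) get labeled."""

    lookback_min: float = 30.0

    def __post_init__(self) -> None:
        if self.lookback_min <= 0:
            raise ValueError("lookback must be positive")

    @property
    def lookback_ms(self) -> float:
        return self.lookback_min * MS_PER_MIN


@dataclass(slots=True)
class Window:
    """One sliding window over a contiguous stream segment."""

    start_ms: int
    values: np.ndarray  # (n_samples, n_axes)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AxisFeatureSet:
    """The 17 named statistics of one axis within one window."""

    mean: float
    std: float
    max: float
    min: float
    energy: float
    kurtosis: float
    skewness: float
    rms: float
    rss: float
    sum: float
    sum_abs: float
    mean_abs: float
    range: float
    median: float
    upper_quartile: float
    lower_quartile: float
    mad: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# Windowing

def split_segments(ts: np.ndarray, max_gap_ms: float) -> list[slice]:
    """Split a sorted timestamp array at gaps exceeding ``max_gap_ms``."""
    if len(ts) == 0:
        return []
    breaks = np.flatnonzero(np.diff(ts) > max_gap_ms) + 1
    edges = np.concatenate(([0], breaks, [len(ts)]))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def window_stream(samples, cfg: WindowingConfig | None = None) -> list[Window]:
    """Cut one device's accelerometer stream into sliding windows.

    ``samples`` is a DataFrame with ``timestamp, x, y, z`` columns (or a
    ``(timestamps, values)`` pair of arrays).  Within each contiguous
    segment (gaps larger than twice the nominal sampling interval split the
    stream), windows start every ``step`` samples; the number of windows is
    ``floor(n / step)``, so tail windows may be shorter than ``window_len``
    but never shorter than ``step``.
    """
    cfg = cfg or WindowingConfig()
    if isinstance(samples, pd.DataFrame):
        ts = samples["timestamp"].to_numpy(dtype=np.int64)
        vals = samples[list(AXES)].to_numpy(dtype=float)
    else:
        ts, vals = samples
        ts = np.asarray(ts, dtype=np.int64)
        vals = np.asarray(vals, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
    step = cfg.step
    out: list[Window] = []
    for seg in split_segments(ts, 2.0 * cfg.nominal_gap_ms):
        seg_ts, seg_vals = ts[seg], vals[seg]
        n = len(seg_ts)
        count = n // step
        for i in range(count):
            a = i * step
            b = min(a + cfg.window_len, n)
            out.append(Window(int(seg_ts[a]), seg_vals[a:b]))
    return out


# ---------------------------------------------------------------------------
# The 17 window statistics

def _stat_matrix(w: np.ndarray) -> np.ndarray:
    """All 17 statistics for a batch of equal-length windows.

    ``w`` has shape (n_windows, window_len); the result has shape
    (n_windows, 17) in :data:`FEATURE_NAMES` order.  Conventions: sample SD
    (n-1 denominator); energy = mean of squares; skewness and excess
    kurtosis from central moments, defined as 0 for zero-variance windows;
    quartiles by linear interpolation on the sorted window; MAD is the
    unscaled median absolute deviation from the median.
    """
    w = np.asarray(w, dtype=float)
    n, L = w.shape
    mean = w.mean(axis=1)
    mx = w.max(axis=1)
    mn = w.min(axis=1)
    total = w.sum(axis=1)
    sq = np.square(w).sum(axis=1)
    sum_abs = np.abs(w).sum(axis=1)
    energy = sq / L
    rms = np.sqrt(energy)
    rss = np.sqrt(sq)
    d = w - mean[:, None]
    m2 = np.square(d).mean(axis=1)
    m3 = np.power(d, 3).mean(axis=1)
    m4 = np.power(d, 4).mean(axis=1)
    std = np.sqrt(m2 * L / (L - 1)) if L > 1 else np.zeros(n)
    degenerate = (mx - mn) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(degenerate, 0.0, m3 / np.power(m2, 1.5))
        kurt = np.where(degenerate, 0.0, m4 / np.square(m2) - 3.0)
    med = np.median(w, axis=1)
    q3 = np.quantile(w, 0.75, axis=1)
    q1 = np.quantile(w, 0.25, axis=1)
    mad = np.median(np.abs(w - med[:, None]), axis=1)
    return np.column_stack([
        mean, std, mx, mn, energy, kurt, skew, rms, rss, total,
        sum_abs, sum_abs / L, mx - mn, med, q3, q1, mad,
    ])


def axis_features(values: Sequence[float]) -> AxisFeatureSet:
    """Compute the 17 statistics of a single axis window."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("axis_features requires a non-empty window")
    if v.size < 4:
        logger.debug("axis_features on %d samples: higher moments have "
                     "low support", v.size)
    row = _stat_matrix(v[None, :])[0]
    return AxisFeatureSet(*(float(x) for x in row))


def axis_feature_matrix(windows: Sequence[np.ndarray]) -> np.ndarray:
    """The 17 statistics for many (possibly ragged) 1-D windows."""
    out = np.empty((len(windows), N_AXIS_FEATURES))
    by_len: dict[int, list[int]] = {}
    for i, win in enumerate(windows):
        by_len.setdefault(len(win), []).append(i)
    for L, idx in by_len.items():
        if L == 0:
            raise ValueError("empty window in batch")
        batch = np.stack([np.asarray(windows[i], dtype=float) for i in idx])
        out[idx] = _stat_matrix(batch)
    return out


def device_feature_matrix(windows: Sequence[Window]) -> np.ndarray:
    """Per-window 51-vectors [x(17), y(17), z(17)] for one device."""
    if not windows:
        return np.empty((0, N_DEVICE_FEATURES))
    cols = []
    for axis in range(3):
        cols.append(axis_feature_matrix([w.values[:, axis] for w in windows]))
    return np.hstack(cols)


def accel_window_features(phone_window: np.ndarray | None,
                          watch_window: np.ndarray | None,
                          impute_phone: np.ndarray | None = None,
                          impute_watch: np.ndarray | None = None,
                          ) -> tuple[np.ndarray, bool]:
    """The 102-element accelerometer vector for one paired window.

    Either device's (n, 3) sample block may be absent; the missing 51-block
    is filled from the provided participant-level mean vector and the
    returned flag is set.  Both devices absent is an error (the caller
    drops such windows).
    """
    if phone_window is None and watch_window is None:
        raise ValueError("both devices absent; window must be dropped")
    imputed = False
    blocks = []
    for win, fill in ((phone_window, impute_phone),
                      (watch_window, impute_watch)):
        if win is not None:
            win = np.asarray(win, dtype=float)
            blocks.append(np.hstack(
                [_stat_matrix(win[:, a][None, :]).ravel() for a in range(3)]))
        else:
            if fill is None:
                raise ValueError("missing device block without an imputation "
                                 "vector")
            blocks.append(np.asarray(fill, dtype=float))
            imputed = True
    vec = np.hstack(blocks)
    if vec.shape != (N_ACCEL_FEATURES,):
        raise ValueError(f"accelerometer vector has length {vec.size}, "
                         f"expected {N_ACCEL_FEATURES}")
    return vec, imputed


# ---------------------------------------------------------------------------
# EMA linkage and per-period aggregates

def link_ema_labels(window_starts, ema: pd.DataFrame,
                    cfg: EmaLinkConfig | None = None,
                    cluster: str = "physical") -> np.ndarray:
    """Label duplication: each window start in [checkin - lookback, checkin)
    of an answered EMA receives that EMA's answer for ``cluster``.

    Returns a float array aligned with ``window_starts``; unlabeled windows
    are NaN.  The interval is half-open, so a window starting exactly at the
    check-in time stays unlabeled.
    """
    cfg = cfg or EmaLinkConfig()
    starts = np.asarray(window_starts, dtype=np.int64)
    labels = np.full(len(starts), np.nan)
    answered = ema[ema["answered"] == 1]
    for t, ans in zip(answered["checkin_time"].to_numpy(dtype=np.int64),
                      answered[cluster].to_numpy(dtype=float)):
        mask = (starts >= t - cfg.lookback_ms) & (starts < t)
        labels[mask] = ans
    return labels


def period_counts(events: pd.DataFrame, checkin_ms: int,
                  cfg: EmaLinkConfig | None = None) -> tuple[int, int]:
    """Step and significant-motion counts over [checkin - lookback, checkin)."""
    cfg = cfg or EmaLinkConfig()
    if len(events) == 0:
        return 0, 0
    t = events["timestamp"].to_numpy(dtype=np.int64)
    in_period = (t >= checkin_ms - cfg.lookback_ms) & (t < checkin_ms)
    kinds = events["kind"].to_numpy()
    steps = int(np.sum(in_period & (kinds == "step")))
    sig = int(np.sum(in_period & (kinds == "significant_motion")))
    return steps, sig


def hrm_features(hrm: pd.DataFrame, checkin_ms: int,
                 cfg: EmaLinkConfig | None = None
                 ) -> tuple[float, float]:
    """Heart-rate mean and sample SD over the pre-EMA period (NaN if empty)."""
    cfg = cfg or EmaLinkConfig()
    if len(hrm) == 0:
        return np.nan, np.nan
    t = hrm["timestamp"].to_numpy(dtype=np.int64)
    mask = (t >= checkin_ms - cfg.lookback_ms) & (t < checkin_ms)
    bpm = hrm["bpm"].to_numpy(dtype=float)[mask]
    if bpm.size == 0:
        return np.nan, np.nan
    sd = float(np.std(bpm, ddof=1)) if bpm.size > 1 else 0.0
    return float(bpm.mean()), sd


# ---------------------------------------------------------------------------
# Participant-level extraction

PHYSICAL_FEATURES = ACCEL_COLUMNS + ("steps", "sigmotion")        # 104
MOOD_FEATURES = PHYSICAL_FEATURES + ("hrm_mean", "hrm_sd")        # 106


def extract_features(dataset: ParticipantDataset,
                     windowing: WindowingConfig | None = None,
                     link: EmaLinkConfig | None = None) -> pd.DataFrame:
    """One row per labeled window for a participant.

    Columns: the 102 accelerometer features (``p_x_mean`` … ``w_z_mad``),
    ``steps``, ``sigmotion``, ``hrm_mean``, ``hrm_sd``, ``label_physical``,
    ``label_mood``, ``checkin_time``, ``window_start`` plus imputation
    flags ``watch_imputed`` and ``hrm_imputed``.
    """
    windowing = windowing or WindowingConfig()
    link = link or EmaLinkConfig()

    win_p = window_stream(dataset.accel_phone, windowing)
    win_w = window_stream(dataset.accel_watch, windowing)
    feats = {"phone": device_feature_matrix(win_p),
             "watch": device_feature_matrix(win_w)}
    starts = {"phone": np.array([w.start_ms for w in win_p], dtype=np.int64),
              "watch": np.array([w.start_ms for w in win_w], dtype=np.int64)}

    answered = dataset.ema[dataset.ema["answered"] == 1]
    rows_accel: list[np.ndarray] = []
    rows_meta: list[tuple] = []
    imput_pending: list[int] = []   # row indices awaiting watch imputation
    hrm_pending: list[int] = []
    hrm_values: list[float] = []

    device_means = {
        dev: (feats[dev].mean(axis=0) if len(feats[dev]) else None)
        for dev in ("phone", "watch")
    }

    n_dropped = 0
    for _, ema_row in answered.iterrows():
        t = int(ema_row["checkin_time"])
        lo = t - link.lookback_ms
        sel = {dev: np.flatnonzero((starts[dev] >= lo) & (starts[dev] < t))
               for dev in ("phone", "watch")}
        np_, nw = len(sel["phone"]), len(sel["watch"])
        if np_ == 0 and nw == 0:
            continue
        if np_ and nw and np_ != nw:
            logger.debug("period %d: unequal window counts phone=%d watch=%d;"
                         " pairing the first %d", t, np_, nw, min(np_, nw))
        n = max(np_, nw) if (np_ == 0 or nw == 0) else min(np_, nw)

        steps, sig = period_counts(dataset.events, t, link)
        hmean, hsd = hrm_features(dataset.hrm, t, link)
        if not np.isnan(hmean):
            hrm_values.append(hmean)

        for i in range(n):
            p_feat = feats["phone"][sel["phone"][i]] if i < np_ else None
            w_feat = feats["watch"][sel["watch"][i]] if i < nw else None
            if p_feat is None and w_feat is None:
                n_dropped += 1
                continue
            if p_feat is None:
                p_feat = device_means["phone"]
                if p_feat is None:
                    n_dropped += 1
                    continue
            watch_imputed = w_feat is None
            if watch_imputed:
                w_feat = device_means["watch"]
            row_idx = len(rows_accel)
            if watch_imputed and w_feat is None:
                imput_pending.append(row_idx)
                w_feat = np.full(N_DEVICE_FEATURES, np.nan)
            start_ms = int(starts["phone"][sel["phone"][i]]) if i < np_ \
                else int(starts["watch"][sel["watch"][i]])
            if np.isnan(hmean):
                hrm_pending.append(row_idx)
            rows_accel.append(np.hstack([p_feat, w_feat]))
            rows_meta.append((start_ms, t, steps, sig, hmean, hsd,
                              watch_imputed))

    if n_dropped:
        logger.warning("%s: dropped %d windows with no usable device data",
                       dataset.participant_id, n_dropped)
    if not rows_accel:
        cols = list(ACCEL_COLUMNS) + [
            "steps", "sigmotion", "hrm_mean", "hrm_sd", "label_physical",
            "label_mood", "checkin_time", "window_start", "watch_imputed",
            "hrm_imputed"]
        return pd.DataFrame(columns=cols)

    accel = np.vstack(rows_accel)
    meta = pd.DataFrame(rows_meta, columns=[
        "window_start", "checkin_time", "steps", "sigmotion", "hrm_mean",
        "hrm_sd", "watch_imputed"])

    # participant-level mean imputation for periods with no HRM coverage
    meta["hrm_imputed"] = meta["hrm_mean"].isna()
    if meta["hrm_imputed"].any():
        fill = float(np.mean(hrm_values)) if hrm_values else 70.0
        meta.loc[meta["hrm_imputed"], "hrm_mean"] = fill
        meta.loc[meta["hrm_sd"].isna(), "hrm_sd"] = 0.0
        logger.warning("%s: imputed HRM features for %d windows",
                       dataset.participant_id, int(meta["hrm_imputed"].sum()))

    df = pd.DataFrame(accel, columns=list(ACCEL_COLUMNS))
    for c in meta.columns:
        df[c] = meta[c].to_numpy()
    df["label_physical"] = link_ema_labels(df["window_start"], dataset.ema,
                                           link, "physical")
    df["label_mood"] = link_ema_labels(df["window_start"], dataset.ema,
                                       link, "mood")
    df = df[df["label_physical"].notna() | df["label_mood"].notna()]
    return df.reset_index(drop=True)


def feature_matrix(df: pd.DataFrame, cluster: str) -> tuple[np.ndarray,
                                                            np.ndarray]:
    """(X, y) for one symptom cluster from an extracted feature table."""
    if cluster == "physical":
        cols, label = PHYSICAL_FEATURES, "label_physical"
    elif cluster == "mood":
        cols, label = MOOD_FEATURES, "label_mood"
    else:
        raise KeyError(f"no learned model for cluster {cluster!r}")
    sub = df[df[label].notna()]
    return sub[list(cols)].to_numpy(dtype=float), \
        sub[label].to_numpy(dtype=int)
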