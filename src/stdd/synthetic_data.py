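"""Synthetic multi-participant study generator.

Latent daily symptom levels (1-10 ordinals for physical activity, mood,
sleep, social activity and food intake), conditioned on a participant's
depression-severity group, drive every sensor stream and EMA answer, so
that both stages of the classification architecture can be exercised with
known ground truth:

* daily levels are drawn once per day around group-conditioned baselines
  (normal > mild > moderate for mood/activity/social/sleep; food intake
  elevated in the severe group);
* at each of the six EMA slots a *momentary* level — the daily level plus a
  bounded +-1 fluctuation — determines both the self-reported answer and the
  intensity of the sensor burst preceding the check-in, so reported labels
  never deviate from the daily latent level by more than 1;
* the accelerometer is duty-cycled: a 50 Hz burst (both devices) covers the
  seconds immediately before each answered check-in, step/significant-motion
  events fill the 30-minute look-back period with level-proportional Poisson
  rates, and heart rate shifts with the momentary physical and mood levels;
* each night has a latent sleep interval inside 22:00-10:00 whose duration
  encodes the sleep level; ambient light is dark (< 10 lux) and the screen
  unused exactly during that interval.

``simulate_study`` materialises the dataset in the on-disk layout expected
by :mod:`stdd.sensing_io` and writes the latent truth alongside for test
use.  Identical seeds produce byte-identical CSV files.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import sensing_io as sio
from .sensing_io import (EMA_SLOT_HOURS, MS_PER_DAY, MS_PER_HOUR, MS_PER_MIN,
                         ParticipantManifest, local_to_ms)

logger = logging.getLogger("stdd.synthetic_data")

GROUPS = ("normal", "mild", "moderate", "severe")
CLUSTERS = ("physical", "mood", "sleep", "social", "food")

#: Group-conditioned baseline levels.  Mood, activity, social and sleep
#: decrease monotonically with severity; food intake is elevated in the
#: severe group.
GROUP_BASELINES: dict[str, dict[str, float]] = {
    "normal":   {"physical": 8.0, "mood": 8.0, "sleep": 9.0,
                 "social": 8.0, "food": 5.0},
    "mild":     {"physical": 6.0, "mood": 6.0, "sleep": 7.0,
                 "social": 6.0, "food": 5.0},
    "moderate": {"physical": 4.0, "mood": 4.0, "sleep": 5.0,
                 "social": 4.0, "food": 5.0},
    "severe":   {"physical": 2.5, "mood": 2.5, "sleep": 3.0,
                 "social": 2.5, "food": 8.0},
}

GROUP_INTERVIEW = {
    "normal": "none",
    "mild": "remission_or_partial",
    "moderate": "other_depressive_disorder",
    "severe": "mdd_confirmed",
}

#: Default per-slot answer probabilities (observed field response rates).
DEFAULT_COMPLIANCE: dict[int, float] = {
    7: 0.38, 10: 0.60, 13: 0.64, 16: 0.61, 19: 0.60, 22: 0.58,
}


@dataclass(frozen=True)
class StudyConfig:
    """Generator conditions; defaults are the study's nominal design."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 5 for g in GROUPS})
    n_days: int = 28
    start_date: Date = Date(2023, 3, 6)
    timezone: str = "UTC"

    # latent dynamics
    level_sd: float = 0.8            # daily jitter around the baseline
    slot_dev_prob: float = 0.30      # P(momentary level deviates by +-1)
    baseline_jitter: float = 0.3     # per-participant baseline perturbation
    compliance: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLIANCE))

    # accelerometer bursts (duty-cycled sensing before each answered EMA)
    rate_hz: float = 50.0
    burst_s: float = 30.0
    accel_amp_base: float = 0.2      # m/s^2 oscillation at level 0
    accel_amp_per_level: float = 0.25
    accel_noise_sd: float = 0.05
    watch_amp_factor: float = 1.3
    gait_hz: float = 2.0

    # discrete events per 30-min pre-EMA period
    steps_per_level: float = 30.0
    sigmotion_base: float = 1.0
    sigmotion_per_level: float = 0.5

    # heart rate (1 sample / min)
    hr_base: float = 55.0
    hr_per_physical: float = 1.5
    hr_per_mood: float = 2.5
    hr_noise_sd: float = 2.0
    hr_awake: float = 62.0
    hr_sleep: float = 52.0
    hr_rest_noise_sd: float = 3.0

    # ambient light
    light_period_s: float = 300.0
    sleep_lux_max: float = 8.0       # generated darkness, below the 10-lux rule
    bright_lux_min: float = 30.0
    bright_lux_max: float = 400.0

    # sleep interval geometry
    sleep_baseline_h: float = 7.0
    sleep_h_per_level: float = 4.0 / 9.0   # duration lost per level below 10
    onset_mean_h: float = 23.0
    onset_sd_h: float = 0.3
    onset_min_h: float = 22.25
    onset_max_h: float = 23.75

    # social streams (per day)
    calls_per_level: float = 0.4
    call_duration_s_per_level: float = 60.0
    social_apps_per_level: float = 0.6
    app_duration_s_mean: float = 180.0
    other_apps_per_day: float = 1.0
    screen_sessions_per_hour: float = 2.0


@dataclass
class ParticipantProfile:
    """Per-participant generative parameters (deterministic in its seed)."""

    participant_id: str
    group: str
    baseline_levels: dict[str, float]
    level_sd: dict[str, float]
    compliance: dict[int, float]
    seed: int
    phq9: int
    interview_outcome: str
    timezone: str = "UTC"

    def manifest(self) -> ParticipantManifest:
        return ParticipantManifest(self.participant_id, self.phq9,
                                   self.interview_outcome, self.timezone)


@dataclass
class LatentDay:
    """Ground truth for one participant-day."""

    date: Date
    levels: dict[str, int]
    sleep_onset_ms: int     # absolute epoch ms; the night starting this date
    sleep_offset_ms: int

    @property
    def sleep_duration_h(self) -> float:
        return (self.sleep_offset_ms - self.sleep_onset_ms) / MS_PER_HOUR


@dataclass
class DayStreams:
    """All raw streams generated for one participant-day."""

    accel_phone: pd.DataFrame
    accel_watch: pd.DataFrame
    hrm: pd.DataFrame
    light: pd.DataFrame
    events: pd.DataFrame
    calls: pd.DataFrame
    apps: pd.DataFrame
    ema: pd.DataFrame


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _clip_level(x: float) -> int:
    return int(min(10, max(1, x)))


def make_profile(group: str, participant_id: str, seed: int,
                 config: StudyConfig | None = None) -> ParticipantProfile:
    """Deterministic participant profile for ``(group, id, seed)``."""
    if group not in GROUPS:
        raise KeyError(f"unknown depression group {group!r}")
    config = config or StudyConfig()
    mix = zlib.crc32(participant_id.encode("utf-8"))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, mix,
                                GROUPS.index(group)]))
    j = config.baseline_jitter
    baselines = {
        c: float(np.clip(GROUP_BASELINES[group][c] + rng.uniform(-j, j),
                         1.0, 10.0))
        for c in CLUSTERS
    }
    if group == "normal":
        phq9 = int(rng.integers(0, 10))
    else:
        phq9 = int(rng.integers(10, 28))
    return ParticipantProfile(
        participant_id=participant_id, group=group,
        baseline_levels=baselines,
        level_sd={c: config.level_sd for c in CLUSTERS},
        compliance=dict(config.compliance), seed=int(seed), phq9=phq9,
        interview_outcome=GROUP_INTERVIEW[group],
        timezone=config.timezone)


def _slot_deviation(rng: np.random.Generator, p: float) -> int:
    return int(rng.choice((-1, 0, 1), p=(p / 2, 1 - p, p / 2)))


def _burst(rng: np.random.Generator, t0_ms: int, level: int, amp_factor: float,
           cfg: StudyConfig) -> pd.DataFrame:
    n = int(round(cfg.burst_s * cfg.rate_hz))
    gap = 1000.0 / cfg.rate_hz
    ts = (t0_ms + np.round(np.arange(n) * gap)).astype(np.int64)
    amp = (cfg.accel_amp_base + cfg.accel_amp_per_level * level) * amp_factor
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tsec = np.arange(n) / cfg.rate_hz
    carrier = 2.0 * np.pi * cfg.gait_hz * tsec + phase
    noise = rng.normal(0.0, cfg.accel_noise_sd, size=(3, n))
    x = amp * np.sin(carrier) + noise[0]
    y = amp * np.sin(carrier + 2.1) + noise[1]
    z = 9.81 + amp * np.cos(carrier) + noise[2]
    return pd.DataFrame({"timestamp": ts,
                         "x": np.round(x, 4), "y": np.round(y, 4),
                         "z": np.round(z, 4)})


def simulate_day(profile: ParticipantProfile, day: Date,
                 rng: np.random.Generator,
                 config: StudyConfig | None = None,
                 prev_latent: LatentDay | None = None,
                 ) -> tuple[LatentDay, DayStreams]:
    """Generate the latent state and all raw streams for one day.

    The EMA sleep answer refers to the night *ending* this morning, i.e. the
    previous day's latent sleep level (the day's own level for day 0).
    """
    cfg = config or StudyConfig()
    tz = profile.timezone
    day_start = local_to_ms(pd.Timestamp(day), tz)

    levels = {
        c: _clip_level(_round_half_up(
            profile.baseline_levels[c] + rng.normal(0.0, profile.level_sd[c])))
        for c in CLUSTERS
    }
    dur_h = cfg.sleep_baseline_h - (10 - levels["sleep"]) * cfg.sleep_h_per_level
    onset_h = float(np.clip(rng.normal(cfg.onset_mean_h, cfg.onset_sd_h),
                            cfg.onset_min_h, cfg.onset_max_h))
    onset_ms = int(day_start + onset_h * MS_PER_HOUR)
    offset_ms = int(onset_ms + dur_h * MS_PER_HOUR)
    latent = LatentDay(day, levels, onset_ms, offset_ms)

    # the morning tail of the *previous* night falls inside this day
    prev_offset = (prev_latent.sleep_offset_ms if prev_latent is not None
                   else int(day_start + 6.5 * MS_PER_HOUR))
    sleep_ref_level = (prev_latent.levels["sleep"] if prev_latent is not None
                       else levels["sleep"])

    def asleep(ts: np.ndarray) -> np.ndarray:
        return (ts < prev_offset) | ((ts >= onset_ms) & (ts < offset_ms))

    # ---- EMA slots and momentary levels ---------------------------------
    ema_rows = []
    accel_phone, accel_watch = [], []
    event_rows: list[tuple[int, str]] = []
    hr_periods: list[tuple[int, int, float]] = []  # (lo, hi, mean bpm)
    for hour in EMA_SLOT_HOURS:
        slot_ms = int(day_start + hour * MS_PER_HOUR)
        answered = bool(rng.random() < profile.compliance[hour])
        if not answered:
            ema_rows.append({"checkin_time": slot_ms, "answered": 0,
                             "physical": np.nan, "mood": np.nan,
                             "sleep": np.nan, "social": np.nan,
                             "food": np.nan})
            continue
        p = cfg.slot_dev_prob
        m_phys = _clip_level(levels["physical"] + _slot_deviation(rng, p))
        m_mood = _clip_level(levels["mood"] + _slot_deviation(rng, p))
        a_sleep = _clip_level(sleep_ref_level + _slot_deviation(rng, p))
        a_social = _clip_level(levels["social"] + _slot_deviation(rng, p))
        a_food = _clip_level(levels["food"] + _slot_deviation(rng, p))
        ema_rows.append({"checkin_time": slot_ms, "answered": 1,
                         "physical": m_phys, "mood": m_mood,
                         "sleep": a_sleep, "social": a_social,
                         "food": a_food})

        burst_t0 = slot_ms - int(cfg.burst_s * 1000)
        accel_phone.append(_burst(rng, burst_t0, m_phys, 1.0, cfg))
        accel_watch.append(_burst(rng, burst_t0, m_phys,
                                  cfg.watch_amp_factor, cfg))

        period_lo = slot_ms - 30 * MS_PER_MIN
        n_steps = int(rng.poisson(cfg.steps_per_level * m_phys))
        for t in sorted(rng.integers(period_lo, slot_ms, size=n_steps)):
            event_rows.append((int(t), "step"))
        n_sig = int(rng.poisson(cfg.sigmotion_base
                                + cfg.sigmotion_per_level * m_phys))
        for t in sorted(rng.integers(period_lo, slot_ms, size=n_sig)):
            event_rows.append((int(t), "significant_motion"))

        hr_periods.append((period_lo, slot_ms,
                           cfg.hr_base + cfg.hr_per_physical * m_phys
                           + cfg.hr_per_mood * m_mood))
        # answering the prompt lights the screen
        event_rows.append((slot_ms + 2_000, "screen_on"))
        event_rows.append((slot_ms + 62_000, "screen_off"))

    # ---- heart rate: one sample per minute ------------------------------
    hr_ts = (day_start + MS_PER_MIN * np.arange(1440)).astype(np.int64)
    night = asleep(hr_ts)
    bpm = np.where(night,
                   cfg.hr_sleep + rng.normal(0, cfg.hr_noise_sd, 1440),
                   cfg.hr_awake + rng.normal(0, cfg.hr_rest_noise_sd, 1440))
    for lo, hi, mean_bpm in hr_periods:
        sel = (hr_ts >= lo) & (hr_ts < hi)
        bpm[sel] = mean_bpm + rng.normal(0, cfg.hr_noise_sd, int(sel.sum()))
    hrm = pd.DataFrame({"timestamp": hr_ts, "bpm": np.round(bpm, 2)})

    # ---- ambient light ---------------------------------------------------
    n_light = int(MS_PER_DAY / (cfg.light_period_s * 1000))
    light_ts = (day_start + np.round(np.arange(n_light)
                                     * cfg.light_period_s * 1000)
                ).astype(np.int64)
    dark = asleep(light_ts)
    lux = np.where(dark, rng.uniform(0.0, cfg.sleep_lux_max, n_light),
                   rng.uniform(cfg.bright_lux_min, cfg.bright_lux_max,
                               n_light))
    light = pd.DataFrame({"timestamp": light_ts, "lux": np.round(lux, 2)})

    # ---- background screen sessions (awake only) -------------------------
    awake_lo, awake_hi = prev_offset, onset_ms
    awake_h = (awake_hi - awake_lo) / MS_PER_HOUR
    n_sessions = int(rng.poisson(cfg.screen_sessions_per_hour * awake_h))
    for t in sorted(rng.integers(awake_lo, awake_hi, size=n_sessions)):
        on = int(t)
        off = min(on + int(rng.uniform(30, 300) * 1000), onset_ms - 1000)
        if off > on:
            event_rows.append((on, "screen_on"))
            event_rows.append((off, "screen_off"))

    # ---- calls and app sessions (social level) ---------------------------
    call_rows = []
    n_calls = int(rng.poisson(cfg.calls_per_level * levels["social"]))
    for t in sorted(rng.integers(awake_lo, awake_hi, size=n_calls)):
        direction = "incoming" if rng.random() < 0.5 else "outgoing"
        dur = rng.exponential(cfg.call_duration_s_per_level
                              * levels["social"])
        call_rows.append({"start": int(t), "direction": direction,
                          "duration_s": round(float(dur), 1)})

    app_rows = []
    n_social_apps = int(rng.poisson(cfg.social_apps_per_level
                                    * levels["social"]))
    for t in sorted(rng.integers(awake_lo, awake_hi, size=n_social_apps)):
        dur = rng.exponential(cfg.app_duration_s_mean) + 5.0
        app_rows.append({"start": int(t), "app_id": "social_app",
                         "is_social": 1, "duration_s": round(float(dur), 1)})
    n_other = int(rng.poisson(cfg.other_apps_per_day))
    for t in sorted(rng.integers(awake_lo, awake_hi, size=n_other)):
        dur = rng.exponential(cfg.app_duration_s_mean) + 5.0
        app_rows.append({"start": int(t), "app_id": "other_app",
                         "is_social": 0, "duration_s": round(float(dur), 1)})

    def _frame(rows, kind):
        if not rows:
            return sio.empty_frame(kind)
        df = pd.DataFrame(rows)
        return df.sort_values(sio.STREAM_SPECS[kind].time_col,
                              kind="stable").reset_index(drop=True)

    events = _frame([{"timestamp": t, "kind": k} for t, k in event_rows],
                    "events")
    streams = DayStreams(
        accel_phone=(pd.concat(accel_phone, ignore_index=True)
                     if accel_phone else sio.empty_frame("accel")),
        accel_watch=(pd.concat(accel_watch, ignore_index=True)
                     if accel_watch else sio.empty_frame("accel")),
        hrm=hrm, light=light, events=events,
        calls=_frame(call_rows, "calls"), apps=_frame(app_rows, "apps"),
        ema=pd.DataFrame(ema_rows))
    return latent, streams


def _participant_seed(study_seed: int, participant_id: str) -> int:
    return (int(study_seed) * 1_000_003
            + zlib.crc32(participant_id.encode())) & 0x7FFFFFFF


def simulate_study(n_per_group: Mapping[str, int] | None = None,
                   n_days: int | None = None, seed: int = 42,
                   out_dir: str | Path = "stdd_synthetic",
                   config: StudyConfig | None = None) -> Path:
    """Generate a complete study dataset on disk.

    Writes one directory per participant in the :mod:`stdd.sensing_io`
    layout plus ``_latent_truth.csv`` at the root (ground-truth daily levels
    and sleep intervals, for validation only).  Fully deterministic in
    ``seed``.
    """
    cfg = config or StudyConfig()
    if n_per_group is not None:
        cfg = replace(cfg, n_per_group=dict(n_per_group))
    if n_days is not None:
        cfg = replace(cfg, n_days=int(n_days))
    for g, n in cfg.n_per_group.items():
        if g not in GROUPS:
            raise KeyError(f"unknown group {g!r}")
        if n < 1:
            raise ValueError("n_per_group values must be >= 1")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    latent_rows = []
    idx = 0
    for group in GROUPS:
        for _ in range(int(cfg.n_per_group.get(group, 0))):
            idx += 1
            pid = f"p{idx:02d}"
            profile = make_profile(group, pid, seed, cfg)
            rng = np.random.default_rng(np.random.SeedSequence(
                [_participant_seed(seed, pid), 1]))
            parts: dict[str, list[pd.DataFrame]] = {
                k: [] for k in ("accel_phone", "accel_watch", "hrm", "light",
                                "events", "calls", "apps", "ema")}
            prev = None
            for d in range(cfg.n_days):
                day = cfg.start_date + timedelta(days=d)
                latent, streams = simulate_day(profile, day, rng, cfg, prev)
                prev = latent
                for k in parts:
                    parts[k].append(getattr(streams, k))
                latent_rows.append({
                    "participant_id": pid, "date": day.isoformat(),
                    **{c: latent.levels[c] for c in CLUSTERS},
                    "sleep_onset_ms": latent.sleep_onset_ms,
                    "sleep_offset_ms": latent.sleep_offset_ms,
                    "sleep_duration_h": round(latent.sleep_duration_h, 4),
                })
            pdir = out / pid
            pdir.mkdir(exist_ok=True)
            for fname, (kind, _dev) in sio.DATASET_LAYOUT.items():
                key = fname[:-4]
                frame = pd.concat(parts[key], ignore_index=True)
                sio.write_frame(frame, kind, pdir / fname)
            sio.write_manifest(profile.manifest(), pdir / "manifest.csv")
            logger.info("simulated %s (%s): %d days", pid, group, cfg.n_days)

    pd.DataFrame(latent_rows).to_csv(out / "_latent_truth.csv", index=False)
    return out


def read_latent_truth(dataset_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(dataset_dir) / "_latent_truth.csv",
                       dtype={"participant_id": object})
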