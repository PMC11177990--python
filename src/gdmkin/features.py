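"""Kinematic GDM features: magnitude statistics, entropy, zero-crossings.

Per positive 3-s window, eight features are computed from the velocity
magnitude and eight from the acceleration magnitude: minimum, median,
maximum, RMS, a fixed-bin histogram entropy, and three zero-crossing
features taken per axis and averaged across the three axes — sign-change
count, mean constant-sign run length, and the Shannon entropy of the run
length distribution. Zero-crossing features quantify jerkiness: choreatic
or overshooting movement flips the sign of the band-passed acceleration
more often, producing more crossings with shorter, more variable runs.

Aggregation to subject level is median within each day (robust to outlier
windows), then an unweighted mean across days; daily episode counts are
summed within the day and averaged across days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ProcessedSignals
from .segmentation import (
    DURATION_THRESHOLDS,
    GdmEpisode,
    WindowGrid,
    duration_threshold_counts,
    windows_to_episodes,
)

#: Magnitude-histogram caps (entropy binning range), in signal units.
#: Chosen from the synthetic generator's typical dynamic range; values above
#: the cap land in the top bin.
DEFAULT_ACCEL_CAP = 2.0  # m/s^2
DEFAULT_VEL_CAP = 0.5  # integral units


@dataclass(frozen=True)
class FeatureConfig:
    n_bins: int = 128
    accel_cap: float = DEFAULT_ACCEL_CAP
    vel_cap: float = DEFAULT_VEL_CAP
    per_episode: bool = False  # compute features per merged episode instead of per window

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


SIGNAL_FEATURES = (
    "min",
    "median",
    "max",
    "rms",
    "entropy",
    "zc_count",
    "zc_mean_duration",
    "zc_duration_entropy",
)

COUNT_FEATURES = ("gdm_count",) + tuple(
    f"gdm_count_gt_{th:g}".replace(".", "_") for th in DURATION_THRESHOLDS
)

FEATURE_COLUMNS = tuple(
    f"{sig}_{feat}" for sig in ("velocity", "acceleration") for feat in SIGNAL_FEATURES
) + COUNT_FEATURES


def magnitude_stats(mag: np.ndarray) -> tuple[float, float, float, float]:
    """(min, median, max, rms) of a magnitude window."""
    mag = np.asarray(mag, dtype=float)
    if mag.size == 0:
        raise ValueError("empty window")
    return (
        float(mag.min()),
        float(np.median(mag)),
        float(mag.max()),
        float(np.sqrt(np.mean(mag**2))),
    )


def magnitude_entropy(mag: np.ndarray, n_bins: int = 128, cap: float = 1.0) -> float:
    """Shannon entropy (nats) of a fixed-bin magnitude histogram.

    Bins are ``n_bins`` equal widths on [0, cap]; values above the cap are
    clipped into the last bin, empty bins contribute zero. A degenerate
    window with all samples in one bin has entropy 0.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.size == 0:
        raise ValueError("empty window")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    clipped = np.clip(mag, 0.0, cap)
    hist, _ = np.histogram(clipped, bins=n_bins, range=(0.0, cap))
    p = hist[hist > 0] / mag.size
    return float(-np.sum(p * np.log(p)))


def _runs_one_axis(x: np.ndarray) -> np.ndarray:
    """Lengths of maximal constant-sign runs; zeros join the preceding run."""
    signs = np.sign(x)
    nz = signs != 0
    if not nz.any():
        return np.array([len(x)])
    # forward-fill zeros with the preceding sign; leading zeros take the first sign
    idx = np.where(nz, np.arange(len(x)), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = signs[idx]
    first = np.flatnonzero(nz)[0]
    filled[:first] = signs[first]
    change = np.flatnonzero(filled[1:] != filled[:-1])
    return np.diff(np.r_[0, change + 1, len(x)])


def zero_crossing_features(axes: np.ndarray) -> tuple[float, float, float]:
    """(count, mean run duration, run-duration entropy), averaged across axes.

    Per axis: crossings are strict sign changes between consecutive samples
    (zero samples attach to the preceding sign, no epsilon threshold); runs
    are the maximal constant-sign segments, so count + 1 = number of runs;
    the duration entropy is the plug-in Shannon entropy (nats) of the
    empirical run-length distribution with unit-sample bins. An all-zero
    axis reports count 0, mean duration = window length, entropy 0.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    counts, mean_durs, ents = [], [], []
    # accept (n, k) sample-major windows or a single 1-D axis
    cols = axes.T if axes.shape[0] > axes.shape[1] else axes
    for x in cols:
        runs = _runs_one_axis(x)
        counts.append(len(runs) - 1)
        mean_durs.append(float(np.mean(runs)))
        _, freq = np.unique(runs, return_counts=True)
        p = freq / freq.sum()
        ents.append(float(-np.sum(p * np.log(p))))
    return float(np.mean(counts)), float(np.mean(mean_durs)), float(np.mean(ents))


def _signal_features(mag: np.ndarray, axes: np.ndarray, cfg: FeatureConfig, cap: float) -> dict:
    mn, med, mx, rms = magnitude_stats(mag)
    ent = magnitude_entropy(mag, cfg.n_bins, cap)
    zc, zc_dur, zc_ent = zero_crossing_features(axes)
    return {
        "min": mn,
        "median": med,
        "max": mx,
        "rms": rms,
        "entropy": ent,
        "zc_count": zc,
        "zc_mean_duration": zc_dur,
        "zc_duration_entropy": zc_ent,
    }


def window_features(
    signals: ProcessedSignals, start: int, stop: int, cfg: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """The 16 velocity + acceleration features for one sample slice."""
    out: dict[str, float] = {}
    vel = _signal_features(signals.vel_mag[start:stop], signals.vel[start:stop], cfg, cfg.vel_cap)
    acc = _signal_features(
        signals.accel_mag[start:stop], signals.accel[start:stop], cfg, cfg.accel_cap
    )
    out.update({f"velocity_{k}": v for k, v in vel.items()})
    out.update({f"acceleration_{k}": v for k, v in acc.items()})
    return out


def extract_day_features(
    signals: ProcessedSignals,
    labels: np.ndarray,
    grid: WindowGrid = WindowGrid(),
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-window feature rows and episode duration counts for one day.

    By default features are computed on each positive 3-s window; with
    ``cfg.per_episode`` they are computed once per merged episode instead.
    """
    episodes = windows_to_episodes(labels, grid)
    counts = duration_threshold_counts(episodes)
    rate = signals.sample_rate
    rows: list[dict[str, float]] = []
    if cfg.per_episode:
        slices = [(int(ep.start * rate), int(ep.end * rate)) for ep in episodes]
    else:
        wlen = int(round(grid.window_length * rate))
        slices = [
            (int(round(i * grid.stride * rate)), int(round(i * grid.stride * rate)) + wlen)
            for i in np.flatnonzero(labels)
        ]
    for i0, i1 in slices:
        i1 = min(i1, len(signals.accel_mag))
        if i1 > i0:
            rows.append(window_features(signals, i0, i1, cfg))
    columns = [f"{sig}_{f}" for sig in ("velocity", "acceleration") for f in SIGNAL_FEATURES]
    return pd.DataFrame(rows, columns=columns), counts


def aggregate_daily(window_rows: pd.DataFrame) -> pd.Series | None:
    """Median of each feature over one day's GDM windows (None if no windows)."""
    if len(window_rows) == 0:
        warnings.warn("day with zero GDM windows excluded from aggregation", stacklevel=2)
        return None
    return window_rows.median()


def aggregate_subject(daily_rows: list[pd.Series]) -> pd.Series:
    """Unweighted mean of daily medians across a subject's valid days."""
    valid = [row for row in daily_rows if row is not None]
    if not valid:
        raise ValueError("subject has no day with GDM windows")
    return pd.concat(valid, axis=1).mean(axis=1)


def subject_feature_row(
    day_results: list[tuple[pd.DataFrame, dict[str, int]]],
) -> pd.Series:
    """Combine one subject's per-day window features and counts into one row.

    Kinematic features: mean across days of daily medians. Count features:
    mean across days of the day's episode totals (counts are summed within
    the day by construction, then averaged, not medianed).
    """
    dailies = [aggregate_daily(df) for df, _ in day_results]
    feats = aggregate_subject(dailies)
    count_df = pd.DataFrame([c for _, c in day_results])
    feats["gdm_count"] = count_df["total"].mean()
    for th in DURATION_THRESHOLDS:
        key = f"gt_{th:g}".replace(".", "_")
        feats[f"gdm_count_{key}"] = count_df[key].mean()
    feats["n_days"] = len([d for d in dailies if d is not None])
    return feats
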