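"""Window-level GDM detection and merging of windows into episodes.

The detection unit is a 3-second window: a window counts as goal-directed
movement when at least 1.5 s of it overlaps GDM activity. Two detectors
share this interface — an oracle that reads the simulator's ground-truth
intervals, and a heuristic envelope detector for streams without labels
(the study's learned detector is deliberately not re-implemented; anything
honouring the same window contract can be dropped in). Consecutive positive
windows are merged into episodes so durations beyond a single window are
expressible, and episode counts above a set of duration thresholds
(4.5 … 16.5 s) are the count features of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ProcessedSignals
from .synthetic import AccelRecording

DURATION_THRESHOLDS = (4.5, 7.5, 10.5, 13.5, 16.5)


@dataclass(frozen=True)
class WindowGrid:
    window_length: float = 3.0  # s
    stride: float = 3.0  # s, non-overlapping by default
    min_gdm_coverage: float = 1.5  # s of GDM required for a positive window

    def __post_init__(self) -> None:
        if not 0 < self.min_gdm_coverage <= self.window_length:
            raise ValueError("need 0 < min_gdm_coverage <= window_length")
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    def n_windows(self, duration: float) -> int:
        if duration < self.window_length:
            return 0
        return int(np.floor((duration - self.window_length) / self.stride)) + 1

    def window_start(self, index: int) -> float:
        return index * self.stride


@dataclass
class GdmEpisode:
    start: float  # s
    end: float  # s
    member_windows: list[int] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end - self.start


def label_windows_oracle(recording: AccelRecording, grid: WindowGrid = WindowGrid()) -> np.ndarray:
    """Ground-truth window labels from the recording's true GDM intervals.

    A window is positive iff its total overlap with the union of true
    intervals reaches ``min_gdm_coverage`` seconds.
    """
    if recording.true_gdm_intervals is None:
        raise ValueError("recording has no ground-truth intervals; use the heuristic detector")
    n = grid.n_windows(recording.duration)
    labels = np.zeros(n, dtype=bool)
    starts = np.arange(n) * grid.stride
    ends = starts + grid.window_length
    overlap = np.zeros(n)
    for a, b in recording.true_gdm_intervals:
        overlap += np.clip(np.minimum(ends, b) - np.maximum(starts, a), 0.0, None)
    labels = overlap >= grid.min_gdm_coverage - 1e-12
    return labels


def label_windows_heuristic(
    signals: ProcessedSignals,
    grid: WindowGrid = WindowGrid(),
    threshold: float = 0.05,
    smooth_s: float = 0.25,
) -> np.ndarray:
    """Envelope-threshold window labels for streams without ground truth.

    A sample is "active" when the smoothed acceleration-magnitude envelope
    exceeds ``threshold`` (m/s^2); a window is positive when its active time
    reaches ``min_gdm_coverage``.
    """
    rate = signals.sample_rate
    mag = signals.accel_mag
    w = max(int(smooth_s * rate), 1)
    env = np.convolve(mag, np.ones(w) / w, mode="same")
    active = env > threshold
    n = grid.n_windows(len(mag) / rate)
    labels = np.zeros(n, dtype=bool)
    need = grid.min_gdm_coverage * rate
    wlen = int(round(grid.window_length * rate))
    for i in range(n):
        i0 = int(round(i * grid.stride * rate))
        labels[i] = active[i0 : i0 + wlen].sum() >= need - 1e-9
    return labels


def windows_to_episodes(labels: np.ndarray, grid: WindowGrid = WindowGrid()) -> list[GdmEpisode]:
    """Merge maximal runs of consecutive positive windows into episodes.

    Episode bounds are the outer bounds of the run's windows; with the
    default non-overlapping grid an episode of ``k`` windows lasts exactly
    ``3 k`` seconds.
    """
    labels = np.asarray(labels, dtype=bool)
    episodes: list[GdmEpisode] = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i]:
            j = i
            while j + 1 < n and labels[j + 1]:
                j += 1
            episodes.append(
                GdmEpisode(
                    start=grid.window_start(i),
                    end=grid.window_start(j) + grid.window_length,
                    member_windows=list(range(i, j + 1)),
                )
            )
            i = j + 1
        else:
            i += 1
    return episodes


def duration_threshold_counts(
    episodes: list[GdmEpisode], thresholds: tuple[float, ...] = DURATION_THRESHOLDS
) -> dict[str, int]:
    """Total episode count plus counts strictly exceeding each duration threshold."""
    durations = np.array([ep.duration for ep in episodes], dtype=float)
    counts = {"total": int(durations.size)}
    for th in thresholds:
        key = f"gt_{th:g}".replace(".", "_")
        counts[key] = int(np.sum(durations > th))
    return counts
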