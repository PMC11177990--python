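"""Synthetic multi-day wrist-accelerometer cohorts with ground-truth labels.

Generates tri-axial acceleration streams for three groups — manifest
Huntington's disease (HD), prodromal HD (pHD) and controls (CTR) — whose
goal-directed movements (GDMs) differ in the ways the downstream analysis
is designed to detect: lower peak/median velocity, more acceleration
zero-crossings with shorter constant-sign segments (a chorea/jerkiness
surrogate), and fewer long-duration GDMs in the HD-like group. Clinical
scores (UHDRS motor/functional, TFC, and the upper-limb UHDRS-UL item sum)
are coupled monotonically to a latent severity in [0, 1].

Every recording carries exact GDM interval labels, so the segmentation
stage can be evaluated against ground truth without any external data.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import signal as _signal

GROUPS = ("HD", "pHD", "CTR")

#: Default severity interval per group (latent scale, 0 = healthy).
SEVERITY_INTERVALS = {"CTR": (0.0, 0.1), "pHD": (0.1, 0.4), "HD": (0.4, 1.0)}

#: Default group sizes mirroring the study cohort (HD, pHD, CTR).
DEFAULT_GROUP_SIZES = (16, 7, 16)


@dataclass
class SubjectProfile:
    """Latent movement phenotype of one simulated subject.

    ``severity`` drives every group contrast: reach amplitude (and hence
    peak velocity) shrinks with severity, band-limited jerk noise
    (``tremor_amplitude``) grows with it, and the probability that a GDM is
    drawn from the long-duration regime falls with it.
    """

    subject_id: str
    group: str
    severity: float
    reach_amplitude_mean: float = 0.4  # m, healthy point-to-point reach
    movement_time_mean: float = 3.0  # s, typical GDM duration
    tremor_amplitude: float = 0.0  # m/s^2 RMS of band-limited jerk noise
    tremor_band: tuple[float, float] = (2.0, 10.0)  # Hz
    gdm_rate_per_hour: float = 100.0
    long_gdm_fraction: float = 0.25
    pause_probability: float = 0.0  # chance of a mid-movement pause
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if self.movement_time_mean <= 0:
            raise ValueError("movement_time_mean must be positive")


@dataclass
class AccelRecording:
    """One subject-day tri-axial acceleration stream (m/s^2, gravity included)."""

    subject_id: str
    day_index: int
    sample_rate: float
    accel: np.ndarray  # (n, 3)
    true_gdm_intervals: list[tuple[float, float]] = field(default_factory=list)
    worn_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.worn_mask is None:
            self.worn_mask = np.ones(len(self.accel), dtype=bool)
        dur = self.duration
        prev_end = -np.inf
        for start, end in self.true_gdm_intervals:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(f"interval ({start}, {end}) outside recording")
            if start < prev_end:
                raise ValueError("true_gdm_intervals must be sorted and disjoint")
            prev_end = end

    @property
    def duration(self) -> float:
        return len(self.accel) / self.sample_rate

    def time(self) -> np.ndarray:
        return np.arange(len(self.accel)) / self.sample_rate


@dataclass
class ClinicalScores:
    """UHDRS-style scores for one visit; ``uhdrs_ul`` is always the item sum."""

    uhdrs_motor: int
    uhdrs_functional: int
    tfc: int
    item_scores: dict[str, int]

    @property
    def uhdrs_ul(self) -> int:
        return int(sum(self.item_scores.values()))

    def as_dict(self) -> dict[str, int]:
        return {
            "uhdrs_motor": self.uhdrs_motor,
            "uhdrs_functional": self.uhdrs_functional,
            "tfc": self.tfc,
            "uhdrs_ul": self.uhdrs_ul,
        }


#: The ten upper-limb items summed into UHDRS-UL (five per limb).
UL_ITEMS = tuple(
    f"{item}_{side}"
    for item in ("finger_tapping", "pronate_supinate", "rigidity", "dystonia", "chorea")
    for side in ("left", "right")
)


@dataclass
class CohortMember:
    profile: SubjectProfile
    recordings: list[AccelRecording]
    scores: ClinicalScores


def default_profile(
    subject_id: str, group: str, severity: float, rng_seed: int = 0, **overrides
) -> SubjectProfile:
    """Build a profile whose contrast parameters follow the latent severity.

    The slopes are calibrated so the simulated cohort shows daily GDM counts
    near 1100–1200 per 12 waking hours, a long-GDM share falling from ~24 %
    (healthy) to ~9 % (severity 0.7), and jerk noise that inflates
    acceleration zero-crossings in proportion to severity.
    """
    params = dict(
        reach_amplitude_mean=0.4 * (1.0 - 0.5 * severity),
        tremor_amplitude=0.12 * severity,
        gdm_rate_per_hour=100.0 - 10.0 * severity,
        long_gdm_fraction=max(0.25 - 0.23 * severity, 0.02),
        pause_probability=0.5 * max(0.0, severity - 0.5),
    )
    params.update(overrides)
    return SubjectProfile(
        subject_id=subject_id, group=group, severity=severity, rng_seed=rng_seed, **params
    )


@lru_cache(maxsize=32)
def _band_sos(low: float, high: float, rate: float) -> np.ndarray:
    return _signal.butter(2, [low, high], btype="bandpass", fs=rate, output="sos")


def _band_limited_noise(
    n: int, band: tuple[float, float], rate: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """White Gaussian noise confined to ``band`` and scaled to target RMS, (n, 3)."""
    high = min(band[1], 0.45 * rate)
    sos = _band_sos(band[0], high, rate)
    white = rng.standard_normal((n, 3))
    shaped = _signal.sosfilt(sos, white, axis=0)
    scale = np.sqrt(np.mean(shaped**2, axis=0))
    scale[scale == 0] = 1.0
    return shaped * (rms / scale)


def _min_jerk_accel(n: int, duration: float, amplitude: float, rate: float) -> np.ndarray:
    """Closed-form minimum-jerk acceleration along the movement axis.

    Position follows x(tau) = D (10 tau^3 - 15 tau^4 + 6 tau^5), so the
    acceleration is a(tau) = D/T^2 (60 tau - 180 tau^2 + 120 tau^3), with a
    single interior sign change at tau = 1/2.
    """
    tau = np.arange(n) / (rate * duration)
    return (amplitude / duration**2) * (60 * tau - 180 * tau**2 + 120 * tau**3)


#: Sub-movement duration bounds: a GDM longer than the upper bound is built
#: as a chain of min-jerk sub-reaches, the way sustained goal-directed
#: activity decomposes into successive sub-movements. Keeping sub-movements
#: short also keeps their velocity content above the 0.1 Hz high-pass edge.
SUBMOVEMENT_RANGE = (1.0, 3.0)


def _split_submovements(duration: float, rng: np.random.Generator) -> list[float]:
    lo, hi = SUBMOVEMENT_RANGE
    if duration <= hi:
        return [duration]
    parts: list[float] = []
    remaining = duration
    while remaining > hi:
        d = rng.uniform(lo, hi)
        parts.append(d)
        remaining -= d
    parts.append(max(remaining, 0.1))
    return parts


def simulate_gdm_trajectory(
    profile: SubjectProfile,
    duration: float,
    rng: np.random.Generator,
    sample_rate: float = 50.0,
) -> np.ndarray:
    """Simulate one goal-directed movement as a tri-axial acceleration segment.

    A GDM up to ~3 s is a single minimum-jerk point-to-point reach along a
    random 3-D direction; longer GDMs are chains of such sub-reaches, each
    with its own direction. Reach amplitude scales with sub-movement
    duration and shrinks linearly with severity, so peak velocity is
    strictly lower at higher severity for the same seed and duration.
    Band-limited stochastic jerk noise proportional to ``tremor_amplitude``
    is added, and high-severity subjects may pause between sub-movements.

    Returns an ``(n, 3)`` array in m/s^2, gravity-free; ``n`` =
    ``round(duration * sample_rate)``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = max(int(round(duration * sample_rate)), 4)
    amp_scale = max(1.0 - 0.5 * profile.severity, 0.05)
    ref_dur = SUBMOVEMENT_RANGE[1]

    accel = np.zeros((n, 3))
    pos = 0
    for sub_dur in _split_submovements(duration, rng):
        if pos > 0 and rng.random() < profile.pause_probability:
            pos += int(rng.uniform(0.3, 1.0) * sample_rate)  # still pause between reaches
        m = int(round(sub_dur * sample_rate))
        if pos >= n or m < 2:
            break
        m = min(m, n - pos)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        # amplitude proportional to sub-duration keeps peak velocity
        # (~1.875 D / T) independent of T and linear in the severity scale
        amplitude = profile.reach_amplitude_mean * amp_scale * (sub_dur / ref_dur)
        along = _min_jerk_accel(m, m / sample_rate, amplitude, sample_rate)
        accel[pos : pos + m] += np.outer(along, direction)
        pos += m

    if profile.tremor_amplitude > 0:
        accel += _band_limited_noise(
            n, profile.tremor_band, sample_rate, profile.tremor_amplitude, rng
        )
    return accel


def _draw_gdm_durations(profile: SubjectProfile, k: int, rng: np.random.Generator) -> np.ndarray:
    """Two-regime duration mixture: short reaches 1–6 s, long sequences 8–20 s."""
    long = rng.random(k) < profile.long_gdm_fraction
    durations = rng.uniform(1.0, 6.0, size=k)
    durations[long] = rng.uniform(8.0, 20.0, size=int(long.sum()))
    return durations


def _gravity(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Constant-magnitude 9.81 m/s^2 gravity vector with slow orientation drift."""
    t = np.arange(n) / rate
    theta0, phi0 = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
    # drift well below the 0.1 Hz high-pass edge so preprocessing removes it
    theta = theta0 + 0.15 * np.sin(2 * np.pi * 0.002 * t + rng.uniform(0, 2 * np.pi))
    phi = phi0 + 0.15 * np.sin(2 * np.pi * 0.0013 * t + rng.uniform(0, 2 * np.pi))
    g = 9.81
    return np.column_stack(
        (g * np.sin(theta) * np.cos(phi), g * np.sin(theta) * np.sin(phi), g * np.cos(theta))
    )


def assemble_day(
    profile: SubjectProfile,
    day_index: int,
    day_length_hours: float,
    rng: np.random.Generator,
    sample_rate: float = 50.0,
    idle_noise_rms: float = 0.02,
) -> AccelRecording:
    """Assemble one waking day: GDM segments interleaved with idle noise.

    The GDM count is Poisson with mean ``gdm_rate_per_hour * day_length``;
    durations come from the two-regime mixture, so the expected number of
    GDMs longer than 7.5 s falls with severity. Segments are placed without
    overlap by distributing the idle time into random gaps. A slowly
    drifting gravity projection is added to all samples.
    """
    if day_length_hours <= 0:
        raise ValueError("day_length_hours must be positive")
    total_s = day_length_hours * 3600.0
    n_total = int(round(total_s * sample_rate))

    k = rng.poisson(profile.gdm_rate_per_hour * day_length_hours)
    durations = _draw_gdm_durations(profile, k, rng)
    # drop movements that cannot fit
    while durations.sum() > 0.9 * total_s and len(durations):
        durations = durations[:-1]
    k = len(durations)

    accel = idle_noise_rms * rng.standard_normal((n_total, 3))

    intervals: list[tuple[float, float]] = []
    if k:
        idle = total_s - durations.sum()
        gaps = rng.random(k + 1)
        gaps = gaps / gaps.sum() * idle
        start = 0.0
        for i in range(k):
            start += gaps[i]
            seg = simulate_gdm_trajectory(profile, durations[i], rng, sample_rate)
            i0 = int(round(start * sample_rate))
            i1 = min(i0 + len(seg), n_total)
            accel[i0:i1] += seg[: i1 - i0]
            intervals.append((i0 / sample_rate, i1 / sample_rate))
            start += durations[i]

    accel += _gravity(n_total, sample_rate, rng)
    return AccelRecording(
        subject_id=profile.subject_id,
        day_index=day_index,
        sample_rate=sample_rate,
        accel=accel,
        true_gdm_intervals=intervals,
    )


def severity_to_scores(
    severity: float, rng: np.random.Generator, noise_scale: float = 1.0
) -> ClinicalScores:
    """Map latent severity to UHDRS-style clinical scores with ordinal noise.

    The maps are monotone in expectation: motor and each upper-limb item
    increase with severity, TFC (0–13, 13 = fully functional) and the
    functional score decrease. UHDRS-UL is never set directly — it is the
    sum of the ten item scores by construction. Slopes are anchored so a
    severity-0.7 subject scores near the published HD group means (motor
    ~46, TFC ~9) and a near-zero severity subject near the control means.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")

    def _ordinal(x: float, lo: int, hi: int, sd: float) -> int:
        return int(np.clip(round(x + rng.normal(0.0, sd * noise_scale)), lo, hi))

    motor = _ordinal(80.0 * severity**1.5, 0, 124, 3.0)
    functional = _ordinal(25.0 - 8.0 * severity**1.2, 0, 25, 1.0)
    tfc = _ordinal(13.0 - 6.5 * severity**1.3, 0, 13, 0.7)
    items = {name: _ordinal(4.0 * severity**1.2, 0, 4, 0.4) for name in UL_ITEMS}
    return ClinicalScores(
        uhdrs_motor=motor, uhdrs_functional=functional, tfc=tfc, item_scores=items
    )


def generate_cohort(
    group_sizes: tuple[int, int, int] = DEFAULT_GROUP_SIZES,
    seed: int = 0,
    n_days: int = 7,
    day_length_hours: float = 12.0,
    sample_rate: float = 50.0,
    severity_intervals: dict[str, tuple[float, float]] | None = None,
    profile_overrides: dict | None = None,
) -> list[CohortMember]:
    """Generate a labelled cohort: profiles, multi-day recordings, scores.

    ``group_sizes`` is (HD, pHD, CTR). Fully reproducible given ``seed``:
    every subject-day stream is drawn from an independent spawned
    sub-generator, so the cohort is bit-identical across calls.
    """
    if any(s < 0 for s in group_sizes):
        raise ValueError("group sizes must be non-negative")
    intervals = dict(SEVERITY_INTERVALS)
    if severity_intervals:
        intervals.update(severity_intervals)
    bounds = sorted(intervals.values())
    for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
        if hi1 > lo2:
            warnings.warn("group severity intervals overlap", stacklevel=2)

    root = np.random.SeedSequence(seed)
    cohort: list[CohortMember] = []
    idx = 0
    for group, size in zip(GROUPS, group_sizes):
        lo, hi = intervals[group]
        for _ in range(size):
            (sub_ss,) = root.spawn(1)
            rng = np.random.default_rng(sub_ss)
            severity = rng.uniform(lo, hi)
            profile = default_profile(
                f"S{idx:03d}",
                group,
                severity,
                rng_seed=int(sub_ss.entropy % 2**31),
                **(profile_overrides or {}),
            )
            recordings = [
                assemble_day(profile, day, day_length_hours, rng, sample_rate)
                for day in range(n_days)
            ]
            scores = severity_to_scores(severity, rng)
            cohort.append(CohortMember(profile, recordings, scores))
            idx += 1
    return cohort


# ---------------------------------------------------------------------------
# CSV writers: one recording file per subject-day, an interval sidecar, and a
# cohort manifest tying subjects to files, group labels and clinical scores.
# ---------------------------------------------------------------------------


def write_recording(recording: AccelRecording, path: Path) -> None:
    t = recording.time()
    arr = np.column_stack((t, recording.accel))
    header = "t,ax,ay,az"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.6f")


def write_intervals(recording: AccelRecording, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s"])
        for start, end in recording.true_gdm_intervals:
            writer.writerow([f"{start:.4f}", f"{end:.4f}"])


def read_recording(path: Path, sample_rate: float | None = None) -> np.ndarray:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data


def read_intervals(path: Path) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((float(row["start_s"]), float(row["end_s"])))
    return out


def write_cohort(cohort: list[CohortMember], outdir: Path) -> Path:
    """Write every recording + sidecar and a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    fields = [
        "subject_id",
        "group",
        "severity",
        "day_index",
        "sample_rate",
        "recording_file",
        "intervals_file",
        "uhdrs_motor",
        "uhdrs_functional",
        "tfc",
        "uhdrs_ul",
    ]
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for member in cohort:
            scores = member.scores.as_dict()
            for rec in member.recordings:
                stem = f"{rec.subject_id}_day{rec.day_index}"
                rec_path = outdir / f"{stem}.csv"
                int_path = outdir / f"{stem}_intervals.csv"
                write_recording(rec, rec_path)
                write_intervals(rec, int_path)
                writer.writerow(
                    {
                        "subject_id": rec.subject_id,
                        "group": member.profile.group,
                        "severity": f"{member.profile.severity:.6f}",
                        "day_index": rec.day_index,
                        "sample_rate": rec.sample_rate,
                        "recording_file": rec_path.name,
                        "intervals_file": int_path.name,
                        **scores,
                    }
                )
    return manifest
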