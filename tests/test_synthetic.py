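"""Generator contracts: closed-form kinematics, effect directions, score coupling."""

import numpy as np
import pytest
from scipy import integrate, stats

from gdmkin.synthetic import (
    UL_ITEMS,
    assemble_day,
    default_profile,
    generate_cohort,
    severity_to_scores,
    simulate_gdm_trajectory,
)

RATE = 50.0


def _profile(severity=0.0, **kw):
    return default_profile("X", "CTR", severity=severity, **kw)


class TestTrajectory:
    def test_single_reach_matches_minimum_jerk_closed_form(self, rng):
        """A noise-free short reach follows a(tau) ∝ 60tau - 180tau^2 + 120tau^3."""
        prof = _profile(tremor_amplitude=0.0, pause_probability=0.0)
        duration = 2.0
        seg = simulate_gdm_trajectory(prof, duration, rng, sample_rate=RATE)
        n = len(seg)
        tau = np.arange(n) / n
        shape = 60 * tau - 180 * tau**2 + 120 * tau**3
        for axis in range(3):
            x = seg[:, axis]
            assert abs(np.corrcoef(x, shape)[0, 1]) > 1 - 1e-10
            signs = np.sign(x[1:-1])
            signs = signs[signs != 0]  # the exact tau = 1/2 sample sits on zero
            flips = np.sum(signs[1:] != signs[:-1])
            assert flips == 1  # single interior zero-crossing at tau = 1/2

    def test_peak_velocity_strictly_lower_at_high_severity(self):
        seed = 99
        segs = {}
        for sev in (0.0, 1.0):
            prof = _profile(severity=sev, tremor_amplitude=0.0, pause_probability=0.0)
            segs[sev] = simulate_gdm_trajectory(
                prof, 2.5, np.random.default_rng(seed), sample_rate=RATE
            )
        peaks = {
            sev: np.max(
                np.linalg.norm(
                    integrate.cumulative_trapezoid(seg, dx=1 / RATE, axis=0, initial=0), axis=1
                )
            )
            for sev, seg in segs.items()
        }
        assert peaks[1.0] < peaks[0.0]

    def test_tremor_noise_inflates_zero_crossings(self):
        """Band-limited jerk noise strictly raises the mean sign-change count."""

        def mean_zc(tremor, n_draws=25):
            counts = []
            for seed in range(n_draws):
                prof = _profile(tremor_amplitude=tremor)
                seg = simulate_gdm_trajectory(prof, 2.0, np.random.default_rng(seed), RATE)
                for axis in range(3):
                    s = np.sign(seg[:, axis])
                    s = s[s != 0]
                    counts.append(np.sum(s[1:] != s[:-1]))
            return np.mean(counts)

        assert mean_zc(0.1) > mean_zc(0.0)

    def test_long_gdm_built_from_submovements_keeps_velocity_scale(self, rng):
        """A 15 s GDM should not be one slow reach: its speed stays comparable
        to a short reach's, because it chains ordinary sub-movements."""
        prof = _profile(tremor_amplitude=0.0)
        long_seg = simulate_gdm_trajectory(prof, 15.0, rng, RATE)
        short_seg = simulate_gdm_trajectory(prof, 2.0, rng, RATE)

        def peak_speed(seg):
            v = integrate.cumulative_trapezoid(seg, dx=1 / RATE, axis=0, initial=0)
            return np.max(np.linalg.norm(v, axis=1))

        assert peak_speed(long_seg) > 0.3 * peak_speed(short_seg)

    def test_non_positive_duration_rejected(self, rng):
        with pytest.raises(ValueError, match="duration"):
            simulate_gdm_trajectory(_profile(), 0.0, rng)


class TestAssembleDay:
    def test_zero_rate_gives_no_intervals(self, rng):
        rec = assemble_day(_profile(gdm_rate_per_hour=0.0), 0, 0.1, rng, RATE)
        assert rec.true_gdm_intervals == []

    def test_no_long_regime_no_long_episodes(self, rng):
        prof = _profile(long_gdm_fraction=0.0, gdm_rate_per_hour=200.0)
        rec = assemble_day(prof, 0, 0.2, rng, RATE)
        durations = [e - s for s, e in rec.true_gdm_intervals]
        assert durations and max(durations) < 7.5  # short regime tops out at 6 s

    def test_interval_count_is_poisson(self):
        """Pooled interval count over 50 seeded days sits within 3 SD of the
        configured Poisson mean."""
        prof = _profile(gdm_rate_per_hour=80.0)
        day_h = 0.25
        counts = [
            len(assemble_day(prof, 0, day_h, np.random.default_rng(s), RATE).true_gdm_intervals)
            for s in range(50)
        ]
        expected = prof.gdm_rate_per_hour * day_h * 50
        assert abs(sum(counts) - expected) <= 3 * np.sqrt(expected)

    def test_intervals_sorted_disjoint_within_duration(self, rng):
        rec = assemble_day(_profile(), 0, 0.3, rng, RATE)
        prev = 0.0
        for start, end in rec.true_gdm_intervals:
            assert prev <= start < end <= rec.duration + 1e-9
            prev = end

    def test_movement_confined_to_labelled_intervals(self, rng):
        """With idle noise off, high-frequency content exists only inside the
        ground-truth intervals (label soundness)."""
        prof = _profile(gdm_rate_per_hour=30.0)
        rec = assemble_day(prof, 0, 0.1, rng, RATE, idle_noise_rms=0.0)
        jerk = np.abs(np.diff(rec.accel, axis=0)).sum(axis=1)
        inside = np.zeros(len(jerk), dtype=bool)
        for s, e in rec.true_gdm_intervals:
            inside[int(s * RATE) : int(e * RATE)] = True
        assert rec.true_gdm_intervals  # non-degenerate draw
        assert jerk[~inside].max() < 0.01  # only slow gravity drift outside
        assert jerk[inside].max() > 0.01


class TestCohort:
    def test_cohort_shape_arithmetic(self):
        cohort = generate_cohort(
            group_sizes=(16, 7, 16), seed=0, n_days=7, day_length_hours=0.01
        )
        assert len(cohort) == 39
        assert sum(len(m.recordings) for m in cohort) == 273

    def test_same_seed_bit_identical(self):
        kw = dict(group_sizes=(1, 1, 1), seed=42, n_days=1, day_length_hours=0.05)
        a = generate_cohort(**kw)
        b = generate_cohort(**kw)
        for ma, mb in zip(a, b):
            assert ma.profile == mb.profile
            np.testing.assert_array_equal(ma.recordings[0].accel, mb.recordings[0].accel)
            assert ma.scores.as_dict() == mb.scores.as_dict()

    def test_overlapping_severity_intervals_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            generate_cohort(
                group_sizes=(1, 1, 0),
                seed=0,
                n_days=1,
                day_length_hours=0.01,
                severity_intervals={"CTR": (0.0, 0.3), "pHD": (0.2, 0.5)},
            )

    def test_motor_score_calibration_anchors(self):
        """Group-mean synthetic motor scores sit near the published cohort
        anchors: ~46 for manifest HD, ~1 for controls."""
        rng = np.random.default_rng(3)
        hd = [severity_to_scores(rng.uniform(0.4, 1.0), rng).uhdrs_motor for _ in range(400)]
        ctr = [severity_to_scores(rng.uniform(0.0, 0.1), rng).uhdrs_motor for _ in range(400)]
        assert abs(np.mean(hd) - 46) < 6
        assert abs(np.mean(ctr) - 1) < 1.5


class TestScores:
    def test_healthy_anchor_zero_noise(self, rng):
        scores = severity_to_scores(0.0, rng, noise_scale=0.0)
        assert all(v == 0 for v in scores.item_scores.values())
        assert scores.uhdrs_ul == 0
        assert scores.tfc == 13

    def test_ul_is_item_sum(self, rng):
        for _ in range(20):
            s = severity_to_scores(rng.uniform(0, 1), rng)
            assert s.uhdrs_ul == sum(s.item_scores.values())
            assert set(s.item_scores) == set(UL_ITEMS)

    def test_severity_score_rank_coupling(self, rng):
        sev = rng.uniform(0, 1, size=200)
        draws = [severity_to_scores(s, rng) for s in sev]
        motor = [d.uhdrs_motor for d in draws]
        tfc = [d.tfc for d in draws]
        ul = [d.uhdrs_ul for d in draws]
        assert stats.spearmanr(sev, motor).statistic > 0.8
        assert stats.spearmanr(sev, tfc).statistic < -0.8
        assert stats.spearmanr(sev, ul).statistic > 0.8

    def test_severity_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="severity"):
            severity_to_scores(1.5, rng)
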