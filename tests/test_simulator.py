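"""Generator behaviour: latent traces, IMU synthesis, coach labels, corruption."""

import numpy as np
import pytest

import zonewear as zw
from zonewear.simulate import (
    CoachModel,
    ParameterError,
    corrupt_timestamps,
    emit_coach_labels,
    orthogonalize_zone_directions,
    random_profile,
    sample_zone_trace,
    synthesize_imu,
)

from conftest import scaled_cohort_config


def profile(seed=0, **kw):
    return random_profile("P1", seed, **kw)


# ----------------------------------------------------------------------
# zone traces
# ----------------------------------------------------------------------
class TestZoneTrace:
    def test_transition_count_matches_renewal_oracle(self):
        """Mean state changes over many seeds matches an independent
        renewal-process simulation with the same dwell distributions."""
        p = profile(zone_dwell_in_mean=1.0, zone_dwell_out_mean=1.5)
        duration = 600.0
        counts = [
            sample_zone_trace(p, duration, seed=s).n_transitions for s in range(200)
        ]
        # oracle: plain renewal simulation without any trace machinery
        rng = np.random.default_rng(99)
        oracle_counts = []
        for _ in range(2000):
            t, k, n = 0.0, 0, 0
            means = [1.5 * 60, 1.0 * 60]
            while True:
                t += rng.gamma(2.0, means[k % 2] / 2.0)
                if t >= duration:
                    break
                k += 1
                n += 1
            oracle_counts.append(n)
        mean, omean = np.mean(counts), np.mean(oracle_counts)
        osd = np.std(oracle_counts) / np.sqrt(200)
        assert abs(mean - omean) < 4 * osd

    def test_infinite_dwell_gives_almost_no_transitions(self):
        p = profile(zone_dwell_in_mean=200.0, zone_dwell_out_mean=200.0)
        # dwell mean (200 min) is >= 10x the session (10 min)
        counts = [sample_zone_trace(p, 600.0, seed=s).n_transitions for s in range(100)]
        assert np.mean([c <= 1 for c in counts]) >= 0.95

    def test_seeded_determinism(self):
        p = profile()
        a = sample_zone_trace(p, 1200.0, seed=7)
        b = sample_zone_trace(p, 1200.0, seed=7)
        assert np.array_equal(a.transition_times, b.transition_times)
        assert np.array_equal(a.states, b.states)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sample_zone_trace(profile(), -1.0, seed=0)
        bad = profile()
        bad.zone_dwell_in_mean = 0.0
        with pytest.raises(ParameterError):
            sample_zone_trace(bad, 100.0, seed=0)

    def test_trace_invariants(self):
        tr = sample_zone_trace(profile(zone_dwell_in_mean=0.5, zone_dwell_out_mean=0.5), 600.0, seed=3)
        assert tr.transition_times[0] == 0.0 and tr.states[0] == 0
        assert np.all(np.diff(tr.transition_times) > 0)
        assert np.all(tr.states[1:] != tr.states[:-1])
        assert tr.transition_times[-1] < tr.session_duration


# ----------------------------------------------------------------------
# IMU synthesis
# ----------------------------------------------------------------------
class TestSynthesizeImu:
    def test_shape_rate_and_determinism(self):
        p = profile()
        tr = sample_zone_trace(p, 120.0, seed=1)
        a = synthesize_imu(p, tr, seed=2)
        b = synthesize_imu(p, tr, seed=2)
        assert a.channels.shape == (1200, 12)
        assert np.allclose(np.diff(a.timestamps), 0.1)
        assert np.array_equal(a.channels, b.channels)

    def test_zero_signal_classes_indistinguishable(self):
        """Without zone modulation, in/out windows carry no information:
        a discriminant oracle scores at chance."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        cfg = scaled_cohort_config(8.0, signal_scale=0.0, shared_gain=0.0)
        cohort = zw.generate_cohort(cfg, seed=5)
        zw.build_windows(cohort, stride=5)
        accs = []
        for pl in cohort.players:
            X, y = pl.windows.inputs, pl.windows.targets
            if len(np.unique(y)) < 2:
                continue
            F = np.concatenate([X.mean(axis=1), X.std(axis=1)], axis=1)
            half = len(F) // 2
            lda = LinearDiscriminantAnalysis().fit(F[:half], y[:half])
            accs.append(lda.score(F[half:], y[half:]))
        # chance with margin for temporal label autocorrelation
        assert 0.25 <= float(np.mean(accs)) <= 0.75

    def test_default_cohort_oracle_separability(self):
        """Calibration invariant: a discriminant on window summary features
        exceeds 90% within-player accuracy and transfers at <= 60% across
        players on the default cohort."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        within, transfer = [], []
        for seed in range(5):
            cohort = zw.generate_cohort(scaled_cohort_config(10.0), seed=seed)
            zw.build_windows(cohort, stride=5)
            feats = {
                pl.player_id: (
                    np.concatenate(
                        [pl.windows.inputs.mean(axis=1), pl.windows.inputs.std(axis=1)],
                        axis=1,
                    ),
                    pl.windows.targets,
                )
                for pl in cohort.players
            }
            for pid, (F, y) in feats.items():
                keep = np.arange(len(F)) % 3 != 0
                lda = LinearDiscriminantAnalysis().fit(F[keep], y[keep])
                within.append(lda.score(F[~keep], y[~keep]))
                for qid, (F2, y2) in feats.items():
                    if qid != pid:
                        transfer.append(lda.score(F2, y2))
        assert float(np.mean(within)) >= 0.90
        assert float(np.mean(transfer)) <= 0.60

    def test_study_replica_raw_sample_count(self):
        """4 players x 75 min x 10 Hz = 180,000 raw samples before corruption."""
        cfg = zw.study_replica()
        total = 0
        for idx in range(4):
            p = random_profile(f"P{idx+1}", idx)
            tr = sample_zone_trace(p, cfg.session_minutes * 60.0, seed=idx)
            total += len(synthesize_imu(p, tr, seed=idx))
        assert total == 4 * 75 * 60 * 10

    def test_duration_mismatch_rejected(self):
        p = profile()
        tr = sample_zone_trace(p, 0.1, seed=0)
        with pytest.raises(ParameterError):
            synthesize_imu(p, tr, seed=0)


# ----------------------------------------------------------------------
# coach labels
# ----------------------------------------------------------------------
class TestCoachLabels:
    def _flat_trace(self, duration=600.0):
        return zw.ZoneTrace(np.array([0.0]), np.array([0], np.int8), duration)

    def test_no_transitions_sparse_single_initial_event(self):
        ev = emit_coach_labels(self._flat_trace(), CoachModel(style="sparse"), seed=0)
        assert len(ev) == 1 and ev[0].timestamp == 0.0 and ev[0].state == 0

    def test_perfect_observer_event_count(self):
        p = profile(zone_dwell_in_mean=0.5, zone_dwell_out_mean=0.5)
        tr = sample_zone_trace(p, 600.0, seed=4)
        coach = CoachModel(style="sparse", detection_latency_mean=0.0,
                           detection_latency_sd=0.0, miss_prob=0.0)
        ev = emit_coach_labels(tr, coach, seed=0)
        assert len(ev) == tr.n_transitions + 1

    def test_verbose_labels_at_least_3x_sparse(self):
        """Verbose vs sparse labeling on the study-replica trace reproduces
        the many-vs-few label count pattern (mean ratio >= 3 over seeds)."""
        p = profile()
        verbose = CoachModel(style="verbose", verbose_reemit_period=2.5)
        sparse = CoachModel(style="sparse")
        v_counts, s_counts = [], []
        for s in range(20):
            tr = sample_zone_trace(p, 75 * 60.0, seed=s)
            v_counts.append(len(emit_coach_labels(tr, verbose, seed=s)))
            s_counts.append(len(emit_coach_labels(tr, sparse, seed=s)))
        assert np.mean(v_counts) >= 3.0 * np.mean(s_counts)

    def test_event_state_matches_latent_state(self):
        p = profile(zone_dwell_in_mean=0.5, zone_dwell_out_mean=0.5)
        tr = sample_zone_trace(p, 600.0, seed=9)
        ev = emit_coach_labels(tr, CoachModel(style="verbose", verbose_reemit_period=0.5), seed=1)
        for e in ev:
            assert e.state == tr.state_at(e.timestamp)
        assert all(a.timestamp <= b.timestamp for a, b in zip(ev, ev[1:]))

    def test_label_carried_forward_matches_trace_outside_latency(self):
        """With no misses, last-label-carried-forward equals the latent
        trace except within one latency window after each transition."""
        p = profile(zone_dwell_in_mean=0.8, zone_dwell_out_mean=1.0)
        tr = sample_zone_trace(p, 600.0, seed=2)
        coach = CoachModel(style="sparse", detection_latency_mean=2.0,
                           detection_latency_sd=1.0, miss_prob=0.0)
        ev = emit_coach_labels(tr, coach, seed=3)
        t = np.arange(0, 600.0, 0.1)
        times = np.array([e.timestamp for e in ev])
        states = np.array([e.state for e in ev])
        lcf = states[np.clip(np.searchsorted(times, t, side="right") - 1, 0, None)]
        latent = tr.state_at(t)
        mismatch = lcf != latent
        # every mismatching sample lies within the max emitted latency of a transition
        max_latency = max(
            (e.timestamp - tt)
            for e in ev[1:]
            for tt in [tr.transition_times[np.searchsorted(tr.transition_times, e.timestamp, side="right") - 1]]
        )
        for ti in t[mismatch]:
            prev = tr.transition_times[np.searchsorted(tr.transition_times, ti, side="right") - 1]
            assert ti - prev <= max_latency + 0.1


# ----------------------------------------------------------------------
# corruption
# ----------------------------------------------------------------------
class TestCorruption:
    def _series(self, n=10000, seed=0):
        rng = np.random.default_rng(seed)
        return zw.ImuSeries("P", np.arange(n) * 0.1, rng.standard_normal((n, 12)))

    def test_zero_rates_identity(self):
        s = self._series(500)
        out, rec = corrupt_timestamps(s, 0.0, 0.0, seed=1)
        assert np.array_equal(out.timestamps, s.timestamps)
        assert np.array_equal(out.channels, s.channels)
        assert len(rec.duplicated_indices) == 0 and len(rec.dropped_indices) == 0

    def test_duplicate_count_binomial(self):
        s = self._series(10000)
        _, rec = corrupt_timestamps(s, 0.05, 0.0, seed=2)
        n, p = 10000, 0.05
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(rec.duplicated_indices) - n * p) < 3 * sd

    def test_rates_out_of_range_rejected(self):
        s = self._series(100)
        with pytest.raises(ParameterError):
            corrupt_timestamps(s, 0.5, 0.0, seed=0)
        with pytest.raises(ParameterError):
            corrupt_timestamps(s, 0.0, -0.1, seed=0)

    def test_corrupt_then_clean_recovers_linear_ramp(self):
        """Linear interpolation is exact on linear signals: corruption
        followed by cleaning restores a ramp bit-for-bit (up to fp error)."""
        n = 2000
        t = np.arange(n) * 0.1
        ramp = np.outer(t, np.linspace(0.5, 3.0, 12))
        s = zw.ImuSeries("P", t, ramp)
        corrupted, _ = corrupt_timestamps(s, 0.05, 0.05, seed=3)
        cleaned, report = zw.clean_series(corrupted)
        assert len(cleaned) == n
        assert np.max(np.abs(cleaned.channels - ramp)) < 1e-9
        assert report.duplicates_removed > 0 and report.samples_interpolated > 0


# ----------------------------------------------------------------------
# cohort-level invariants
# ----------------------------------------------------------------------
class TestCohortInvariants:
    def test_signature_cross_player_independence(self):
        """Flattened signatures of independently drawn profiles are
        uncorrelated: mean |r| over 50 pairs < 0.15."""
        rs = []
        for k in range(50):
            a = random_profile("A", 2 * k).personal_signature.ravel()
            b = random_profile("B", 2 * k + 1).personal_signature.ravel()
            rs.append(abs(np.corrcoef(a, b)[0, 1]))
        assert float(np.mean(rs)) < 0.15

    def test_orthogonalized_offsets(self):
        profiles = [random_profile(f"P{i}", i) for i in range(4)]
        orthogonalize_zone_directions(profiles)
        dirs = [p.personal_offset_direction() for p in profiles]
        for i in range(4):
            assert np.isclose(np.linalg.norm(dirs[i]), 1.0)
            for j in range(i + 1, 4):
                assert abs(dirs[i] @ dirs[j]) < 1e-9

    def test_generate_cohort_deterministic(self):
        cfg = scaled_cohort_config(3.0)
        a = zw.generate_cohort(cfg, seed=8)
        b = zw.generate_cohort(cfg, seed=8)
        for pa, pb in zip(a.players, b.players):
            assert np.array_equal(pa.series.channels, pb.series.channels)
            assert [e.timestamp for e in pa.events] == [e.timestamp for e in pb.events]
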