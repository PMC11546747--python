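"""Unit PSTH normalization, encoding features, iterative k-means patterns."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rewardseek import synth
from rewardseek.events import TrialEvents
from rewardseek.spikes import (
    SmoothingConfig,
    SpikeSession,
    UnitPSTH,
    build_unit_psths,
    cluster_encoding_patterns,
    discover_encoding_patterns,
    extract_encoding_features,
    gaussian_kernel,
    smooth_rows,
    window_aucz,
)
from conftest import DRUG_MIX, FOOD_MIX


class TestSmoothing:
    def test_kernel_sums_to_one(self):
        assert gaussian_kernel(8, 3.0).sum() == pytest.approx(1.0)

    def test_constant_trace_unchanged(self):
        x = np.full((3, 50), 2.5)
        assert np.allclose(smooth_rows(x, SmoothingConfig()), 2.5)

    def test_mean_preserved_for_interior_bump(self):
        x = np.zeros((1, 100))
        x[0, 40:60] = np.hanning(20)
        sm = smooth_rows(x, SmoothingConfig())
        assert abs(sm.mean() - x.mean()) < 1e-10


class TestBuildUnitPSTHs:
    def test_homogeneous_unit_normalizes_to_one(self, pr_events):
        rng = np.random.default_rng(0)
        dur = pr_events.duration
        units = [(u, np.sort(rng.uniform(0, dur, rng.poisson(10 * dur)))) for u in range(12)]
        sess = SpikeSession(units=units, session_duration=dur)
        psths = build_unit_psths(sess, pr_events)
        rate = np.mean([p.mean_rate_trace.mean() for p in psths])
        se = 1.0 / np.sqrt(10 * dur * 12)
        assert abs(rate - 1.0) < 4 * se

    def test_identical_trains_identical_psths(self, pr_events):
        st = np.sort(np.random.default_rng(1).uniform(0, pr_events.duration, 3000))
        sess = SpikeSession(
            units=[(0, st), (1, st), (2, st + 0.001)],
            session_duration=pr_events.duration + 1,
        )
        psths = build_unit_psths(sess, pr_events)
        assert np.array_equal(psths[0].z, psths[1].z)

    def test_zero_spike_unit_excluded_with_warning(self, pr_events):
        st = np.sort(np.random.default_rng(2).uniform(0, pr_events.duration, 2000))
        sess = SpikeSession(
            units=[(0, st), (1, np.array([]))], session_duration=pr_events.duration
        )
        with pytest.warns(UserWarning, match="zero spikes"):
            psths = build_unit_psths(sess, pr_events)
        assert len(psths) == 1

    def test_no_cues_rejected(self, food_session):
        empty = TrialEvents.from_records([], session_length=100.0)
        with pytest.raises(ValueError):
            build_unit_psths(food_session, empty)


def _flat_psth(n_bins=100, value=0.0):
    t = np.linspace(-2, 8, n_bins, endpoint=False) + 0.05
    z = np.full((5, n_bins), value)
    return UnitPSTH(
        unit_id=0, z=z, rate=np.ones_like(z), time=t,
        session_mean_rate=5.0,
        cross_unit_mean=np.ones(n_bins), cross_unit_sd=np.ones(n_bins),
    )


class TestEncodingFeatures:
    def test_flat_trace(self):
        f = extract_encoding_features(_flat_psth())
        assert f.n_transients == 0
        assert f.t_first_transient == pytest.approx(8.0, abs=0.1)  # sentinel: span end
        assert f.mean_cue_activity == 0.0 and f.mean_reward_activity == 0.0

    def test_single_bump_onset(self):
        p = _flat_psth()
        bump = (p.time >= 0.4) & (p.time < 1.0)
        p.rate = p.rate + np.where(bump, 2.0, 0.0)
        f = extract_encoding_features(p)
        assert f.n_transients == 1
        assert f.t_first_transient == pytest.approx(0.45, abs=0.1)

    def test_window_means_are_arithmetic(self):
        p = _flat_psth()
        p.z = p.z + np.where((p.time >= 0) & (p.time < 2), 2.0, 0.0)
        f = extract_encoding_features(p)
        assert f.mean_cue_activity == pytest.approx(2.0)
        assert f.mean_reward_activity == pytest.approx(0.0)

    def test_z_mode_threshold(self):
        p = _flat_psth()
        p.z = p.z + np.where((p.time >= 1) & (p.time < 2), 4.0, 0.0)
        f = extract_encoding_features(p, transient_mode="z")
        assert f.n_transients == 1
        assert f.t_first_transient == pytest.approx(1.05, abs=0.1)


class TestWindowAUCz:
    def test_constant_windows(self):
        p = _flat_psth(value=1.0)
        assert window_aucz(p, (0.0, 2.0)) == pytest.approx(2.0)
        p2 = _flat_psth(value=-1.0)
        assert window_aucz(p2, (2.0, 7.0)) == pytest.approx(-5.0)

    def test_triangle(self):
        p = _flat_psth(n_bins=1000)
        tri = np.clip(2.0 * (1 - np.abs(p.time - 1.0)), 0.0, None)
        p.z = np.tile(tri, (5, 1))
        assert window_aucz(p, (0.0, 2.0)) == pytest.approx(2.0, abs=0.01)

    def test_linearity(self):
        p = _flat_psth(n_bins=200)
        rng = np.random.default_rng(3)
        p.z = np.tile(rng.standard_normal(200), (5, 1))
        a = window_aucz(p, (0.0, 7.0))
        p.z = 2.5 * p.z
        assert window_aucz(p, (0.0, 7.0)) == pytest.approx(2.5 * a)

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            window_aucz(_flat_psth(), (5.0, 9.0))


def _run_discovery(mix, n_units, seed):
    events = synth.pr_like_events(30)
    sess = synth.gen_spike_session(
        synth.SpikeGenSpec(n_units=n_units, profile_mix=mix, seed=seed), events
    )
    _, _, model = discover_encoding_patterns(sess, events, seed=seed)
    truth = [sess.profiles[uid] for uid, _ in sess.units]
    pred = ["c%d" % a if a >= 0 else "non" for a in model.assignments]
    return model, adjusted_rand_score(truth, pred)


class TestClustering:
    def test_food_like_four_patterns(self):
        model, ari = _run_discovery(FOOD_MIX, 150, seed=1)
        assert model.k == 4
        assert ari >= 0.9
        labels = set(model.semantic_labels.values())
        assert {"cue_activated", "cue_inhibited", "reward_activated",
                "reward_inhibited"} <= labels

    def test_drug_like_three_patterns(self):
        model, ari = _run_discovery(DRUG_MIX, 120, seed=1)
        assert model.k == 3
        assert ari >= 0.9
        assert "press_inhibited" in set(model.semantic_labels.values())

    def test_identical_units_single_pattern(self, pr_events):
        st = np.sort(np.random.default_rng(4).uniform(0, pr_events.duration, 4000))
        # all units identical: features coincide, k stays at the floor
        sess = SpikeSession(
            units=[(u, st) for u in range(20)], session_duration=pr_events.duration + 1
        )
        psths = build_unit_psths(sess, pr_events)
        feats = [extract_encoding_features(p) for p in psths]
        model = cluster_encoding_patterns(feats, seed=0, k_start=2, max_k=4)
        assert model.n_clusters_total == 2  # k cannot grow on identical points

    def test_outlier_threshold_monotonicity(self, food_session, pr_events):
        psths = build_unit_psths(food_session, pr_events)
        feats = [extract_encoding_features(p) for p in psths]
        profs = np.stack([p.mean_trace for p in psths])
        rates = np.stack([p.mean_rate_trace for p in psths])
        counts = []
        for pct in (80.0, 90.0, 97.5, 100.0):
            m = cluster_encoding_patterns(
                feats, profiles=profs, rate_profiles=rates, time=psths[0].time,
                seed=1, outlier_percentile=pct,
            )
            counts.append((m.assignments >= 0).sum())
        assert counts == sorted(counts)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            cluster_encoding_patterns([], seed=0)
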