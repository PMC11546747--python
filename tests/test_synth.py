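"""Synthetic-data generators: determinism and planted ground truth."""

import numpy as np
import pytest

from rewardseek import synth


class TestPhotometryGen:
    def test_determinism(self):
        spec = synth.PhotometryGenSpec(duration=30.0, transient_times=np.array([5.0]), seed=4)
        a = synth.gen_photometry_session(spec)
        b = synth.gen_photometry_session(spec)
        assert np.array_equal(a.signal_470, b.signal_470)
        assert np.array_equal(a.iso_405, b.iso_405)

    def test_zero_amp_channels_differ_only_by_noise(self):
        spec = synth.PhotometryGenSpec(
            duration=30.0, transient_amp=0.0, transient_times=np.array([5.0]),
            iso_artifact_gain=1.0, noise_sd=0.001, seed=0,
        )
        rec = synth.gen_photometry_session(spec)
        assert np.abs(rec.signal_470 - rec.iso_405).max() < 10 * 0.001

    def test_shared_artifact_correlation_noiseless(self):
        spec = synth.PhotometryGenSpec(
            duration=60.0, transient_amp=0.0, transient_times=np.array([]),
            noise_sd=0.0, seed=1,
        )
        rec = synth.gen_photometry_session(spec)
        r = np.corrcoef(rec.signal_470, rec.iso_405)[0, 1]
        assert r >= 0.99

    def test_transient_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            synth.PhotometryGenSpec(duration=10.0, transient_times=np.array([12.0]))


class TestSpikeGen:
    def test_determinism(self, pr_events):
        spec = synth.SpikeGenSpec(n_units=10, seed=9)
        a = synth.gen_spike_session(spec, pr_events)
        b = synth.gen_spike_session(spec, pr_events)
        for (ua, sa), (ub, sb) in zip(a.units, b.units):
            assert ua == ub and np.array_equal(sa, sb)

    def test_cue_gain_thinning_oracle(self):
        """Peri-cue rate of a cue-activated unit is ~gain x baseline."""
        events = synth.pr_like_events(120)
        spec = synth.SpikeGenSpec(
            n_units=20,
            profile_mix={"cue_activated": 1.0},
            baseline_rate_range=(8.0, 8.0),
            gain=3.0,
            seed=2,
        )
        sess = synth.gen_spike_session(spec, events)
        cues = events.times_of("cue_on")
        in_rate, out_count, out_time = [], 0.0, 0.0
        for _, st in sess.units:
            n_in = sum(((st >= c) & (st < c + 2.0)).sum() for c in cues)
            in_rate.append(n_in / (2.0 * len(cues)))
        in_rate = np.asarray(in_rate)
        expect = 3.0 * 8.0
        se = np.sqrt(expect / (2.0 * len(cues)))  # Poisson SE per unit
        assert abs(in_rate.mean() - expect) < 2 * se

    def test_nonencoding_flat(self):
        events = synth.pr_like_events(100)
        spec = synth.SpikeGenSpec(
            n_units=30, profile_mix={"nonencoding": 1.0},
            baseline_rate_range=(6.0, 6.0), seed=3,
        )
        sess = synth.gen_spike_session(spec, events)
        cues = events.times_of("cue_on")
        rates = []
        for _, st in sess.units:
            n_in = sum(((s >= c) & (s < c + 2.0)).sum() for c in cues for s in [st])
            rates.append(n_in / (2.0 * len(cues)))
        se = np.sqrt(6.0 / (2.0 * len(cues)) / 30)
        assert abs(np.mean(rates) - 6.0) < 3 * se

    def test_empty_events_rejected(self):
        from rewardseek.events import TrialEvents

        empty = TrialEvents.from_records([], session_length=10.0)
        with pytest.raises(ValueError):
            synth.gen_spike_session(synth.SpikeGenSpec(n_units=2, seed=0), empty)


class TestTensorGen:
    def test_noiseless_rank1_is_exactly_rank_one(self):
        X, _ = synth.gen_trial_tensor(
            synth.TensorGenSpec(U=10, T=6, P=20, r_true=1, noise_sd=0.0, seed=0)
        )
        for mode in range(3):
            unf = np.moveaxis(X.X, mode, 0).reshape(X.X.shape[mode], -1)
            s = np.linalg.svd(unf, compute_uv=False)
            assert s[1] / s[0] < 1e-12

    def test_determinism(self):
        spec = synth.TensorGenSpec(U=12, T=8, P=16, r_true=2, seed=5)
        a, _ = synth.gen_trial_tensor(spec)
        b, _ = synth.gen_trial_tensor(spec)
        assert np.array_equal(a.X, b.X)

    def test_group_shift_zero_symmetric(self):
        labels = np.array(["CTRL"] * 50 + ["PCE"] * 50)
        spec = synth.TensorGenSpec(
            U=100, T=8, P=30, r_true=2, seed=6, group_labels=labels,
            group_loading_shift=np.zeros(2),
        )
        _, truth = synth.gen_trial_tensor(spec)
        d = truth.W[labels == "PCE"].mean(0) - truth.W[labels == "CTRL"].mean(0)
        assert np.abs(d).max() < 0.3  # sampling noise only

    def test_rank_exceeding_dims_rejected(self):
        with pytest.raises(ValueError):
            synth.TensorGenSpec(U=10, T=4, P=20, r_true=5)

    def test_snr_calibration(self):
        spec = synth.TensorGenSpec(U=40, T=8, P=30, r_true=4, snr=5.0, seed=7)
        X, truth = synth.gen_trial_tensor(spec)
        noise = X.X - truth.reconstruct()
        snr = np.linalg.norm(truth.reconstruct()) / np.linalg.norm(noise)
        assert snr == pytest.approx(5.0, rel=0.05)


class TestDemandGen:
    def test_noiseless_values_and_monotonicity(self):
        spec = synth.DemandGenSpec(Q0_true=50, alpha_true=0.002, k_true=2.0, noise_sd=0.0)
        df = synth.gen_demand_observations(spec)
        q = df.sort_values("price")["consumption"].to_numpy()
        assert np.all(np.diff(q) < 0)  # strictly decreasing in price
        from rewardseek.demand import demand_model

        assert demand_model(50, 0.002, 2.0, 0.0) == pytest.approx(50.0)

    def test_determinism_and_ground_truth(self):
        spec = synth.DemandGenSpec(seed=8)
        a = synth.gen_demand_observations(spec)
        b = synth.gen_demand_observations(spec)
        assert np.array_equal(a["consumption"], b["consumption"])
        assert a.attrs["ground_truth"]["Q0"] == 50.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            synth.DemandGenSpec(Q0_true=-1)
        with pytest.raises(ValueError):
            synth.DemandGenSpec(alpha_true=0.0)
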