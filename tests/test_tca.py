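"""CP decomposition: ALS correctness, similarity, rank selection, groups."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from rewardseek import synth
from rewardseek.tca import (
    CPModel,
    TrialTensor,
    compare_group_loadings,
    cp_als,
    factor_similarity,
    select_rank,
    truncate_to_first_trials,
)


def _direct_cp_fit(X, r, seed=0):
    """Independent CP oracle: joint nonlinear least squares on all factors."""
    U, T, P = X.shape
    rng = np.random.default_rng(seed)

    def unpack(theta):
        W = theta[: U * r].reshape(U, r)
        B = theta[U * r : U * r + T * r].reshape(T, r)
        A = theta[U * r + T * r :].reshape(P, r)
        return W, B, A

    def resid(theta):
        W, B, A = unpack(theta)
        return (np.einsum("ur,tr,pr->utp", W, B, A) - X).ravel()

    best = None
    for _ in range(3):
        theta0 = 0.5 * rng.standard_normal(r * (U + T + P))
        sol = least_squares(resid, theta0, method="lm", max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
    W, B, A = unpack(best.x)
    return CPModel(r=r, W=W, B=B, A=A).normalized(), np.sqrt(2 * best.cost)


class TestTruncate:
    def _subject(self, u, t, seed):
        rng = np.random.default_rng(seed)
        return TrialTensor(X=rng.standard_normal((u, t, 10)))

    def test_first_trials_retained(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 12, 10))
        out = truncate_to_first_trials([TrialTensor(X=X)], n=8)
        assert out.shape == (4, 8, 10)
        assert np.array_equal(out.X, X[:, :8, :])

    def test_units_concatenated(self):
        out = truncate_to_first_trials([self._subject(50, 9, 1), self._subject(50, 10, 2)], n=8)
        assert out.shape[0] == 100

    def test_short_subject_rejected(self):
        with pytest.raises(ValueError, match="fewer than 8"):
            truncate_to_first_trials([self._subject(5, 7, 3)], n=8)


class TestCPALS:
    def test_noiseless_rank2_recovery(self):
        X, truth = synth.gen_trial_tensor(
            synth.TensorGenSpec(U=25, T=8, P=30, r_true=2, noise_sd=0.0, seed=1)
        )
        m = cp_als(X, 2, n_restarts=3, seed=0)
        assert m.rel_error(X.X) < 1e-6
        assert factor_similarity(m, truth.normalized()) >= 0.95

    def test_objective_monotone(self):
        X, _ = synth.gen_trial_tensor(
            synth.TensorGenSpec(U=20, T=8, P=25, r_true=3, snr=3.0, seed=2)
        )
        m = cp_als(X, 3, seed=5)
        assert np.all(np.diff(m.objective_trace) <= 1e-9 * max(m.objective_trace))

    def test_rank1_all_ones(self):
        X = np.ones((4, 5, 6))
        m = cp_als(X, 1, seed=0)
        assert np.abs(m.reconstruct() - X).max() < 1e-10

    def test_invalid_inputs(self):
        X = np.ones((4, 5, 6))
        with pytest.raises(ValueError):
            cp_als(X, 5, seed=0)
        with pytest.raises(ValueError):
            cp_als(np.zeros((3, 3, 3)), 1, seed=0)

    def test_agreement_with_direct_least_squares_oracle(self):
        """ALS matches an independent joint-NLS fit on small random tensors."""
        rng = np.random.default_rng(3)
        for trial in range(10):
            r = int(rng.integers(1, 3))
            W = rng.standard_normal((5, r))
            B = rng.standard_normal((4, r))
            A = rng.standard_normal((6, r))
            X = np.einsum("ur,tr,pr->utp", W, B, A)
            m = cp_als(X, r, n_restarts=3, seed=trial)
            oracle, oracle_resid = _direct_cp_fit(X, r, seed=trial)
            nX = np.linalg.norm(X)
            assert m.rel_error(X) < 1e-6
            assert abs(m.rel_error(X) - oracle_resid / nX) < 1e-6


class TestFactorSimilarity:
    def _model(self, seed, r=4):
        rng = np.random.default_rng(seed)
        return CPModel(
            r=r, W=rng.standard_normal((100, r)),
            B=rng.standard_normal((8, r)), A=rng.standard_normal((60, r)),
        ).normalized()

    def test_self_similarity(self):
        m = self._model(0)
        assert factor_similarity(m, m) == pytest.approx(1.0)

    def test_permutation_and_rescale_invariance(self):
        m = self._model(1)
        perm = [2, 0, 3, 1]
        scales = np.array([0.5, 2.0, -1.5, 3.0])
        m2 = CPModel(
            r=4,
            W=m.W[:, perm] * scales,
            B=m.B[:, perm] / scales,
            A=m.A[:, perm] * np.array([1.0, -1.0, 1.0, -1.0]),
        )
        # flip signs consistently so the 3-mode product is unchanged
        m2.B = m2.B * np.array([1.0, -1.0, 1.0, -1.0])
        assert factor_similarity(m, m2) == pytest.approx(1.0)

    def test_independent_models_dissimilar(self):
        hits = sum(
            factor_similarity(self._model(2 * s), self._model(2 * s + 1)) < 0.5
            for s in range(20)
        )
        assert hits >= 19

    def test_rank_mismatch(self):
        with pytest.raises(ValueError):
            factor_similarity(self._model(0, r=2), self._model(1, r=3))


class TestSelectRank:
    def test_noiseless_rank1(self):
        X, _ = synth.gen_trial_tensor(
            synth.TensorGenSpec(U=15, T=8, P=20, r_true=1, noise_sd=0.0, seed=4)
        )
        res = select_rank(X, [1, 2, 3], runs_per_candidate=5, seed=0)
        assert res.selected_r == 1

    def test_pure_noise_selects_none(self):
        rng = np.random.default_rng(5)
        X = TrialTensor(X=rng.standard_normal((40, 8, 30)))
        res = select_rank(X, [1, 2, 3], runs_per_candidate=5, seed=0)
        assert res.selected_r is None

    def test_deterministic_given_seed(self):
        X, _ = synth.gen_trial_tensor(
            synth.TensorGenSpec(U=20, T=8, P=20, r_true=2, snr=5.0, seed=6)
        )
        a = select_rank(X, [1, 2, 3], runs_per_candidate=4, seed=9)
        b = select_rank(X, [1, 2, 3], runs_per_candidate=4, seed=9)
        assert a.selected_r == b.selected_r and a.similarity == b.similarity

    def test_invalid_threshold(self):
        X = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            select_rank(X, [1], similarity_threshold=1.5, seed=0)


class TestGroupLoadings:
    def _tensor(self, shift, seed=7):
        labels = np.array(["CTRL"] * 150 + ["PCE"] * 150)
        spec = synth.TensorGenSpec(
            U=300, T=8, P=30, r_true=3, snr=8.0, seed=seed,
            group_labels=labels, group_loading_shift=shift,
        )
        X, truth = synth.gen_trial_tensor(spec)
        return X, truth, labels

    def test_null_shift_small_effect(self):
        X, truth, labels = self._tensor(np.zeros(3))
        out = compare_group_loadings(truth, labels)
        assert all(abs(row["cohens_d"]) < 0.2 for row in out)

    def test_planted_shift_detected_on_target_component(self):
        X, truth, labels = self._tensor(np.array([0.4, 0.0, 0.0]))
        m = cp_als(X, 3, n_restarts=3, seed=1)
        # match fitted components to truth before reading effects
        out = compare_group_loadings(m, labels)
        ds = sorted((abs(r["cohens_d"]) for r in out), reverse=True)
        assert ds[0] > 0.5 and ds[1] < 0.3

    def test_label_length_mismatch(self):
        _, truth, _ = self._tensor(np.zeros(3))
        with pytest.raises(ValueError):
            compare_group_loadings(truth, ["CTRL"] * 10)
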