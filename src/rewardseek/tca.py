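"""Canonical polyadic (CP) tensor decomposition of trial tensors.

A session of simultaneously recorded units is arranged as a three-way
tensor X of shape U × T × P (units × trials × within-trial time bins) and
factorized as

    X_utp ≈ Σ_r  w_ur · b_tr · a_pr

by alternating least squares (ALS): each factor matrix is updated by
solving its linear least-squares subproblem while the other two are held
fixed, cyclically, until the relative change in the sum of squared
residuals falls below tolerance.  Components ("cell assemblies") carry a
unit-loading vector w_r, a trial-trend b_r and a within-trial temporal
motif a_r.

Because CP fitting is non-convex, the rank is chosen by cross-run
convergence: at each candidate rank, several independently initialized
models are fit; the selected rank is the smallest whose runs agree (mean
pairwise factor similarity above threshold) while also reaching the
reconstruction-error floor attained by any stable candidate.

Scale/permutation ambiguity is resolved by norm-balancing: each
component's scale is concentrated into the unit loadings, with the trial
and temporal factor columns normalized to unit length, so unit loadings
are comparable across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class TrialTensor:
    """Unit × trial × time data tensor with axis metadata."""

    X: np.ndarray  # (U, T, P)
    unit_ids: list | None = None
    group_labels: np.ndarray | None = None
    trial_indices: np.ndarray | None = None
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("tensor must be 3-way (units x trials x time)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("tensor entries must be finite")
        if self.X.shape[1] < 2:
            raise ValueError("need at least 2 trials")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.X.shape


@dataclass
class CPModel:
    """Rank-r CP model: unit, trial and within-trial factor matrices."""

    r: int
    W: np.ndarray  # (U, r) unit loadings (carry component scale)
    B: np.ndarray  # (T, r) trial factors, unit-norm columns
    A: np.ndarray  # (P, r) within-trial factors, unit-norm columns
    objective_trace: list = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ur,tr,pr->utp", self.W, self.B, self.A)

    def rel_error(self, X: np.ndarray) -> float:
        return float(np.linalg.norm(X - self.reconstruct()) / np.linalg.norm(X))

    def normalized(self) -> "CPModel":
        """Concentrate component scale into W; B, A columns unit-norm."""
        nb = np.linalg.norm(self.B, axis=0)
        na = np.linalg.norm(self.A, axis=0)
        nb = np.where(nb == 0, 1.0, nb)
        na = np.where(na == 0, 1.0, na)
        return CPModel(
            r=self.r,
            W=self.W * nb * na,
            B=self.B / nb,
            A=self.A / na,
            objective_trace=self.objective_trace,
        )


@dataclass
class RankSelectionResult:
    selected_r: int | None  # smallest rank both stable across runs and at the error floor
    similarity: dict  # candidate rank -> mean pairwise factor similarity
    rel_errors: dict  # candidate rank -> mean relative reconstruction error


def truncate_to_first_trials(subject_tensors: list[TrialTensor], n: int = 8) -> TrialTensor:
    """Keep only each subject's first ``n`` trials and stack units.

    Restricting to the first trials (the lowest reward count completed by
    every subject) makes the trial axis the same length for all subjects so
    their units can be concatenated along U.
    """
    if not subject_tensors:
        raise ValueError("no subjects")
    short = [i for i, t in enumerate(subject_tensors) if t.shape[1] < n]
    if short:
        raise ValueError(f"subjects with fewer than {n} trials: {short}")
    p0 = subject_tensors[0].shape[2]
    if any(t.shape[2] != p0 for t in subject_tensors):
        raise ValueError("within-trial axes differ across subjects")
    X = np.concatenate([t.X[:, :n, :] for t in subject_tensors], axis=0)
    ids, groups = [], []
    for i, t in enumerate(subject_tensors):
        u = t.shape[0]
        ids.extend(t.unit_ids if t.unit_ids is not None else [(i, j) for j in range(u)])
        groups.extend(t.group_labels if t.group_labels is not None else ["?"] * u)
    return TrialTensor(
        X=X,
        unit_ids=ids,
        group_labels=np.asarray(groups),
        trial_indices=np.arange(1, n + 1),
        time=subject_tensors[0].time,
    )


def _als_single(X: np.ndarray, r: int, tol: float, max_iter: int, rng, nonneg: bool) -> CPModel:
    U, T, P = X.shape
    W = rng.standard_normal((U, r))
    B = rng.standard_normal((T, r))
    A = rng.standard_normal((P, r))
    X0 = X.reshape(U, T * P)  # mode-0 unfolding
    X1 = np.moveaxis(X, 1, 0).reshape(T, U * P)
    X2 = np.moveaxis(X, 2, 0).reshape(P, U * T)
    normX2 = float((X**2).sum())
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        # W update: X0 ≈ W (B ⊙ A)^T  with Khatri-Rao columns b_r ⊗ a_r
        KR = (B[:, None, :] * A[None, :, :]).reshape(T * P, r)
        G = (B.T @ B) * (A.T @ A)
        W = np.linalg.solve(G + 1e-12 * np.eye(r), (X0 @ KR).T).T
        if nonneg:
            W = np.clip(W, 0.0, None)
        KR = (W[:, None, :] * A[None, :, :]).reshape(U * P, r)
        G = (W.T @ W) * (A.T @ A)
        B = np.linalg.solve(G + 1e-12 * np.eye(r), (X1 @ KR).T).T
        KR = (W[:, None, :] * B[None, :, :]).reshape(U * T, r)
        G = (W.T @ W) * (B.T @ B)
        A = np.linalg.solve(G + 1e-12 * np.eye(r), (X2 @ KR).T).T
        # SSE via Gram identity
        G_all = (W.T @ W) * (B.T @ B) * (A.T @ A)
        cross = float(np.einsum("pr,pr->", X2 @ KR, A))
        sse = max(normX2 - 2.0 * cross + float(G_all.sum()), 0.0)
        trace.append(sse)
        if np.isfinite(prev) and prev - sse <= tol * max(prev, 1e-30):
            break
        prev = sse
    model = CPModel(r=r, W=W, B=B, A=A, objective_trace=trace)
    return model.normalized()


def cp_als(
    X: TrialTensor | np.ndarray,
    r: int,
    n_restarts: int = 1,
    tol: float = 1e-9,
    max_iter: int = 500,
    seed: int = 0,
    nonneg: bool = False,
) -> CPModel:
    """Best-of-restarts CP decomposition by alternating least squares.

    Each restart starts from independent standard-normal factor matrices
    (seeds derived from ``seed``); the model with the lowest final sum of
    squared residuals is returned, norm-balanced.
    """
    Xa = X.X if isinstance(X, TrialTensor) else np.asarray(X, dtype=float)
    if not 1 <= r <= min(Xa.shape):
        raise ValueError(f"rank {r} outside [1, {min(Xa.shape)}]")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if not Xa.any():
        raise ValueError("all-zero tensor is degenerate")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        m = _als_single(Xa, r, tol, max_iter, np.random.default_rng(child), nonneg)
        if best is None or m.objective_trace[-1] < best.objective_trace[-1]:
            best = m
    return best


def _congruence(F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(F1, axis=0, keepdims=True)
    n2 = np.linalg.norm(F2, axis=0, keepdims=True)
    n1 = np.where(n1 == 0, 1.0, n1)
    n2 = np.where(n2 == 0, 1.0, n2)
    return (F1 / n1).T @ (F2 / n2)


def factor_similarity(m1: CPModel, m2: CPModel) -> float:
    """Cross-run similarity of two CP models, in [0, 1].

    Components are matched by maximum-weight bipartite assignment on the
    product of per-mode cosine congruences; the score is the mean matched
    product.  Invariant to component permutation and to sign/scale
    rebalancing across modes (sign flips cancel in the three-mode product).
    """
    if m1.r != m2.r:
        raise ValueError("rank mismatch")
    S = _congruence(m1.W, m2.W) * _congruence(m1.B, m2.B) * _congruence(m1.A, m2.A)
    row, col = linear_sum_assignment(-S)
    return float(np.clip(S[row, col].mean(), 0.0, 1.0))


def select_rank(
    X: TrialTensor | np.ndarray,
    candidates: list[int],
    runs_per_candidate: int = 10,
    similarity_threshold: float = 0.8,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 500,
    error_tolerance: float = 0.02,
) -> RankSelectionResult:
    """Smallest candidate rank that converges across runs at the error floor.

    A candidate "converges" when the mean pairwise :func:`factor_similarity`
    over ``runs_per_candidate`` independently initialized fits reaches
    ``similarity_threshold``.  Because a rank-r approximation below the true
    rank is essentially unique, under-ranked fits are also stable, so
    stability alone cannot identify the model order; the selected rank is
    the smallest converging candidate whose mean relative reconstruction
    error is within ``error_tolerance`` of the best error achieved by any
    converging candidate.  Returns None when no candidate converges.
    """
    if not candidates:
        raise ValueError("no candidate ranks")
    if not 0 < similarity_threshold <= 1:
        raise ValueError("similarity_threshold must be in (0, 1]")
    cands = sorted(candidates)
    Xa = X.X if isinstance(X, TrialTensor) else np.asarray(X, dtype=float)
    sims, errs = {}, {}
    ss = np.random.SeedSequence(seed)
    for r, child in zip(cands, ss.spawn(len(cands))):
        runs = [
            _als_single(Xa, r, tol, max_iter, np.random.default_rng(c), False)
            for c in child.spawn(runs_per_candidate)
        ]
        pair = [
            factor_similarity(runs[i], runs[j])
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        sims[r] = float(np.mean(pair)) if pair else 1.0
        errs[r] = float(np.mean([m.rel_error(Xa) for m in runs]))
    stable = [r for r in cands if sims[r] >= similarity_threshold]
    selected = None
    if stable:
        floor = min(errs[r] for r in stable)
        selected = next(r for r in stable if errs[r] <= floor + error_tolerance)
    return RankSelectionResult(selected_r=selected, similarity=sims, rel_errors=errs)


def compare_group_loadings(model: CPModel, group_labels) -> list[dict]:
    """Per-component group means of unit loadings and standardized difference.

    The standardized difference is Cohen's d with pooled SD; significance
    testing is left to standard tools downstream.
    """
    labels = np.asarray(group_labels)
    if len(labels) != model.W.shape[0]:
        raise ValueError("group label vector length must match number of units")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    g0, g1 = groups
    out = []
    for r in range(model.r):
        w = model.W[:, r]
        w0, w1 = w[labels == g0], w[labels == g1]
        s_p = np.sqrt(
            ((len(w0) - 1) * w0.var(ddof=1) + (len(w1) - 1) * w1.var(ddof=1))
            / max(len(w0) + len(w1) - 2, 1)
        )
        out.append(
            {
                "component": r,
                f"mean_{g0}": float(w0.mean()),
                f"mean_{g1}": float(w1.mean()),
                "difference": float(w1.mean() - w0.mean()),
                "cohens_d": float((w1.mean() - w0.mean()) / s_p) if s_p > 0 else 0.0,
            }
        )
    return out
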