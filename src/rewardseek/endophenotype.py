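"""Behavioral endophenotyping and loading-based behavior prediction.

Reduces a subjects × metrics behavioral matrix (demand parameters, FR/PR
performance, ...) to low-dimensional endophenotype scores by PCA on the
correlation matrix, and predicts a behavioral target (latency to a late PR
reward) from per-unit tensor loadings with an interchangeable regression
strategy evaluated on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass
class EndophenotypeResult:
    loadings: pd.DataFrame  # metrics x components, orthonormal columns
    scores: pd.DataFrame  # subjects x components
    variance_explained: np.ndarray  # fraction per component, non-increasing


def pca_endophenotype(matrix: pd.DataFrame, n_components: int | None = None) -> EndophenotypeResult:
    """PCA of the correlation matrix of standardized behavioral metrics.

    Metrics are standardized to mean 0, SD 1 (heterogeneous units), so the
    decomposition is of the correlation matrix; scores are the standardized
    data projected onto the eigenvectors.  The sign convention fixes the
    largest-magnitude loading of each component positive.

    Raises
    ------
    ValueError
        If fewer than 3 subjects or 2 metrics remain, or a metric is
        constant (named in the message).
    """
    df = matrix.dropna()
    n, m = df.shape
    if n < 3 or m < 2:
        raise ValueError("need at least 3 subjects and 2 metrics")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if len(const):
        names = [df.columns[i] for i in const]
        raise ValueError(f"constant metric(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    if n_components is not None:
        evals, evecs = evals[:n_components], evecs[:, :n_components]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    return EndophenotypeResult(
        loadings=pd.DataFrame(evecs, index=df.columns, columns=comp_names),
        scores=pd.DataFrame(Z @ evecs, index=df.index, columns=comp_names),
        variance_explained=evals / m,
    )


def predict_latency_from_loadings(
    loadings: np.ndarray,
    targets: np.ndarray,
    split: float = 0.8,
    regressor=None,
    seed: int = 0,
) -> dict:
    """Held-out prediction of a behavioral target from unit loadings.

    Fits ``regressor`` (default: gradient-boosted decision trees) on a
    seeded ``split`` fraction of the rows of ``loadings`` and reports the
    Pearson correlation between predicted and true targets on the held-out
    rows.  The regression strategy is interchangeable: any object with
    fit/predict works.
    """
    W = np.asarray(loadings, dtype=float)
    y = np.asarray(targets, dtype=float)
    if W.ndim != 2 or len(W) != len(y):
        raise ValueError("loadings must be 2-D with one row per target")
    if len(y) < 20:
        raise ValueError("need at least 20 samples")
    if not 0.5 < split < 0.95:
        raise ValueError("split must be in (0.5, 0.95)")
    if np.all(y == y[0]):
        raise ValueError("constant target: correlation undefined")
    if regressor is None:
        from sklearn.ensemble import GradientBoostingRegressor

        regressor = GradientBoostingRegressor(random_state=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    n_train = int(round(split * len(y)))
    train, test = perm[:n_train], perm[n_train:]
    regressor.fit(W[train], y[train])
    pred = regressor.predict(W[test])
    r = pearsonr(pred, y[test]).statistic if len(test) >= 2 else np.nan
    return {
        "pearson_r": float(r),
        "predictions": pred,
        "true_values": y[test],
        "test_indices": test,
    }
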