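"""Exponential demand-curve economics.

Fits the exponential model of demand

    log10 Q(price) = log10 Q0 + k · (e^(−α·Q0·price) − 1)

to consumption-vs-price data and derives, per subject,

    EV   = 1 / (α · k^1.5 · 100)                      (essential value)
    Pmax = (1 / (Q0 · α · k^1.5)) · (0.083·k + 0.65)  (price at peak output)

where Q0 is maximal demand at zero cost (hedonic set point), α the rate of
decline in relative consumption (price sensitivity), and k a shared scaling
constant reflecting the log10 range of the data.  Pmax approximates the
price maximizing response output price·Q(price), the inflection between
inelastic and elastic demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

K_POLICIES = ("shared_pooled", "fixed", "per_subject")


@dataclass
class DemandFit:
    """Fitted exponential-demand parameters with derived metrics."""

    Q0: float
    alpha: float
    k: float
    EV: float
    Pmax: float
    r2: float
    k_policy: str

    def predict(self, prices) -> np.ndarray:
        return predict_consumption(self.Q0, self.alpha, self.k, prices)


def demand_model(Q0: float, alpha: float, k: float, price) -> np.ndarray:
    """Q(price) = Q0 · 10^(k·(e^(−α·Q0·price) − 1))."""
    price = np.asarray(price, dtype=float)
    return Q0 * 10.0 ** (k * (np.exp(-alpha * Q0 * price) - 1.0))


def predict_consumption(Q0: float, alpha: float, k: float, prices) -> np.ndarray:
    """Model-predicted consumption at each price (errors on negative price)."""
    prices = np.asarray(prices, dtype=float)
    if np.any(prices < 0):
        raise ValueError("prices must be non-negative")
    return demand_model(Q0, alpha, k, prices)


def response_output(Q0: float, alpha: float, k: float, price) -> np.ndarray:
    """Responses emitted at each price: price · Q(price)."""
    price = np.asarray(price, dtype=float)
    return price * demand_model(Q0, alpha, k, price)


def derived_metrics(Q0: float, alpha: float, k: float) -> dict:
    """Essential value and Pmax from fitted parameters (exact formulas)."""
    if Q0 <= 0 or alpha <= 0 or k <= 0:
        raise ValueError("Q0, alpha and k must all be > 0")
    ks = k**1.5
    return {
        "EV": 1.0 / (alpha * ks * 100.0),
        "Pmax": (1.0 / (Q0 * alpha * ks)) * (0.083 * k + 0.65),
    }


def pooled_k(consumptions) -> float:
    """Shared k: the log10 range of positive mean consumption in the data."""
    c = np.asarray(consumptions, dtype=float)
    c = c[c > 0]
    if len(c) < 2:
        raise ValueError("need at least 2 positive consumption values for pooled k")
    k = float(np.log10(c.max()) - np.log10(c.min()))
    if k <= 0:
        raise ValueError("degenerate consumption range; k would be <= 0")
    return k


def fit_demand_curve(
    prices,
    consumption,
    k_policy: str = "shared_pooled",
    k_value: float | None = None,
    zero_handling: str = "drop",
    zero_replacement: float = 0.1,
) -> DemandFit:
    """Nonlinear least squares on log10 consumption vs price.

    Parameters
    ----------
    prices, consumption
        Paired observations; a price of 0 is allowed as the zero-cost anchor.
    k_policy
        "shared_pooled" (k = log10 range of this dataset's positive
        consumption; pass a precomputed pooled value via ``k_value`` to share
        it across subjects), "fixed" (``k_value`` required), or
        "per_subject" (k fitted jointly with Q0 and α).
    zero_handling
        Zero-consumption bins are dropped from the log-space fit ("drop")
        or replaced with ``zero_replacement`` rewards ("replace").

    The fit runs in log10 space from 5 deterministic starting points and is
    bounded (Q0 in (0, 10·max consumption], α in (0, 1]); the best solution
    by residual norm is returned with EV/Pmax and R² in log space.
    """
    if k_policy not in K_POLICIES:
        raise ValueError(f"unknown k_policy {k_policy!r}")
    p = np.asarray(prices, dtype=float)
    q = np.asarray(consumption, dtype=float)
    if p.shape != q.shape:
        raise ValueError("prices and consumption must have equal length")
    if zero_handling == "replace":
        q = np.where(q == 0, zero_replacement, q)
    elif zero_handling != "drop":
        raise ValueError(f"unknown zero_handling {zero_handling!r}")
    keep = q > 0
    p, q = p[keep], q[keep]
    if len(np.unique(p)) < 3:
        raise ValueError("need at least 3 distinct prices with positive consumption")
    logq = np.log10(q)

    if k_policy == "fixed":
        if k_value is None or k_value <= 0:
            raise ValueError("k_policy='fixed' requires positive k_value")
        k = float(k_value)
    elif k_policy == "shared_pooled":
        k = float(k_value) if k_value is not None else pooled_k(q)
    else:
        k = None  # fitted

    qmax = q.max()
    fit_k = k is None

    def resid(theta):
        Q0, alpha = theta[0], theta[1]
        kk = theta[2] if fit_k else k
        return np.log10(Q0) + kk * (np.exp(-alpha * Q0 * p) - 1.0) - logq

    lo = [1e-9, 1e-9] + ([1e-3] if fit_k else [])
    hi = [10.0 * qmax, 1.0] + ([10.0] if fit_k else [])
    alpha0s = [1e-4, 1e-3, 1e-2, 1e-1, 1.0 / (qmax * (p.max() + 1.0))]
    best = None
    for a0 in alpha0s:
        x0 = [min(qmax, 10.0 * qmax), a0] + ([2.0] if fit_k else [])
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("demand fit failed from all starting points")
    Q0, alpha = float(best.x[0]), float(best.x[1])
    k = float(best.x[2]) if fit_k else float(k)
    ss_res = float(2.0 * best.cost)
    ss_tot = float(((logq - logq.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    d = derived_metrics(Q0, alpha, k)
    return DemandFit(Q0=Q0, alpha=alpha, k=k, EV=d["EV"], Pmax=d["Pmax"], r2=r2,
                     k_policy=k_policy)


def fit_demand_table(
    table: pd.DataFrame,
    k_policy: str = "shared_pooled",
    k_value: float | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit every subject in a long-form table.

    ``table`` needs columns ``subject_id``, ``price``, ``consumption``
    (optional ``group`` is carried through).  Under "shared_pooled" one k —
    the log10 range of the pooled positive consumption — is used for all
    subjects.
    """
    if k_policy == "shared_pooled" and k_value is None:
        k_value = pooled_k(table["consumption"])
    rows = []
    for sid, sub in table.groupby("subject_id", sort=True):
        fit = fit_demand_curve(
            sub["price"], sub["consumption"], k_policy=k_policy, k_value=k_value, **kwargs
        )
        row = {
            "subject_id": sid,
            "Q0": fit.Q0,
            "alpha": fit.alpha,
            "k": fit.k,
            "EV": fit.EV,
            "Pmax": fit.Pmax,
            "r2": fit.r2,
        }
        if "group" in sub.columns:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
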