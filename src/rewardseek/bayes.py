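"""Bayesian logistic regression for encoding-bias tests.

Asks whether treatment group membership (e.g. prenatal drug exposure)
biases the probability that a recorded unit falls into one encoding class
rather than another.  The model is a two-group logistic regression

    y_i ~ Bernoulli(sigmoid(beta0 + beta1 * x_i)),   x_i in {0, 1}

with a mixture-of-g-priors treatment coefficient: beta1 | g ~ N(0, g) and
a compound confluent hypergeometric (CCH) hyperprior on the shrinkage
variable u = 1/(1+g),

    p(u) ∝ u^(a/2−1) (1−u)^(b/2−1) exp(−s·u),   u in (0, 1),

which for the default hyperparameters (a = 0.5, b = 2, s = 0) reduces to a
Beta(1/4, 1) density on u.  The intercept gets a weakly informative
N(0, intercept_sd²) prior shared by both models.  Evidence for a group
effect is the Bayes factor BF10 = m1/m0, the ratio of marginal likelihoods
of the treatment model and the intercept-only null, labeled with Jeffreys
evidence categories.

Because the group indicator is binary, the likelihood depends on the data
only through the 2×2 success counts, so the marginal likelihoods are
low-dimensional integrals evaluated by deterministic quadrature: the
mixture prior on beta1 is first marginalized over u (after the smoothing
substitution u = v^(2/a), which removes the u^(a/2−1) endpoint
singularity), then the (beta0, beta1) integral is taken on a dense grid.
A fully brute-force 3-D grid integrator is included as an internal
cross-check against parameterization error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PriorSpec:
    """CCH hyperprior on the shrinkage variable plus intercept prior SD."""

    a: float = 0.5
    b: float = 2.0
    s: float = 0.0
    intercept_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.s < 0:
            raise ValueError("need a > 0, b > 0, s >= 0")


@dataclass
class PosteriorSummary:
    beta_mean: float
    beta_ci: tuple[float, float]
    bf10: float
    bf01: float
    evidence_label: str
    n_per_cell: dict
    separation_warning: bool = False


def _counts(y: np.ndarray, x: np.ndarray) -> tuple[int, int, int, int]:
    n0 = int((x == 0).sum())
    n1 = int((x == 1).sum())
    k0 = int(y[x == 0].sum())
    k1 = int(y[x == 1].sum())
    return n0, k0, n1, k1


def _loglik(b0, b1, n0, k0, n1, k1):
    """Binomial log-likelihood on (possibly broadcast) coefficient arrays."""
    eta0 = b0
    eta1 = b0 + b1
    # log sigmoid / log(1 - sigmoid), numerically stable
    ls0, lc0 = -np.logaddexp(0.0, -eta0), -np.logaddexp(0.0, eta0)
    ls1, lc1 = -np.logaddexp(0.0, -eta1), -np.logaddexp(0.0, eta1)
    return k0 * ls0 + (n0 - k0) * lc0 + k1 * ls1 + (n1 - k1) * lc1


def _u_nodes(prior: PriorSpec, n: int = 80):
    """Quadrature nodes/weights for E_u[f(g(u))] under the CCH prior.

    Substituting u = v^(2/a) turns the u^(a/2−1) factor into a constant, so
    Gauss-Legendre on v in (0,1) converges fast.  Weights are normalized to
    sum 1 (the prior normalizer cancels).
    """
    v, wv = np.polynomial.legendre.leggauss(n)
    v = 0.5 * (v + 1.0)
    wv = 0.5 * wv
    u = v ** (2.0 / prior.a)
    dens = (1.0 - u) ** (prior.b / 2.0 - 1.0) * np.exp(-prior.s * u)
    w = wv * dens
    return u, w / w.sum()


def _beta1_prior_density(beta1: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Marginal prior density of beta1 after integrating out g."""
    u, w = _u_nodes(prior)
    g = (1.0 - u) / u
    g = np.clip(g, 1e-12, None)
    dens = np.exp(-0.5 * beta1[:, None] ** 2 / g[None, :]) / np.sqrt(2.0 * np.pi * g[None, :])
    return dens @ w


def _marginal_null(n0, k0, n1, k1, prior: PriorSpec, n_grid: int = 4001, span: float = 15.0):
    b0 = np.linspace(-span, span, n_grid)
    ll = _loglik(b0, 0.0, n0, k0, n1, k1)
    pb0 = np.exp(-0.5 * b0**2 / prior.intercept_sd**2) / (
        np.sqrt(2.0 * np.pi) * prior.intercept_sd
    )
    return float(np.trapezoid(np.exp(ll) * pb0, b0))


def _marginal_alt(
    n0, k0, n1, k1, prior: PriorSpec,
    n_b0: int = 801, n_b1: int = 2001, span0: float = 15.0, span1: float = 40.0,
):
    """Marginal likelihood of the treatment model and posterior of beta1."""
    b0 = np.linspace(-span0, span0, n_b0)
    b1 = np.linspace(-span1, span1, n_b1)
    pb1 = _beta1_prior_density(b1, prior)
    pb0 = np.exp(-0.5 * b0**2 / prior.intercept_sd**2) / (
        np.sqrt(2.0 * np.pi) * prior.intercept_sd
    )
    ll = _loglik(b0[:, None], b1[None, :], n0, k0, n1, k1)
    integrand = np.exp(ll) * pb0[:, None] * pb1[None, :]
    over_b0 = np.trapezoid(integrand, b0, axis=0)  # unnormalized posterior of beta1
    m1 = float(np.trapezoid(over_b0, b1))
    return m1, b1, over_b0


def _marginal_alt_grid3d(
    n0, k0, n1, k1, prior: PriorSpec,
    n_b0: int = 401, n_b1: int = 801, n_u: int = 2000,
    span0: float = 15.0, span1: float = 40.0,
):
    """Brute-force 3-D grid integration over (beta0, beta1, u): oracle path."""
    b0 = np.linspace(-span0, span0, n_b0)
    b1 = np.linspace(-span1, span1, n_b1)
    v = (np.arange(n_u) + 0.5) / n_u  # midpoint rule in substituted variable
    u = v ** (2.0 / prior.a)
    dens = (1.0 - u) ** (prior.b / 2.0 - 1.0) * np.exp(-prior.s * u)
    wu = dens / dens.sum()
    g = np.clip((1.0 - u) / u, 1e-12, None)
    pb1 = (
        np.exp(-0.5 * b1[:, None] ** 2 / g[None, :]) / np.sqrt(2.0 * np.pi * g[None, :])
    ) @ wu
    pb0 = np.exp(-0.5 * b0**2 / prior.intercept_sd**2) / (
        np.sqrt(2.0 * np.pi) * prior.intercept_sd
    )
    ll = _loglik(b0[:, None], b1[None, :], n0, k0, n1, k1)
    integrand = np.exp(ll) * pb0[:, None] * pb1[None, :]
    return float(np.trapezoid(np.trapezoid(integrand, b0, axis=0), b1))


def fit_bayes_logistic(
    y, x, prior: PriorSpec | None = None, _oracle: bool = False
) -> PosteriorSummary:
    """Bayes-factor test of a binary group effect on a binary outcome.

    Parameters
    ----------
    y, x
        Binary outcome and binary group indicator per unit (same length,
        n >= 10, both predictor levels present).
    prior
        Hyperprior specification; defaults to CCH(0.5, 2, 0).
    _oracle
        Use the brute-force 3-D grid integrator for the alternative
        marginal (internal cross-check).

    Returns the posterior mean and equal-tailed 95% credible interval of
    the group log-odds coefficient, BF10, BF01 and a Jeffreys evidence
    label.  Complete separation (an empty cell) is flagged but inference
    proceeds — the prior regularizes.
    """
    prior = prior or PriorSpec()
    y = np.asarray(y, dtype=int)
    x = np.asarray(x, dtype=int)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if len(y) < 10:
        raise ValueError("need n >= 10")
    if set(np.unique(x)) != {0, 1}:
        raise ValueError("predictor must contain both levels 0 and 1")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcome must be binary")
    n0, k0, n1, k1 = _counts(y, x)
    sep = 0 in (k0, n0 - k0, k1, n1 - k1)
    if sep:
        warnings.warn("empty cell (separation); prior regularizes the fit", stacklevel=2)

    m0 = _marginal_null(n0, k0, n1, k1, prior)
    if _oracle:
        m1 = _marginal_alt_grid3d(n0, k0, n1, k1, prior)
        _, b1, post = _marginal_alt(n0, k0, n1, k1, prior)
    else:
        m1, b1, post = _marginal_alt(n0, k0, n1, k1, prior)
    bf10 = m1 / m0

    Z = np.trapezoid(post, b1)
    pdf = post / Z
    mean = float(np.trapezoid(b1 * pdf, b1))
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(b1))))
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, b1))
    hi = float(np.interp(0.975, cdf, b1))
    return PosteriorSummary(
        beta_mean=mean,
        beta_ci=(lo, hi),
        bf10=float(bf10),
        bf01=float(1.0 / bf10),
        evidence_label=classify_evidence(bf10),
        n_per_cell={"n_x0": n0, "k_x0": k0, "n_x1": n1, "k_x1": k1},
        separation_warning=sep,
    )


def classify_evidence(bf10: float) -> str:
    """Jeffreys evidence category for a Bayes factor.

    BF10 >= 1 is labeled in favor of the alternative (H1); BF10 < 1 is
    classified on its reciprocal in favor of the null (H0).
    """
    if not np.isfinite(bf10) or bf10 <= 0:
        raise ValueError("bf10 must be a positive finite number")
    if bf10 >= 1:
        bf, hyp = bf10, "H1"
    else:
        bf, hyp = 1.0 / bf10, "H0"
    if bf < 3:
        cat = "anecdotal"
    elif bf < 10:
        cat = "moderate"
    elif bf < 30:
        cat = "strong"
    elif bf < 100:
        cat = "very strong"
    else:
        cat = "extreme"
    return f"{cat} ({hyp})"
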