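"""Tail probabilities and multiple-testing helpers used across the pipeline.

Conventions, kept distinct on purpose:

* the CIMS binomial test is inclusive, P(X >= a);
* the peak-model Poisson and negative-binomial tails are strict, P(X > x).

The negative binomial is parameterized by its mean ``mu`` and dispersion
``alpha`` with variance ``mu + alpha * mu**2``; ``alpha -> 0`` recovers the
Poisson.  In scipy terms the size parameter is ``1/alpha`` and the success
probability ``(1/alpha) / (1/alpha + mu)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import DataError

# below this, dispersion is numerically indistinguishable from Poisson
ALPHA_POISSON_LIMIT = 1e-8


def binomial_tail_pvalue(a: int, y: int, p: float) -> float:
    """Inclusive upper tail P(X >= a) for X ~ Binomial(y, p).

    This is the CIMS test: ``a`` mutations observed among ``y`` reads
    covering a position, against the genome-wide per-base mutation rate
    ``p`` of the same subtype.
    """
    if not 0 <= a <= y:
        raise DataError(f"require 0 <= a <= y, got a={a}, y={y}")
    if not 0.0 <= p <= 1.0:
        raise DataError(f"mutation rate must lie in [0, 1], got {p}")
    if a == 0:
        return 1.0
    # sf(a-1) = P(X > a-1) = P(X >= a)
    return float(sps.binom.sf(a - 1, y, p))


def poisson_tail(x: int, lam: float) -> float:
    """Strict upper tail P(X > x) for X ~ Poisson(lam); lam = 0 gives 0."""
    if lam < 0:
        raise DataError(f"Poisson mean must be >= 0, got {lam}")
    if x < 0:
        raise DataError(f"count must be >= 0, got {x}")
    if lam == 0.0:
        return 0.0
    return float(sps.poisson.sf(x, lam))


def nb_tail(x, mu: float, alpha: float):
    """Strict upper tail P(X > x) for the NB(mu, alpha) distribution.

    Accepts a scalar or array ``x``.  For dispersion below
    ``ALPHA_POISSON_LIMIT`` the Poisson tail is used.
    """
    if mu < 0 or alpha < 0:
        raise DataError(f"require mu >= 0 and alpha >= 0, got mu={mu}, alpha={alpha}")
    x = np.asarray(x)
    if mu == 0.0:
        out = np.zeros(x.shape)
        return float(out) if out.ndim == 0 else out
    if alpha < ALPHA_POISSON_LIMIT:
        out = sps.poisson.sf(x, mu)
    else:
        size = 1.0 / alpha
        out = sps.nbinom.sf(x, size, size / (size + mu))
    return float(out) if np.ndim(out) == 0 else np.asarray(out)


def nb_logpmf(x, mu, alpha: float):
    """Log pmf of NB(mu, alpha); vectorized over ``x`` and ``mu``."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < ALPHA_POISSON_LIMIT:
        return sps.poisson.logpmf(x, mu)
    inv = 1.0 / alpha
    return (
        gammaln(x + inv)
        - gammaln(x + 1.0)
        - gammaln(inv)
        + x * (np.log(mu) - np.log(mu + inv))
        + inv * (np.log(inv) - np.log(mu + inv))
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone in rank and >= the raw p-values elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def product_pvalue(p1, p2, calibrated: bool = False):
    """Combine two upper-tail p-values as their product.

    The product c = p1*p2 is the pipeline's ranking score.  With
    ``calibrated=True`` the product is mapped through its exact null
    distribution under independence, P(P1*P2 <= c) = c * (1 - log c),
    which is the two-test Fisher combination expressed on the product
    scale.
    """
    c = np.asarray(p1, dtype=float) * np.asarray(p2, dtype=float)
    if not calibrated:
        return c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, c * (1.0 - np.log(c)), 0.0)
    return np.minimum(out, 1.0)
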