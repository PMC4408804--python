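"""Independent brute-force oracles for the tail probabilities.

These deliberately avoid scipy's distribution machinery (the code under
test uses it): binomial terms via math.comb, Poisson and NB terms via
direct series with math.lgamma.
"""

import math


def binom_tail(a: int, y: int, p: float) -> float:
    """P(X >= a) by direct summation with exact binomial coefficients."""
    if a == 0:
        return 1.0
    return sum(math.comb(y, x) * p**x * (1 - p) ** (y - x) for x in range(a, y + 1))


def poisson_tail(x: int, lam: float) -> float:
    """P(X > x) by direct summation of the upper pmf terms."""
    if lam == 0:
        return 0.0
    total = 0.0
    for k in range(x + 1, x + 5000):
        term = math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
        total += term
        if term < total * 1e-18 and k > lam:
            break
    return total


def nb_logpmf(k: int, mu: float, alpha: float) -> float:
    inv = 1.0 / alpha
    return (
        math.lgamma(k + inv)
        - math.lgamma(k + 1)
        - math.lgamma(inv)
        + k * (math.log(mu) - math.log(mu + inv))
        + inv * (math.log(inv) - math.log(mu + inv))
    )


def nb_tail(x: int, mu: float, alpha: float) -> float:
    """P(X > x) for NB(mu, alpha) by direct summation of upper pmf terms."""
    total = 0.0
    for k in range(x + 1, x + 100_000):
        term = math.exp(nb_logpmf(k, mu, alpha))
        total += term
        if term < total * 1e-18 and k > mu:
            break
    return total


def bh_stepup(pvals):
    """Step-up BH adjustment done by hand (sort, scale, cummin, unsort)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    scaled = [pvals[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(scaled[i], 1.0)
    return out
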