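"""Maximum-likelihood negative-binomial fits.

Two fits are needed by the pipeline:

* a two-parameter regression of CLIP window counts on log RNA-seq counts,
  log mu(r) = a + b * log(r + c), with a global dispersion alpha
  (variance mu + alpha * mu**2) — the exon-window background model;
* a one-sample NB(mu, alpha) over region totals — the miRNA-region model,
  which has no RNA-seq control.

Both are fitted by direct likelihood maximization with the dispersion on
the log scale and several starting values (a moment estimate plus fixed
fallbacks), and report standard errors from the finite-difference observed
information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DataError
from .stats import nb_logpmf

_LOG_ALPHA_MIN = np.log(1e-8)
_LOG_ALPHA_MAX = np.log(1e4)


@dataclass
class NBRegressionFit:
    """Fitted CLIP-vs-RNA-seq background regression.

    mean model: log mu(r) = a + b * log(r + pseudocount)
    """

    a: float
    b: float
    alpha: float
    log_likelihood: float
    converged: bool
    pseudocount: float = 1.0
    se: dict = field(default_factory=dict)  # keys: a, b, alpha
    n: int = 0

    def mu(self, r):
        return np.exp(self.a + self.b * np.log(np.asarray(r, dtype=float) + self.pseudocount))


@dataclass
class NBOneSampleFit:
    mu: float
    alpha: float
    log_likelihood: float
    converged: bool
    se: dict = field(default_factory=dict)
    n: int = 0


def _numerical_hessian(f, theta, rel_step=1e-4):
    """Central-difference Hessian of scalar f at theta."""
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4.0 * h[i] * h[j])
    return H


def _se_from_hessian(nll, theta_hat, names):
    """Delta-method standard errors; the last coordinate is log(alpha)."""
    try:
        H = _numerical_hessian(nll, theta_hat)
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0) or np.any(~np.isfinite(var)):
            return {}
        se = dict(zip(names, np.sqrt(var)))
        if "log_alpha" in se:
            # se(alpha) = alpha * se(log alpha)
            se["alpha"] = float(np.exp(theta_hat[-1]) * se.pop("log_alpha"))
        return {k: float(v) for k, v in se.items()}
    except np.linalg.LinAlgError:
        return {}


def _moment_alpha(x, mu):
    """Method-of-moments dispersion from residuals around a mean vector."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    num = np.sum((x - mu) ** 2 - mu)
    den = np.sum(mu**2)
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def fit_nb_regression(
    x,
    r,
    pseudocount: float = 1.0,
    min_windows: int = 200,
) -> NBRegressionFit:
    """Fit log E(X|r) = a + b log(r + pseudocount) with NB errors by MLE.

    ``x`` are CLIP window counts, ``r`` the normalized RNA-seq counts for
    the same windows.  Raises :class:`DataError` when fewer than
    ``min_windows`` windows are supplied.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.shape != r.shape or x.ndim != 1:
        raise DataError("x and r must be 1-D vectors of equal length")
    if x.size < min_windows:
        raise DataError(f"need at least {min_windows} windows to fit, got {x.size}")
    if np.any(r < 0) or np.any(x < 0):
        raise DataError("counts must be non-negative")

    t = np.log(r + pseudocount)

    def nll(theta):
        a, b, log_alpha = theta
        mu = np.exp(np.clip(a + b * t, -30.0, 30.0))
        ll = np.sum(nb_logpmf(x, mu, float(np.exp(log_alpha))))
        return -ll if np.isfinite(ll) else 1e300

    # crude start from least squares on the log scale
    A = np.vstack([np.ones_like(t), t]).T
    coef, *_ = np.linalg.lstsq(A, np.log(x + 1.0), rcond=None)
    mu0 = np.exp(np.clip(A @ coef, -30, 30))
    alpha_mom = _moment_alpha(x, mu0)

    starts = []
    for a0 in {max(alpha_mom, 1e-3), 0.1, 1.0}:
        starts.append(np.array([coef[0], coef[1], np.log(a0)]))

    best = None
    for s in starts:
        res = optimize.minimize(
            nll,
            s,
            method="L-BFGS-B",
            bounds=[(-50, 50), (-50, 50), (_LOG_ALPHA_MIN, _LOG_ALPHA_MAX)],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    converged = bool(best.success and np.all(np.isfinite(theta)))
    alpha_hat = float(np.exp(theta[2]))
    if alpha_hat <= 2 * np.exp(_LOG_ALPHA_MIN):
        alpha_hat = 0.0
    se = _se_from_hessian(nll, best.x, ["a", "b", "log_alpha"]) if converged else {}
    return NBRegressionFit(
        a=float(theta[0]),
        b=float(theta[1]),
        alpha=alpha_hat,
        log_likelihood=float(-best.fun),
        converged=converged,
        pseudocount=pseudocount,
        se=se,
        n=int(x.size),
    )


def fit_nb_one_sample(counts, min_regions: int = 20) -> NBOneSampleFit:
    """MLE of (mu, alpha) for an i.i.d. NB sample of region totals.

    For this parameterization the MLE of the mean is the sample mean, so
    alpha is profiled on the log scale.  When the moment estimate of the
    dispersion is <= 0 the fit degenerates gracefully to Poisson
    (alpha = 0).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < min_regions:
        raise DataError(f"need at least {min_regions} regions, got {x.size}")
    if np.any(x < 0):
        raise DataError("counts must be non-negative")
    if np.all(x == 0):
        raise DataError("all-zero counts: nothing to fit")

    mu_hat = float(np.mean(x))
    alpha_mom = _moment_alpha(x, np.full_like(x, mu_hat))

    def nll_alpha(log_alpha):
        ll = np.sum(nb_logpmf(x, mu_hat, float(np.exp(log_alpha))))
        return -ll if np.isfinite(ll) else np.inf

    if alpha_mom <= 0:
        ll = float(np.sum(nb_logpmf(x, mu_hat, 0.0)))
        se = {"mu": float(np.sqrt(mu_hat / x.size))}
        return NBOneSampleFit(mu=mu_hat, alpha=0.0, log_likelihood=ll,
                              converged=True, se=se, n=int(x.size))

    res = optimize.minimize_scalar(
        nll_alpha, bounds=(_LOG_ALPHA_MIN, _LOG_ALPHA_MAX), method="bounded",
        options={"xatol": 1e-10},
    )
    alpha_hat = float(np.exp(res.x))
    if alpha_hat <= 2 * np.exp(_LOG_ALPHA_MIN):
        alpha_hat = 0.0

    def nll_joint(theta):
        mu, log_alpha = theta
        if mu <= 0:
            return np.inf
        ll = np.sum(nb_logpmf(x, mu, float(np.exp(log_alpha))))
        return -ll if np.isfinite(ll) else np.inf

    se = {}
    if alpha_hat > 0:
        se = _se_from_hessian(nll_joint, np.array([mu_hat, np.log(alpha_hat)]),
                              ["mu", "log_alpha"])
    if "mu" not in se:
        se["mu"] = float(np.sqrt(max(mu_hat + alpha_hat * mu_hat**2, 1e-12) / x.size))
    return NBOneSampleFit(
        mu=mu_hat,
        alpha=alpha_hat,
        log_likelihood=float(-res.fun),
        converged=bool(alpha_hat == 0.0 or res.success),
        se=se,
        n=int(x.size),
    )
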