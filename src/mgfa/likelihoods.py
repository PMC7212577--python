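"""Per-view observation models.

Gaussian data enter the variational objective exactly.  Bernoulli and
Poisson data are handled through local quadratic lower bounds on the
log-likelihood, one auxiliary parameter zeta per observed entry.  Each bound
is expressible as a Gaussian pseudo-observation (pseudo-data ytilde with
pseudo-precision tau-tilde), which lets the Gaussian update machinery for
factors and weights be reused unchanged for non-Gaussian views.

Bernoulli uses the Jaakkola–Jordan logistic bound (tight at |x| = zeta).
Poisson uses a uniform-curvature quadratic bound around zeta for the
log-likelihood under a softplus rate; the curvature constant is

    kappa(y) = 1/4 + 0.17 * y,

since sup_x softplus''(x) = 1/4 and sup_x [-(d^2/dx^2) log softplus(x)]
= 0.1671 < 0.17 (numerically; the supremum sits near x = 0.5).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

#: uniform bound on the curvature of -log softplus; see module docstring
POISSON_CURVATURE_C = 0.17

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def softplus(x):
    return np.logaddexp(0.0, x)


def jj_lambda(zeta):
    """Jaakkola–Jordan lambda(zeta) = tanh(zeta/2)/(4 zeta), with lambda(0) = 1/8."""
    zeta = np.asarray(zeta, dtype=float)
    out = np.full(zeta.shape, 0.125)
    nz = np.abs(zeta) > 1e-8
    out[nz] = np.tanh(zeta[nz] / 2.0) / (4.0 * zeta[nz])
    return out if out.ndim else float(out)


# ---------------------------------------------------------------- gaussian
def gaussian_expected_loglik(y, mask, ex, exx, e_tau, e_logtau):
    """Exact E_q[log N(y | x, 1/tau)] summed over observed entries.

    Parameters
    ----------
    y, mask : (N, D) data and observation mask.
    ex, exx : (N, D) first and second moments of the linear predictor
        x = sum_k z_k w_k under q; ``exx`` must be the true second moment
        (mean squared plus propagated variance), not ``ex**2``.
    e_tau, e_logtau : (D,) expectations of the noise precision and its log.
    """
    if np.any(e_tau <= 0):
        raise ValueError("noise precision expectations must be positive")
    quad = y * y - 2.0 * y * ex + exx
    n_obs = mask.sum(axis=0)
    return float(
        np.sum(n_obs * (0.5 * e_logtau - _HALF_LOG_2PI))
        - 0.5 * np.sum(e_tau * np.sum(quad * mask, axis=0))
    )


# --------------------------------------------------------------- bernoulli
def bernoulli_bound(y, ex, exx, zeta):
    """Jaakkola–Jordan lower bound on E_q[log p(y | x)], logistic link.

    log p(y|x) = log sigmoid((2y-1) x) >= log sigmoid(zeta)
                 + (y - 1/2) x - zeta/2 - lambda(zeta) (x^2 - zeta^2)

    evaluated in expectation (x -> E[x], x^2 -> E[x^2]).  Equality holds for
    a point mass at |x| = zeta.
    """
    lam = jj_lambda(zeta)
    return (
        np.log(expit(zeta)) + (np.asarray(y) - 0.5) * ex - zeta / 2.0
        - lam * (exx - zeta ** 2)
    )


def bernoulli_zeta(exx):
    """Optimal zeta = sqrt(E[x^2]) of the logistic bound."""
    return np.sqrt(np.maximum(exx, 0.0))


def bernoulli_pseudo(y, zeta):
    """Gaussian pseudo-observation equivalent to the logistic bound.

    Returns (tau_tilde, y_tilde): the bound's quadratic part equals
    -tau_tilde/2 (x - y_tilde)^2 + const with tau_tilde = 2 lambda(zeta).
    """
    tau = 2.0 * jj_lambda(zeta)
    return tau, (np.asarray(y, dtype=float) - 0.5) / tau


# ----------------------------------------------------------------- poisson
def _poisson_f(y, x):
    """Exact Poisson log-pmf term f(x) = y log softplus(x) - softplus(x) (no y! term)."""
    rate = np.maximum(softplus(x), 1e-300)
    return y * np.log(rate) - rate


def _poisson_fprime(y, x):
    rate = np.maximum(softplus(x), 1e-300)
    return expit(x) * (y / rate - 1.0)


def poisson_kappa(y):
    """Curvature constant kappa(y) = 1/4 + c*y bounding -f'' uniformly in x."""
    return 0.25 + POISSON_CURVATURE_C * np.asarray(y, dtype=float)


def poisson_bound(y, ex, exx, zeta):
    """Quadratic lower bound on E_q[y log softplus(x) - softplus(x)].

    f(x) >= f(zeta) + f'(zeta)(x - zeta) - kappa(y)/2 (x - zeta)^2, with
    kappa a uniform curvature bound; tight (equality) at x = zeta.  The
    log y! normalizer is included so the bound compares to the full log-pmf.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or np.any(y_arr != np.round(y_arr)):
        raise ValueError("poisson observations must be non-negative integers")
    from scipy.special import gammaln

    kap = poisson_kappa(y_arr)
    return (
        _poisson_f(y_arr, zeta)
        + _poisson_fprime(y_arr, zeta) * (ex - zeta)
        - 0.5 * kap * (exx - 2.0 * zeta * ex + zeta ** 2)
        - gammaln(y_arr + 1.0)
    )


def poisson_zeta(ex):
    """Optimal expansion point zeta = E[x] of the curvature bound."""
    return np.asarray(ex, dtype=float)


def poisson_pseudo(y, zeta):
    """Gaussian pseudo-observation equivalent of the Poisson bound.

    tau_tilde = kappa(y) (independent of zeta); y_tilde = zeta + f'(zeta)/kappa.
    """
    y_arr = np.asarray(y, dtype=float)
    kap = poisson_kappa(y_arr)
    return kap, zeta + _poisson_fprime(y_arr, zeta) / kap


def exact_loglik(likelihood, y, x):
    """Exact log p(y | x) for a scalar/array linear predictor (reference)."""
    from scipy.stats import poisson as _pois

    if likelihood == "gaussian":
        raise ValueError("gaussian handled by gaussian_expected_loglik")
    if likelihood == "bernoulli":
        return np.log(expit((2.0 * np.asarray(y) - 1.0) * x))
    if likelihood == "poisson":
        return _pois.logpmf(np.asarray(y), softplus(x))
    raise ValueError(likelihood)
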