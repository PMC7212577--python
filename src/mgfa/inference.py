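"""Mean-field coordinate-ascent variational inference for the factor model.

Each sweep updates, in a fixed canonical order, the local bound parameters
(non-gaussian views), weights, factor values, ARD precisions, sparsity
levels and noise precisions.  Every sub-update is the exact mean-field
optimum of the ELBO given all other factors of q, so the ELBO is
non-decreasing across sweeps up to floating-point error.  Missing data are
handled by restricting all sufficient statistics to observed entries; no
imputation takes place during inference.

The same update kernels serve stochastic inference (see :mod:`mgfa.svi`):
they accept a sample subset per group, per-group scaling of sufficient
statistics, and a step size ``rho`` interpolating natural parameters of the
global posteriors.  With the full sample set and ``rho = 1`` they reduce
exactly to the coordinate-ascent updates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, xlogy

from . import likelihoods as lik
from .model import (
    BetaPosterior,
    GammaPosterior,
    ModelState,
    NormalPosterior,
    SpikeSlabPosterior,
    TrainingOptions,
    TrainingTrace,
)

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

# factor considered dead mid-training when both its largest |E[z]| and its
# variance-explained proxy fall below this
_DEAD_TOL = 1e-10


# ----------------------------------------------------------------- helpers
def _logit(p):
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p) - np.log1p(-p)


def _block_targets(state, ds, gname, vname, rows=None):
    """Per-entry working precision and regression target for one block.

    Gaussian views: precision = mask * E[tau_d], target = y.  Non-gaussian
    views: the local quadratic bound at the current zeta defines a Gaussian
    pseudo-observation (pseudo-precision, pseudo-data); masked entries get
    zero precision so they never contribute.
    """
    key = (gname, vname)
    likelihood = ds.view(vname).likelihood
    y = ds.y[key]
    m = ds.mask[key]
    if rows is not None:
        y = y[rows]
        m = m[rows]
    if likelihood == "gaussian":
        T = m * state.tau[key].mean
        return T, y
    zeta = state.zeta[key]
    if rows is not None:
        zeta = zeta[rows]
    if likelihood == "bernoulli":
        tt, x = lik.bernoulli_pseudo(y, zeta)
    else:
        tt, x = lik.poisson_pseudo(y, zeta)
    return m * tt, x


def _predictor_moments(state, gname, vname, rows=None):
    """First/second moments of the linear predictor x = sum_k z_k w_k."""
    z = state.z[gname]
    w = state.w[vname]
    ez, ezz = z.e, z.e2
    if rows is not None:
        ez, ezz = ez[rows], ezz[rows]
    ex = ez @ w.e.T
    exx = ex ** 2 + ezz @ w.e2.T - (ez ** 2) @ (w.e ** 2).T
    return ex, exx


def _check_finite(name, *arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise RuntimeError(f"non-finite values produced by the {name} update")


# ------------------------------------------------------------ sub-updates
def _update_zeta(state, ds, rows=None):
    for g in ds.group_names:
        r = None if rows is None else rows[g]
        for v in ds.view_names:
            likelihood = ds.view(v).likelihood
            if likelihood == "gaussian":
                continue
            ex, exx = _predictor_moments(state, g, v, rows=r)
            new = lik.bernoulli_zeta(exx) if likelihood == "bernoulli" else lik.poisson_zeta(ex)
            if r is None:
                state.zeta[(g, v)] = new
            else:
                state.zeta[(g, v)][r] = new
            _check_finite("zeta", new)


def _update_w(state, ds, opts, rows=None, scale=None, rho=1.0):
    """Spike-and-slab weight update, factor columns swept sequentially."""
    for v in ds.view_names:
        wpost = state.w[v]
        e_alpha = state.alpha_w[v].mean
        lt = state.theta_w[v].mean_log - state.theta_w[v].mean_log1m
        per_group = []
        K = state.K
        D = ds.view(v).n_features
        foo = np.zeros((D, K))
        for g in ds.group_names:
            r = None if rows is None else rows[g]
            s_g = 1.0 if scale is None else scale[g]
            T, X = _block_targets(state, ds, g, v, rows=r)
            z = state.z[g]
            ez = z.e if r is None else z.e[r]
            ezz = z.e2 if r is None else z.e2[r]
            foo += s_g * (T.T @ ezz)
            P = ez @ wpost.e.T
            per_group.append((T, X, ez, P, s_g))
        ew = wpost.e  # refreshed column-wise below
        for k in range(K):
            bar = np.zeros(D)
            for T, X, ez, P, s_g in per_group:
                R = X - P + np.outer(ez[:, k], ew[:, k])
                bar += s_g * ((T * R).T @ ez[:, k])
            hat_prec = foo[:, k] + e_alpha[k]
            hat_var = 1.0 / hat_prec
            hat_mu = bar * hat_var
            hat_logit = lt[k] + 0.5 * np.log(e_alpha[k] * hat_var) + 0.5 * hat_mu ** 2 / hat_var
            if rho >= 1.0:
                new_var = hat_var
                new_mu = hat_mu
                new_prob = expit(hat_logit)
                new_var0 = 1.0 / e_alpha[k]
            else:
                prec = (1.0 - rho) / wpost.var[:, k] + rho * hat_prec
                mmp = (1.0 - rho) * wpost.mean[:, k] / wpost.var[:, k] + rho * bar
                new_var = 1.0 / prec
                new_mu = mmp * new_var
                new_prob = expit((1.0 - rho) * _logit(wpost.prob[:, k]) + rho * hat_logit)
                new_var0 = 1.0 / ((1.0 - rho) / wpost.var0[k] + rho * e_alpha[k])
            ew_old = ew[:, k].copy()
            wpost.mean[:, k] = new_mu
            wpost.var[:, k] = new_var
            wpost.prob[:, k] = new_prob
            wpost.var0[k] = new_var0
            delta = wpost.e[:, k] - ew_old
            for T, X, ez, P, s_g in per_group:
                P += np.outer(ez[:, k], delta)
        _check_finite("weights", wpost.mean, wpost.var, wpost.prob)


def _update_z(state, ds, opts, rows=None):
    """Factor-value update (local variables); exact for the selected rows."""
    for g in ds.group_names:
        r = None if rows is None else rows[g]
        zpost = state.z[g]
        K = state.K
        spike = isinstance(zpost, SpikeSlabPosterior)
        if state.alpha_z is not None:
            e_alpha = state.alpha_z[g].mean
            e_logalpha = state.alpha_z[g].mean_log
        else:
            e_alpha = np.ones(K)
            e_logalpha = np.zeros(K)
        if spike:
            lt = state.theta_z[g].mean_log - state.theta_z[g].mean_log1m
        per_view = []
        n = ds.group(g).n_samples if r is None else len(r)
        foo = np.zeros((n, K))
        for v in ds.view_names:
            T, X = _block_targets(state, ds, g, v, rows=r)
            w = state.w[v]
            foo += T @ w.e2
            ez = zpost.e if r is None else zpost.e[r]
            P = ez @ w.e.T
            per_view.append((T, X, w, P))
        ez_cur = zpost.e if r is None else zpost.e[r]
        ez_cur = ez_cur.copy()
        for k in range(K):
            bar = np.zeros(n)
            for T, X, w, P in per_view:
                R = X - P + np.outer(ez_cur[:, k], w.e[:, k])
                bar += (T * R) @ w.e[:, k]
            hat_prec = foo[:, k] + e_alpha[k]
            new_var = 1.0 / hat_prec
            new_mu = bar * new_var
            if spike:
                logit = lt[k] + 0.5 * np.log(e_alpha[k] * new_var) + 0.5 * new_mu ** 2 / new_var
                new_prob = expit(logit)
            idx = slice(None) if r is None else r
            zpost.mean[idx, k] = new_mu
            zpost.var[idx, k] = new_var
            if spike:
                zpost.prob[idx, k] = new_prob
                zpost.var0[k] = 1.0 / e_alpha[k]
                new_e = new_prob * new_mu
            else:
                new_e = new_mu
            delta = new_e - ez_cur[:, k]
            ez_cur[:, k] = new_e
            for T, X, w, P in per_view:
                P += np.outer(delta, w.e[:, k])
        _check_finite("factors", zpost.mean, zpost.var)


def _interp_gamma(post, a_hat, b_hat, rho):
    if rho >= 1.0:
        post.a = np.asarray(a_hat, dtype=float) + np.zeros_like(post.a)
        post.b = np.asarray(b_hat, dtype=float) + np.zeros_like(post.b)
    else:
        post.a = (1.0 - rho) * post.a + rho * a_hat
        post.b = (1.0 - rho) * post.b + rho * b_hat


def _update_alpha_w(state, ds, opts, rho=1.0):
    pr = opts.priors
    for v in ds.view_names:
        wpost = state.w[v]
        D = wpost.mean.shape[0]
        a_hat = pr.ard_shape + 0.5 * D
        b_hat = pr.ard_rate + 0.5 * wpost.e_what2.sum(axis=0)
        _interp_gamma(state.alpha_w[v], a_hat, b_hat, rho)
        _check_finite("alpha_w", state.alpha_w[v].a, state.alpha_w[v].b)


def _update_alpha_z(state, ds, opts, rows=None, scale=None, rho=1.0):
    if state.alpha_z is None:
        return
    pr = opts.priors
    for g in ds.group_names:
        zpost = state.z[g]
        r = None if rows is None else rows[g]
        s_g = 1.0 if scale is None else scale[g]
        if isinstance(zpost, SpikeSlabPosterior):
            stats = zpost.e_what2
        else:
            stats = zpost.e2
        if r is not None:
            stats = stats[r]
        a_hat = pr.ard_shape + 0.5 * s_g * stats.shape[0]
        b_hat = pr.ard_rate + 0.5 * s_g * stats.sum(axis=0)
        _interp_gamma(state.alpha_z[g], a_hat, b_hat, rho)
        _check_finite("alpha_z", state.alpha_z[g].a, state.alpha_z[g].b)


def _update_theta_w(state, ds, opts, rho=1.0):
    pr = opts.priors
    for v in ds.view_names:
        lam = state.w[v].prob
        D = lam.shape[0]
        a_hat = pr.sparsity_a + lam.sum(axis=0)
        b_hat = pr.sparsity_b + D - lam.sum(axis=0)
        _interp_gamma(state.theta_w[v], a_hat, b_hat, rho)
        _check_finite("theta_w", state.theta_w[v].a, state.theta_w[v].b)


def _update_theta_z(state, ds, opts, rows=None, scale=None, rho=1.0):
    if state.theta_z is None:
        return
    pr = opts.priors
    for g in ds.group_names:
        zpost = state.z[g]
        if not isinstance(zpost, SpikeSlabPosterior):
            continue
        r = None if rows is None else rows[g]
        s_g = 1.0 if scale is None else scale[g]
        lam = zpost.prob if r is None else zpost.prob[r]
        a_hat = pr.sparsity_a + s_g * lam.sum(axis=0)
        b_hat = pr.sparsity_b + s_g * (lam.shape[0] - lam.sum(axis=0))
        _interp_gamma(state.theta_z[g], a_hat, b_hat, rho)
        _check_finite("theta_z", state.theta_z[g].a, state.theta_z[g].b)


def _update_tau(state, ds, opts, rows=None, scale=None, rho=1.0):
    pr = opts.priors
    for g in ds.group_names:
        r = None if rows is None else rows[g]
        s_g = 1.0 if scale is None else scale[g]
        for v in ds.view_names:
            if ds.view(v).likelihood != "gaussian":
                continue
            key = (g, v)
            y = ds.y[key]
            m = ds.mask[key]
            if r is not None:
                y, m = y[r], m[r]
            ex, exx = _predictor_moments(state, g, v, rows=r)
            quad = (y * y - 2.0 * y * ex + exx) * m
            a_hat = pr.noise_shape + 0.5 * s_g * m.sum(axis=0)
            b_hat = pr.noise_rate + 0.5 * s_g * quad.sum(axis=0)
            _interp_gamma(state.tau[key], a_hat, b_hat, rho)
            _check_finite("tau", state.tau[key].a, state.tau[key].b)


# --------------------------------------------------------------- sweeps
def vi_iteration(state: ModelState, ds, opts: TrainingOptions) -> ModelState:
    """One full coordinate-ascent sweep in canonical order.

    Order: local bound parameters (zeta) -> weights per view -> factors per
    group -> ARD precisions (weights, factors) -> sparsity levels (weights,
    factors) -> noise precisions.  Each sub-update is exact, so the ELBO
    cannot decrease beyond numerical round-off.
    """
    _update_zeta(state, ds)
    _update_w(state, ds, opts)
    _update_z(state, ds, opts)
    _update_alpha_w(state, ds, opts)
    _update_alpha_z(state, ds, opts)
    _update_theta_w(state, ds, opts)
    _update_theta_z(state, ds, opts)
    _update_tau(state, ds, opts)
    return state


# ----------------------------------------------------------------- ELBO
def _spike_slab_term(post, theta, e_alpha, e_logalpha):
    """E_q[log p(what, s | alpha, theta)] + H[q(what, s)], summed."""
    lam, mu, var, var0 = post.prob, post.mean, post.var, post.var0
    lt, lt1 = theta.mean_log, theta.mean_log1m
    e_w2 = lam * (mu ** 2 + var) + (1.0 - lam) * var0
    t = np.sum(lam * lt + (1.0 - lam) * lt1)
    t += np.sum(0.5 * e_logalpha * lam.shape[0]) - lam.size * _HALF_LOG_2PI
    t -= 0.5 * np.sum(e_alpha * e_w2.sum(axis=0))
    # entropy: Bernoulli part plus branch-conditional Gaussians
    t -= np.sum(xlogy(lam, lam) + xlogy(1.0 - lam, 1.0 - lam))
    t += np.sum(lam * 0.5 * (np.log(2.0 * np.pi * var) + 1.0))
    t += np.sum((1.0 - lam) * 0.5 * (np.log(2.0 * np.pi * var0) + 1.0))
    return float(t)


def _normal_term(post, e_alpha, e_logalpha):
    """E_q[log p(z | alpha)] + H[q(z)] for a dense Gaussian posterior."""
    mu, var = post.mean, post.var
    n = mu.shape[0]
    t = 0.5 * n * np.sum(e_logalpha) - mu.size * _HALF_LOG_2PI
    t -= 0.5 * np.sum(e_alpha * (mu ** 2 + var).sum(axis=0))
    t += 0.5 * np.sum(np.log(2.0 * np.pi * var) + 1.0)
    return float(t)


def compute_elbo(state: ModelState, ds, opts: TrainingOptions) -> float:
    """Evidence lower bound: E_q[log p(Y, params)] - E_q[log q].

    Likelihood terms are summed over observed entries only; non-gaussian
    views contribute their local-bound surrogate at the current zeta.
    """
    pr = opts.priors
    total = 0.0
    # data terms
    for g in ds.group_names:
        for v in ds.view_names:
            key = (g, v)
            likelihood = ds.view(v).likelihood
            y, m = ds.y[key], ds.mask[key]
            ex, exx = _predictor_moments(state, g, v)
            if likelihood == "gaussian":
                tau = state.tau[key]
                total += lik.gaussian_expected_loglik(y, m, ex, exx, tau.mean, tau.mean_log)
            elif likelihood == "bernoulli":
                total += float(np.sum(lik.bernoulli_bound(y, ex, exx, state.zeta[key]) * m))
            else:
                b = lik.poisson_bound(np.where(m, y, 0.0), ex, exx, state.zeta[key])
                total += float(np.sum(b * m))
    # weights
    for v in ds.view_names:
        total += _spike_slab_term(state.w[v], state.theta_w[v],
                                  state.alpha_w[v].mean, state.alpha_w[v].mean_log)
        total -= state.alpha_w[v].kl_to(pr.ard_shape, pr.ard_rate)
        total -= state.theta_w[v].kl_to(pr.sparsity_a, pr.sparsity_b)
    # factors
    for g in ds.group_names:
        zpost = state.z[g]
        if state.alpha_z is not None:
            e_a = state.alpha_z[g].mean
            e_la = state.alpha_z[g].mean_log
        else:
            e_a = np.ones(state.K)
            e_la = np.zeros(state.K)
        if isinstance(zpost, SpikeSlabPosterior):
            total += _spike_slab_term(zpost, state.theta_z[g], e_a, e_la)
            total -= state.theta_z[g].kl_to(pr.sparsity_a, pr.sparsity_b)
        else:
            total += _normal_term(zpost, e_a, e_la)
        if state.alpha_z is not None:
            total -= state.alpha_z[g].kl_to(pr.ard_shape, pr.ard_rate)
    # noise
    for key, tau in state.tau.items():
        total -= tau.kl_to(pr.noise_shape, pr.noise_rate)
    return float(total)


# ------------------------------------------------------------ initialize
def initialize(ds, opts: TrainingOptions) -> ModelState:
    """Deterministic initialization from principal components.

    Factor means are set to the first K principal-component scores of the
    feature-wise concatenated, group-wise stacked data matrix; missing
    entries are zero-filled (the per-group feature mean, for centered data)
    for the decomposition only.  Scores are standardized to unit variance
    per factor.  Weights start at zero mean, unit slab variance, inclusion
    probability 1/2; Gamma/Beta posteriors start at their priors.
    """
    pr = opts.priors
    K = opts.n_factors
    # concatenated matrix
    rows = []
    for g in ds.groups:
        parts = []
        for v in ds.views:
            key = (g.name, v.name)
            block = ds.y[key] * ds.mask[key]
            # column-center observed values so raw 0/1 or count scales do not
            # inject a mean component into the decomposition
            cnt = ds.mask[key].sum(axis=0)
            mean = np.divide(block.sum(axis=0), cnt, out=np.zeros(block.shape[1]),
                             where=cnt > 0)
            parts.append(np.where(ds.mask[key], ds.y[key] - mean, 0.0))
        rows.append(np.hstack(parts))
    A = np.vstack(rows)
    feasible = min(A.shape)
    if K > feasible:
        warnings.warn(f"n_factors={K} exceeds feasible rank {feasible}; reduced")
        K = feasible
    if np.any(A):
        U, S, _ = np.linalg.svd(A, full_matrices=False)
        scores = U[:, :K] * S[:K]
        sd = scores.std(axis=0)
        scores = np.divide(scores, sd, out=scores, where=sd > 0)
    else:
        scores = np.zeros((A.shape[0], K))

    pos = 0
    z = {}
    alpha_z = {} if opts.ard_factors else None
    theta_z = {} if opts.spike_slab_factors else None
    for g in ds.groups:
        sc = scores[pos: pos + g.n_samples]
        pos += g.n_samples
        if opts.spike_slab_factors:
            z[g.name] = SpikeSlabPosterior(sc.copy(), np.ones_like(sc),
                                           np.full(sc.shape, 0.5),
                                           np.full(K, pr.ard_rate / pr.ard_shape))
            theta_z[g.name] = BetaPosterior(np.full(K, pr.sparsity_a),
                                            np.full(K, pr.sparsity_b))
        else:
            z[g.name] = NormalPosterior(sc.copy(), np.ones_like(sc))
        if opts.ard_factors:
            alpha_z[g.name] = GammaPosterior(np.full(K, pr.ard_shape),
                                             np.full(K, pr.ard_rate))
    w, alpha_w, theta_w = {}, {}, {}
    tau, zeta = {}, {}
    for v in ds.views:
        D = v.n_features
        w[v.name] = SpikeSlabPosterior(np.zeros((D, K)), np.ones((D, K)),
                                       np.full((D, K), 0.5),
                                       np.full(K, pr.ard_rate / pr.ard_shape))
        alpha_w[v.name] = GammaPosterior(np.full(K, pr.ard_shape),
                                         np.full(K, pr.ard_rate))
        theta_w[v.name] = BetaPosterior(np.full(K, pr.sparsity_a),
                                        np.full(K, pr.sparsity_b))
        for g in ds.groups:
            key = (g.name, v.name)
            if v.likelihood == "gaussian":
                tau[key] = GammaPosterior(np.full(D, pr.noise_shape),
                                          np.full(D, pr.noise_rate))
            else:
                zeta[key] = np.ones((g.n_samples, D))
    return ModelState(w, z, alpha_w, alpha_z, theta_w, theta_z, tau, zeta, K)


# ------------------------------------------------------------------- fit
def _factor_activity_proxy(state, ds):
    """Cheap per-factor signal proxy: sum over blocks of sum (z_k w_k)^2 / sum y^2."""
    num = np.zeros(state.K)
    den = 0.0
    for g in ds.group_names:
        for v in ds.view_names:
            key = (g, v)
            m = ds.mask[key]
            ez2 = state.z[g].e ** 2
            ew2 = state.w[v].e ** 2
            num += ((m.T @ ez2) * ew2).sum(axis=0)
            den += float((ds.y[key] ** 2 * m).sum())
    return num / max(den, 1e-300)


def _drop_dead_factors(state, ds):
    """Remove factors whose posterior has collapsed to an effective zero."""
    maxabs = np.zeros(state.K)
    for g in ds.group_names:
        maxabs = np.maximum(maxabs, np.abs(state.z[g].e).max(axis=0))
    proxy = _factor_activity_proxy(state, ds)
    keep = np.nonzero((maxabs > _DEAD_TOL) | (proxy > _DEAD_TOL))[0]
    if 0 < len(keep) < state.K:
        new = state.select_factors(keep)
        state.__dict__.update(new.__dict__)
    return state


def fit(ds, opts: TrainingOptions):
    """Train the model; returns ``(state, trace)``.

    Dispatches to full coordinate ascent (``mode='vi'``) or stochastic
    epochs (``mode='svi'``); in both modes convergence is declared when the
    change of the full-data ELBO between successive iterations drops below
    ``convergence_tol`` (absolute by default, relative if requested).
    Deterministic given the options (the SVI batch schedule is seeded).
    """
    if any(not ds.centered[v.name] for v in ds.views if v.likelihood == "gaussian"):
        warnings.warn("gaussian views not centered; centering a copy per group")
        ds = ds.center_per_group()
    state = initialize(ds, opts)
    trace = TrainingTrace(mode=opts.mode)
    if opts.mode == "svi":
        from .svi import make_batch_plan, learning_rate, svi_iteration
        step = 0
    prev = None
    for it in range(opts.max_iterations):
        if opts.mode == "vi":
            vi_iteration(state, ds, opts)
        else:
            plan = make_batch_plan(ds, opts.batch_fraction,
                                   seed=opts.seed, epoch=it)
            for batch in plan.batches:
                rho = min(1.0, learning_rate(step, opts.learning_rate,
                                             opts.forgetting_rate))
                svi_iteration(state, ds, batch, rho, opts)
                step += 1
        elbo = compute_elbo(state, ds, opts)
        if not np.isfinite(elbo):
            trace.elbo.append(elbo)
            raise RuntimeError(f"ELBO diverged at iteration {it + 1}; trace: {trace.elbo}")
        if opts.drop_inactive:
            _drop_dead_factors(state, ds)
        trace.elbo.append(elbo)
        trace.active_factors.append(state.K)
        if prev is not None:
            delta = abs(elbo - prev)
            denom = max(abs(elbo), 1e-300) if opts.tol_scale == "relative" else 1.0
            if delta / denom < opts.convergence_tol:
                trace.converged = True
                break
        prev = elbo
    trace.iterations_to_convergence = len(trace.elbo)
    return state, trace


def prune_factors(state: ModelState, r2, min_r2: float) -> ModelState:
    """Drop factors explaining less than ``min_r2`` everywhere; reorder the rest.

    ``r2`` is a :class:`~mgfa.downstream.VarianceExplained` whose factor axis
    matches the state.  Kept factors are renumbered by total variance
    explained, descending.  ``min_r2`` is on the fraction scale (0.01 = 1%).
    """
    if min_r2 < 0:
        raise ValueError("min_r2 must be >= 0")
    per_factor = np.nan_to_num(r2.r2, nan=0.0)
    best = per_factor.reshape(state.K, -1).max(axis=1)
    tot = per_factor.reshape(state.K, -1).sum(axis=1)
    keep = np.nonzero(best >= min_r2)[0] if min_r2 > 0 else np.arange(state.K)
    if len(keep) == 0:
        warnings.warn("all factors pruned (min_r2 too high?)")
        return state.select_factors([])
    order = keep[np.argsort(-tot[keep], kind="stable")]
    return state.select_factors(order)
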