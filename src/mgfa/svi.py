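"""Stochastic variational inference: mini-batches and natural-gradient steps.

Each epoch partitions every group's samples into batches (stratified, so
every group contributes to every step).  Local variables (factor values and
local bound parameters of the batch samples) are updated exactly as in the
full sweep, restricted to the batch.  Global posteriors (weights, ARD and
sparsity levels, noise precisions) take a natural-gradient step of size
rho: their natural parameters are interpolated between the current value
and the full-data optimum estimated from batch sufficient statistics scaled
by N_g / |batch_g| per group,

    eta_new = (1 - rho) * eta_old + rho * eta_hat.

The step size follows rho(t) = lr * (1 + kappa * t)^(-3/4) with t counted
per update step; with the default forgetting rate kappa > 0 this satisfies
the Robbins–Monro conditions, so the scheme is a convergent stochastic
approximation.  With a single full batch and rho = 1 every update collapses
to the plain coordinate-ascent sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import (
    _update_alpha_w,
    _update_alpha_z,
    _update_tau,
    _update_theta_w,
    _update_theta_z,
    _update_w,
    _update_z,
    _update_zeta,
)


def learning_rate(t, lr_start, forgetting):
    """Step-size schedule rho(t) = lr_start * (1 + forgetting * t)^(-3/4)."""
    if lr_start <= 0:
        raise ValueError("lr_start must be > 0")
    if forgetting < 0:
        raise ValueError("forgetting rate must be >= 0")
    return lr_start * (1.0 + forgetting * t) ** (-0.75)


@dataclass
class BatchPlan:
    """One epoch's sample partition: ``batches[i][group] -> index array``."""

    epoch: int
    batches: list
    fraction: float


def make_batch_plan(ds, fraction, seed, epoch=0) -> BatchPlan:
    """Partition each group's samples into ceil(1/fraction) stratified batches.

    Sampling is without replacement within the epoch; batch sizes within a
    group differ by at most one sample.  The shuffle is deterministic given
    (seed, epoch) and reshuffles every epoch.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_batches = int(np.ceil(1.0 / fraction))
    for g in ds.groups:
        if g.n_samples < n_batches:
            raise ValueError(
                f"fraction {fraction} yields an empty batch for group {g.name!r} "
                f"({g.n_samples} samples, {n_batches} batches)"
            )
    rng = np.random.default_rng([int(seed) % (2 ** 31), epoch])
    per_group = {}
    for g in ds.groups:
        idx = rng.permutation(g.n_samples)
        per_group[g.name] = np.array_split(idx, n_batches)
    batches = [
        {gname: np.sort(parts[b]) for gname, parts in per_group.items()}
        for b in range(n_batches)
    ]
    return BatchPlan(epoch=epoch, batches=batches, fraction=fraction)


def svi_iteration(state, ds, batch, rho, opts):
    """One stochastic step on a batch with step size ``rho`` in (0, 1].

    Update order matches the full sweep (local bounds, weights, factors,
    ARD, sparsity, noise); sample-dependent sufficient statistics are scaled
    to full-data size before the natural-parameter interpolation.
    """
    if not (0 < rho <= 1):
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    scale = {g.name: g.n_samples / len(batch[g.name]) for g in ds.groups}
    _update_zeta(state, ds, rows=batch)
    _update_w(state, ds, opts, rows=batch, scale=scale, rho=rho)
    _update_z(state, ds, opts, rows=batch)
    _update_alpha_w(state, ds, opts, rho=rho)
    _update_alpha_z(state, ds, opts, rows=batch, scale=scale, rho=rho)
    _update_theta_w(state, ds, opts, rho=rho)
    _update_theta_z(state, ds, opts, rows=batch, scale=scale, rho=rho)
    _update_tau(state, ds, opts, rows=batch, scale=scale, rho=rho)
    return state
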