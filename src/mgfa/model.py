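"""Variational posterior containers for the group factor analysis model.

Generative model, per sample group g and feature view m:

    Y_gm = Z_g W_m^T + eps_gm

with Z_g (N_g x K) factor values, W_m (D_m x K) weights.  Regularization is
symmetric on both sides and two-level:

* ARD: a Gamma precision alpha per (factor, view) on weights and per
  (factor, group) on factor values, shrinking whole factor columns to zero
  where a factor is inactive — this is what yields differential factor
  activity across views and groups.
* Spike-and-slab: each weight (optionally each factor value) is s * what
  with s ~ Bernoulli(theta), what ~ N(0, 1/alpha); theta has a Beta prior.

The spike-and-slab posterior is parameterized jointly, q(s, what) =
q(s) q(what | s), avoiding the mean-field pathology of factorizing s and
what independently: q(what | s=1) = N(mean, var), q(what | s=0) equals the
expected prior N(0, var0) with var0 = 1/E[alpha] frozen at update time.
Gaussian noise has a Gamma precision tau per (feature, group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import digamma, betaln, gammaln


@dataclass
class PriorHyperparameters:
    """Hyperparameters of the Gamma/Beta priors.

    ARD and noise Gammas default to (1e-5, 1e-5): broad and essentially
    uninformative while keeping expectations finite.  The sparsity Beta
    defaults to uniform.
    """

    ard_shape: float = 1e-5
    ard_rate: float = 1e-5
    noise_shape: float = 1e-5
    noise_rate: float = 1e-5
    sparsity_a: float = 1.0
    sparsity_b: float = 1.0

    def __post_init__(self):
        for f, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"prior hyperparameter {f} must be > 0")


@dataclass
class TrainingOptions:
    """Options controlling inference.

    ``convergence_tol`` applies to the ELBO difference between successive
    iterations (epochs in SVI mode, where the ELBO is always evaluated on
    the full dataset).  ``tol_scale`` chooses between the absolute rule
    (|dELBO| < tol) and a relative one (|dELBO| / |ELBO| < tol); the
    absolute rule is scale-dependent, so the relative form is offered for
    datasets of very different sizes.  SVI defaults: half-data batches,
    starting learning rate 1.0, forgetting rate 0.25.
    """

    n_factors: int = 10
    convergence_tol: float = 1e-4
    tol_scale: str = "absolute"  # or "relative"
    max_iterations: int = 1000
    mode: str = "vi"  # or "svi"
    batch_fraction: float = 0.5
    learning_rate: float = 1.0
    forgetting_rate: float = 0.25
    seed: int = 0
    priors: PriorHyperparameters = field(default_factory=PriorHyperparameters)
    spike_slab_factors: bool = False
    ard_factors: bool = True
    drop_inactive: bool = True

    def __post_init__(self):
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if not (0 < self.batch_fraction <= 1):
            raise ValueError("batch_fraction must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.forgetting_rate < 0:
            raise ValueError("forgetting_rate must be >= 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.mode not in ("vi", "svi"):
            raise ValueError("mode must be 'vi' or 'svi'")
        if self.tol_scale not in ("absolute", "relative"):
            raise ValueError("tol_scale must be 'absolute' or 'relative'")


@dataclass
class GammaPosterior:
    """q = Gamma(a, b) elementwise (shape/rate)."""

    a: np.ndarray
    b: np.ndarray

    @property
    def mean(self):
        return self.a / self.b

    @property
    def mean_log(self):
        return digamma(self.a) - np.log(self.b)

    def kl_to(self, a0, b0):
        """KL(q || Gamma(a0, b0)), summed over elements."""
        a, b = self.a, self.b
        return float(np.sum(
            (a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
            + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b
        ))

    def copy(self):
        return GammaPosterior(self.a.copy(), self.b.copy())


@dataclass
class BetaPosterior:
    """q = Beta(a, b) elementwise."""

    a: np.ndarray
    b: np.ndarray

    @property
    def mean_log(self):
        return digamma(self.a) - digamma(self.a + self.b)

    @property
    def mean_log1m(self):
        return digamma(self.b) - digamma(self.a + self.b)

    def kl_to(self, a0, b0):
        a, b = self.a, self.b
        return float(np.sum(
            betaln(a0, b0) - betaln(a, b)
            + (a - a0) * digamma(a) + (b - b0) * digamma(b)
            + (a0 - a + b0 - b) * digamma(a + b)
        ))

    def copy(self):
        return BetaPosterior(self.a.copy(), self.b.copy())


@dataclass
class SpikeSlabPosterior:
    """Joint spike-and-slab posterior over a (rows x K) coefficient matrix.

    mean, var : slab moments of q(what | s=1), per element.
    prob : inclusion probability q(s=1); all ones when the spike is disabled.
    var0 : per-factor variance of the spike branch q(what | s=0) = N(0, var0),
        frozen to 1/E[alpha] at the time of the last coefficient update.
    """

    mean: np.ndarray
    var: np.ndarray
    prob: np.ndarray
    var0: np.ndarray

    @property
    def e(self):
        """E[s * what]"""
        return self.prob * self.mean

    @property
    def e2(self):
        """E[(s * what)^2]"""
        return self.prob * (self.mean ** 2 + self.var)

    @property
    def e_what2(self):
        """E[what^2] under the full mixture (enters the ARD update)."""
        return self.prob * (self.mean ** 2 + self.var) + (1.0 - self.prob) * self.var0

    def copy(self):
        return SpikeSlabPosterior(self.mean.copy(), self.var.copy(),
                                  self.prob.copy(), self.var0.copy())


@dataclass
class NormalPosterior:
    """Dense Gaussian posterior over a (rows x K) coefficient matrix."""

    mean: np.ndarray
    var: np.ndarray

    @property
    def e(self):
        return self.mean

    @property
    def e2(self):
        return self.mean ** 2 + self.var

    def copy(self):
        return NormalPosterior(self.mean.copy(), self.var.copy())


class ModelState:
    """All variational posteriors of a model, keyed by view/group name.

    Attributes
    ----------
    w : dict view -> SpikeSlabPosterior (D_m x K)
    z : dict group -> SpikeSlabPosterior or NormalPosterior (N_g x K)
    alpha_w : dict view -> GammaPosterior (K,)
    alpha_z : dict group -> GammaPosterior (K,) or None (ARD on factors off)
    theta_w : dict view -> BetaPosterior (K,)
    theta_z : dict group -> BetaPosterior (K,) or None (spike on factors off)
    tau : dict (group, view) -> GammaPosterior (D_m,), gaussian views only
    zeta : dict (group, view) -> ndarray (N_g, D_m), non-gaussian views only
    """

    def __init__(self, w, z, alpha_w, alpha_z, theta_w, theta_z, tau, zeta, K):
        self.w = w
        self.z = z
        self.alpha_w = alpha_w
        self.alpha_z = alpha_z
        self.theta_w = theta_w
        self.theta_z = theta_z
        self.tau = tau
        self.zeta = zeta
        self.K = K

    def copy(self):
        cp = lambda d: None if d is None else {k: v.copy() for k, v in d.items()}
        return ModelState(cp(self.w), cp(self.z), cp(self.alpha_w), cp(self.alpha_z),
                          cp(self.theta_w), cp(self.theta_z), cp(self.tau),
                          {k: v.copy() for k, v in self.zeta.items()}, self.K)

    def select_factors(self, idx):
        """Return a state restricted (and reordered) to factor columns ``idx``."""
        idx = np.asarray(idx, dtype=int)
        st = self.copy()
        for v, post in st.w.items():
            st.w[v] = SpikeSlabPosterior(post.mean[:, idx], post.var[:, idx],
                                         post.prob[:, idx], post.var0[idx])
        for g, post in st.z.items():
            if isinstance(post, SpikeSlabPosterior):
                st.z[g] = SpikeSlabPosterior(post.mean[:, idx], post.var[:, idx],
                                             post.prob[:, idx], post.var0[idx])
            else:
                st.z[g] = NormalPosterior(post.mean[:, idx], post.var[:, idx])
        for d in (st.alpha_w, st.theta_w, st.alpha_z, st.theta_z):
            if d is None:
                continue
            for k, post in d.items():
                d[k] = type(post)(post.a[idx], post.b[idx])
        st.K = len(idx)
        return st


@dataclass
class TrainingTrace:
    """Per-iteration ELBO and active-factor history of a fit."""

    elbo: list = field(default_factory=list)
    active_factors: list = field(default_factory=list)
    mode: str = "vi"
    iterations_to_convergence: int = -1
    converged: bool = False
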