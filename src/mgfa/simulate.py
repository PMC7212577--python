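"""Draws datasets from the model's own generative process.

The simulator is the test bed for the whole package: factors with designed
on/off activity across groups and views, spike-and-slab weights, per-view
likelihoods and missing-at-random masks.  Per-group and per-view random
streams are derived from one root seed, so changing one view's feature
count never perturbs another view's draws.

Defaults describe a mid-sized single-cell style study: K=5 factors, G=3
groups of 500 samples, M=2 gaussian views of 1000 features, unit noise,
weight sparsity 0.5, and 10% missing entries.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .datasets import GroupSpec, MultiOmicsDataset, ViewSpec
from .likelihoods import softplus


@dataclass
class SimulationSpec:
    """Configuration of one simulated study.

    activity_z : (K, G) non-negative scales of factor values per group
        (0 switches a factor off in that group).
    activity_w : (K, M) non-negative scales of weights per view.
    sparsity_w : probability that an individual weight is non-zero
        (scalar or (K, M)).
    noise_var : per-view gaussian noise variance (ignored for non-gaussian
        views, where the link fixes the observation model).
    """

    n_factors: int = 5
    n_samples: tuple = (500, 500, 500)
    n_features: tuple = (1000, 1000)
    likelihoods: tuple = ("gaussian", "gaussian")
    activity_z: np.ndarray = None
    activity_w: np.ndarray = None
    sparsity_w: float = 0.5
    noise_var: tuple = None
    missing_fraction: float = 0.1
    seed: int = 0
    group_names: tuple = None
    view_names: tuple = None

    def __post_init__(self):
        G, M, K = len(self.n_samples), len(self.n_features), self.n_factors
        if K < 1 or G < 1 or M < 1:
            raise ValueError("all dimensions must be >= 1")
        if any(n < 1 for n in self.n_samples) or any(d < 1 for d in self.n_features):
            raise ValueError("all dimensions must be >= 1")
        if len(self.likelihoods) != M:
            raise ValueError("need one likelihood per view")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.activity_z is None:
            self.activity_z = np.ones((K, G))
        self.activity_z = np.asarray(self.activity_z, dtype=float)
        if self.activity_w is None:
            self.activity_w = np.ones((K, M))
        self.activity_w = np.asarray(self.activity_w, dtype=float)
        if self.activity_z.shape != (K, G) or self.activity_w.shape != (K, M):
            raise ValueError("activity matrices must be (K, G) and (K, M)")
        if np.any(self.activity_z < 0) or np.any(self.activity_w < 0):
            raise ValueError("activity scales must be >= 0")
        self.sparsity_w = np.broadcast_to(
            np.asarray(self.sparsity_w, dtype=float), (K, M)).copy()
        if np.any(self.sparsity_w < 0) or np.any(self.sparsity_w > 1):
            raise ValueError("sparsity_w must be in [0, 1]")
        if self.noise_var is None:
            self.noise_var = tuple(1.0 for _ in range(M))
        if len(self.noise_var) != M or any(s < 0 for s in self.noise_var):
            raise ValueError("need one non-negative noise variance per view")
        if self.group_names is None:
            self.group_names = tuple(f"group{g}" for g in range(G))
        if self.view_names is None:
            self.view_names = tuple(f"view{m}" for m in range(M))

    # ---- plain-text config round trip --------------------------------
    def to_config(self, path):
        cfg = configparser.ConfigParser()
        cfg["model"] = {
            "n_factors": str(self.n_factors),
            "missing_fraction": str(float(self.missing_fraction)),
            "seed": str(self.seed),
        }
        for g, (name, n) in enumerate(zip(self.group_names, self.n_samples)):
            cfg[f"group:{name}"] = {
                "n_samples": str(n),
                "activity": " ".join(str(float(x)) for x in self.activity_z[:, g]),
            }
        for m, name in enumerate(self.view_names):
            cfg[f"view:{name}"] = {
                "n_features": str(self.n_features[m]),
                "likelihood": self.likelihoods[m],
                "activity": " ".join(str(float(x)) for x in self.activity_w[:, m]),
                "sparsity": " ".join(str(float(x)) for x in self.sparsity_w[:, m]),
                "noise_var": str(float(self.noise_var[m])),
            }
        with open(path, "w") as fh:
            cfg.write(fh)

    @classmethod
    def from_config(cls, path):
        cfg = configparser.ConfigParser()
        if not cfg.read(path):
            raise FileNotFoundError(path)
        groups = [s for s in cfg.sections() if s.startswith("group:")]
        views = [s for s in cfg.sections() if s.startswith("view:")]
        K = int(cfg["model"]["n_factors"])
        az = np.column_stack([
            np.fromstring(cfg[s]["activity"], sep=" ") for s in groups]) if groups else None
        aw = np.column_stack([
            np.fromstring(cfg[s]["activity"], sep=" ") for s in views])
        sw = np.column_stack([
            np.fromstring(cfg[s]["sparsity"], sep=" ") for s in views])
        return cls(
            n_factors=K,
            n_samples=tuple(int(cfg[s]["n_samples"]) for s in groups),
            n_features=tuple(int(cfg[s]["n_features"]) for s in views),
            likelihoods=tuple(cfg[s]["likelihood"] for s in views),
            activity_z=az,
            activity_w=aw,
            sparsity_w=sw,
            noise_var=tuple(float(cfg[s]["noise_var"]) for s in views),
            missing_fraction=float(cfg["model"]["missing_fraction"]),
            seed=int(cfg["model"]["seed"]),
            group_names=tuple(s.split(":", 1)[1] for s in groups),
            view_names=tuple(s.split(":", 1)[1] for s in views),
        )


@dataclass
class GroundTruth:
    """True latent quantities behind a simulated dataset."""

    z: dict  # group -> (N_g, K)
    w: dict  # view -> (D_m, K)
    activity_z: np.ndarray  # (K, G)
    activity_w: np.ndarray  # (K, M)
    noise_var: tuple
    spec: SimulationSpec = None


def simulate(spec: SimulationSpec):
    """Draw ``(dataset, truth)`` from the generative model.

    Factor values are N(0, 1) scaled per (factor, group); weights are
    Bernoulli(sparsity) x N(0, 1) scaled per (factor, view).  Gaussian
    blocks add N(0, noise_var) noise; bernoulli blocks threshold a logistic
    link, poisson blocks draw counts at a softplus rate.  A
    ``missing_fraction`` of entries is masked uniformly at random.
    """
    G, M, K = len(spec.n_samples), len(spec.n_features), spec.n_factors
    for m in range(M):
        if (spec.likelihoods[m] == "gaussian" and spec.noise_var[m] == 0
                and np.all(spec.activity_w[:, m] == 0)):
            raise ValueError(
                f"view {spec.view_names[m]!r}: zero activity with zero gaussian "
                "noise gives a degenerate constant block"
            )
    root = np.random.SeedSequence(spec.seed)
    # fixed spawn layout: G factor streams, M weight streams, G*M noise, G*M mask
    children = root.spawn(G + M + 2 * G * M)
    z_rngs = [np.random.default_rng(children[g]) for g in range(G)]
    w_rngs = [np.random.default_rng(children[G + m]) for m in range(M)]
    e_rngs = [np.random.default_rng(children[G + M + i]) for i in range(G * M)]
    m_rngs = [np.random.default_rng(children[G + M + G * M + i]) for i in range(G * M)]

    z_true = {}
    for g, name in enumerate(spec.group_names):
        z_true[name] = z_rngs[g].standard_normal((spec.n_samples[g], K)) * spec.activity_z[:, g]
    w_true = {}
    for m, name in enumerate(spec.view_names):
        raw = w_rngs[m].standard_normal((spec.n_features[m], K))
        on = w_rngs[m].random((spec.n_features[m], K)) < spec.sparsity_w[:, m]
        w_true[name] = raw * on * spec.activity_w[:, m]

    views = [
        ViewSpec(name, spec.likelihoods[m],
                 [f"{name}_f{j}" for j in range(spec.n_features[m])])
        for m, name in enumerate(spec.view_names)
    ]
    groups = [
        GroupSpec(name, [f"{name}_s{i}" for i in range(spec.n_samples[g])])
        for g, name in enumerate(spec.group_names)
    ]
    y, mask = {}, {}
    for g, gname in enumerate(spec.group_names):
        for m, vname in enumerate(spec.view_names):
            i = g * M + m
            x = z_true[gname] @ w_true[vname].T
            if spec.likelihoods[m] == "gaussian":
                block = x + e_rngs[i].standard_normal(x.shape) * np.sqrt(spec.noise_var[m])
            elif spec.likelihoods[m] == "bernoulli":
                block = (e_rngs[i].random(x.shape) < expit(x)).astype(float)
            else:
                block = e_rngs[i].poisson(softplus(x)).astype(float)
            obs = m_rngs[i].random(x.shape) >= spec.missing_fraction
            y[(gname, vname)] = block
            mask[(gname, vname)] = obs
    ds = MultiOmicsDataset(views, groups, y, mask)
    truth = GroundTruth(z=z_true, w=w_true, activity_z=spec.activity_z.copy(),
                        activity_w=spec.activity_w.copy(),
                        noise_var=tuple(spec.noise_var), spec=spec)
    return ds, truth


def match_factors(z_true: dict, z_est: dict, group_order):
    """Greedy one-to-one matching of estimated to true factors.

    Factor columns are compared by absolute Pearson correlation of factor
    values over all samples (groups concatenated in the given order).
    Returns ``(pairs, corr)`` where pairs is a list of (true_k, est_k).
    """
    zt = np.vstack([z_true[g] for g in group_order])
    ze = np.vstack([z_est[g] for g in group_order])
    Kt, Ke = zt.shape[1], ze.shape[1]
    C = np.zeros((Kt, Ke))
    for i in range(Kt):
        for j in range(Ke):
            st, se = zt[:, i].std(), ze[:, j].std()
            if st > 0 and se > 0:
                C[i, j] = abs(np.corrcoef(zt[:, i], ze[:, j])[0, 1])
    pairs = []
    used_t, used_e = set(), set()
    flat = np.argsort(-C, axis=None)
    for idx in flat:
        i, j = divmod(idx, Ke)
        if i in used_t or j in used_e:
            continue
        pairs.append((i, j))
        used_t.add(i)
        used_e.add(j)
        if len(pairs) == min(Kt, Ke):
            break
    return pairs, C


def activity_recovery_score(truth: GroundTruth, r2, z_est: dict, threshold: float = 0.01):
    """Fraction of activity cells recovered by the fitted model.

    The true pattern is the binarized activity design: factor k active in
    group g (scale > 0) and in view m.  The inferred pattern binarizes
    variance explained at ``threshold`` (per group: maximum over views; per
    view: maximum over groups) after greedily matching estimated to true
    factors by absolute factor-value correlation.  True factors left
    unmatched (fewer estimated than true factors) count as fully missed.
    Returns a value in [0, 1].
    """
    group_order = list(truth.z.keys())
    Kt = truth.activity_z.shape[0]
    G = truth.activity_z.shape[1]
    M = truth.activity_w.shape[1]
    true_g = truth.activity_z > 0
    true_v = truth.activity_w > 0
    pairs, _ = match_factors(truth.z, z_est, group_order)
    est = {i: j for i, j in pairs}
    r2_arr = np.nan_to_num(np.asarray(r2.r2), nan=0.0)  # (K_est, G, M)
    hits = 0
    for i in range(Kt):
        if i in est:
            j = est[i]
            inf_g = r2_arr[j].max(axis=1) >= threshold  # (G,)
            inf_v = r2_arr[j].max(axis=0) >= threshold  # (M,)
            hits += int(np.sum(inf_g == true_g[i])) + int(np.sum(inf_v == true_v[i]))
    return hits / (Kt * (G + M))
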