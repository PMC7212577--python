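"""Post-training analytics: variance decomposition, weights, enrichment, imputation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .inference import _block_targets
from .likelihoods import softplus


@dataclass
class VarianceExplained:
    """Coefficient of determination per (factor, group, view).

    r2 : (K, G, M), fraction scale, clipped below at zero for reporting.
    r2_raw : same without clipping (a factor can have negative raw R² in a
        block where its rank-1 reconstruction adds more variance than it
        removes; factors are not orthogonal, so per-factor values are not
        additive either).
    total : (G, M) using the full K-factor reconstruction.
    NaN marks blocks with no observed variation (undefined R²).
    """

    r2: np.ndarray
    r2_raw: np.ndarray
    total: np.ndarray
    groups: list
    views: list
    factors: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, f in enumerate(self.factors):
            for g, gn in enumerate(self.groups):
                for m, vn in enumerate(self.views):
                    rows.append((f, gn, vn, self.r2[k, g, m]))
        return pd.DataFrame(rows, columns=["factor", "group", "view", "r2"])

    def totals_frame(self) -> pd.DataFrame:
        rows = [
            (gn, vn, self.total[g, m])
            for g, gn in enumerate(self.groups)
            for m, vn in enumerate(self.views)
        ]
        return pd.DataFrame(rows, columns=["group", "view", "total_r2"])


def _r2_targets(state, ds, gname, vname):
    """Observed target on the model's gaussian working scale.

    Gaussian views: the (centered) data.  Non-gaussian views: the pseudo-data
    implied by the current local bounds, which live on the linear-predictor
    scale where the factorization is defined.
    """
    key = (gname, vname)
    if ds.view(vname).likelihood == "gaussian":
        return ds.y[key], ds.mask[key]
    _, x = _block_targets(state, ds, gname, vname)
    return x, ds.mask[key]


def variance_explained(state, ds) -> VarianceExplained:
    """R² of each factor's rank-1 reconstruction within every block.

    R²(k, g, m) = 1 - sum_obs (y - E[z_k] E[w_k]^T)² / sum_obs y², the
    conventional coefficient of determination of the factor-k reconstruction
    against the centered observations; the total per block uses all K
    factors jointly.
    """
    K = state.K
    G, M = len(ds.groups), len(ds.views)
    r2 = np.full((K, G, M), np.nan)
    total = np.full((G, M), np.nan)
    for g, gname in enumerate(ds.group_names):
        ez = state.z[gname].e
        for m, vname in enumerate(ds.view_names):
            y, mask = _r2_targets(state, ds, gname, vname)
            ew = state.w[vname].e
            ss_tot = float((y ** 2 * mask).sum())
            if ss_tot == 0.0:
                continue
            full = ez @ ew.T
            total[g, m] = 1.0 - float(((y - full) ** 2 * mask).sum()) / ss_tot
            for k in range(K):
                rec = np.outer(ez[:, k], ew[:, k])
                r2[k, g, m] = 1.0 - float(((y - rec) ** 2 * mask).sum()) / ss_tot
    return VarianceExplained(
        r2=np.where(np.isnan(r2), np.nan, np.clip(r2, 0.0, None)),
        r2_raw=r2,
        total=total,
        groups=list(ds.group_names),
        views=list(ds.view_names),
        factors=[f"factor{k + 1}" for k in range(K)],
    )


def top_weights(state, view, factor, n, scale=False):
    """Top-n features of one factor in one view, by absolute weight.

    Returns a list of ``(feature_name, signed_weight)`` sorted by |weight|
    descending; ties keep original feature order.  ``scale=True`` rescales
    to max |weight| = 1 for display.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if view not in state.w:
        raise KeyError(f"unknown view {view!r}")
    if not (0 <= factor < state.K):
        raise IndexError(f"factor index {factor} out of range (K={state.K})")
    w = state.w[view].e[:, factor]
    if scale:
        mx = np.abs(w).max()
        if mx > 0:
            w = w / mx
    order = np.argsort(-np.abs(w), kind="stable")[: min(n, len(w))]
    names = _feature_names(state, view, len(w))
    return [(names[i], float(w[i])) for i in order]


def _feature_names(state, view, d):
    names = getattr(state, "feature_names", {}).get(view) if hasattr(state, "feature_names") else None
    return names if names is not None else [f"{view}_f{j}" for j in range(d)]


def enrichment_test(weights, feature_names, gene_sets, use_absolute=True, fdr=0.01):
    """Competitive gene-set test on one factor's weights.

    For every set, a Welch (unequal-variance) two-sample t-test contrasts
    the weights of the foreground features (set members present in the
    view) against all remaining features; by default absolute weights are
    compared, so enrichment means larger magnitude regardless of direction.
    P-values are Benjamini–Hochberg adjusted across the sets of this factor;
    the significance flag applies ``fdr`` (default 1%) to the adjusted
    values.  Sets with fewer than two matched features are skipped.
    """
    w = np.abs(weights) if use_absolute else np.asarray(weights, dtype=float)
    index = {f: i for i, f in enumerate(feature_names)}
    rows = []
    for set_name, members in gene_sets.items():
        idx = [index[f] for f in members if f in index]
        if len(idx) < 2:
            warnings.warn(f"gene set {set_name!r}: fewer than 2 matched features; skipped")
            continue
        fg = w[idx]
        bg = np.delete(w, idx)
        t, p = stats.ttest_ind(fg, bg, equal_var=False)
        rows.append((set_name, len(idx), float(t), float(p)))
    if not rows:
        return pd.DataFrame(columns=["set", "size", "t", "p", "p_adj", "significant"])
    df = pd.DataFrame(rows, columns=["set", "size", "t", "p"])
    _, p_adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["p_adj"] = p_adj
    df["significant"] = df["p_adj"] < fdr
    return df


def enrichment(state, ds, view, factor, gene_sets, use_absolute=True, fdr=0.01):
    """Gene-set enrichment of one factor in one view (see :func:`enrichment_test`)."""
    if view not in state.w:
        raise KeyError(f"unknown view {view!r}")
    if not (0 <= factor < state.K):
        raise IndexError(f"factor index {factor} out of range (K={state.K})")
    weights = state.w[view].e[:, factor]
    names = ds.view(view).feature_names
    return enrichment_test(weights, names, gene_sets, use_absolute=use_absolute, fdr=fdr)


def read_gmt(path):
    """Read gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def reconstruct(state, ds):
    """Model reconstruction of every block, defined at masked positions too.

    Gaussian views return E[Z] E[W]^T plus the group-wise feature means that
    were removed by centering; bernoulli views return success probabilities
    (logistic link); poisson views return rates (softplus link).  Values at
    unobserved positions are the model's imputations.
    """
    out = {}
    for gname in ds.group_names:
        ez = state.z[gname].e
        for vname in ds.view_names:
            key = (gname, vname)
            x = ez @ state.w[vname].e.T
            likelihood = ds.view(vname).likelihood
            if likelihood == "gaussian":
                out[key] = x + ds.feature_means[key]
            elif likelihood == "bernoulli":
                out[key] = expit(x)
            else:
                out[key] = softplus(x)
    return out


def export_factors(state, ds, path=None) -> pd.DataFrame:
    """Factor values as a tidy table (sample, group, factor1..K), optionally TSV.

    This is the hand-off point to external embedding or clustering tools.
    """
    rows = []
    for g in ds.groups:
        ez = state.z[g.name].e
        for i, s in enumerate(g.sample_names):
            rows.append([s, g.name] + list(ez[i]))
    cols = ["sample", "group"] + [f"factor{k + 1}" for k in range(state.K)]
    df = pd.DataFrame(rows, columns=cols)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
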