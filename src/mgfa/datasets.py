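"""Multi-group, multi-view dataset container and preprocessing.

A dataset holds one numeric matrix per (sample group, feature view) pair,
oriented samples x features, together with a boolean mask of observed
entries.  Views are disjoint feature sets (e.g. one omic layer each) and may
declare different observation models; groups are disjoint sample sets (e.g.
batches or developmental stages).  Missing entries are first-class: every
operation restricts itself to observed positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LIKELIHOODS = ("gaussian", "bernoulli", "poisson")


@dataclass
class ViewSpec:
    """One feature view: a named, typed set of features.

    Parameters
    ----------
    name : str
        View label, unique within a dataset.
    likelihood : str
        Observation model, one of ``gaussian``, ``bernoulli``, ``poisson``.
    feature_names : list of str
        Feature labels, unique within the view and disjoint from every
        other view's features.
    """

    name: str
    likelihood: str
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.likelihood not in LIKELIHOODS:
            raise ValueError(
                f"unknown likelihood {self.likelihood!r}; expected one of {LIKELIHOODS}"
            )
        if len(self.feature_names) < 1:
            raise ValueError(f"view {self.name!r} needs at least one feature")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"duplicate feature names in view {self.name!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class GroupSpec:
    """One sample group: a named set of samples."""

    name: str
    sample_names: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.sample_names) < 1:
            raise ValueError(f"group {self.name!r} needs at least one sample")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValueError(f"duplicate sample names in group {self.name!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)


class MultiOmicsDataset:
    """Blocks ``Y[g, m]`` of shape ``(N_g, D_m)`` with observation masks.

    Attributes
    ----------
    views, groups : lists of ViewSpec / GroupSpec (fixed order).
    y : dict ``(group, view) -> ndarray`` — data, zeros at unobserved slots.
    mask : dict ``(group, view) -> bool ndarray`` — True where observed.
    centered : dict ``view -> bool`` — per-view centering flag.
    feature_means : dict ``(group, view) -> ndarray`` — means subtracted by
        :meth:`center_per_group` (zeros before centering), re-added when
        reconstructing on the original scale.
    """

    def __init__(self, views, groups, y, mask):
        self.views = list(views)
        self.groups = list(groups)
        if len({v.name for v in self.views}) != len(self.views):
            raise ValueError("duplicate view names")
        if len({g.name for g in self.groups}) != len(self.groups):
            raise ValueError("duplicate group names")
        all_feats = [f for v in self.views for f in v.feature_names]
        if len(set(all_feats)) != len(all_feats):
            raise ValueError("views must have pairwise disjoint feature sets")
        all_samps = [s for g in self.groups for s in g.sample_names]
        if len(set(all_samps)) != len(all_samps):
            raise ValueError("groups must be pairwise disjoint sample sets")
        self.y = {}
        self.mask = {}
        for g in self.groups:
            for v in self.views:
                key = (g.name, v.name)
                block = np.asarray(y[key], dtype=float)
                m = np.asarray(mask[key], dtype=bool)
                if block.shape != (g.n_samples, v.n_features):
                    raise ValueError(
                        f"block {key}: shape {block.shape} != "
                        f"({g.n_samples}, {v.n_features})"
                    )
                if m.shape != block.shape:
                    raise ValueError(f"block {key}: mask shape mismatch")
                block = np.where(m, block, 0.0)  # masked values never leak
                _check_support(block, m, v, key)
                self.y[key] = block
                self.mask[key] = m
        self.centered = {v.name: False for v in self.views}
        self.feature_means = {
            (g.name, v.name): np.zeros(v.n_features)
            for g in self.groups
            for v in self.views
        }

    # -- introspection -------------------------------------------------
    @property
    def view_names(self):
        return [v.name for v in self.views]

    @property
    def group_names(self):
        return [g.name for g in self.groups]

    def view(self, name) -> ViewSpec:
        return self.views[self.view_names.index(name)]

    def group(self, name) -> GroupSpec:
        return self.groups[self.group_names.index(name)]

    @property
    def n_samples_total(self) -> int:
        return sum(g.n_samples for g in self.groups)

    def copy(self) -> "MultiOmicsDataset":
        ds = MultiOmicsDataset.__new__(MultiOmicsDataset)
        ds.views = [ViewSpec(v.name, v.likelihood, list(v.feature_names)) for v in self.views]
        ds.groups = [GroupSpec(g.name, list(g.sample_names)) for g in self.groups]
        ds.y = {k: a.copy() for k, a in self.y.items()}
        ds.mask = {k: a.copy() for k, a in self.mask.items()}
        ds.centered = dict(self.centered)
        ds.feature_means = {k: a.copy() for k, a in self.feature_means.items()}
        return ds

    # -- long-format round trip ---------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Export observed entries as a (sample, group, feature, view, value) table."""
        rows = []
        for g in self.groups:
            for v in self.views:
                key = (g.name, v.name)
                obs = np.nonzero(self.mask[key])
                for n, d in zip(*obs):
                    rows.append(
                        (g.sample_names[n], g.name, v.feature_names[d], v.name,
                         self.y[key][n, d])
                    )
        return pd.DataFrame(rows, columns=["sample", "group", "feature", "view", "value"])

    # -- preprocessing -------------------------------------------------
    def center_per_group(self) -> "MultiOmicsDataset":
        """Subtract each feature's observed mean within every group (gaussian views).

        Intercept (group-offset) effects are removed so that factors capture
        shared axes of variation rather than mean shifts between groups.
        Bernoulli and Poisson views are left untouched: centering would break
        their support.  Idempotent; a feature with no observed entry in a
        group is left as-is.
        """
        ds = self.copy()
        for v in ds.views:
            if v.likelihood != "gaussian":
                continue
            if ds.centered[v.name]:
                warnings.warn(f"view {v.name!r} already centered; no-op")
                continue
            for g in ds.groups:
                key = (g.name, v.name)
                m = ds.mask[key]
                counts = m.sum(axis=0)
                sums = ds.y[key].sum(axis=0)
                means = np.divide(sums, counts, out=np.zeros_like(sums),
                                  where=counts > 0)
                ds.y[key] = np.where(m, ds.y[key] - means, 0.0)
                ds.feature_means[key] = ds.feature_means[key] + means
            ds.centered[v.name] = True
        return ds

    def select_highly_variable(self, n_per_view) -> "MultiOmicsDataset":
        """Keep each view's top-n features by pooled variance.

        Variance is computed over observed entries pooled across groups after
        per-group mean removal (for gaussian views), so between-group offsets
        do not dominate the ranking.  Ties keep the earlier feature.
        """
        for v_name, n in n_per_view.items():
            if n <= 0:
                raise ValueError(f"n_per_view[{v_name!r}] must be positive, got {n}")
        keep = {}
        work = self if all(
            self.centered[v.name] for v in self.views if v.likelihood == "gaussian"
        ) else self.center_per_group()
        for v in self.views:
            if v.name not in n_per_view or n_per_view[v.name] >= v.n_features:
                keep[v.name] = np.arange(v.n_features)
                continue
            ssq = np.zeros(v.n_features)
            cnt = np.zeros(v.n_features)
            for g in self.groups:
                key = (g.name, v.name)
                ssq += (work.y[key] ** 2 * work.mask[key]).sum(axis=0)
                cnt += work.mask[key].sum(axis=0)
            var = np.divide(ssq, cnt, out=np.zeros_like(ssq), where=cnt > 0)
            # stable sort on -var keeps original order among ties
            order = np.argsort(-var, kind="stable")[: n_per_view[v.name]]
            keep[v.name] = np.sort(order)
        ds = MultiOmicsDataset.__new__(MultiOmicsDataset)
        ds.groups = [GroupSpec(g.name, list(g.sample_names)) for g in self.groups]
        ds.views = [
            ViewSpec(v.name, v.likelihood, [v.feature_names[i] for i in keep[v.name]])
            for v in self.views
        ]
        ds.y = {}
        ds.mask = {}
        ds.feature_means = {}
        for g in self.groups:
            for v in self.views:
                key = (g.name, v.name)
                idx = keep[v.name]
                ds.y[key] = self.y[key][:, idx].copy()
                ds.mask[key] = self.mask[key][:, idx].copy()
                ds.feature_means[key] = self.feature_means[key][idx].copy()
        ds.centered = dict(self.centered)
        return ds


def _check_support(block, mask, view, key):
    obs = block[mask]
    if view.likelihood == "bernoulli":
        if not np.all((obs == 0) | (obs == 1)):
            raise ValueError(f"bernoulli block {key} has values outside {{0,1}}")
    elif view.likelihood == "poisson":
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise ValueError(f"poisson block {key} has negative or non-integer values")


def assemble_dataset(table, likelihoods=None) -> MultiOmicsDataset:
    """Build a dataset from a long-format table.

    Parameters
    ----------
    table : DataFrame with columns sample, group, feature, view, value.
        ``NaN`` values mark explicitly-listed unobserved entries; any
        (sample, feature) pair absent from the table is likewise unobserved.
    likelihoods : dict view -> str, optional
        Observation model per view (default gaussian).

    Row/column order follows first appearance in the table, so assembly is
    invariant to row shuffling only up to that canonical order; re-assembling
    an exported table reproduces the dataset exactly.
    """
    required = ["sample", "group", "feature", "view", "value"]
    if not all(c in table.columns for c in required):
        raise ValueError(f"table must have columns {required}")
    if len(table) == 0:
        raise ValueError("empty table")
    likelihoods = likelihoods or {}

    df = table[required].copy()
    dup = df.duplicated(subset=["sample", "group", "feature", "view"])
    if dup.any():
        k = df[dup].iloc[0]
        raise ValueError(
            f"duplicate key (sample={k['sample']!r}, group={k['group']!r}, "
            f"feature={k['feature']!r}, view={k['view']!r})"
        )
    fv = df[["feature", "view"]].drop_duplicates()
    bad_f = fv["feature"][fv["feature"].duplicated()]
    if len(bad_f):
        raise ValueError(f"feature {bad_f.iloc[0]!r} assigned to more than one view")
    sg = df[["sample", "group"]].drop_duplicates()
    bad_s = sg["sample"][sg["sample"].duplicated()]
    if len(bad_s):
        raise ValueError(f"sample {bad_s.iloc[0]!r} assigned to more than one group")

    view_order = list(dict.fromkeys(df["view"]))
    group_order = list(dict.fromkeys(df["group"]))
    views = []
    for v in view_order:
        feats = list(dict.fromkeys(df.loc[df["view"] == v, "feature"]))
        views.append(ViewSpec(v, likelihoods.get(v, "gaussian"), feats))
    groups = []
    for gname in group_order:
        samps = list(dict.fromkeys(df.loc[df["group"] == gname, "sample"]))
        groups.append(GroupSpec(gname, samps))

    y, mask = {}, {}
    for g in groups:
        srow = {s: i for i, s in enumerate(g.sample_names)}
        sub_g = df[df["group"] == g.name]
        for v in views:
            key = (g.name, v.name)
            fcol = {f: j for j, f in enumerate(v.feature_names)}
            block = np.zeros((g.n_samples, v.n_features))
            m = np.zeros((g.n_samples, v.n_features), dtype=bool)
            sub = sub_g[sub_g["view"] == v.name]
            rows = sub["sample"].map(srow).to_numpy()
            cols = sub["feature"].map(fcol).to_numpy()
            vals = sub["value"].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            block[rows[ok], cols[ok]] = vals[ok]
            m[rows[ok], cols[ok]] = True
            y[key] = block
            mask[key] = m
    return MultiOmicsDataset(views, groups, y, mask)


def read_long_table(path, likelihoods=None) -> MultiOmicsDataset:
    """Read a delimited long-format file (TSV/CSV; 'NA'/empty = unobserved)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True,
                     dtype={"sample": str, "group": str, "feature": str, "view": str})
    return assemble_dataset(df, likelihoods=likelihoods)


def read_matrix_blocks(blocks, views=None, groups=None) -> MultiOmicsDataset:
    """Assemble a dataset from per-(group, view) matrix files.

    ``blocks`` maps ``(group, view)`` to either a dense delimited file
    (rows = samples, columns = features, header row and index column of
    names, NaN = unobserved) or a Matrix Market ``.mtx`` file accompanied by
    ``<stem>.rownames.txt`` / ``<stem>.colnames.txt``.
    """
    from scipy.io import mmread

    y, mask = {}, {}
    view_feats, group_samps = {}, {}
    likelihoods = {v.name: v.likelihood for v in views} if views else {}
    for (gname, vname), path in blocks.items():
        path = str(path)
        if path.endswith(".mtx"):
            mat = np.asarray(mmread(path).todense(), dtype=float)
            stem = path[: -len(".mtx")]
            with open(stem + ".rownames.txt") as fh:
                rown = [l.strip() for l in fh if l.strip()]
            with open(stem + ".colnames.txt") as fh:
                coln = [l.strip() for l in fh if l.strip()]
            m = np.ones(mat.shape, dtype=bool)
        else:
            df = pd.read_csv(path, sep=None, engine="python", index_col=0)
            mat = df.to_numpy(dtype=float)
            rown = [str(s) for s in df.index]
            coln = [str(c) for c in df.columns]
            m = np.isfinite(mat)
            mat = np.where(m, mat, 0.0)
        y[(gname, vname)] = mat
        mask[(gname, vname)] = m
        if vname in view_feats and view_feats[vname] != coln:
            raise ValueError(f"inconsistent feature names for view {vname!r}")
        view_feats[vname] = coln
        if gname in group_samps and group_samps[gname] != rown:
            raise ValueError(f"inconsistent sample names for group {gname!r}")
        group_samps[gname] = rown
    vspecs = [ViewSpec(v, likelihoods.get(v, "gaussian"), f) for v, f in view_feats.items()]
    gspecs = [GroupSpec(g, s) for g, s in group_samps.items()]
    return MultiOmicsDataset(vspecs, gspecs, y, mask)


def binomial_rate_and_mvalue(successes, trials, min_trials, eps=1e-3):
    """Binomial-rate M-value for coverage-based assays (methylation, accessibility).

    The per-feature rate is the binomial MLE successes/trials; entries with
    fewer than ``min_trials`` reads are returned as missing (NaN).  Rates are
    clamped to ``[eps, 1-eps]`` before the logit-like transform
    ``M = log2(rate / (1 - rate))`` so that fully (un)methylated features map
    to finite values.

    Accepts scalars or arrays; returns float or ndarray with NaN for
    low-coverage entries.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if min_trials < 1:
        raise ValueError("min_trials must be >= 1")
    if np.any(s < 0) or np.any(t < 0) or np.any(s > t):
        raise ValueError("need 0 <= successes <= trials")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.clip(np.divide(s, t, out=np.zeros_like(s), where=t > 0), eps, 1 - eps)
        m = np.log2(rate / (1.0 - rate))
    m = np.where(t >= min_trials, m, np.nan)
    if np.isscalar(successes) or np.ndim(successes) == 0:
        return float(m)
    return m
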