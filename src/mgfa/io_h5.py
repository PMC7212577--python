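"""Versioned HDF5 model container.

Layout (all names stored, fixed little-endian float64/int64 on every
platform):

    /format_version                 attribute, "major.minor"
    /dims/{views,groups}            names, likelihoods, feature/sample names
    /expectations/W/<view>          mean, var, prob, var0 (slab parameters)
    /expectations/Z/<group>         mean, var [, prob, var0]
    /posteriors/alpha_w/<view>      a, b        (same for alpha_z, theta_w,
                                    theta_z, tau/<group>/<view>)
    /zeta/<group>/<view>            local bound parameters (non-gaussian)
    /model_options                  JSON of TrainingOptions
    /training_stats                 elbo, active_factors, mode, iterations
    /variance_explained             r2, r2_raw, total
    /data/<group>/<view>            y, mask, feature_means (optional)

Loading a container without /data yields a model usable for factor/weight
queries; recomputing variance explained then requires the original dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .datasets import GroupSpec, MultiOmicsDataset, ViewSpec
from .downstream import VarianceExplained
from .model import (
    BetaPosterior,
    GammaPosterior,
    ModelState,
    NormalPosterior,
    PriorHyperparameters,
    SpikeSlabPosterior,
    TrainingOptions,
    TrainingTrace,
)

FORMAT_VERSION = "1.0"

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(grp, name, values):
    grp.create_dataset(name, data=np.array([str(v) for v in values], dtype=object),
                       dtype=_STR)


def _read_strings(grp, name):
    return [s.decode() if isinstance(s, bytes) else str(s) for s in grp[name][()]]


def _arr(x):
    return np.asarray(x, dtype="<f8")


def save_model(path, state: ModelState, trace: TrainingTrace, r2: VarianceExplained,
               opts: TrainingOptions, ds: MultiOmicsDataset = None):
    """Write a trained model (and optionally its dataset) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_factors"] = int(state.K)
        dims = f.create_group("dims")
        if ds is not None:
            _write_strings(dims, "views", ds.view_names)
            _write_strings(dims, "groups", ds.group_names)
            _write_strings(dims, "likelihoods", [v.likelihood for v in ds.views])
            for v in ds.views:
                _write_strings(dims, f"features_{v.name}", v.feature_names)
            for g in ds.groups:
                _write_strings(dims, f"samples_{g.name}", g.sample_names)
        else:
            _write_strings(dims, "views", list(state.w.keys()))
            _write_strings(dims, "groups", list(state.z.keys()))

        ew = f.create_group("expectations/W")
        for v, post in state.w.items():
            grp = ew.create_group(v)
            grp["mean"] = _arr(post.mean)
            grp["var"] = _arr(post.var)
            grp["prob"] = _arr(post.prob)
            grp["var0"] = _arr(post.var0)
        ez = f.create_group("expectations/Z")
        for g, post in state.z.items():
            grp = ez.create_group(g)
            grp["mean"] = _arr(post.mean)
            grp["var"] = _arr(post.var)
            if isinstance(post, SpikeSlabPosterior):
                grp["prob"] = _arr(post.prob)
                grp["var0"] = _arr(post.var0)

        post_grp = f.create_group("posteriors")
        for name, coll in (("alpha_w", state.alpha_w), ("alpha_z", state.alpha_z),
                           ("theta_w", state.theta_w), ("theta_z", state.theta_z)):
            if coll is None:
                continue
            grp = post_grp.create_group(name)
            for key, p in coll.items():
                sub = grp.create_group(key)
                sub["a"] = _arr(p.a)
                sub["b"] = _arr(p.b)
        tau_grp = post_grp.create_group("tau")
        for (g, v), p in state.tau.items():
            sub = tau_grp.create_group(f"{g}/{v}")
            sub["a"] = _arr(p.a)
            sub["b"] = _arr(p.b)
        zeta_grp = f.create_group("zeta")
        for (g, v), z in state.zeta.items():
            zeta_grp[f"{g}/{v}"] = _arr(z)

        opt_d = asdict(opts)
        f["model_options"] = json.dumps(opt_d)

        ts = f.create_group("training_stats")
        ts["elbo"] = _arr(trace.elbo)
        ts["active_factors"] = np.asarray(trace.active_factors, dtype="<i8")
        ts.attrs["mode"] = trace.mode
        ts.attrs["iterations_to_convergence"] = int(trace.iterations_to_convergence)
        ts.attrs["converged"] = bool(trace.converged)

        if r2 is not None:
            vg = f.create_group("variance_explained")
            vg["r2"] = _arr(r2.r2)
            vg["r2_raw"] = _arr(r2.r2_raw)
            vg["total"] = _arr(r2.total)
            _write_strings(vg, "factors", r2.factors)

        if ds is not None:
            data = f.create_group("data")
            for g in ds.group_names:
                for v in ds.view_names:
                    key = (g, v)
                    sub = data.create_group(f"{g}/{v}")
                    sub["y"] = _arr(ds.y[key])
                    sub["mask"] = ds.mask[key].astype("<i1")
                    sub["feature_means"] = _arr(ds.feature_means[key])
                    sub.attrs["centered"] = bool(ds.centered[v])


def load_model(path):
    """Load a container; returns ``(state, trace, r2, opts, ds_or_None)``."""
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"cannot read model container {path}: {e}") from None
    with f:
        version = f.attrs.get("format_version")
        if version is None:
            raise ValueError("not a model container: missing format_version")
        major = str(version).split(".")[0]
        if major != FORMAT_VERSION.split(".")[0]:
            raise ValueError(
                f"unsupported container version {version} "
                f"(supported major: {FORMAT_VERSION.split('.')[0]})"
            )
        for required in ("expectations", "expectations/W", "expectations/Z"):
            if required not in f:
                raise ValueError(f"invalid container: missing /{required}")
        K = int(f.attrs["n_factors"])

        w = {}
        for v, grp in f["expectations/W"].items():
            w[v] = SpikeSlabPosterior(grp["mean"][()], grp["var"][()],
                                      grp["prob"][()], grp["var0"][()])
        z = {}
        for g, grp in f["expectations/Z"].items():
            if "prob" in grp:
                z[g] = SpikeSlabPosterior(grp["mean"][()], grp["var"][()],
                                          grp["prob"][()], grp["var0"][()])
            else:
                z[g] = NormalPosterior(grp["mean"][()], grp["var"][()])

        def read_coll(name, cls):
            if f"posteriors/{name}" not in f:
                return None
            return {k: cls(sub["a"][()], sub["b"][()])
                    for k, sub in f[f"posteriors/{name}"].items()}

        alpha_w = read_coll("alpha_w", GammaPosterior)
        alpha_z = read_coll("alpha_z", GammaPosterior)
        theta_w = read_coll("theta_w", BetaPosterior)
        theta_z = read_coll("theta_z", BetaPosterior)
        tau = {}
        if "posteriors/tau" in f:
            for g, ggrp in f["posteriors/tau"].items():
                for v, sub in ggrp.items():
                    tau[(g, v)] = GammaPosterior(sub["a"][()], sub["b"][()])
        zeta = {}
        if "zeta" in f:
            for g, ggrp in f["zeta"].items():
                for v, dset in ggrp.items():
                    zeta[(g, v)] = dset[()]
        state = ModelState(w, z, alpha_w, alpha_z, theta_w, theta_z, tau, zeta, K)

        opt_d = json.loads(f["model_options"][()])
        opt_d["priors"] = PriorHyperparameters(**opt_d["priors"])
        opts = TrainingOptions(**opt_d)

        ts = f["training_stats"]
        trace = TrainingTrace(
            elbo=list(ts["elbo"][()]),
            active_factors=list(ts["active_factors"][()]),
            mode=str(ts.attrs["mode"]),
            iterations_to_convergence=int(ts.attrs["iterations_to_convergence"]),
            converged=bool(ts.attrs["converged"]),
        )

        r2 = None
        if "variance_explained" in f:
            vg = f["variance_explained"]
            groups = _read_strings(f["dims"], "groups")
            views = _read_strings(f["dims"], "views")
            r2 = VarianceExplained(
                r2=vg["r2"][()], r2_raw=vg["r2_raw"][()], total=vg["total"][()],
                groups=groups, views=views, factors=_read_strings(vg, "factors"),
            )

        ds = None
        if "data" in f:
            views = _read_strings(f["dims"], "views")
            groups = _read_strings(f["dims"], "groups")
            liks = _read_strings(f["dims"], "likelihoods")
            vspecs = [
                ViewSpec(v, liks[i], _read_strings(f["dims"], f"features_{v}"))
                for i, v in enumerate(views)
            ]
            gspecs = [
                GroupSpec(g, _read_strings(f["dims"], f"samples_{g}"))
                for g in groups
            ]
            y, mask = {}, {}
            means, centered = {}, {}
            for g in groups:
                for v in views:
                    sub = f[f"data/{g}/{v}"]
                    y[(g, v)] = sub["y"][()]
                    mask[(g, v)] = sub["mask"][()].astype(bool)
                    means[(g, v)] = sub["feature_means"][()]
                    centered[v] = bool(sub.attrs["centered"])
            ds = MultiOmicsDataset(vspecs, gspecs, y, mask)
            ds.feature_means = means
            ds.centered = centered
    return state, trace, r2, opts, ds
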