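import numpy as np
import pytest
from scipy import stats

import mgfa
from mgfa import inference
from mgfa.datasets import GroupSpec, MultiOmicsDataset, ViewSpec
from mgfa.model import TrainingOptions
from conftest import quick_opts


class TestInitialize:
    def test_rank_one_scores_collinear_with_truth(self):
        spec = mgfa.SimulationSpec(n_factors=1, n_samples=(30,), n_features=(12,),
                                   likelihoods=("gaussian",), noise_var=(0.0,),
                                   missing_fraction=0.0, seed=6)
        ds, truth = mgfa.simulate(spec)
        ds = ds.center_per_group()
        state = mgfa.initialize(ds, quick_opts(n_factors=1))
        r = np.corrcoef(truth.z["group0"][:, 0], state.z["group0"].mean[:, 0])[0, 1]
        assert abs(r) > 0.9999

    def test_deterministic(self, small_gaussian):
        ds, _ = small_gaussian
        s1 = mgfa.initialize(ds, quick_opts())
        s2 = mgfa.initialize(ds, quick_opts())
        for g in ds.group_names:
            np.testing.assert_array_equal(s1.z[g].mean, s2.z[g].mean)
        for v in ds.view_names:
            np.testing.assert_array_equal(s1.w[v].mean, s2.w[v].mean)

    def test_all_zero_data_gives_zero_factors(self):
        view = ViewSpec("v", "gaussian", ["f1", "f2"])
        group = GroupSpec("g", ["s1", "s2", "s3"])
        ds = MultiOmicsDataset([view], [group], {("g", "v"): np.zeros((3, 2))},
                               {("g", "v"): np.ones((3, 2), bool)})
        ds.centered["v"] = True
        state = mgfa.initialize(ds, quick_opts(n_factors=2))
        np.testing.assert_array_equal(state.z["g"].mean, 0.0)

    def test_excess_factors_reduced_with_warning(self, small_gaussian):
        ds, _ = small_gaussian
        with pytest.warns(UserWarning, match="feasible rank"):
            state = mgfa.initialize(ds, quick_opts(n_factors=500))
        assert state.K == min(ds.n_samples_total, sum(v.n_features for v in ds.views))


class TestViIteration:
    def test_fixed_point(self, small_gaussian):
        ds, _ = small_gaussian
        opts = quick_opts(max_iterations=200, convergence_tol=1e-12, drop_inactive=False)
        state, _ = mgfa.fit(ds, opts)
        e0 = mgfa.compute_elbo(state, ds, opts)
        mgfa.vi_iteration(state, ds, opts)
        e1 = mgfa.compute_elbo(state, ds, opts)
        assert abs(e1 - e0) <= 1e-6 * abs(e0)

    def test_perturbed_state_recovers_monotonically(self, small_gaussian):
        ds, _ = small_gaussian
        opts = quick_opts(max_iterations=100, drop_inactive=False)
        state, _ = mgfa.fit(ds, opts)
        e_conv = mgfa.compute_elbo(state, ds, opts)
        rng = np.random.default_rng(0)
        for v in ds.view_names:
            state.w[v].mean += 0.5 * rng.standard_normal(state.w[v].mean.shape)
        e_pert = mgfa.compute_elbo(state, ds, opts)
        assert e_pert < e_conv
        prev = e_pert
        for _ in range(5):
            mgfa.vi_iteration(state, ds, opts)
            e = mgfa.compute_elbo(state, ds, opts)
            assert e >= prev - 1e-8 * abs(prev)
            prev = e
        assert prev > e_pert

    def test_masked_entries_inert(self, mixed_likelihoods):
        ds1, _ = mixed_likelihoods
        ds2 = ds1.copy()
        rng = np.random.default_rng(1)
        for key in ds2.y:
            fuzz = 10 * rng.standard_normal(ds2.y[key].shape)
            if ds2.view(key[1]).likelihood == "bernoulli":
                fuzz = (fuzz > 0).astype(float)
            ds2.y[key] = np.where(ds2.mask[key], ds2.y[key], fuzz)
        opts = quick_opts(drop_inactive=False)
        s1 = mgfa.initialize(ds1, opts)
        s2 = mgfa.initialize(ds2, opts)
        for _ in range(3):
            mgfa.vi_iteration(s1, ds1, opts)
            mgfa.vi_iteration(s2, ds2, opts)
        for v in ds1.view_names:
            np.testing.assert_array_equal(s1.w[v].mean, s2.w[v].mean)
        assert mgfa.compute_elbo(s1, ds1, opts) == mgfa.compute_elbo(s2, ds2, opts)

    def test_nonfinite_input_aborts_with_diagnostic(self, small_gaussian):
        ds, _ = small_gaussian
        opts = quick_opts(drop_inactive=False)
        state = mgfa.initialize(ds, opts)
        key = (ds.group_names[0], ds.view_names[0])
        ds.y[key][0, 0] = np.inf
        with pytest.raises(RuntimeError, match="weights"):
            mgfa.vi_iteration(state, ds, opts)

    @pytest.mark.parametrize("seed,liks,ss", [
        (0, ("gaussian",), False),
        (1, ("gaussian", "bernoulli"), False),
        (2, ("poisson", "gaussian"), True),
        (3, ("bernoulli", "poisson"), True),
    ])
    def test_elbo_monotone(self, seed, liks, ss):
        rng = np.random.default_rng(seed)
        spec = mgfa.SimulationSpec(
            n_factors=int(rng.integers(1, 4)),
            n_samples=tuple(rng.integers(15, 40, size=rng.integers(1, 3))),
            n_features=tuple(rng.integers(8, 25, size=len(liks))),
            likelihoods=liks, noise_var=tuple(1.0 for _ in liks),
            missing_fraction=float(rng.uniform(0.1, 0.3)), seed=seed + 100,
        )
        ds, _ = mgfa.simulate(spec)
        ds = ds.center_per_group()
        opts = quick_opts(n_factors=3, spike_slab_factors=ss, drop_inactive=False)
        state = mgfa.initialize(ds, opts)
        prev = mgfa.compute_elbo(state, ds, opts)
        for _ in range(8):
            mgfa.vi_iteration(state, ds, opts)
            e = mgfa.compute_elbo(state, ds, opts)
            assert e >= prev - 1e-8 * abs(prev)
            prev = e


class TestElbo:
    def test_no_observations_leaves_only_kl_terms(self):
        view = ViewSpec("v", "gaussian", ["f1", "f2"])
        group = GroupSpec("g", ["s1", "s2"])
        y = {("g", "v"): np.zeros((2, 2))}
        m_all = {("g", "v"): np.ones((2, 2), bool)}
        m_none = {("g", "v"): np.zeros((2, 2), bool)}
        opts = quick_opts(n_factors=1)
        ds_none = MultiOmicsDataset([view], [group], y, m_none)
        ds_none.centered["v"] = True
        state = mgfa.initialize(ds_none, opts)
        # all-masked: the data term vanishes; ELBO equals minus the sum of
        # KL-type terms, which for this all-zero init must not be positive
        e = mgfa.compute_elbo(state, ds_none, opts)
        assert np.isfinite(e)
        # removing the only data makes the ELBO independent of y values
        ds_none2 = MultiOmicsDataset([view], [group],
                                     {("g", "v"): np.full((2, 2), 7.0)}, m_none)
        ds_none2.centered["v"] = True
        assert mgfa.compute_elbo(mgfa.initialize(ds_none2, opts), ds_none2, opts) == e

    def test_degenerate_q_data_term_matches_normal_logpdf(self):
        """With q collapsed near point masses the gaussian data term approaches
        the exact log-density at those values."""
        view = ViewSpec("v", "gaussian", ["f1"])
        group = GroupSpec("g", ["s1"])
        y_val, z_val, w_val, tau_val = 0.7, 1.3, 0.4, 2.0
        ds = MultiOmicsDataset([view], [group], {("g", "v"): np.array([[y_val]])},
                               {("g", "v"): np.ones((1, 1), bool)})
        ds.centered["v"] = True
        opts = quick_opts(n_factors=1, drop_inactive=False)
        state = mgfa.initialize(ds, opts)
        eps = 1e-12
        state.z["g"].mean[:] = z_val
        state.z["g"].var[:] = eps
        state.w["v"].mean[:] = w_val
        state.w["v"].var[:] = eps
        state.w["v"].prob[:] = 1.0 - 1e-15
        big = 1e14
        state.tau[("g", "v")].a = np.array([tau_val * big])
        state.tau[("g", "v")].b = np.array([big])
        ex, exx = inference._predictor_moments(state, "g", "v")
        from mgfa.likelihoods import gaussian_expected_loglik
        term = gaussian_expected_loglik(ds.y[("g", "v")], ds.mask[("g", "v")], ex, exx,
                                        state.tau[("g", "v")].mean,
                                        state.tau[("g", "v")].mean_log)
        exact = stats.norm.logpdf(y_val, z_val * w_val, 1 / np.sqrt(tau_val))
        assert term == pytest.approx(exact, abs=1e-6)

    def test_monte_carlo_oracle_small_model(self):
        """ELBO equals a sampling estimate of E_q[log p - log q] on a toy model."""
        rng = np.random.default_rng(0)
        y = {("g", "v"): np.array([[0.5, -0.2], [1.0, 0.3]])}
        m = {("g", "v"): np.ones((2, 2), bool)}
        ds = MultiOmicsDataset([ViewSpec("v", "gaussian", ["f1", "f2"])],
                               [GroupSpec("g", ["s1", "s2"])], y, m)
        ds.centered["v"] = True
        opts = quick_opts(n_factors=1, drop_inactive=False, spike_slab_factors=True)
        state = mgfa.initialize(ds, opts)
        for _ in range(3):
            mgfa.vi_iteration(state, ds, opts)
        elbo = mgfa.compute_elbo(state, ds, opts)

        pr = opts.priors
        N = 300000
        Y = y[("g", "v")]
        lp = np.zeros(N)
        lq = np.zeros(N)

        def gamma_term(post, a0, b0):
            s = rng.gamma(post.a, 1 / post.b, size=(N,) + post.a.shape)
            return s, (stats.gamma.logpdf(s, a0, scale=1 / b0).reshape(N, -1).sum(1),
                       stats.gamma.logpdf(s, post.a, scale=1 / post.b).reshape(N, -1).sum(1))

        def beta_term(post, a0, b0):
            s = rng.beta(post.a, post.b, size=(N,) + post.a.shape)
            return s, (stats.beta.logpdf(s, a0, b0).reshape(N, -1).sum(1),
                       stats.beta.logpdf(s, post.a, post.b).reshape(N, -1).sum(1))

        a_w, (p1, q1) = gamma_term(state.alpha_w["v"], pr.ard_shape, pr.ard_rate)
        lp += p1; lq += q1
        a_z, (p1, q1) = gamma_term(state.alpha_z["g"], pr.ard_shape, pr.ard_rate)
        lp += p1; lq += q1
        tt, (p1, q1) = gamma_term(state.tau[("g", "v")], pr.noise_shape, pr.noise_rate)
        lp += p1; lq += q1
        th_w, (p1, q1) = beta_term(state.theta_w["v"], pr.sparsity_a, pr.sparsity_b)
        lp += p1; lq += q1
        th_z, (p1, q1) = beta_term(state.theta_z["g"], pr.sparsity_a, pr.sparsity_b)
        lp += p1; lq += q1

        def spike_slab_draw(post, th, a_draw):
            R = post.mean.shape[0]
            s = rng.random((N, R)) < post.prob[:, 0]
            on = rng.normal(post.mean[:, 0], np.sqrt(post.var[:, 0]), size=(N, R))
            off = rng.normal(0, np.sqrt(post.var0[0]), size=(N, R))
            wh = np.where(s, on, off)
            lq_ = np.where(
                s, np.log(post.prob[:, 0]) + stats.norm.logpdf(wh, post.mean[:, 0],
                                                               np.sqrt(post.var[:, 0])),
                np.log(1 - post.prob[:, 0]) + stats.norm.logpdf(wh, 0, np.sqrt(post.var0[0])),
            ).sum(1)
            lp_ = stats.norm.logpdf(wh, 0, np.sqrt(1 / a_draw)).sum(1)
            lp_ += np.where(s, np.log(th), np.log(1 - th)).sum(1)
            return s * wh, lp_, lq_

        Wd, p1, q1 = spike_slab_draw(state.w["v"], th_w, a_w)
        lp += p1; lq += q1
        Zd, p1, q1 = spike_slab_draw(state.z["g"], th_z, a_z)
        lp += p1; lq += q1
        X = Zd[:, :, None] * Wd[:, None, :]
        lp += stats.norm.logpdf(Y[None], X, np.sqrt(1 / tt)[:, None, :]).reshape(N, -1).sum(1)
        vals = lp - lq
        se = vals.std() / np.sqrt(N)
        assert abs(elbo - vals.mean()) < 3 * se


class TestInvariances:
    def test_sample_permutation_equivariance(self, small_gaussian):
        ds, _ = small_gaussian
        opts = quick_opts(drop_inactive=False)
        state = mgfa.initialize(ds, opts)
        g0 = ds.group_names[0]
        perm = np.random.default_rng(2).permutation(ds.group(g0).n_samples)
        ds_p = ds.copy()
        for v in ds.view_names:
            ds_p.y[(g0, v)] = ds_p.y[(g0, v)][perm]
            ds_p.mask[(g0, v)] = ds_p.mask[(g0, v)][perm]
        state_p = state.copy()
        state_p.z[g0].mean = state_p.z[g0].mean[perm]
        state_p.z[g0].var = state_p.z[g0].var[perm]
        mgfa.vi_iteration(state, ds, opts)
        mgfa.vi_iteration(state_p, ds_p, opts)
        np.testing.assert_allclose(state_p.z[g0].mean, state.z[g0].mean[perm], atol=1e-12)
        for v in ds.view_names:
            np.testing.assert_allclose(state_p.w[v].mean, state.w[v].mean, atol=1e-12)

    def test_factor_sign_flip_leaves_elbo_unchanged(self, fitted):
        ds, _, state, _ = fitted
        opts = quick_opts()
        e0 = mgfa.compute_elbo(state, ds, opts)
        flipped = state.copy()
        for g in ds.group_names:
            flipped.z[g].mean[:, 0] *= -1
        for v in ds.view_names:
            flipped.w[v].mean[:, 0] *= -1
        e1 = mgfa.compute_elbo(flipped, ds, opts)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_single_group_reduces_to_weight_side_model(self):
        """With one group and factor-side regularization off, the prior
        structure collapses to the predecessor's: plain N(0,1) factors and
        weight-side ARD + spike-and-slab only."""
        spec = mgfa.SimulationSpec(n_factors=2, n_samples=(30,), n_features=(15,),
                                   likelihoods=("gaussian",), missing_fraction=0.0, seed=8)
        ds, _ = mgfa.simulate(spec)
        ds = ds.center_per_group()
        opts = quick_opts(n_factors=2, ard_factors=False, spike_slab_factors=False,
                          drop_inactive=False)
        state, _ = mgfa.fit(ds, opts)
        assert state.alpha_z is None and state.theta_z is None
        from mgfa.model import NormalPosterior
        zpost = state.z["group0"]
        assert isinstance(zpost, NormalPosterior)
        # factor prior term equals the standard-normal expression
        got = inference._normal_term(zpost, np.ones(state.K), np.zeros(state.K))
        mu, var = zpost.mean, zpost.var
        manual = float(np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * (mu ** 2 + var)
                              + 0.5 * (np.log(2 * np.pi * var) + 1.0)))
        assert got == pytest.approx(manual, rel=1e-12)


class TestFit:
    def test_identical_seeds_identical_traces(self, small_gaussian):
        ds, _ = small_gaussian
        for mode in ("vi", "svi"):
            o = quick_opts(max_iterations=8, mode=mode, seed=5)
            _, t1 = mgfa.fit(ds, o)
            _, t2 = mgfa.fit(ds, quick_opts(max_iterations=8, mode=mode, seed=5))
            np.testing.assert_array_equal(t1.elbo, t2.elbo)

    def test_single_factor_recovery(self):
        spec = mgfa.SimulationSpec(n_factors=1, n_samples=(200,), n_features=(100,),
                                   likelihoods=("gaussian",), noise_var=(0.2,),
                                   missing_fraction=0.0, seed=13)
        ds, truth = mgfa.simulate(spec)
        ds = ds.center_per_group()
        state, _ = mgfa.fit(ds, quick_opts(n_factors=1, max_iterations=100))
        rz = np.corrcoef(truth.z["group0"][:, 0], state.z["group0"].e[:, 0])[0, 1]
        rw = np.corrcoef(truth.w["view0"][:, 0], state.w["view0"].e[:, 0])[0, 1]
        assert abs(rz) > 0.95 and abs(rw) > 0.95

    def test_rank_one_data_shrinks_spare_factors(self):
        spec = mgfa.SimulationSpec(n_factors=1, n_samples=(200,), n_features=(100,),
                                   likelihoods=("gaussian",), noise_var=(0.2,),
                                   missing_fraction=0.0, seed=17)
        ds, _ = mgfa.simulate(spec)
        ds = ds.center_per_group()
        state, _ = mgfa.fit(ds, quick_opts(n_factors=5, max_iterations=150))
        r2 = mgfa.variance_explained(state, ds)
        strong = (np.nan_to_num(r2.r2).reshape(state.K, -1).max(axis=1) >= 0.01).sum()
        assert strong == 1

    def test_uncentered_input_warns_and_centers(self):
        spec = mgfa.SimulationSpec(n_factors=1, n_samples=(20,), n_features=(8,),
                                   likelihoods=("gaussian",), missing_fraction=0.0, seed=2)
        ds, _ = mgfa.simulate(spec)
        with pytest.warns(UserWarning, match="not centered"):
            mgfa.fit(ds, quick_opts(n_factors=1, max_iterations=3))


class TestPruneFactors:
    def _fake_r2(self, values):
        class R:
            pass
        r = R()
        arr = np.asarray(values, dtype=float)[:, None, None]
        r.r2 = arr
        return r

    def _state(self, K):
        opts = quick_opts(n_factors=K, drop_inactive=False)
        spec = mgfa.SimulationSpec(n_factors=K, n_samples=(12,), n_features=(10,),
                                   likelihoods=("gaussian",), missing_fraction=0.0, seed=1)
        ds, _ = mgfa.simulate(spec)
        ds = ds.center_per_group()
        return mgfa.initialize(ds, opts)

    def test_one_percent_filter(self):
        state = self._state(3)
        pruned = mgfa.prune_factors(state, self._fake_r2([0.30, 0.009, 0.05]), 0.01)
        assert pruned.K == 2

    def test_zero_threshold_keeps_all(self):
        state = self._state(3)
        assert mgfa.prune_factors(state, self._fake_r2([0.3, 0.0, 0.1]), 0.0).K == 3

    def test_zero_variance_factor_removed(self):
        state = self._state(2)
        assert mgfa.prune_factors(state, self._fake_r2([0.2, 0.0]), 1e-9).K == 1

    def test_reordered_by_total_variance(self):
        state = self._state(3)
        state.w[state_view(state)].mean[:] = np.arange(3)[None, :]
        pruned = mgfa.prune_factors(state, self._fake_r2([0.05, 0.30, 0.10]), 0.01)
        # factor with highest total r2 first: original order (2, 3, 1)
        np.testing.assert_array_equal(pruned.w[state_view(pruned)].mean[0], [1.0, 2.0, 0.0])

    def test_all_pruned_warns(self):
        state = self._state(2)
        with pytest.warns(UserWarning, match="pruned"):
            pruned = mgfa.prune_factors(state, self._fake_r2([0.001, 0.002]), 0.5)
        assert pruned.K == 0


def state_view(state):
    return next(iter(state.w))
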