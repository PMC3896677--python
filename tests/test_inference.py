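"""Design construction, network fitting, CV selection, and prior overlap."""

import itertools

import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy.optimize import minimize

import embryogrn as eg
from embryogrn.datatypes import GeneNetwork, ObservationSet, PriorNetwork
from embryogrn.inference import _blocks, _per_gene_stacks
from embryogrn.solver import _cv_grid


def _steady(values, **kw):
    values = np.asarray(values, dtype=float)
    names = [f"g{i}" for i in range(values.shape[0])]
    return ObservationSet(values=values, mode="steady_state", gene_names=names, **kw)


def _series(series_list, **kw):
    """Build a time-series ObservationSet from a list of (p, k) arrays."""
    values = np.concatenate(series_list, axis=1)
    p, _ = values.shape
    k = series_list[0].shape[1]
    obs_ids = np.repeat(np.arange(1, len(series_list) + 1), k)
    tps = np.tile(np.arange(1, k + 1), len(series_list))
    return ObservationSet(
        values=values,
        mode="time_series",
        gene_names=[f"g{i}" for i in range(p)],
        obs_ids=obs_ids,
        time_points=tps,
        **kw,
    )


class TestNormalization:
    def test_divides_each_row_by_its_max(self):
        out = eg.normalize_by_gene_max(np.array([[2.0, 4.0, 8.0], [5.0, 5.0, 5.0]]))
        assert_allclose(out, [[0.25, 0.5, 1.0], [1.0, 1.0, 1.0]])
        assert_allclose(out.max(axis=1), 1.0)

    def test_all_zero_row_names_the_gene(self):
        with pytest.raises(ValueError, match="vegt"):
            eg.normalize_by_gene_max(np.array([[1.0, 2.0], [0.0, 0.0]]), ["foxh1", "vegt"])


class TestKnockoutMask:
    def test_zeroes_only_knocked_entries(self):
        obs = _steady([[0.5], [0.3]], knockout_mask=[[True], [False]])
        assert_allclose(eg.apply_knockout_mask(obs), [[0.0], [0.3]])

    def test_identity_without_knockouts(self):
        obs = _steady([[0.5], [0.3]])
        assert_allclose(eg.apply_knockout_mask(obs), obs.values)

    def test_full_knockout_zeroes_column(self):
        obs = _steady([[0.5], [0.3]], knockout_mask=[[True], [True]])
        assert_allclose(eg.apply_knockout_mask(obs), [[0.0], [0.0]])


class TestDesignODE:
    def test_single_sample_outer_products(self):
        # x = (1, 2): self-position zeroed per target row
        dm = eg.build_design_ode(_steady([[1.0], [2.0]]))
        assert_allclose(dm.D[0], [[0.0, 0.0], [0.0, 4.0]])
        assert_allclose(dm.D[1], [[1.0, 0.0], [0.0, 0.0]])
        assert_allclose(dm.U, np.outer([1.0, 2.0], [1.0, 2.0]))

    def test_missing_sample_excluded_from_that_gene_only(self):
        obs = _steady(
            [[1.0, 0.0], [2.0, 3.0]],
            missing_mask=[[False, True], [False, False]],
        )
        dm = eg.build_design_ode(obs)
        # sample 2 dropped from D^0 only; regressor there has gene 0 zeroed anyway
        assert_allclose(dm.D[0], [[0.0, 0.0], [0.0, 4.0]])
        assert_allclose(dm.D[1], [[1.0, 0.0], [0.0, 0.0]])

    def test_wrong_mode_rejected(self):
        series = _series([np.array([[1.0, 0.0], [0.0, 2.0]])])
        with pytest.raises(ValueError, match="steady_state"):
            eg.build_design_ode(series)


class TestDesignMarkov:
    def test_single_transition_outer_products(self):
        dm = eg.build_design_markov(_series([np.array([[1.0, 0.0], [0.0, 2.0]])]))
        assert_allclose(dm.U, [[0.0, 2.0], [0.0, 0.0]])
        for i in range(2):
            assert_allclose(dm.D[i], [[1.0, 0.0], [0.0, 0.0]])

    def test_knocked_regulator_contributes_zero(self):
        series = np.array([[1.0, 0.0], [1.0, 2.0]])
        ko = np.array([[True, False], [False, False]])
        dm = eg.build_design_markov(_series([series], knockout_mask=ko))
        # regressor x^1 = (0, 1): gene 0's contribution removed
        assert_allclose(dm.D[0], [[0.0, 0.0], [0.0, 1.0]])
        assert_allclose(dm.U, [[0.0, 0.0], [0.0, 2.0]])

    def test_four_time_points_accumulate_three_transitions(self, rng):
        series = rng.uniform(0.1, 1.0, size=(3, 4))
        dm = eg.build_design_markov(_series([series]))
        expected = sum(np.outer(series[:, k], series[:, k]) for k in range(3))
        assert_allclose(dm.D[0], expected)

    def test_single_time_point_observation_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            _series([np.array([[1.0], [2.0]])])


class TestFitNetwork:
    def test_row_separability_matches_joint_minimizer(self, rng):
        # the row-wise coordinate solution must attain the joint optimum
        p = 3
        series = [rng.normal(size=(p, 3)) for _ in range(3)]
        obs = _series(series)
        prior = PriorNetwork.from_edges([("g0", "g1")], obs.gene_names)
        alpha, beta = 0.05, 0.04
        net = eg.fit_network(obs, prior=prior, model_kind="markov", alpha=alpha, beta=beta, tol=1e-10)
        dm = eg.build_design_markov(obs)

        def joint_objective(wflat):
            W = wflat.reshape(p, p)
            val = 0.0
            for i in range(p):
                val += W[i] @ dm.D[i] @ W[i] - 2 * W[i] @ dm.U[:, i]
            lam = alpha + beta * prior.w0
            return val + np.sum(lam * np.abs(W))

        res = minimize(joint_objective, rng.normal(size=p * p) * 0.1, method="Powell",
                       options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 100000})
        assert joint_objective(net.W.ravel()) <= res.fun + 1e-8

    def test_large_alpha_empties_network(self, small_markov_world):
        _, _, noisy = small_markov_world
        net = eg.fit_network(noisy, model_kind="markov", alpha=1e6)
        assert np.count_nonzero(net.W) == 0

    def test_ode_mode_fixes_zero_diagonal(self, rng):
        obs = _steady(rng.uniform(0.1, 1.0, size=(4, 6)))
        net = eg.fit_network(obs, model_kind="ode", alpha=0.01)
        assert_allclose(np.diag(net.W), 0.0)

    def test_degenerate_gene_warns_and_returns_zero_row(self):
        obs = _steady(
            [[1.0, 2.0], [1.0, 1.0], [0.5, 0.8]],
            missing_mask=[[True, True], [False, False], [False, False]],
        )
        with pytest.warns(RuntimeWarning, match="g0"):
            net = eg.fit_network(obs, model_kind="ode", alpha=0.1)
        assert_allclose(net.W[0], 0.0)


class TestLooCV:
    def test_requires_two_observations(self):
        obs = _steady([[1.0], [2.0]])
        with pytest.raises(ValueError, match="at least 2"):
            eg.loo_cv_fit(obs, model_kind="ode")

    def test_single_pair_grid_matches_manual_heldout_error(self, rng):
        # with one (alpha, beta) pair the CV error is exactly the summed
        # held-out residual of models trained on the complement
        p = 3
        series = [rng.normal(size=(p, 3)) for _ in range(4)]
        obs = _series(series)
        Z, X, M = _blocks(obs, "markov")
        D_stack, u_stack = _per_gene_stacks(Z, X, M, "markov")
        alpha, beta = 0.2, 0.0
        g = 1
        a, b, err = _cv_grid(
            np.ascontiguousarray(D_stack[g]), np.ascontiguousarray(u_stack[g]),
            Z, np.ascontiguousarray(X[:, :, g]), np.ascontiguousarray(M[:, :, g]),
            np.array([alpha]), np.array([beta]), np.ones(p), 1e-10, 100000,
        )
        assert (a, b) == (alpha, beta)
        manual = 0.0
        for o in range(4):
            D_tr = D_stack[g].sum(axis=0) - D_stack[g][o]
            u_tr = u_stack[g].sum(axis=0) - u_stack[g][o]
            w = eg.solve_row(D_tr, u_tr, alpha=alpha, tol=1e-10)
            manual += float(np.sum((Z[o] @ w - X[o, :, g]) ** 2))
        assert_allclose(err, manual, rtol=1e-8)

    def test_duplicate_observations_heldout_equals_insample(self, rng):
        # n identical observations: the held-out copy is indistinguishable
        # from a training copy, so CV error = n * per-copy in-sample residual
        p = 3
        one = rng.normal(size=(p, 3))
        obs = _series([one.copy() for _ in range(4)])
        Z, X, M = _blocks(obs, "markov")
        D_stack, u_stack = _per_gene_stacks(Z, X, M, "markov")
        g = 0
        alpha = 0.3
        a, b, err = _cv_grid(
            np.ascontiguousarray(D_stack[g]), np.ascontiguousarray(u_stack[g]),
            Z, np.ascontiguousarray(X[:, :, g]), np.ascontiguousarray(M[:, :, g]),
            np.array([alpha]), np.array([0.0]), np.ones(p), 1e-10, 100000,
        )
        w = eg.solve_row(D_stack[g].sum(0) - D_stack[g][0], u_stack[g].sum(0) - u_stack[g][0],
                         alpha=alpha, tol=1e-10)
        per_copy = float(np.sum((Z[0] @ w - X[0, :, g]) ** 2))
        assert_allclose(err, 4 * per_copy, rtol=1e-8)

    def test_noise_free_markov_recovery(self, small_markov_world):
        net, clean, _ = small_markov_world
        fitted, fit = eg.loo_cv_fit(clean, model_kind="markov", grid_depth=12)
        assert fit.total_cv_error < 1e-10
        assert np.max(np.abs(fitted.W - net.W)) < 1e-4

    def test_noise_free_ode_recovery(self, rng):
        # steady states live on the nullspace of I - W; a rank-one
        # construction W = I - a b' with a = 1/b has zero diagonal and a
        # (p-1)-dimensional consistent sample space, enough for recovery
        p = 6
        b = rng.uniform(0.5, 2.0, p) * rng.choice([-1.0, 1.0], p)
        W = np.eye(p) - np.outer(1.0 / b, b)
        V = rng.normal(size=(p, p + 4))
        V = V - np.outer(b, b @ V) / (b @ b)
        obs = _steady(V)
        fitted, fit = eg.loo_cv_fit(obs, model_kind="ode", grid_depth=12)
        assert fit.total_cv_error < 1e-10
        assert np.max(np.abs(fitted.W - W)) < 1e-4

    def test_beta_frees_prior_edges(self, small_markov_world):
        # with every true edge exempt, CV can only improve
        net, _, noisy = small_markov_world
        _, fit_none = eg.loo_cv_fit(noisy, model_kind="markov", grid_depth=10)
        prior = eg.make_prior_matrix(net, 25, 0, seed=0)
        _, fit_prior = eg.loo_cv_fit(noisy, prior=prior, model_kind="markov", grid_depth=10)
        assert fit_prior.total_cv_error <= fit_none.total_cv_error + 1e-9


class TestThresholdAndOverlap:
    def _net(self, W):
        W = np.asarray(W, dtype=float)
        names = [f"g{i}" for i in range(W.shape[0])]
        return GeneNetwork(W=W, gene_names=names, model_kind="markov")

    def test_threshold_keeps_large_signed_weights(self):
        net = self._net([[0.0, 0.3], [-0.1, 0.0]])
        assert eg.threshold_network(net, 0.25) == [("g1", "g0", 0.3)]
        assert len(eg.threshold_network(net, 0.0)) == 2
        assert eg.threshold_network(net, 0.5) == []

    def test_overlap_is_direction_sensitive(self):
        prior = PriorNetwork.from_edges([("g0", "g1")], ["g0", "g1"])
        count, matched = eg.prior_overlap([("g0", "g1", 0.4)], prior)
        assert count == 1 and matched == [("g0", "g1", 0.4)]
        count, _ = eg.prior_overlap([("g1", "g0", 0.4)], prior)
        assert count == 0
        with pytest.raises(KeyError, match="gX"):
            eg.prior_overlap([("gX", "g1", 0.1)], prior)

    def test_full_and_disjoint_overlap(self):
        prior = PriorNetwork.from_edges([("g0", "g1"), ("g1", "g2")], ["g0", "g1", "g2"])
        edges = [("g0", "g1", 1.0), ("g1", "g2", -1.0), ("g2", "g0", 0.5)]
        assert eg.prior_overlap(edges, prior)[0] == 2
        assert eg.prior_overlap([("g2", "g0", 0.5)], prior)[0] == 0


class TestOverlapPvalue:
    def test_empty_prior_gives_p_one(self):
        net = GeneNetwork(W=np.array([[0.0, 1.0], [0.5, 0.0]]),
                          gene_names=["g0", "g1"], model_kind="markov")
        prior = PriorNetwork.all_penalized(["g0", "g1"])
        assert eg.prior_overlap_pvalue(net, prior, 0.1, n_perm=19, seed=0) == 1.0

    def test_add_one_bounds(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 4))
        net = GeneNetwork(W=W, gene_names=list("abcd"), model_kind="markov")
        prior = PriorNetwork.from_edges([("a", "b"), ("c", "d")], list("abcd"))
        p = eg.prior_overlap_pvalue(net, prior, 0.5, n_perm=99, seed=1)
        assert 1 / 100 <= p <= 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 3 genes: six off-diagonal entries, 720 equally likely arrangements
        W = np.array([[0.0, 0.9, 0.1], [0.05, 0.0, 0.8], [0.2, 0.02, 0.0]])
        net = GeneNetwork(W=W, gene_names=["a", "b", "c"], model_kind="markov")
        prior = PriorNetwork.from_edges([("b", "a"), ("c", "b")], ["a", "b", "c"])
        tau = 0.5
        exempt = (prior.w0 == 0) & ~np.eye(3, dtype=bool)
        positions = np.argwhere(~np.eye(3, dtype=bool))
        vals = W[~np.eye(3, dtype=bool)]
        observed = np.sum((np.abs(W) >= tau) & (W != 0) & exempt)
        hits = total = 0
        for perm in itertools.permutations(vals):
            Wp = np.zeros((3, 3))
            for (i, j), v in zip(positions, perm):
                Wp[i, j] = v
            total += 1
            if np.sum((np.abs(Wp) >= tau) & (Wp != 0) & exempt) >= observed:
                hits += 1
        exact = hits / total
        mc = eg.prior_overlap_pvalue(net, prior, tau, n_perm=4000, seed=5)
        assert abs(mc - exact) < 0.05
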