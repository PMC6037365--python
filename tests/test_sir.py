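"""SIR simulator: degenerate limits, cross-simulator agreement, seeding."""

import numpy as np
import pytest

import ocrank as oc


def naive_sir(g, seeds, beta, gamma, rng):
    """Independent, set-based reimplementation of the synchronous dynamics."""
    susceptible = set(range(g.n)) - set(seeds)
    infected = set(seeds)
    recovered = set()
    traj = [len(infected)]
    while infected:
        newly = set()
        for u in sorted(infected):
            for v in g.neighbors(u):
                if v in susceptible and v not in newly and rng.random() < beta:
                    newly.add(int(v))
        for u in sorted(infected):
            if rng.random() < gamma:
                recovered.add(u)
        infected = (infected - recovered) | newly
        susceptible -= newly
        traj.append(traj[-1] + len(newly))
    return traj


class TestParams:
    @pytest.mark.parametrize("beta,gamma,reps", [(-0.1, 1, 1), (1.1, 1, 1), (0.5, 0, 1), (0.5, 1, 0)])
    def test_invalid_rejected(self, beta, gamma, reps):
        with pytest.raises(ValueError):
            oc.SIRParams(beta=beta, gamma=gamma, reps=reps)


class TestEpidemicThreshold:
    def test_ring(self, toys):
        assert oc.epidemic_threshold(toys["ring"]) == pytest.approx(0.5)

    def test_star(self, toys):
        assert oc.epidemic_threshold(toys["star"]) == pytest.approx(0.4)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            oc.epidemic_threshold(oc.Graph(["a"], []))


class TestSirRun:
    def test_beta_zero_no_transmission(self, toys):
        rng = np.random.default_rng(0)
        res = oc.sir_run(toys["ring"], [0, 3], beta=0.0, gamma=1.0, rng=rng)
        assert res.final_size == 2

    def test_deterministic_wavefront_is_bfs(self, toys):
        g = toys["two_clique_bridge"]
        res = oc.sir_run(g, [1], beta=1.0, gamma=1.0, rng=np.random.default_rng(0))
        assert res.final_size == g.n
        # BFS layers from node 1: itself, its clique (incl. bridge), far clique
        np.testing.assert_array_equal(res.trajectory, [1, 7, 13, 13])

    def test_disconnected_component_bound(self):
        g = oc.Graph(list("abcde"), [(0, 1), (1, 2), (3, 4)])
        res = oc.sir_run(g, [3], beta=1.0, gamma=1.0, rng=np.random.default_rng(0))
        assert res.final_size == 2

    def test_empty_seed_set_rejected(self, toys):
        with pytest.raises(ValueError):
            oc.sir_run(toys["ring"], [], 0.5, 1.0, np.random.default_rng(0))

    def test_trajectory_monotone_bounded(self, benchmark):
        g, _ = benchmark
        for rep in range(20):
            rng = np.random.default_rng(rep)
            res = oc.sir_run(g, [rep], beta=0.05, gamma=0.7, rng=rng)
            assert (np.diff(res.trajectory) >= 0).all()
            assert res.final_size <= g.n
            assert res.final_size >= 1


class TestInfluence:
    def test_beta_zero(self, toys):
        assert oc.influence(toys["ring"], 0, oc.SIRParams(beta=0.0, reps=5, seed=0)) == (1.0, 0.0)

    def test_deterministic_limit(self, toys):
        g = toys["ring"]
        mean, se = oc.influence(g, 2, oc.SIRParams(beta=1.0, gamma=1.0, reps=10, seed=0))
        assert (mean, se) == (float(g.n), 0.0)

    def test_reproducible_given_seed(self, toys):
        p = oc.SIRParams(beta=0.4, gamma=0.8, reps=50, seed=11)
        a = oc.influence(toys["two_clique_bridge"], 0, p)
        b = oc.influence(toys["two_clique_bridge"], 0, p)
        assert a == b

    def test_cross_simulator_agreement(self):
        """Mean outbreak size matches an independent naive simulator within
        Monte-Carlo error on a 20-ring."""
        g = oc.Graph([str(i) for i in range(20)], [(i, (i + 1) % 20) for i in range(20)])
        reps = 2000
        mine, se = oc.influence(g, 0, oc.SIRParams(beta=0.5, gamma=1.0, reps=reps, seed=0))
        rng = np.random.default_rng(123)
        other = np.array([naive_sir(g, [0], 0.5, 1.0, rng)[-1] for _ in range(reps)])
        se_other = other.std(ddof=1) / np.sqrt(reps)
        assert abs(mine - other.mean()) < 3 * np.hypot(se, se_other)

    @pytest.mark.parametrize("gamma", [1.0, 0.6])
    def test_cross_simulator_on_toys(self, toys, gamma):
        for name in ["star", "two_clique_bridge"]:
            g = toys[name]
            reps = 1500
            mine, se = oc.influence(g, 0, oc.SIRParams(beta=0.3, gamma=gamma, reps=reps, seed=1))
            rng = np.random.default_rng(7)
            other = np.array([naive_sir(g, [0], 0.3, gamma, rng)[-1] for _ in range(reps)])
            se_o = other.std(ddof=1) / np.sqrt(reps)
            assert abs(mine - other.mean()) < 3 * np.hypot(se, se_o), name

    def test_monotone_in_beta(self, toys):
        """Mean final size is non-decreasing in the infection probability."""
        g = toys["two_clique_bridge"]
        means = []
        for beta in [0.1, 0.3, 0.5]:
            m, se = oc.influence(g, 0, oc.SIRParams(beta=beta, gamma=1.0, reps=5000, seed=2))
            means.append((m, se))
        for (m1, s1), (m2, s2) in zip(means, means[1:]):
            assert m2 > m1 - 2 * np.hypot(s1, s2)


class TestInfluenceRanking:
    def test_all_tied_at_beta_one(self, toys):
        rs = oc.influence_ranking(toys["ring"], oc.SIRParams(beta=1.0, gamma=1.0, reps=3, seed=0))
        assert np.ptp(rs.values) == 0.0

    def test_star_center_spreads_most(self, toys):
        g = toys["star"]
        rs = oc.influence_ranking(g, oc.SIRParams(beta=0.5, gamma=1.0, reps=2000, seed=0))
        assert rs.values[0] >= rs.values[1:].max()

    def test_deterministic(self, toys):
        p = oc.SIRParams(beta=0.3, gamma=1.0, reps=30, seed=5)
        a = oc.influence_ranking(toys["star"], p)
        b = oc.influence_ranking(toys["star"], p)
        np.testing.assert_array_equal(a.values, b.values)


class TestTopKSpreadCurve:
    def test_beta_zero_flat_at_k(self, toys):
        g = toys["two_clique_bridge"]
        dc = oc.degree_centrality(g)
        curves = oc.topk_spread_curve(g, [dc], 3, oc.SIRParams(beta=0.0, reps=5, seed=0))
        mean, se = curves["DC"]
        np.testing.assert_array_equal(mean, 3.0)

    def test_beta_one_reaches_reachable_set(self):
        g = oc.Graph(list("abcde"), [(0, 1), (1, 2), (3, 4)])
        rs = oc.RankScores("seedset", np.array([1.0, 0, 0, 0.9, 0]))
        curves = oc.topk_spread_curve(g, [rs], 2, oc.SIRParams(beta=1.0, gamma=1.0, reps=3, seed=0))
        assert curves["seedset"][0][-1] == 5.0

    def test_identical_topk_sets_identical_curves(self, toys):
        g = toys["two_clique_bridge"]
        a = oc.RankScores("m1", np.arange(13, dtype=float))
        b = oc.RankScores("m2", np.arange(13, dtype=float) * 2)
        curves = oc.topk_spread_curve(g, [a, b], 4, oc.SIRParams(beta=0.3, reps=20, seed=0))
        np.testing.assert_array_equal(curves["m1"][0], curves["m2"][0])

    def test_k_too_large_rejected(self, toys):
        with pytest.raises(ValueError):
            oc.topk_spread_curve(toys["path"], [oc.degree_centrality(toys["path"])], 5,
                                 oc.SIRParams(beta=0.1, reps=2, seed=0))
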