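import numpy as np
import pytest
from scipy import optimize

from morphotraj.phylo import (ancestral_states_scp, calibrate_branch_lengths, k_mult,
                              permutation_signal_test, scp_quadratic_form)
from morphotraj.tree import TimeTree


def balanced_tree(n_tips, branch=1.0):
    names = iter(f"L{i}" for i in range(n_tips))

    def build(m):
        if m == 1:
            return f"{next(names)}:{branch}"
        return f"({build(m // 2)},{build(m - m // 2)}):{branch}"

    return TimeTree.from_newick(f"({build(n_tips // 2)},{build(n_tips - n_tips // 2)});")


class TestCalibration:
    def test_root_extension_forces_positive_cherry(self):
        topo = TimeTree.from_newick("(A,B);")
        cal = calibrate_branch_lengths(topo, {"A": 200.0, "B": 200.0})
        lengths = sorted(cal.length[v] for v in range(cal.n_nodes) if v != cal.root)
        assert lengths == [1.0, 1.0]

    def test_zero_chain_shares_time_equally(self):
        # a 6-Myr positive branch above a chain of two zero-length
        # branches: the time is divided equally, 2 Myr each
        topo = TimeTree.from_newick("(O,(A,(B,C)));")
        ages = {"O": 95.0, "A": 100.0, "B": 100.0, "C": 100.0}
        cal = calibrate_branch_lengths(topo, ages, root_extension=6.0)
        # root age 106; zero chain root->(A,..)->(B,C) spans the 6 Myr
        inner = cal.mrca(["A", "C"])
        cherry = cal.mrca(["B", "C"])
        assert cal.length[inner] == pytest.approx(2.0)
        assert cal.length[cherry] == pytest.approx(2.0)
        assert cal.length[cal.tip_index("B")] == pytest.approx(2.0)
        assert cal.length[cal.tip_index("A")] == pytest.approx(4.0)
        for v in range(cal.n_nodes):
            if v != cal.root:
                assert cal.length[v] > 0

    def test_missing_tip_age(self):
        topo = TimeTree.from_newick("(A,B);")
        with pytest.raises(KeyError):
            calibrate_branch_lengths(topo, {"A": 10.0})


class TestScp:
    def test_two_tip_midpoint(self):
        t = TimeTree.from_newick("(A:1,B:1);")
        recon = ancestral_states_scp(t, {"A": 0.0, "B": 4.0})
        assert recon.state_of(t.root)[0] == pytest.approx(2.0)

    def test_inverse_length_weighting(self):
        # minimize x^2/1 + (x-4)^2/3 -> x = 1
        t = TimeTree.from_newick("(A:1,B:3);")
        recon = ancestral_states_scp(t, {"A": 0.0, "B": 4.0})
        assert recon.state_of(t.root)[0] == pytest.approx(1.0)

    def test_matches_numeric_minimizer_on_5_tip_tree(self, rng):
        t = TimeTree.from_newick("((A:2,B:1):1.5,((C:1,D:2):0.5,E:3):1);")
        y = {l: float(v) for l, v in zip(sorted(t.tip_labels), rng.normal(size=5))}
        recon = ancestral_states_scp(t, y)

        tipvals = {t.tip_index(l): v for l, v in y.items()}
        internal = [v for v in range(t.n_nodes) if t.children[v]]

        def objective(x):
            states = dict(tipvals)
            states.update(zip(internal, x))
            return sum((states[v] - states[t.parent[v]]) ** 2 / t.length[v]
                       for v in range(t.n_nodes) if v != t.root)

        res = optimize.minimize(objective, np.zeros(len(internal)), method="BFGS",
                                options={"gtol": 1e-12})
        assert recon.tree_length == pytest.approx(res.fun, abs=1e-6)
        np.testing.assert_allclose(recon.node_states[internal, 0], res.x, atol=1e-5)

    def test_equals_brownian_ml_states_scalar(self, rng):
        """Weighted SCP states equal the Brownian-motion ML ancestral
        states, computed independently via the GLS conditional mean."""
        t = TimeTree.from_newick("((A:2,B:1):1.5,((C:1,D:2):0.5,E:3):1);")
        order = t.tip_labels
        y = rng.normal(size=5)
        recon = ancestral_states_scp(t, dict(zip(order, y)))

        C = t.phylo_covariance(order)
        Cinv = np.linalg.inv(C)
        one = np.ones(5)
        mu = (one @ Cinv @ y) / (one @ Cinv @ one)
        depth = t.depths()
        for node in range(t.n_nodes):
            if not t.children[node]:
                continue
            # covariance of node with each tip = depth of their MRCA
            cov = np.array([_shared_depth(t, node, t.tip_index(l), depth)
                            for l in order])
            ml = mu + cov @ Cinv @ (y - mu)
            assert recon.state_of(node)[0] == pytest.approx(ml, abs=1e-8)

    def test_doubling_branch_lengths_halves_tree_length(self, rng):
        t = balanced_tree(8)
        Y = rng.normal(size=(8, 3))
        tl1 = ancestral_states_scp(t, Y).tree_length
        t2 = TimeTree(t.parent, t.length * 2, t.labels)
        tl2 = ancestral_states_scp(t2, Y).tree_length
        assert tl2 == pytest.approx(tl1 / 2, rel=1e-12)

    def test_tree_length_invariant_under_trait_rotation(self, rng):
        t = balanced_tree(8)
        Y = rng.normal(size=(8, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        tl1 = ancestral_states_scp(t, Y).tree_length
        tl2 = ancestral_states_scp(t, Y @ q).tree_length
        assert tl1 == pytest.approx(tl2, rel=1e-10)

    def test_quadratic_form_matches_direct_solution(self, rng):
        t = balanced_tree(8)
        Y = rng.normal(size=(8, 3))
        M = scp_quadratic_form(t)
        order = [t.labels[v] for v in t.tips]
        recon = ancestral_states_scp(t, Y, tip_order=order)
        assert np.trace(Y.T @ M @ Y) == pytest.approx(recon.tree_length, rel=1e-10)


def _anc_set(t, node):
    out, v = set(), node
    while v >= 0:
        out.add(v)
        v = t.parent[v]
    return out


def _is_ancestor(t, a, b):
    return a in _anc_set(t, b)


def _shared_depth(t, a, b, depth):
    return max(depth[v] for v in (_anc_set(t, a) & _anc_set(t, b)))


class TestSignalTests:
    def test_permutation_test_power_under_brownian(self, rng):
        t = balanced_tree(32, branch=2.0)
        C = t.phylo_covariance()
        L = np.linalg.cholesky(C)
        significant = 0
        for rep in range(100):
            Y = L @ rng.normal(size=(32, 3))
            res = permutation_signal_test(t, Y, n_perm=199, seed=rep)
            significant += res.p_value < 0.05
        assert significant >= 95

    def test_type_one_error_with_iid_states(self, rng):
        t = balanced_tree(16, branch=3.0)
        rejections = 0
        R = 300
        for rep in range(R):
            y = rng.normal(size=(16, 1))
            res = permutation_signal_test(t, y, n_perm=199, seed=rep)
            rejections += res.p_value <= 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / R)
        assert abs(rejections / R - 0.05) <= band

    def test_seeded_reproducibility(self, rng):
        t = balanced_tree(8)
        Y = rng.normal(size=(8, 2))
        a = permutation_signal_test(t, Y, n_perm=300, seed=5)
        b = permutation_signal_test(t, Y, n_perm=300, seed=5)
        assert a.p_value == b.p_value and a.statistic == b.statistic


class TestKmult:
    def test_brownian_calibration_mean_near_one(self, rng):
        t = balanced_tree(64)
        L = np.linalg.cholesky(t.phylo_covariance())
        ks = []
        for rep in range(200):
            Y = L @ rng.normal(size=(64, 5))
            ks.append(k_mult(t, Y, n_perm=1, seed=rep).statistic)
        assert abs(np.mean(ks) - 1.0) < 0.1

    def test_identical_states_degenerate(self):
        t = balanced_tree(8)
        with pytest.raises(ValueError, match="identical"):
            k_mult(t, np.ones((8, 3)), n_perm=10)

    def test_strong_signal_detected(self, rng):
        t = balanced_tree(32, branch=2.0)
        L = np.linalg.cholesky(t.phylo_covariance())
        Y = L @ rng.normal(size=(32, 3))
        res = k_mult(t, Y, n_perm=499, seed=0)
        assert res.p_value < 0.05
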