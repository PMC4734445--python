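import numpy as np
import pytest

from morphotraj import synthetic as syn
from morphotraj.superimposition import centroid_size, gpa
from morphotraj.allometry import regress_shape_on_size


class TestBaseSkull:
    def test_default_geometry(self, base_skull):
        assert base_skull.k == 71
        assert centroid_size(base_skull) > 0
        assert base_skull.is_semilandmark.sum() == 51

    def test_deterministic(self):
        a, b = syn.make_base_skull(), syn.make_base_skull()
        np.testing.assert_array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("k", [10, 40, 71, 90])
    def test_region_masks_partition(self, k):
        regions = syn.skull_regions(k)
        combined = np.concatenate(list(regions.values()))
        assert sorted(combined) == list(range(k))
        assert syn.make_base_skull(k).k == k

    def test_too_few_landmarks(self):
        with pytest.raises(ValueError):
            syn.make_base_skull(5)


class TestTruth:
    def test_allometric_vector_in_shape_space(self, base_skull):
        truth = syn.make_truth()
        v = truth.allometric_vector
        assert np.linalg.norm(v) == pytest.approx(1.0)
        B = syn.similarity_null_basis(truth.base_shape)
        assert np.abs(B.T @ v).max() < 1e-10

    def test_bm_basis_orthonormal_and_off_allometric_axis(self):
        truth = syn.make_truth()
        D = truth.bm_directions
        np.testing.assert_allclose(D.T @ D, np.eye(D.shape[1]), atol=1e-10)
        assert np.abs(D.T @ truth.allometric_vector).max() < 1e-10


class TestSimulateOntogeny:
    def test_noiseless_pair_lies_on_axis(self):
        from tests.conftest import to_aligned_frame
        truth = syn.make_truth(noise_sd=0.0)
        base = syn.make_base_skull()
        juv, adult = syn.simulate_ontogeny(base, truth, 4.0, 5.5)
        # tangent-projected coordinates: the chord between two shapes on
        # the unit sphere bends off the growth axis, the projection does not
        sample = gpa([juv, adult])
        diff = sample.procrustes_coords[1] - sample.procrustes_coords[0]
        v = to_aligned_frame(truth.allometric_vector, truth, sample)
        cos = abs(diff @ v) / (np.linalg.norm(diff) * np.linalg.norm(v))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_axis_recovered_by_regression(self):
        truth = syn.make_truth(seed=5, noise_sd=0.0)
        base = syn.make_base_skull()
        rng = np.random.default_rng(5)
        configs = []
        for i in range(20):
            lo = rng.uniform(3.5, 4.5)
            j, a = syn.simulate_ontogeny(base, truth, lo, lo + 1.5, rng=rng,
                                         taxon=f"t{i}")
            j.specimen_id, a.specimen_id = f"j{i}", f"a{i}"
            configs.extend([j, a])
        sample = gpa(configs)
        res = regress_shape_on_size(sample, groups=[c.taxon for c in configs],
                                    n_perm=0)
        from tests.conftest import to_aligned_frame
        v = to_aligned_frame(truth.allometric_vector, truth, sample)
        cos = abs(res.unit_axis @ v) / np.linalg.norm(v)
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_zero_allometry_makes_stages_equal(self):
        truth = syn.make_truth(noise_sd=0.0, allometric_slope=0.0)
        base = syn.make_base_skull()
        juv, adult = syn.simulate_ontogeny(base, truth, 4.0, 5.0)
        sample = gpa([juv, adult], tangent_project=False)
        assert np.abs(sample.procrustes_coords[0]
                      - sample.procrustes_coords[1]).max() < 1e-9

    def test_requires_growth(self):
        truth = syn.make_truth()
        with pytest.raises(ValueError):
            syn.simulate_ontogeny(syn.make_base_skull(), truth, 5.0, 4.0)

    def test_slope_of_rs_vs_logcs_matches_injection(self):
        """The fitted allometric slope reproduces the injected shape
        change per log CS within two standard errors."""
        truth = syn.make_truth(seed=9)
        base = syn.make_base_skull()
        rng = np.random.default_rng(9)
        configs = []
        for i in range(30):
            lo = rng.uniform(3.5, 4.5)
            j, a = syn.simulate_ontogeny(base, truth, lo, lo + 1.5, rng=rng,
                                         taxon=f"t{i}")
            j.specimen_id, a.specimen_id = f"j{i}", f"a{i}"
            configs.extend([j, a])
        sample = gpa(configs)
        groups = [c.taxon for c in configs]
        res = regress_shape_on_size(sample, groups=groups, n_perm=0)
        # within-group-centered score-vs-size slope (sizes are taxon-relative)
        x = np.array(sample.log_cs)
        s = np.array(res.regression_scores)
        for g in set(groups):
            idx = [i for i, gi in enumerate(groups) if gi == g]
            x[idx] -= x[idx].mean()
            s[idx] -= s[idx].mean()
        slope = x @ s / (x @ x)
        resid = s - slope * x
        se = np.sqrt(resid @ resid / (len(x) - 2) / (x @ x))
        assert abs(slope - truth.allometric_slope) <= max(2 * se,
                                                          0.05 * truth.allometric_slope)


class TestSimulateClade:
    def test_seed_determinism(self, fixture_tree):
        t1 = syn.make_truth(seed=7)
        t2 = syn.make_truth(seed=7)
        c1, _ = syn.simulate_clade(fixture_tree, t1, juvenile_taxa=["T01"])
        c2, _ = syn.simulate_clade(fixture_tree, t2, juvenile_taxa=["T01"])
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_static_clade_degenerates_k_statistic(self, fixture_tree):
        from morphotraj.phylo import k_mult
        truth = syn.make_truth(noise_sd=0.0, bm_rate=0.0, bm_iso_rate=0.0)
        configs, info = syn.simulate_clade(fixture_tree, truth)
        states = info["node_states"][fixture_tree.tips]
        with pytest.raises(ValueError, match="identical"):
            k_mult(fixture_tree, states - states[0], n_perm=10)

    def test_kmult_near_one_for_simulated_means(self, fixture_tree):
        """Noiseless simulated adult means are Brownian on the tree, so
        the K statistic averages about 1 over replicates."""
        from morphotraj.phylo import k_mult
        ks = []
        for rep in range(100):
            truth = syn.make_truth(seed=100 + rep, noise_sd=0.0)
            _, info = syn.simulate_clade(fixture_tree, truth)
            Y = info["node_states"][fixture_tree.tips]
            ks.append(k_mult(fixture_tree, Y - Y.mean(axis=0),
                             n_perm=1, seed=rep).statistic)
        assert abs(np.mean(ks) - 1.0) < 0.15

    def test_shift_moves_descendants_along_axis(self, fixture_tree):
        delta = -0.05
        clade = tuple(syn.FIXTURE_CLADES["CladeD"])
        t0 = syn.make_truth(seed=3)
        t1 = syn.make_truth(seed=3, heterochrony_shifts={clade: delta})
        _, i0 = syn.simulate_clade(fixture_tree, t0)
        _, i1 = syn.simulate_clade(fixture_tree, t1)
        node = fixture_tree.mrca(clade)
        moved = i1["node_states"] - i0["node_states"]
        inside = {node}
        stack = [node]
        while stack:
            v = stack.pop()
            inside.update(fixture_tree.children[v])
            stack.extend(fixture_tree.children[v])
        v = t0.allometric_vector
        for n in range(fixture_tree.n_nodes):
            proj = moved[n] @ v
            if n in inside:
                assert proj == pytest.approx(delta, abs=1e-12)
            else:
                assert proj == pytest.approx(0.0, abs=1e-12)
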