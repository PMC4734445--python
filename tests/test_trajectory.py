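import numpy as np
import pytest
from scipy import stats

from morphotraj.trajectory import (OntogeneticTrajectory, PAEDOMORPHOSIS,
                                   PERAMORPHOSIS, UNDETERMINED, change_vector,
                                   ci_threshold, classify_heterochrony,
                                   trajectory_angle, trajectory_length)


def traj(label, juv_shape, adult_shape, juv_cs=1.0, adult_cs=2.0, **vars_):
    t = OntogeneticTrajectory(label=label, juvenile_shape=np.asarray(juv_shape, float),
                              adult_shape=np.asarray(adult_shape, float),
                              juvenile_log_cs=juv_cs, adult_log_cs=adult_cs)
    for k, (jv, av) in vars_.items():
        t.juvenile_vars[k] = jv
        t.adult_vars[k] = av
    return t


class TestChangeVector:
    def test_identical_stages_zero(self):
        t = traj("x", [1, 2, 3], [1, 2, 3])
        assert np.all(change_vector(t) == 0)

    def test_points_juvenile_to_adult(self):
        scores = {"juvenile": [0.0, 0.0], "adult": [3.0, 4.0]}
        v = change_vector(traj("x", [0], [0]), traits=[0, 1], scores=scores)
        np.testing.assert_array_equal(v, [3.0, 4.0])
        assert trajectory_length(v) == 5.0

    def test_componentwise_subtraction(self, rng):
        for _ in range(20):
            j, a = rng.normal(size=(2, 6))
            np.testing.assert_allclose(change_vector(traj("x", j, a)), a - j)


class TestAngle:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 1], [1, 1], 0.0),
        ([1, 0], [-1, 0], 180.0),
        ([1, 0], [0, 1], 90.0),
    ])
    def test_analytic_cases(self, a, b, expected):
        assert trajectory_angle(a, b) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_common_rescaling(self, rng):
        a, b = rng.normal(size=(2, 2))
        assert trajectory_angle(3 * a, 0.5 * b) \
            == pytest.approx(trajectory_angle(a, b), abs=1e-10)

    def test_length_scales_linearly(self, rng):
        v = rng.normal(size=2)
        assert trajectory_length(4 * v) == pytest.approx(4 * trajectory_length(v))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            trajectory_angle([0, 0], [1, 0])


class TestCiThreshold:
    def test_constant_differences_zero_width(self):
        assert ci_threshold(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_t_interval(self, rng):
        d = rng.normal(size=68)
        half = stats.t.ppf(0.975, 67) * d.std(ddof=1) / np.sqrt(68)
        assert ci_threshold(d) == pytest.approx(half, rel=1e-12)
        # two-point case closed form
        assert ci_threshold(np.array([-1.0, 1.0])) \
            == pytest.approx(stats.t.ppf(0.975, 1) * np.sqrt(2) / np.sqrt(2))

    def test_empirical_coverage_near_95(self, rng):
        mu, sigma, n = 0.2, 1.3, 68
        covered = 0
        for _ in range(1000):
            d = rng.normal(mu, sigma, size=n)
            half = ci_threshold(d)
            covered += abs(d.mean() - mu) <= half
        assert 0.93 <= covered / 1000 <= 0.97

    def test_quantile_variant_wider(self, rng):
        d = rng.normal(size=68)
        assert ci_threshold(d, method="quantile") > ci_threshold(d, method="t")

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ci_threshold(np.array([1.0]))


class TestClassification:
    def _pair(self, anc_rs, anc_ed, desc_rs, desc_ed):
        a = traj("anc", [0], [0], regression_score=(0, anc_rs),
                 euclidean_distance=(0, anc_ed))
        d = traj("desc", [0], [0], regression_score=(0, desc_rs),
                 euclidean_distance=(0, desc_ed))
        return a, d

    def test_zero_deltas_undetermined(self):
        a, d = self._pair(0.5, 0.5, 0.5, 0.5)
        call = classify_heterochrony(a, d, ci_rs=0.1, ci_ed=0.1)
        assert call.classification == UNDETERMINED
        assert not call.rs_significant and not call.ed_significant

    def test_both_lower_is_paedomorphosis(self):
        a, d = self._pair(0.5, 0.5, 0.1, 0.1)
        call = classify_heterochrony(a, d, ci_rs=0.1, ci_ed=0.1)
        assert call.classification == PAEDOMORPHOSIS

    def test_both_higher_is_peramorphosis(self):
        a, d = self._pair(0.1, 0.1, 0.5, 0.5)
        call = classify_heterochrony(a, d, ci_rs=0.1, ci_ed=0.1)
        assert call.classification == PERAMORPHOSIS

    def test_disagreement_or_insignificance_undetermined(self):
        # significant but opposite signs
        a, d = self._pair(0.5, 0.1, 0.1, 0.5)
        assert classify_heterochrony(a, d, 0.1, 0.1).classification == UNDETERMINED
        # same sign but one variable below threshold
        a, d = self._pair(0.5, 0.5, 0.1, 0.49)
        call = classify_heterochrony(a, d, 0.1, 0.1)
        assert call.rs_significant and not call.ed_significant
        assert call.classification == UNDETERMINED

    def test_significance_exactly_at_factor_times_ci(self):
        a, d = self._pair(0.0, 0.0, -0.75, -0.75)
        call = classify_heterochrony(a, d, ci_rs=0.5, ci_ed=0.5)
        assert call.rs_significant  # |delta| == 1.5 * ci counts
        assert call.classification == PAEDOMORPHOSIS

    def test_missing_variables_rejected(self):
        a = traj("anc", [0], [0], regression_score=(0, 0.1))
        d = traj("desc", [0], [0], regression_score=(0, 0.2))
        with pytest.raises(ValueError, match="euclidean_distance"):
            classify_heterochrony(a, d, 0.1, 0.1)


class TestAncestralTrajectories:
    def test_clades_resolved_in_both_trees(self, fixture_study):
        result = fixture_study["result"]
        ancestral = [t for t in result.trajectories.values() if t.is_ancestral]
        assert {t.label for t in ancestral} == {"CladeA", "CladeB", "CladeC", "CladeD"}
        for t in ancestral:
            assert t.juvenile_shape.shape == t.adult_shape.shape

    def test_missing_clade_raises(self, fixture_study):
        from morphotraj.pipeline import analyze
        with pytest.raises(KeyError, match="cannot be placed|Nope"):
            analyze(fixture_study["configs"], fixture_study["tree"],
                    clades={"Nope": ["Zeta1", "Zeta2"]}, pairs=[],
                    n_perm_regression=0, n_perm_signal=0)

    def test_shared_ontogeny_recovered_by_ancestor(self):
        """When every taxon shares one noiseless ontogeny, the
        reconstructed ancestral trajectories point along the shared
        growth axis (angle < 5 degrees)."""
        from morphotraj import synthetic as syn
        from morphotraj.pipeline import analyze
        from tests.conftest import to_aligned_frame
        tree = syn.fixture_tree()
        truth = syn.make_truth(seed=21, noise_sd=0.0)
        configs, _ = syn.simulate_clade(tree, truth,
                                        juvenile_taxa=syn.FIXTURE_JUVENILE_TAXA)
        res = analyze(configs, tree, clades=syn.FIXTURE_CLADES,
                      pairs=syn.FIXTURE_PAIRS, n_perm_regression=0, n_perm_signal=0)
        v = to_aligned_frame(truth.allometric_vector, truth, res.aligned)
        for clade in ("CladeA", "CladeB", "CladeC", "CladeD"):
            anc = res.trajectories[clade]
            angle = trajectory_angle(change_vector(anc), v)
            assert min(angle, 180.0 - angle) < 5.0
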