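"""PNO profiles, ancestral tolerances, and age-range correlation."""

import numpy as np
import pandas as pd
import pytest

from phyloniche.enm import NicheModel, fit_maxent
from phyloniche.evolution import (
    PNOProfile,
    age_range_correlation,
    ancestral_tolerance,
    compute_pno,
    node_overlaps,
    pno_weighted_mean,
    variable_bins,
)
from phyloniche.overlap import overlap_matrix
from phyloniche.phylo import Tree, bm_ancestral_states
from phyloniche.synthetic import NicheSpec, sample_occurrences, simulate_tree
from conftest import make_stack


def _stub_model(logistic: np.ndarray, species="sp") -> NicheModel:
    """A NicheModel carrying an arbitrary suitability surface."""
    p = np.asarray(logistic, float)
    return NicheModel(
        species=species, variables=[], feature_names=[], lambdas=np.zeros(0),
        beta=1.0, raw=p / p.sum(), logistic=p, entropy=0.0,
        presence_idx=np.zeros(0, dtype=int),
    )


class TestPNO:
    def test_hand_binning(self):
        stack = make_stack({"v": np.array([[10.0, 10.0, 20.0]])})
        model = _stub_model(np.array([0.5, 0.3, 0.2]))
        prof = compute_pno(model, stack, "v", edges=np.array([5.0, 15.0, 25.0]))
        np.testing.assert_allclose(prof.mass, [0.8, 0.2])

    def test_uniform_suitability_uniform_profile(self):
        stack = make_stack({"v": np.linspace(0, 1, 100).reshape(10, 10)})
        model = _stub_model(np.ones(100))
        prof = compute_pno(model, stack, "v", n_bins=10)
        np.testing.assert_allclose(prof.mass, 0.1, atol=0.011)

    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(0)
        stack = make_stack({"v": rng.normal(size=(8, 8))})
        model = _stub_model(rng.random(64))
        prof = compute_pno(model, stack, "v", n_bins=50)
        assert prof.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_variable_degenerates_with_warning(self):
        stack = make_stack({"v": np.full((3, 3), 7.0)})
        model = _stub_model(np.ones(9))
        with pytest.warns(UserWarning, match="constant"):
            prof = compute_pno(model, stack, "v")
        assert len(prof.mass) == 1 and prof.mass[0] == pytest.approx(1.0)


class TestWeightedMean:
    def test_symmetric_masses(self):
        prof = PNOProfile("s", "v", np.array([5.0, 15, 25, 35]),
                          np.array([0.25, 0.5, 0.25]))
        assert pno_weighted_mean(prof) == pytest.approx(20.0)

    def test_hand_arithmetic(self):
        prof = PNOProfile("s", "v", np.array([5.0, 15, 25]), np.array([0.8, 0.2]))
        assert pno_weighted_mean(prof) == pytest.approx(12.0)

    def test_point_mass(self):
        prof = PNOProfile("s", "v", np.array([0.0, 2, 4]), np.array([0.0, 1.0]))
        assert pno_weighted_mean(prof) == pytest.approx(3.0)

    def test_bin_refinement_stability(self):
        """Halving bin widths moves the mean by less than one coarse bin."""
        rng = np.random.default_rng(3)
        stack = make_stack({"v": rng.normal(size=(12, 12))})
        model = _stub_model(rng.random(144))
        coarse = compute_pno(model, stack, "v", n_bins=25)
        fine = compute_pno(model, stack, "v", n_bins=50)
        width = coarse.edges[1] - coarse.edges[0]
        assert abs(pno_weighted_mean(coarse) - pno_weighted_mean(fine)) < width


class TestAncestralTolerance:
    def _degenerate(self, value, species, variable="v"):
        edges = np.array([value - 1.0, value + 1.0])
        return PNOProfile(species, variable, edges, np.array([1.0]))

    def test_degenerate_profiles_collapse_to_bm(self):
        tree = simulate_tree(5, seed=2)
        vals = {n: float(i) for i, n in enumerate(tree.tip_names)}
        profiles = {n: self._degenerate(v, n) for n, v in vals.items()}
        atp = ancestral_tolerance(tree, profiles, n_samples=10, rng=0)
        direct = bm_ancestral_states(tree, np.array([vals[n] for n in tree.tip_names]))
        for s in atp.node_samples:
            np.testing.assert_allclose(s, direct)

    def test_two_tip_symmetric_root(self):
        tree = Tree.from_newick("(A:1,B:1);")
        profiles = {"A": self._degenerate(0.0, "A"), "B": self._degenerate(10.0, "B")}
        atp = ancestral_tolerance(tree, profiles, n_samples=20, rng=1)
        np.testing.assert_allclose(atp.node_samples[:, 0], 5.0)

    def test_missing_tip_profile_errors(self):
        tree = Tree.from_newick("(A:1,B:1);")
        with pytest.raises(KeyError, match="B"):
            ancestral_tolerance(tree, {"A": self._degenerate(0.0, "A")}, rng=0)

    def test_sample_count(self):
        tree = simulate_tree(4, seed=3)
        profiles = {n: self._degenerate(1.0, n) for n in tree.tip_names}
        atp = ancestral_tolerance(tree, profiles, n_samples=37, rng=0)
        assert atp.node_samples.shape == (37, tree.n_tips - 1)

    def test_bm_root_recovery_on_generator_truth(self):
        """Root reconstruction stays near the true simulated root optimum."""
        from phyloniche.synthetic import evolve_niches

        tree = simulate_tree(10, seed=4)
        root_mu = 20.0
        errs = []
        for s in range(60):
            specs = evolve_niches(
                tree, NicheSpec(mu={"v": root_mu}, sigma={"v": 1.0}),
                bm_rate=4.0, seed=s,
            )
            profiles = {n: self._degenerate(specs[n].mu["v"], n) for n in tree.tip_names}
            atp = ancestral_tolerance(tree, profiles, n_samples=5, rng=s)
            errs.append(atp.node_samples[0, -1] - root_mu)
        # the GLS root estimate is unbiased with variance ~ rate/(1ᵀC⁻¹1)
        assert abs(np.mean(errs)) < 2 * np.std(errs) / np.sqrt(len(errs)) + 0.5


class TestARC:
    def test_three_tip_weighting_rule(self):
        tree = Tree.from_newick("((A:1,B:1):1,C:2);")
        M = pd.DataFrame(
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.4], [0.2, 0.4, 1.0]],
            index=["A", "B", "C"], columns=["A", "B", "C"],
        )
        df = node_overlaps(tree, M, weighting="ft").set_index("node")
        root_row = df.loc[tree.root]
        assert root_row["overlap"] == pytest.approx(0.3)   # mean of o_AC, o_BC
        cherry = df.drop(tree.root).iloc[0]
        assert cherry["overlap"] == pytest.approx(0.9)     # o_AB itself

    def test_mean_weighting_matches_enumeration(self):
        tree = simulate_tree(6, seed=5)
        rng = np.random.default_rng(1)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        Mdf = pd.DataFrame(M, index=tree.tip_names, columns=tree.tip_names)
        df = node_overlaps(tree, Mdf, weighting="mean").set_index("node")
        mrca = tree.mrca_matrix()
        for n in range(tree.n_tips, tree.n_nodes):
            ii, jj = np.nonzero(np.triu(mrca == n, k=1))
            assert df.loc[n, "overlap"] == pytest.approx(M[ii, jj].mean())

    def test_constant_overlap_flat_regression(self):
        tree = simulate_tree(7, seed=6)
        M = pd.DataFrame(np.full((7, 7), 0.4), index=tree.tip_names,
                         columns=tree.tip_names)
        res = age_range_correlation(tree, M, n_permutations=20, rng=0)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert (res.table["flag"] == "").all()

    def test_too_few_nodes_refused(self):
        tree = Tree.from_newick("((A:1,B:1):1,C:2);")
        M = pd.DataFrame(np.eye(3), index=tree.tip_names, columns=tree.tip_names)
        with pytest.raises(ValueError, match="3 internal nodes"):
            age_range_correlation(tree, M, n_permutations=10, rng=0)

    def test_bm_divergence_gives_negative_slope(self, small_scene):
        """Overlap decays with node age when niches diverge by BM."""
        from phyloniche.synthetic import evolve_niches

        cfg, stack, tree = small_scene
        rates = {v: (1.5 * np.std(stack.values(v))) ** 2 for v in stack.variables}
        root = NicheSpec(
            mu={v: float(np.mean(stack.values(v))) for v in stack.variables},
            sigma={v: float(np.std(stack.values(v))) / 2 for v in stack.variables},
        )
        specs = evolve_niches(tree, root, bm_rate=rates, seed=3)
        models = {
            n: fit_maxent(stack, sample_occurrences(stack, specs[n], 25, seed=i, species=n))
            for i, n in enumerate(tree.tip_names)
        }
        ov = overlap_matrix(models)
        res = age_range_correlation(tree, ov, n_permutations=99, rng=0)
        assert res.slope < 0
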