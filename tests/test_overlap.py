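"""Overlap metrics (D, I) and the identity / background randomization tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloniche.enm import fit_maxent
from phyloniche.overlap import (
    background_mask,
    background_test,
    identity_test,
    model_overlap,
    overlap_matrix,
    percentile_bound,
    schoener_D,
    summarize_within_clade,
    warren_I,
    within_clade_pairs,
)
from phyloniche.synthetic import NicheSpec, sample_occurrences
from conftest import make_stack, occ_at_cells


class TestMetrics:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert schoener_D(p, p) == pytest.approx(1.0)
        assert warren_I(p, p) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.5, 0.5])
        assert schoener_D(p, q) == pytest.approx(0.0)
        assert warren_I(p, q) == pytest.approx(0.0)

    def test_hand_worked_values(self):
        assert schoener_D(np.array([0.6, 0.4]), np.array([0.4, 0.6])) == pytest.approx(0.8)
        assert warren_I(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            schoener_D(np.array([0.6, 0.6]), np.array([0.5, 0.5]))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    def test_I_dominates_D_and_symmetry(self, seed, k):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        q = rng.dirichlet(np.ones(k))
        D, I = schoener_D(p, q), warren_I(p, q)
        assert 0.0 <= D <= I <= 1.0 + 1e-12
        assert schoener_D(q, p) == pytest.approx(D)
        assert warren_I(q, p) == pytest.approx(I)
        perm = rng.permutation(k)  # relabeling cells changes nothing
        assert schoener_D(p[perm], q[perm]) == pytest.approx(D)


class TestPercentileBound:
    def test_order_statistic_rank(self):
        null = np.arange(1, 101) / 100.0    # 0.01 .. 1.00
        assert percentile_bound(null, 0.05) == pytest.approx(0.06)  # 6th smallest
        assert percentile_bound(null, 0.95) == pytest.approx(0.96)  # 96th smallest


@pytest.fixture(scope="module")
def two_species_scene():
    rng = np.random.default_rng(1)
    v1 = np.linspace(0, 10, 144).reshape(12, 12)
    v2 = rng.normal(size=(12, 12))
    stack = make_stack({"v1": v1, "v2": v2})
    return stack


class TestIdentityTest:
    def test_identical_samples_never_rejected(self, two_species_scene):
        stack = two_species_scene
        occ = occ_at_cells(stack, [(i, i) for i in range(6)], "A")
        occB = occ_at_cells(stack, [(i, i) for i in range(6)], "B")
        res = identity_test(stack, occ, occB, n_replicates=20, rng=0)
        assert res.observed["D"] == pytest.approx(1.0)
        assert res.verdict == "identity-not-rejected"

    def test_disjoint_niches_rejected(self, two_species_scene):
        stack = two_species_scene
        a = NicheSpec(mu={"v1": 1.0, "v2": 0.0}, sigma={"v1": 0.5, "v2": 2.0})
        b = NicheSpec(mu={"v1": 9.0, "v2": 0.0}, sigma={"v1": 0.5, "v2": 2.0})
        occA = sample_occurrences(stack, a, 25, seed=2, species="A")
        occB = sample_occurrences(stack, b, 25, seed=3, species="B")
        res = identity_test(stack, occA, occB, n_replicates=50, rng=0)
        assert res.verdict == "identity-rejected"
        assert res.observed["D"] < res.lower

    def test_null_sample_length(self, two_species_scene):
        stack = two_species_scene
        a = NicheSpec(mu={"v1": 5.0, "v2": 0.0}, sigma={"v1": 2.0, "v2": 2.0})
        occA = sample_occurrences(stack, a, 20, seed=4, species="A")
        occB = sample_occurrences(stack, a, 20, seed=5, species="B")
        res = identity_test(stack, occA, occB, n_replicates=30, rng=1)
        assert len(res.null) == 30


class TestBackgroundTest:
    def test_verdict_vocabulary_and_reproducibility(self, two_species_scene):
        stack = two_species_scene
        a = NicheSpec(mu={"v1": 4.0, "v2": 0.0}, sigma={"v1": 2.0, "v2": 2.0})
        occA = sample_occurrences(stack, a, 20, seed=6, species="A")
        occB = sample_occurrences(stack, a, 20, seed=7, species="B")
        r1 = background_test(stack, occA, occB, n_replicates=25, rng=3)
        r2 = background_test(stack, occA, occB, n_replicates=25, rng=3)
        assert r1.verdict in {"conservatism", "divergence", "n.s."}
        np.testing.assert_array_equal(r1.null, r2.null)

    def test_background_mask_covers_hull(self, two_species_scene):
        stack = two_species_scene
        occ = occ_at_cells(stack, [(2, 2), (2, 8), (8, 2), (8, 8)], "A")
        bg = background_mask(stack, occ, buffer_cells=0.6)
        # all occupied cells are inside their own background
        from phyloniche.enm import presence_cells

        assert bg[presence_cells(stack, occ)].all()
        assert bg.sum() < stack.n_cells  # and it is a proper subset

    def test_background_too_small_rejected(self, two_species_scene):
        stack = two_species_scene
        occA = occ_at_cells(stack, [(i, i) for i in range(6)], "A")
        occB = occ_at_cells(stack, [(i, (i + 1) % 6) for i in range(6)], "B")
        tiny = np.zeros(stack.n_cells, dtype=bool)
        tiny[:3] = True
        with pytest.raises(ValueError, match="pseudolocalities"):
            background_test(stack, occA, occB, background_B=tiny, n_replicates=5, rng=0)


class TestCladeSummary:
    def test_pair_enumeration(self):
        clades = {f"s{i}": "P" for i in range(6)}
        clades.update({f"n{i}": "N" for i in range(8)})
        clades.update({f"x{i}": "S" for i in range(7)})
        pairs = within_clade_pairs(clades)
        assert {c: len(p) for c, p in pairs.items()} == {"P": 15, "N": 28, "S": 21}
        assert sum(len(p) for p in pairs.values()) == 64

    def test_percentages_rounded(self):
        clades = {f"n{i}": "N" for i in range(8)}
        pairs = within_clade_pairs(clades)["N"]
        verdicts = {frozenset(p): ("conservatism" if k < 17 else "n.s.")
                    for k, p in enumerate(pairs)}
        table = summarize_within_clade(clades, verdicts).set_index("clade")
        assert table.loc["N", "n_pairs"] == 28
        assert table.loc["N", "n_conservatism"] == 17
        assert table.loc["N", "pct_conservatism"] == 61

    def test_zero_significant(self):
        clades = {f"a{i}": "A" for i in range(5)}
        verdicts = {frozenset(p): "n.s." for p in within_clade_pairs(clades)["A"]}
        table = summarize_within_clade(clades, verdicts).set_index("clade")
        assert table.loc["A", "pct_n.s."] == 100

    def test_missing_verdict_errors(self):
        clades = {"a": "A", "b": "A"}
        with pytest.raises(KeyError):
            summarize_within_clade(clades, {})


class TestOverlapMatrix:
    def test_symmetry_unit_diagonal_and_I_ge_D(self, two_species_scene):
        stack = two_species_scene
        specs = {
            "A": NicheSpec(mu={"v1": 3.0, "v2": 0.0}, sigma={"v1": 1.5, "v2": 2.0}),
            "B": NicheSpec(mu={"v1": 6.0, "v2": 0.0}, sigma={"v1": 1.5, "v2": 2.0}),
            "C": NicheSpec(mu={"v1": 9.0, "v2": 0.0}, sigma={"v1": 1.5, "v2": 2.0}),
        }
        models = {
            n: fit_maxent(stack, sample_occurrences(stack, s, 20, seed=i, species=n))
            for i, (n, s) in enumerate(specs.items())
        }
        ov = overlap_matrix(models)
        np.testing.assert_allclose(np.diag(ov.D), 1.0)
        np.testing.assert_allclose(ov.D, ov.D.T)
        assert (ov.I.to_numpy() >= ov.D.to_numpy() - 1e-12).all()
        # a species overlaps its nearer neighbour more
        assert ov.D.loc["A", "B"] > ov.D.loc["A", "C"]
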