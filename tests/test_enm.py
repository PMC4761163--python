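"""Maximum-entropy niche model: fitting, KKT contract, AUC, thresholds."""

import numpy as np
import pytest
from scipy.optimize import minimize

from phyloniche.enm import (
    TooFewOccurrencesError,
    _rank_auc,
    apply_mtp,
    cumulative_clade_map,
    evaluate_auc,
    feature_matrix,
    fit_maxent,
)
from phyloniche.synthetic import NicheSpec, sample_occurrences
from conftest import make_stack, occ_at_cells


@pytest.fixture()
def gradient_stack():
    rng = np.random.default_rng(0)
    v1 = np.linspace(0, 10, 100).reshape(10, 10)
    v2 = rng.normal(size=(10, 10))
    return make_stack({"v1": v1, "v2": v2})


class TestFit:
    def test_raw_is_distribution(self, gradient_stack):
        occ = occ_at_cells(gradient_stack, [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)])
        m = fit_maxent(gradient_stack, occ)
        assert m.raw.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(m.logistic >= 0) and np.all(m.logistic <= 1)
        assert m.entropy >= 0

    def test_no_features_gives_uniform(self, gradient_stack):
        empty = gradient_stack.subset([])
        occ = occ_at_cells(gradient_stack, [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)])
        m = fit_maxent(empty, occ)
        np.testing.assert_allclose(m.raw, 1.0 / empty.n_cells)

    def test_binary_feature_constraint_matching(self):
        # 4 cells; the variable separates cells {0,1} from {2,3}; presences on
        # the first group with beta=0 push all probability onto that group
        stack = make_stack({"v": np.array([[1.0, 1.0], [0.0, 0.0]])})
        occ = occ_at_cells(stack, [(0, 0), (0, 1), (0, 0), (0, 1), (0, 0)])
        m = fit_maxent(stack, occ, beta=0.0, max_iter=500)
        assert m.raw[0] == pytest.approx(0.5, abs=1e-3)
        assert m.raw[1] == pytest.approx(0.5, abs=1e-3)
        assert m.raw[2] + m.raw[3] < 1e-3

    def test_kkt_slack_bound(self, gradient_stack):
        """At the optimum, |E_p[f] − presence mean| ≤ β_j (+ numerical slack)."""
        spec = NicheSpec(mu={"v1": 7.0, "v2": 0.0}, sigma={"v1": 2.0, "v2": 2.0})
        occ = sample_occurrences(gradient_stack, spec, 40, seed=4)
        m = fit_maxent(gradient_stack, occ, beta=1.0)
        F, _, _ = feature_matrix(gradient_stack)
        from phyloniche.enm import presence_cells

        pres = presence_cells(gradient_stack, occ)
        target = F[pres].mean(axis=0)
        bj = 1.0 * F[pres].std(axis=0) / np.sqrt(len(pres))
        gap = np.abs(F.T @ m.raw - target)
        # 2e-3 absorbs the optimizer's stopping slack at its 1e-6 objective tol
        assert np.all(gap <= bj + 2e-3)

    def test_objective_monotone(self, gradient_stack):
        """The penalized convex objective never increases across iterates."""
        from phyloniche.enm import presence_cells
        from scipy.special import logsumexp

        spec = NicheSpec(mu={"v1": 7.0, "v2": 0.0}, sigma={"v1": 2.0, "v2": 2.0})
        occ = sample_occurrences(gradient_stack, spec, 30, seed=5)
        F, _, _ = feature_matrix(gradient_stack)
        pres = presence_cells(gradient_stack, occ)
        target = F[pres].mean(axis=0)
        bj = F[pres].std(axis=0) / np.sqrt(len(pres))
        J = F.shape[1]
        values = []

        def obj(uv):
            lam = uv[:J] - uv[J:]
            eta = F @ lam
            val = logsumexp(eta) - target @ lam + bj @ (uv[:J] + uv[J:])
            p = np.exp(eta - logsumexp(eta))
            g = F.T @ p - target
            return val, np.concatenate([g + bj, -g + bj])

        minimize(obj, np.zeros(2 * J), jac=True, method="L-BFGS-B",
                 bounds=[(0, None)] * 2 * J,
                 callback=lambda xk: values.append(obj(xk)[0]))
        assert np.all(np.diff(values) <= 1e-10)

    def test_too_few_occurrences_excluded(self, gradient_stack):
        occ = occ_at_cells(gradient_stack, [(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(TooFewOccurrencesError, match="excluded from niche analyses"):
            fit_maxent(gradient_stack, occ)

    def test_brute_force_entropy_oracle(self):
        """With β = 0 the fit matches direct constrained-entropy maximization."""
        rng = np.random.default_rng(6)
        stack = make_stack({"v": rng.normal(size=(4, 4))})
        occ = occ_at_cells(stack, [(0, 1), (1, 2), (2, 0), (3, 3), (1, 1)])
        m = fit_maxent(stack, occ, beta=0.0, max_iter=2000)
        F, _, _ = feature_matrix(stack)
        from phyloniche.enm import presence_cells

        target = F[presence_cells(stack, occ)].mean(axis=0)
        n = stack.n_cells

        def neg_entropy(q):
            p = np.abs(q) / np.abs(q).sum()
            return (p * np.log(p + 1e-300)).sum()

        cons = [
            {"type": "eq", "fun": lambda q, j=j: (np.abs(q) / np.abs(q).sum()) @ F[:, j]
             - target[j]}
            for j in range(F.shape[1])
        ]
        res = minimize(neg_entropy, np.full(n, 1.0 / n), constraints=cons,
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        brute = np.abs(res.x) / np.abs(res.x).sum()
        np.testing.assert_allclose(m.raw, brute, atol=5e-4)


class TestAUC:
    def test_perfect_separation(self):
        assert _rank_auc(np.array([0.9, 0.8]), np.array([0.1, 0.2])) == 1.0

    def test_all_ties_half(self):
        assert _rank_auc(np.full(3, 0.5), np.full(10, 0.5)) == 0.5

    def test_strong_signal_high_auc(self, gradient_stack):
        # niche breadth well below the environmental span = strong signal
        spec = NicheSpec(mu={"v1": 8.0, "v2": 0.5}, sigma={"v1": 0.7, "v2": 0.5})
        occ = sample_occurrences(gradient_stack, spec, 30, seed=7)
        rep = evaluate_auc(gradient_stack, occ, n_replicates=10, rng=0)
        assert rep.mean_auc >= 0.85
        assert rep.passed
        assert len(rep.replicate_auc) == 10

    def test_too_few_to_split(self, gradient_stack):
        occ = occ_at_cells(gradient_stack, [(0, 0)])
        with pytest.raises(ValueError):
            evaluate_auc(gradient_stack, occ)


class TestThresholdAndCladeMap:
    def test_mtp_is_min_training_logistic(self, gradient_stack):
        occ = occ_at_cells(gradient_stack, [(i, i) for i in range(6)])
        m = fit_maxent(gradient_stack, occ)
        from phyloniche.enm import presence_cells

        pres = presence_cells(gradient_stack, occ)
        assert m.mtp == m.logistic[pres].min()
        surface = apply_mtp(m, gradient_stack)
        assert surface[gradient_stack.mask].sum() == (m.logistic >= m.mtp).sum()
        # every training presence is inside the suitable area
        for r, c in occ.cells(gradient_stack):
            assert surface[r, c]

    def test_cumulative_map(self, gradient_stack):
        occ = occ_at_cells(gradient_stack, [(i, i) for i in range(6)])
        m = fit_maxent(gradient_stack, occ)
        one = cumulative_clade_map([m], gradient_stack)
        two = cumulative_clade_map([m, m], gradient_stack)
        mask = gradient_stack.mask
        np.testing.assert_allclose(one[mask], m.logistic)
        np.testing.assert_allclose(two[mask], 2 * m.logistic)
        assert np.nanmax(two) <= 2.0
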