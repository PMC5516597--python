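import numpy as np
import pytest
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from _oracles import brute_bh
from recallnet.association import (
    bh_fdr,
    control_analysis,
    hierarchical_cascade,
    residualize,
    robust_r2,
    spearman_assoc,
    volume_association,
)
from recallnet.core import population_edge_mask
from recallnet.metrics import n_possible_edges
from recallnet.synthetic import SyntheticConfig, simulate_cohort

from conftest import SMALL_COHORT_KW


def _cov(cohort, *cols):
    return np.column_stack([cohort.column(c) for c in cols])


class TestResidualize:
    def test_intercept_only_demeans(self, rng):
        y = rng.normal(size=20)
        r = residualize(y, None)
        assert np.allclose(r, y - y.mean())

    def test_exact_linear_gives_zero_residuals(self, rng):
        x = rng.normal(size=30)
        y = 2.0 + 3.0 * x
        assert np.allclose(residualize(y, x[:, None]), 0.0, atol=1e-10)

    def test_matches_normal_equation_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(residualize(y, x[:, None]), y - X @ beta)

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.normal(size=(50, 3))
        r = residualize(rng.normal(size=50), X)
        assert abs(r.mean()) < 1e-10
        assert np.allclose(X.T @ r, 0.0, atol=1e-8)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.normal(size=20), np.column_stack([x, 2 * x]))


class TestSpearman:
    def test_perfect_monotone_association(self):
        x = np.arange(12.0)
        res = spearman_assoc(x, np.exp(x), B=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == res.ci_high == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(12.0)
        assert spearman_assoc(x, -x, B=0).r == pytest.approx(-1.0)

    TOY_X = np.array([1.0, 2, 2, 3, 4, 5, 6, 7, 8, 9])
    TOY_Y = np.array([3.0, 1, 4, 2, 6, 5, 8, 7, 10, 9])

    def test_tied_data_matches_average_rank_pearson(self):
        # hand-assigned average ranks for the tie in x: positions 2,3 -> 2.5
        rx = np.array([1, 2.5, 2.5, 4, 5, 6, 7, 8, 9, 10])
        ry = st.rankdata(self.TOY_Y)
        expected = np.corrcoef(rx, ry)[0, 1]
        res = spearman_assoc(self.TOY_X, self.TOY_Y, B=0)
        assert res.r == pytest.approx(expected)

    def test_p_close_to_permutation_oracle(self, rng):
        x, y = self.TOY_X, self.TOY_Y
        r_obs = abs(spearman_assoc(x, y, B=0).r)
        perm = np.array(
            [abs(st.spearmanr(x, y[rng.permutation(10)])[0]) for _ in range(20000)]
        )
        p_perm = (1 + (perm >= r_obs - 1e-12).sum()) / 20001
        assert spearman_assoc(x, y, B=0).p == pytest.approx(p_perm, abs=0.02)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = spearman_assoc(x, y, B=0).r
        assert spearman_assoc(np.exp(x), y, B=0).r == pytest.approx(base)
        assert spearman_assoc(x, y**3, B=0).r == pytest.approx(base)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_assoc(np.ones(12), np.arange(12.0), B=0)

    def test_bootstrap_ci_brackets_r_and_converges(self, rng):
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(size=300)
        a = spearman_assoc(x, y, B=2000, seed=11)
        b = spearman_assoc(x, y, B=4000, seed=12)
        assert a.ci_low <= a.r <= a.ci_high
        half_a = (a.ci_high - a.ci_low) / 2
        half_b = (b.ci_high - b.ci_low) / 2
        assert abs(half_a - half_b) < 0.01


class TestBH:
    def test_all_ones_rejects_nothing(self):
        res = bh_fdr(np.ones(8))
        assert res.n_rejected == 0 and res.critical_p == 0.0

    def test_all_zeros_rejects_everything(self):
        res = bh_fdr(np.zeros(8))
        assert res.n_rejected == 8

    def test_worked_example(self):
        res = bh_fdr([0.001, 0.01, 0.02, 0.2], q=0.05)
        assert list(res.rejected) == [True, True, True, False]
        assert res.critical_p == pytest.approx(0.02)

    def test_single_p_reduces_to_threshold(self):
        assert bh_fdr([0.04], q=0.05).n_rejected == 1
        assert bh_fdr([0.06], q=0.05).n_rejected == 0

    def test_matches_bruteforce_and_statsmodels(self, rng):
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40)) ** rng.uniform(0.5, 3)
            res = bh_fdr(p, q=0.05)
            assert np.array_equal(res.rejected, brute_bh(p, 0.05))
            sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.array_equal(res.rejected, sm_rej)
            assert np.allclose(res.adjusted, sm_adj)


class TestRobustR2:
    def test_noiseless_linear_fit_is_exact(self, rng):
        X = rng.normal(size=(40, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = 4.0 + X @ beta
        fit = robust_r2(y, X)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.allclose(fit.coefficients, [4.0, *beta], atol=1e-8)

    def test_null_predictors_explain_little(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=1000)
        X = rng.normal(size=(1000, 22))
        assert robust_r2(y, X).r_squared < 0.05

    def test_resists_gross_outliers_better_than_ols(self):
        wins = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            x = rng.normal(size=60)
            y = 2.0 * x + rng.normal(size=60) * 0.5
            out = rng.choice(60, 3, replace=False)
            y[out] += rng.choice([-1, 1], 3) * 25
            rob = robust_r2(y, x[:, None]).coefficients[1]
            Xd = np.column_stack([np.ones(60), x])
            ols = np.linalg.lstsq(Xd, y, rcond=None)[0][1]
            wins += abs(rob - 2.0) < abs(ols - 2.0)
        assert wins >= 190

    def test_agrees_with_statsmodels_rlm(self, rng):
        X = rng.normal(size=(200, 4))
        y = X @ np.array([1.0, 0.5, -1.0, 0.0]) + rng.standard_t(3, size=200)
        fit = robust_r2(y, X)
        rlm = sm.RLM(
            y, sm.add_constant(X), M=sm.robust.norms.TukeyBiweight(c=4.685)
        ).fit(scale_est="mad")
        assert np.allclose(fit.coefficients, rlm.params, atol=5e-3)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="n >"):
            robust_r2(rng.normal(size=5), rng.normal(size=(5, 4)))


@pytest.fixture(scope="module")
def strong_cohort(planted_cohort):
    return planted_cohort


class TestCascade:
    CASCADE_KW = dict(grid_points=5, n_random=0, B=0, seed=0)

    def test_planted_effect_recovers_structure(self, strong_cohort):
        stack, cohort = strong_cohort.stack, strong_cohort.cohort
        mask = population_edge_mask(stack)
        res = hierarchical_cascade(stack, mask, cohort, **self.CASCADE_KW)
        assert res.level1_rejected
        assert set(res.global_adjusted_p) == {
            "network_cost", "global_efficiency_ci", "clustering_ci",
            "char_path_length_ci", "betweenness_ci",
        }
        # >= 4 of the 5 planted nodes recovered at level 2
        planted = {2, 5, 8, 11, 14}
        assert len(planted & set(res.nodal_rejected)) >= 4
        # level-3 tests restricted to retained edges incident to rejected nodes
        rej = set(res.nodal_rejected)
        for _, row in res.edges.iterrows():
            assert row["node_a"] in rej or row["node_b"] in rej
            assert mask.retained[int(row["node_a"]), int(row["node_b"])]
        assert res.nodal_critical_p <= res.q
        assert len(res.edge_rejected) > 0

    def test_null_cohorts_usually_stop_at_level_one(self):
        cfg = SyntheticConfig(rho_global=0.0, n=120, R=16, template_density=0.35)
        rejections = 0
        for s in range(25):
            c = simulate_cohort(cfg.replace(seed=9000 + s))
            mask = population_edge_mask(c.stack)
            res = hierarchical_cascade(
                c.stack, mask, c.cohort, grid_points=4, n_random=0, B=0, seed=s
            )
            rejections += res.level1_rejected
            if not res.level1_rejected:
                assert res.nodal is None and res.edges is None
        assert rejections <= 4  # q = .05 per level-1 family

    def test_misaligned_cohort_is_reordered(self, strong_cohort):
        stack, cohort = strong_cohort.stack, strong_cohort.cohort
        shuffled = cohort.data.sample(frac=1, random_state=0).reset_index(drop=True)
        from recallnet.core import CohortTable

        res_a = hierarchical_cascade(
            stack, population_edge_mask(stack), CohortTable(shuffled), **self.CASCADE_KW
        )
        assert res_a.level1_rejected


class TestControlAnalysis:
    def test_independent_control_changes_little(self, strong_cohort):
        stack, cohort = strong_cohort.stack, strong_cohort.cohort
        arr = stack.weight_array()
        R = stack.atlas.R
        iu, ju = np.triu_indices(R, 1)
        cost = arr[:, iu, ju].sum(1) / n_possible_edges(R)
        recall_res = residualize(cohort.column("recall_total"), _cov(cohort, "age", "gender"))
        cost_res = residualize(cost, _cov(cohort, "age", "gender", "icv"))
        base = st.spearmanr(cost_res, recall_res)[0]
        out = control_analysis(cohort, cost)
        assert abs(out["attention"].r - base) < 0.03
        assert abs(out["working_memory"].r - base) < 0.03

    def test_controlling_for_near_copy_of_cost_removes_association(self):
        cfg = SyntheticConfig(seed=21, rho_global=0.4, n=600, R=16, template_density=0.35)
        c = simulate_cohort(cfg)
        arr = c.stack.weight_array()
        iu, ju = np.triu_indices(16, 1)
        cost = arr[:, iu, ju].sum(1) / n_possible_edges(16)
        data = c.cohort.data.copy()
        noisy = np.random.default_rng(0)
        data["cost_proxy"] = cost * (1 + 0.01 * noisy.standard_normal(len(cost)))
        from recallnet.core import CohortTable

        out = control_analysis(CohortTable(data), cost, controls=("cost_proxy",))
        assert abs(out["cost_proxy"].r) < 0.12  # planted r = .4 wiped out

    def test_controlling_for_cost_itself_is_degenerate(self, strong_cohort):
        stack, cohort = strong_cohort.stack, strong_cohort.cohort
        arr = stack.weight_array()
        R = stack.atlas.R
        iu, ju = np.triu_indices(R, 1)
        cost = arr[:, iu, ju].sum(1) / n_possible_edges(R)
        data = cohort.data.copy()
        data["cost_again"] = cost
        from recallnet.core import CohortTable

        with pytest.raises(ValueError, match="constant"):
            control_analysis(CohortTable(data), cost, controls=("cost_again",))

    def test_controlling_for_recall_itself_is_degenerate(self, strong_cohort):
        stack, cohort = strong_cohort.stack, strong_cohort.cohort
        data = cohort.data.copy()
        data["self"] = data["recall_total"]
        from recallnet.core import CohortTable

        arr = stack.weight_array()
        iu, ju = np.triu_indices(stack.atlas.R, 1)
        cost = arr[:, iu, ju].sum(1) / n_possible_edges(stack.atlas.R)
        with pytest.raises(ValueError, match="constant"):
            control_analysis(CohortTable(data), cost, controls=("self",))


class TestVolumeAssociation:
    def test_null_volumes_yield_no_rejections(self, null_cohort):
        res = volume_association(null_cohort.cohort, null_cohort.stack.atlas)
        assert res.rejected == []
        assert abs(res.mean_volume.r) < 0.2

    def test_planted_volume_effect_detected(self):
        cfg = SyntheticConfig(
            seed=3, volume_effect=((4, 0.3),), **SMALL_COHORT_KW
        ).replace(n=500)
        c = simulate_cohort(cfg)
        res = volume_association(c.cohort, c.stack.atlas)
        assert 4 in res.rejected

    def test_volumes_copied_from_recall_correlate_near_perfectly(self, rng):
        # volumes that ARE the recall phenotype: every node association ~ 1
        # (exactly 1 up to the extra ICV residualization of volumes)
        import pandas as pd
        from recallnet.atlas import NodeAtlas
        from recallnet.core import CohortTable

        n = 200
        atlas = NodeAtlas.generic(4)
        recall = rng.integers(0, 40, n).astype(float)
        data = dict(
            subject_id=[f"S{i}" for i in range(n)],
            recall_total=recall,
            age=rng.normal(23, 3, n),
            gender=rng.integers(0, 2, n),
            icv=rng.normal(1.5e6, 1e5, n),
        )
        for label in atlas.labels:
            data[f"vol_{label}"] = recall + 500.0
        res = volume_association(CohortTable(pd.DataFrame(data)), atlas)
        assert np.all(res.per_node["r"] > 0.99)

    def test_missing_volumes_rejected(self, null_cohort):
        from recallnet.core import CohortTable

        data = null_cohort.cohort.data[
            [c for c in null_cohort.cohort.data.columns if not c.startswith("vol_")]
        ]
        with pytest.raises(ValueError, match="volume"):
            volume_association(CohortTable(data), null_cohort.stack.atlas)
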