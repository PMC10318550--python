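"""Node derivation, out-of-sample risk scores, OR / strata / chi-square / AUC."""

import numpy as np
import pytest

from lesionnet import (
    BinaryMask,
    EmptyNodeMapError,
    NetworkNodeMap,
    StatResult,
    VolumeGrid,
    chi_square,
    derive_nodes,
    fit_logistic,
    loo_risk_scores,
    risk_score,
    roc_auc,
    stratify,
)
from lesionnet.connectome import Z_CLAMP

from .conftest import make_mask


def stat_result(v, p_fwe, sidedness="two"):
    v = np.asarray(v, float)
    n = v.size
    g = VolumeGrid.isotropic((n, 1, 1), 2.0)
    mask = BinaryMask(g, np.ones(g.shape, bool))
    p_fwe = np.asarray(p_fwe, float)
    return StatResult(
        stat=v, df=np.full(n, 10.0), p_unc=p_fwe, p_fwe=p_fwe, q_fdr=p_fwe,
        n_perm=100, seed=0, sidedness=sidedness, analysis_mask=mask,
    )


class TestDeriveNodes:
    def test_selects_significant_negative_voxels(self):
        res = stat_result([-3.0, 2.5, -1.0], [0.01, 0.01, 0.50])
        nodes = derive_nodes(res, alpha=0.05, sign="negative")
        assert list(nodes.nodes.voxels.ravel()) == [True, False, False]
        assert nodes.sign == -1

    def test_positive_sign_on_negative_map_is_empty(self):
        res = stat_result([-3.0, -2.5], [0.01, 0.01])
        with pytest.raises(EmptyNodeMapError):
            derive_nodes(res, alpha=0.05, sign="positive")

    def test_degenerate_alpha_rejected(self):
        res = stat_result([-3.0], [0.01])
        with pytest.raises(ValueError, match="alpha"):
            derive_nodes(res, alpha=0.0)

    def test_fdr_correction_uses_q_values(self):
        res = stat_result([-3.0], [0.2])
        object.__setattr__(res, "q_fdr", np.array([0.01]))
        assert derive_nodes(res, correction="fdr").nodes.n_true == 1


class TestRiskScore:
    def test_lesion_equal_to_nodes_scores_strongly_negative(self, small_study):
        conn = small_study["connectome"]
        truth = small_study["truth"]
        nodes = NetworkNodeMap(truth.node, -1)
        score = risk_score(conn, truth.node, nodes)
        assert score == pytest.approx(-np.arctanh(1 - Z_CLAMP))

    def test_anticorrelated_lesion_scores_positive(self, small_study):
        # a lesion at the negative end of the loading gradient, nodes at +1
        conn = small_study["connectome"]
        truth = small_study["truth"]
        lesion = make_mask(conn.grid, [(2, 6, 6), (3, 6, 6)])  # loading < 0
        nodes = NetworkNodeMap(truth.node, -1)
        assert risk_score(conn, lesion, nodes) > 0


class TestLodoScores:
    def test_scores_never_use_own_dataset_nodes(self, small_study):
        table, folds = loo_risk_scores(
            small_study["cohort"], small_study["connectome"], n_perm=99, seed=0,
            network_values=small_study["network_values"],
        )
        for held_out, fold in folds.items():
            assert held_out not in fold["source_datasets"]
            assert set(fold["source_datasets"]) == (
                set(small_study["cohort"].datasets) - {held_out}
            )

    def test_two_datasets_swap_nodes(self, small_study):
        import dataclasses

        cohort = small_study["cohort"]
        half = len(cohort) // 2
        relabelled = type(cohort)(
            tuple(
                dataclasses.replace(rec, dataset="A" if i < half else "B")
                for i, rec in enumerate(cohort)
            )
        )
        _, folds = loo_risk_scores(
            relabelled, small_study["connectome"], n_perm=99, seed=0, alpha=0.5,
            correction="fdr", network_values=small_study["network_values"],
        )
        assert folds["A"]["source_datasets"] == ["B"]
        assert folds["B"]["source_datasets"] == ["A"]

    def test_deterministic_given_seed(self, small_study):
        a, _ = loo_risk_scores(
            small_study["cohort"], small_study["connectome"], n_perm=49, seed=3,
            network_values=small_study["network_values"], correction="fdr",
            alpha=0.2,
        )
        b, _ = loo_risk_scores(
            small_study["cohort"], small_study["connectome"], n_perm=49, seed=3,
            network_values=small_study["network_values"], correction="fdr",
            alpha=0.2,
        )
        assert a.equals(b)

    def test_single_dataset_rejected(self, small_study):
        cohort = small_study["cohort"]
        sub = cohort.subset(np.array([r.dataset == "stroke" for r in cohort]))
        with pytest.raises(ValueError, match="2 datasets"):
            loo_risk_scores(sub, small_study["connectome"])


class TestFitLogistic:
    def test_two_by_two_closed_form_odds_ratio(self):
        # exposed: 20 epilepsy / 10 not; unexposed: 10 / 20 -> OR = 4
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        x = np.r_[np.ones(30), np.zeros(30)]
        fit = fit_logistic(y, x, standardize=False)
        assert fit.or_per_sd == pytest.approx(4.0, abs=1e-4)
        assert fit.coefficients["score"] == pytest.approx(np.log(4), abs=1e-4)

    def test_null_score_or_near_one(self):
        rng = np.random.default_rng(21)
        y = rng.integers(0, 2, 500)
        s = rng.standard_normal(500)
        fit = fit_logistic(y, s)
        assert fit.ci[0] <= 1.0 <= fit.ci[1]

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        s = np.r_[np.ones(10), -np.ones(10)] + np.linspace(0, 0.1, 20)
        fit = fit_logistic(y, s)
        assert fit.separation and fit.or_per_sd is None

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(10), np.arange(10.0))

    def test_planted_effect_recovered_at_large_n(self):
        # logistic labels with ln(2.8) per SD; fitted OR within 15%
        rng = np.random.default_rng(30)
        s = rng.standard_normal(2000)
        p = 1 / (1 + np.exp(-(-0.619 + np.log(2.8) * s)))
        y = (rng.random(2000) < p).astype(float)
        fit = fit_logistic(y, s)
        assert fit.or_per_sd == pytest.approx(2.8, rel=0.15)


class TestStratify:
    def test_normal_scores_tail_proportions(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(20000)
        y = rng.integers(0, 2, 20000)
        table = stratify(s, y)
        frac = table.counts.sum(axis=0) / table.n
        assert frac[0] == pytest.approx(0.159, abs=0.015)
        assert frac[1] == pytest.approx(0.683, abs=0.015)
        assert frac[2] == pytest.approx(0.159, abs=0.015)

    def test_constant_scores_all_moderate(self):
        with pytest.warns(UserWarning, match="zero score SD"):
            table = stratify(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
        assert table.counts[:, 1].sum() == 10

    def test_exact_boundary_is_moderate(self):
        # mean 0, SD(ddof=1) = sqrt(2): +/- sqrt(2) sit exactly on the cutoffs
        s = np.array([1.0, np.sqrt(2), -1.0, -np.sqrt(2)])
        table = stratify(s, np.zeros(4, int))
        assert table.counts[0, 1] == 4  # everyone moderate
        assert table.counts[:, 0].sum() == 0 and table.counts[:, 2].sum() == 0

    def test_within_dataset_mode_stratifies_each_dataset_alone(self):
        rng = np.random.default_rng(6)
        s = np.r_[rng.standard_normal(30), rng.standard_normal(30) + 50]
        y = rng.integers(0, 2, 60)
        ds = np.r_[["a"] * 30, ["b"] * 30]
        within = stratify(s, y, ds, mode="within")
        parts = (
            stratify(s[:30], y[:30]).counts + stratify(s[30:], y[30:]).counts
        )
        assert np.array_equal(within.counts, parts)
        # pooled cutoffs instead split on the 50-point dataset offset
        pooled = stratify(s, y, ds, mode="pooled")
        assert not np.array_equal(pooled.counts, parts)


class TestChiSquareAndAuc:
    def test_uniform_table_is_zero(self):
        chi2, dof, p = chi_square([[10, 10], [10, 10]])
        assert chi2 == 0.0 and dof == 1 and p == pytest.approx(1.0)

    def test_closed_form_two_by_two(self):
        chi2, dof, _ = chi_square([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)
        assert dof == 1

    def test_two_by_three_df(self):
        assert chi_square([[5, 6, 7], [7, 6, 5]])[1] == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 5]])

    def test_auc_examples_and_flip(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)
        assert roc_auc([1, 0, 1], [1.0, 0.0, 0.9]) == 1.0
        assert roc_auc([1, 0, 1], [0.5, 0.5, 0.5]) == 0.5
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        s = rng.standard_normal(50)
        assert roc_auc(y, s) == pytest.approx(1.0 - roc_auc(y, -s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])
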