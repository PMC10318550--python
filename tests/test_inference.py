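"""Permutation inference: Welch V, Freedman-Lane, FWE/FDR, VLSM, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lesionnet import (
    BinaryMask,
    Cohort,
    DesignMatrix,
    LesionRecord,
    VolumeGrid,
    bh_fdr,
    permutation_group_test,
    residualize,
    vlsm_univariate,
    voxelwise_outcome_correlation,
    welch_v,
)

from .conftest import make_mask
from .oracles import brute_force_group_permutation


def mask_of(n_vox: int) -> BinaryMask:
    g = VolumeGrid.isotropic((n_vox, 1, 1), 2.0)
    return BinaryMask(g, np.ones(g.shape, bool))


class TestWelchV:
    def test_equal_samples_give_zero(self):
        v, df = welch_v([1, 2, 3], [1, 2, 3])
        assert v == 0.0
        assert df == pytest.approx(4.0)

    def test_textbook_example(self):
        v, df = welch_v([1, 2, 3, 4], [3, 4, 5, 6])
        assert v == pytest.approx(-2.19089, abs=1e-5)
        assert df == pytest.approx(6.0)

    def test_degenerate_zero_variance(self):
        v, df = welch_v([5, 5], [5, 5])
        assert v == 0.0 and np.isnan(df)
        v, df = welch_v([5, 5], [7, 7])
        assert np.isinf(v) and v < 0 and np.isnan(df)

    def test_matches_scipy_oracle_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            a = rng.standard_normal(rng.integers(2, 12))
            b = rng.standard_normal(rng.integers(2, 12)) * rng.uniform(0.5, 3)
            v, df = welch_v(a, b)
            t = sps.ttest_ind(a, b, equal_var=False)
            assert v == pytest.approx(t.statistic, abs=1e-10)
            assert df == pytest.approx(t.df, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.lists(st.floats(-5, 5), min_size=2, max_size=8))
    def test_antisymmetric_in_group_order(self, a, b):
        va, _ = welch_v(a, b)
        vb, _ = welch_v(b, a)
        if np.isfinite(va):
            assert va == pytest.approx(-vb, abs=1e-9)


class TestResidualize:
    def test_exact_linear_fit_leaves_zero(self):
        x = np.arange(10.0)
        y = 3.0 + 2.0 * x
        assert np.allclose(residualize(y, x), 0.0, atol=1e-10)

    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 6.0])
        assert np.allclose(residualize(y, None), y - 3.0)

    def test_orthogonal_nuisance_returns_centered_values(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(50)
        zc = z - z.mean()
        y = rng.standard_normal(50)
        y -= y.mean()
        y -= (y @ zc) / (zc @ zc) * zc  # orthogonal to span{1, z}
        assert np.allclose(residualize(y, z), y, atol=1e-10)

    def test_rank_deficient_raises(self):
        z = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            residualize(np.arange(6.0), z)


class TestBhFdr:
    def test_step_up_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_passes_through(self):
        assert bh_fdr(np.array([0.5]))[0] == 0.5

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 40))
            q = bh_fdr(p)
            q_ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, q_ref, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_monotone_and_order_preserving(self, p):
        p = np.array(p)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0) and np.all(q >= p - 1e-12)


class TestPermutationGroupTest:
    def test_two_vs_two_exhaustive_enumeration(self):
        values = np.array([[10.0], [11.0], [1.0], [2.0]])
        design = DesignMatrix(np.array([1, 1, 0, 0]))
        one = permutation_group_test(
            values, design, mask_of(1), n_perm=50, sidedness="greater"
        )
        assert one.exhaustive and one.n_perm == 24
        assert one.p_unc[0] == pytest.approx(1 / 6)
        two = permutation_group_test(values, design, mask_of(1), n_perm=50)
        assert two.p_unc[0] == pytest.approx(2 / 6)

    def test_fwe_dominates_uncorrected(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((12, 40))
        design = DesignMatrix(np.repeat([0, 1], 6), rng.standard_normal(12))
        res = permutation_group_test(values, design, mask_of(40), n_perm=200, seed=1)
        assert np.all(res.p_fwe >= res.p_unc)
        assert np.all(res.p_unc >= 1.0 / (1 + 200))

    def test_seed_fixes_every_output(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal((14, 20))
        design = DesignMatrix(np.repeat([0, 1], 7), rng.standard_normal(14))
        a = permutation_group_test(values, design, mask_of(20), n_perm=150, seed=5)
        b = permutation_group_test(values, design, mask_of(20), n_perm=150, seed=5)
        for f in ("stat", "p_unc", "p_fwe", "q_fdr"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_nuisance_effect_is_removed(self):
        # group difference entirely explained by the covariate -> null p
        rng = np.random.default_rng(10)
        g = np.repeat([0, 1], 10)
        z = g * 2.0 + rng.standard_normal(20) * 0.1
        values = np.outer(z, np.ones(5)) + rng.standard_normal((20, 5)) * 0.5
        res = permutation_group_test(
            values, DesignMatrix(g, z), mask_of(5), n_perm=199, seed=2
        )
        assert np.all(np.abs(res.stat) < 1.0)  # raw group gap is ~ 20 sigma
        assert np.all(res.p_fwe > 0.05)

    def test_roi_restricts_analysis(self):
        rng = np.random.default_rng(11)
        values = rng.standard_normal((12, 8))
        design = DesignMatrix(np.repeat([0, 1], 6))
        g = VolumeGrid.isotropic((8, 1, 1), 2.0)
        roi = make_mask(g, [(0, 0, 0), (3, 0, 0)])
        res = permutation_group_test(
            values, design, BinaryMask(g, np.ones(g.shape, bool)),
            n_perm=99, seed=0, roi=roi,
        )
        assert res.analysis_mask.n_true == 2


class TestVlsm:
    @staticmethod
    def _cohort(grid, lesion_flags, labels):
        records = []
        for i, (flag, lab) in enumerate(zip(lesion_flags, labels)):
            vox = [(0, 0, 0)] if flag else [(4, 4, 4)]
            records.append(
                LesionRecord(f"p{i}", "ds", make_mask(grid, vox + [(2, 2, i % 3)]), lab)
            )
        return Cohort(tuple(records))

    def test_perfectly_predictive_voxel_attains_max_stat(self, grid8):
        lesioned = [1] * 12 + [0] * 12
        labels = [1] * 12 + [0] * 12  # voxel lesioned exactly in epilepsy patients
        cohort = self._cohort(grid8, lesioned, labels)
        res = vlsm_univariate(cohort, (), min_lesioned=5, n_perm=199, seed=0)
        flat = res.analysis_mask.flat_indices()
        peak = flat[np.argmax(np.abs(np.nan_to_num(res.stat)))]
        assert peak == 0  # C-order flat index of voxel (0, 0, 0)

    def test_min_lesioned_excludes_rare_voxels(self, grid8):
        lesioned = [1, 1, 1] + [0] * 21
        labels = ([1, 0] * 12)[:24]
        cohort = self._cohort(grid8, lesioned, labels)
        res = vlsm_univariate(cohort, (), min_lesioned=5, n_perm=49, seed=0)
        assert 0 not in res.analysis_mask.flat_indices()

    def test_no_voxel_meets_threshold_raises(self, grid8):
        cohort = self._cohort(grid8, [1, 0, 1, 0], [1, 0, 1, 0])
        with pytest.raises(ValueError, match="min_lesioned|lesioned in"):
            vlsm_univariate(cohort, (), min_lesioned=20, n_perm=9, seed=0)


class TestOutcomeCorrelation:
    def test_outcome_equal_to_voxel_gives_r_one(self):
        rng = np.random.default_rng(13)
        values = rng.standard_normal((10, 6))
        outcome = values[:, 2].copy()
        res = voxelwise_outcome_correlation(
            values, outcome, mask_of(6), n_perm=99, seed=0
        )
        assert res.stat[2] == pytest.approx(1.0)
        assert res.stat_name == "r"

    def test_constant_outcome_raises(self):
        values = np.random.default_rng(0).standard_normal((8, 3))
        with pytest.raises(ValueError, match="constant"):
            voxelwise_outcome_correlation(values, np.ones(8), mask_of(3), n_perm=9)

    def test_null_outcome_pvalues_are_uniformish(self):
        rng = np.random.default_rng(14)
        values = rng.standard_normal((30, 60))
        outcome = rng.standard_normal(30)
        res = voxelwise_outcome_correlation(
            values, outcome, mask_of(60), n_perm=199, seed=3
        )
        assert 0.0 <= np.mean(res.p_unc <= 0.05) <= 0.15


@pytest.mark.parametrize("n,with_nuisance", [(5, False), (6, True), (7, True)])
def test_exhaustive_matches_independent_enumeration(n, with_nuisance):
    rng = np.random.default_rng(n)
    values = rng.standard_normal((n, 3))
    group = np.zeros(n, int)
    group[: n // 2] = 1
    rng.shuffle(group)
    nuisance = rng.standard_normal(n) if with_nuisance else None
    design = DesignMatrix(group, nuisance)
    res = permutation_group_test(
        values, design, mask_of(3), n_perm=5100, seed=0, sidedness="two"
    )
    assert res.exhaustive
    p_ref, fwe_ref = brute_force_group_permutation(values, group, nuisance, "two")
    assert np.allclose(res.p_unc, p_ref, atol=1e-12)
    assert np.allclose(res.p_fwe, fwe_ref, atol=1e-12)
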