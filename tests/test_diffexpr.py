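"""Permutation test, derived cutoffs, gap statistic and calling rules.

The exhaustive-null path is checked against an independent brute-force
enumerator that recomputes every label split with scipy's Welch t.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import permomics as pm
from conftest import make_matrix


def brute_force_pooled_pvalues(X, n_a):
    """Independent oracle: enumerate all C(n, n_a) splits, Welch t via scipy,
    pool across features, p = (1 + #{|t_null| >= |t_obs|}) / (1 + N)."""
    n = X.shape[1]
    null = []
    for combo in itertools.combinations(range(n), n_a):
        idx_a = list(combo)
        idx_b = [j for j in range(n) if j not in combo]
        t = sps.ttest_ind(X[:, idx_a], X[:, idx_b], axis=1, equal_var=False).statistic
        null.append(np.nan_to_num(t, nan=0.0))
    null = np.abs(np.concatenate(null))
    t_obs = sps.ttest_ind(X[:, :n_a], X[:, n_a:], axis=1, equal_var=False).statistic
    t_obs = np.abs(np.nan_to_num(t_obs, nan=0.0))
    return np.array([(1 + (null >= t).sum()) / (1 + null.size) for t in t_obs])


class TestObservedStats:
    def test_zero_variance_guard(self):
        m = make_matrix([[2, 2, 2, 1, 1, 1], [1, 1, 1, 1, 1, 1]])
        spec = pm.ComparisonSpec(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        out = pm.observed_stats(m, spec)
        assert out.loc["g000", "log2fc"] == 1.0
        assert out.loc["g000", "t"] == pm.diffexpr.T_SENTINEL
        assert out.loc["g001", "t"] == 0.0 and out.loc["g001", "log2fc"] == 0.0

    def test_hand_welch_oracle(self):
        m = make_matrix([[3, 4, 5, 1, 2, 3]])
        spec = pm.ComparisonSpec(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        out = pm.observed_stats(m, spec)
        assert out.loc["g000", "log2fc"] == pytest.approx(2.0)
        assert out.loc["g000", "t"] == pytest.approx(2 * math.sqrt(3 / 2))

    def test_label_swap_antisymmetry(self, null_matrix_3v3, spec_3v3):
        fwd = pm.observed_stats(null_matrix_3v3, spec_3v3)
        swapped = pm.ComparisonSpec(spec_3v3.group_b, spec_3v3.group_a,
                                    spec_3v3.n_permutations, spec_3v3.seed)
        rev = pm.observed_stats(null_matrix_3v3, swapped)
        np.testing.assert_allclose(rev["log2fc"], -fwd["log2fc"])
        np.testing.assert_allclose(rev["t"], -fwd["t"])

    def test_small_group_rejected(self):
        with pytest.raises(pm.PermomicsError):
            pm.ComparisonSpec(["s0"], ["s1", "s2"])


class TestBuildNull:
    def test_exhaustive_3v3_is_20_assignments(self, null_matrix_3v3, spec_3v3):
        null = pm.build_null(null_matrix_3v3, spec_3v3)
        assert null.exhaustive
        assert null.n_permutations == 20
        assert null.size == 20 * null_matrix_3v3.n_features

    def test_sampled_mode_seed_reproducible(self, null_matrix_3v3):
        spec = pm.ComparisonSpec(["s0", "s1", "s2"], ["s3", "s4", "s5"],
                                 n_permutations=50, seed=5,
                                 exhaustive_if_possible=False)
        n1 = pm.build_null(null_matrix_3v3, spec)
        n2 = pm.build_null(null_matrix_3v3, spec)
        assert not n1.exhaustive
        np.testing.assert_array_equal(n1.t, n2.t)

    def test_single_feature_exhaustive_extreme_split(self):
        """Values [1,2,3 | 4,5,6]: the observed split and its mirror are the
        two most extreme of the 20, so p = (1+2)/(1+20) under add-one."""
        m = make_matrix([[1, 2, 3, 4, 5, 6]])
        spec = pm.ComparisonSpec(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        stats = pm.observed_stats(m, spec)
        null = pm.build_null(m, spec)
        out = pm.empirical_pvalues(stats, null)
        assert out["p_empirical"].iloc[0] == pytest.approx(3 / 21)


class TestEmpiricalPvalues:
    def test_oracle_equivalence_exhaustive(self):
        """Pooled exhaustive p equals the brute-force enumerator exactly."""
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (40, 6))
        X[:4, :3] += 2.0  # a few real effects
        m = make_matrix(X)
        spec = pm.ComparisonSpec(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        out = pm.empirical_pvalues(pm.observed_stats(m, spec), pm.build_null(m, spec))
        expected = brute_force_pooled_pvalues(X, 3)
        np.testing.assert_allclose(out["p_empirical"], expected)

    def test_extreme_observation(self):
        stats = pd.DataFrame({"t": [100.0]}, index=["g0"])
        null = pm.NullDistribution(t=np.arange(10000) / 10000.0,
                                   log2fc=np.zeros(1), n_permutations=1,
                                   exhaustive=False, seed=0)
        out = pm.empirical_pvalues(stats, null)
        assert out["p_empirical"].iloc[0] == pytest.approx(1 / 10001)

    def test_zero_statistic_gets_p_one(self):
        stats = pd.DataFrame({"t": [0.0]}, index=["g0"])
        null = pm.NullDistribution(t=np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
                                   log2fc=np.zeros(1), n_permutations=1,
                                   exhaustive=False, seed=0)
        assert pm.empirical_pvalues(stats, null)["p_empirical"].iloc[0] == 1.0

    def test_count_by_hand_toy_null(self):
        stats = pd.DataFrame({"t": [1.5]}, index=["g0"])
        null = pm.NullDistribution(t=np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
                                   log2fc=np.zeros(1), n_permutations=1,
                                   exhaustive=False, seed=0)
        assert pm.empirical_pvalues(stats, null)["p_empirical"].iloc[0] == pytest.approx(0.5)

    def test_swap_leaves_p_unchanged(self, null_matrix_3v3, spec_3v3):
        out = pm.empirical_pvalues(pm.observed_stats(null_matrix_3v3, spec_3v3),
                                   pm.build_null(null_matrix_3v3, spec_3v3))
        swapped = pm.ComparisonSpec(spec_3v3.group_b, spec_3v3.group_a)
        out2 = pm.empirical_pvalues(pm.observed_stats(null_matrix_3v3, swapped),
                                    pm.build_null(null_matrix_3v3, swapped))
        np.testing.assert_allclose(out["p_empirical"], out2["p_empirical"])


class TestDeriveFcCutoff:
    def test_mean_of_magnitudes(self):
        # q2.5=-0.30, q97.5=+0.26 -> 0.28 (built from a two-point distribution)
        vals = np.array([-0.30] * 500 + [0.26] * 500)
        assert pm.derive_fc_cutoff(vals, 2.5, 97.5) == pytest.approx(0.28, abs=1e-6)

    def test_standard_normal_cutoff(self):
        rng = np.random.default_rng(0)
        cutoff = pm.derive_fc_cutoff(rng.normal(0, 1, 10000))
        assert cutoff == pytest.approx(1.96, abs=0.05)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_sign_flip_invariance(self, seed):
        vals = np.random.default_rng(seed).normal(0.3, 1, 500)
        assert pm.derive_fc_cutoff(vals) == pytest.approx(pm.derive_fc_cutoff(-vals))

    def test_empty_null_rejected(self):
        with pytest.raises(pm.PermomicsError):
            pm.derive_fc_cutoff(np.array([]))


class TestGap:
    @pytest.mark.parametrize("a,b,expected", [
        ([5, 6, 7], [1, 2, 3], 2.0),       # separated ranges
        ([4, 6, 7], [1, 5, 3], -1.0),      # overlapping ranges
        ([1, 2, 3], [1, 2, 3], -2.0),      # identical groups: -(range), a high on tie
    ])
    def test_gap_values(self, a, b, expected):
        assert pm.compute_gap(a, b) == expected

    def test_vectorized_matches_scalar(self, null_matrix_3v3, spec_3v3):
        gaps = pm.compute_gaps(null_matrix_3v3, spec_3v3)
        X = null_matrix_3v3.values
        for fid in list(X.index[:10]):
            a = X.loc[fid, spec_3v3.group_a].to_numpy()
            b = X.loc[fid, spec_3v3.group_b].to_numpy()
            assert gaps[fid] == pytest.approx(pm.compute_gap(a, b))

    def test_gap_cutoff_hand_percentiles(self):
        assert pm.derive_gap_cutoff([0.02, 0.05, 0.07, 0.10]) == pytest.approx(0.06)

    def test_gap_cutoff_degenerate_cases(self):
        assert pm.derive_gap_cutoff([0.4, 0.4, 0.4]) == pytest.approx(0.4)
        c = pm.derive_gap_cutoff([0.1, 0.5])
        assert 0.1 <= c <= 0.5


class TestCallFeatures:
    @pytest.fixture
    def deg_cutoffs(self):
        return pm.CutoffSet(p_cutoff=0.05, fc_cutoff=0.58)

    def test_up_call(self, deg_cutoffs):
        stats = pd.DataFrame({"log2fc": [0.60], "p_empirical": [0.04]}, index=["g0"])
        assert pm.call_features(stats, deg_cutoffs)["call"].iloc[0] == "up"

    def test_boundary_fc_is_ns(self, deg_cutoffs):
        stats = pd.DataFrame({"log2fc": [0.58], "p_empirical": [0.04]}, index=["g0"])
        assert pm.call_features(stats, deg_cutoffs)["call"].iloc[0] == "ns"

    def test_boundary_p_is_ns(self, deg_cutoffs):
        stats = pd.DataFrame({"log2fc": [1.0], "p_empirical": [0.05]}, index=["g0"])
        assert pm.call_features(stats, deg_cutoffs)["call"].iloc[0] == "ns"

    def test_gap_stage_filters(self):
        cutoffs = pm.CutoffSet(p_cutoff=0.2, fc_cutoff=0.28,
                               gap_cutoff=0.06, gap_mode="quartile_mean")
        stats = pd.DataFrame({"log2fc": [0.30, -0.30], "p_empirical": [0.15, 0.15],
                              "gap": [0.05, 0.10]}, index=["g0", "g1"])
        out = pm.call_features(stats, cutoffs)
        assert out.loc["g0", "call"] == "ns"     # fails gap stage
        assert out.loc["g1", "call"] == "down"   # |gap| passes

    def test_stage2_subset_of_stage1(self):
        rng = np.random.default_rng(3)
        n = 200
        stats = pd.DataFrame({
            "log2fc": rng.normal(0, 0.5, n),
            "p_empirical": rng.uniform(0.001, 1, n),
            "gap": rng.normal(0, 0.1, n),
        }, index=[f"g{i}" for i in range(n)])
        stage1 = pm.call_features(stats, pm.CutoffSet(0.2, 0.28))
        stage2 = pm.call_features(stats, pm.CutoffSet(0.2, 0.28, gap_cutoff=0.06,
                                                      gap_mode="quartile_mean"))
        s1 = set(stage1.index[stage1["call"] != "ns"])
        s2 = set(stage2.index[stage2["call"] != "ns"])
        assert s2 <= s1


class TestRunComparison:
    def test_deg_postcondition_audit(self):
        design = pm.SimDesign(n_features=500, frac_up=0.05, frac_down=0.05,
                              effect_log2fc=1.0, noise_sd=0.25, seed=7)
        m, _ = pm.generate_expression(design)
        sub = m.subset_samples(m.samples_where(cell_type="CT1"))
        norm = pm.quantile_normalize(pm.log_transform(pm.filter_expressed(sub)))
        spec = pm.ComparisonSpec(
            group_a=norm.samples_where(condition="treated"),
            group_b=norm.samples_where(condition="control"),
            n_permutations=1000, seed=7)
        stats, cutoffs, _ = pm.run_comparison(norm, spec, preset="deg")
        called = stats[stats["call"] != "ns"]
        assert (called["p_empirical"] < 0.05).all()
        assert (called["log2fc"].abs() > 0.58).all()
        assert (called.loc[called["call"] == "up", "log2fc"] > 0).all()

    def test_dep_null_only_small_nested_sets(self):
        """On an all-null proteome the stage-2 set nests in stage-1, both small."""
        frac1, frac2 = [], []
        for seed in range(10):
            design = pm.protein_design(n_features=300, frac_up=0.0, frac_down=0.0,
                                       n_cell_types=1, seed=seed)
            m, _ = pm.generate_proteome(design, 0.0)
            spec = pm.ComparisonSpec(
                group_a=m.samples_where(condition="treated"),
                group_b=m.samples_where(condition="control"),
                n_permutations=500, seed=seed)
            stats, cutoffs, _ = pm.run_comparison(m, spec, preset="dep")
            stage1 = (stats["p_empirical"] < cutoffs.p_cutoff) & \
                     (stats["log2fc"].abs() > cutoffs.fc_cutoff)
            stage2 = stats["call"] != "ns"
            assert set(stats.index[stage2]) <= set(stats.index[stage1])
            frac1.append(stage1.mean())
            frac2.append(stage2.mean())
        assert np.mean(frac1) < 0.2
        assert np.mean(frac2) <= np.mean(frac1)

    def test_preset_layer_mismatch(self, null_matrix_3v3, spec_3v3):
        with pytest.raises(pm.LayerMismatchError):
            pm.run_comparison(null_matrix_3v3, spec_3v3, preset="deg")

    def test_parameter_recovery(self):
        """Planted |log2FC|=1 at noise 0.25, 3v3: sensitivity >= 0.8 and mean
        observed log2FC within +-0.2 of planted, across 10 seeds."""
        sens, biases = [], []
        for seed in range(10):
            design = pm.SimDesign(n_features=400, frac_up=0.05, frac_down=0.05,
                                  effect_log2fc=1.0, noise_sd=0.25,
                                  n_cell_types=1, frac_expressed=1.0, seed=seed)
            m, truth = pm.generate_expression(design)
            norm = pm.quantile_normalize(pm.log_transform(m))
            spec = pm.ComparisonSpec(
                group_a=norm.samples_where(condition="treated"),
                group_b=norm.samples_where(condition="control"),
                n_permutations=1000, seed=seed)
            stats, _, _ = pm.run_comparison(norm, spec, preset="deg")
            tr = truth.set_index("feature_id")
            planted = tr.index[tr["direction"] != "null"]
            called = set(stats.index[stats["call"] != "ns"])
            sens.append(len(called & set(planted)) / len(planted))
            obs = stats.loc[planted, "log2fc"]
            signed_err = obs - tr.loc[planted, "planted_log2fc"]
            biases.append(signed_err.mean())
        assert np.mean(sens) >= 0.8
        assert abs(np.mean(biases)) <= 0.2
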