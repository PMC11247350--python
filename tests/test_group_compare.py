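import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyevo.io_model import Cohort
from polyevo import group_compare as gc


def _ks_brute(a, b):
    """Independent oracle: maximum gap between the two empirical CDFs."""
    grid = np.concatenate([a, b])
    return max(abs((a <= v).mean() - (b <= v).mean()) for v in grid)


class TestTopBottomSets:
    def test_two_of_ten(self):
        p = pd.DataFrame({"t": [0.01, 0.9, 0.5, 0.02, 0.8, 0.3, 0.4, 0.6, 0.7, 0.95]},
                         index=[f"g{i}" for i in range(10)])
        top, bottom = gc.top_bottom_sets(p, "t", 2)
        assert set(top) == {"g0", "g3"}
        assert set(bottom) == {"g1", "g9"}
        assert len(set(top) & set(bottom)) == 0

    @pytest.mark.parametrize("k", [5000, 1000, 500, 50])
    def test_sensitivity_grid_sizes_accepted(self, small_cohort, k):
        cohort, _, _ = small_cohort
        if k > len(cohort.assoc) // 2:
            with pytest.raises(ValueError):
                gc.top_bottom_sets(cohort.assoc, cohort.assoc.columns[0], k)
        else:
            top, bottom = gc.top_bottom_sets(cohort.assoc, cohort.assoc.columns[0], k)
            assert len(top) == len(bottom) == k

    def test_boundary_ties_resolved_lexicographically(self):
        p = pd.DataFrame({"t": [0.1, 0.1, 0.1, 0.9, 0.9, 0.9]},
                         index=["gB", "gA", "gC", "gZ", "gX", "gY"])
        top1, _ = gc.top_bottom_sets(p, "t", 2)
        top2, _ = gc.top_bottom_sets(p.iloc[::-1], "t", 2)
        assert list(top1) == ["gA", "gB"] == list(top2)


class TestKSCompare:
    def test_identical_samples_have_zero_distance(self):
        v = np.arange(20.0)
        D, _ = gc.ks_compare(v, v)
        assert D == 0.0

    def test_disjoint_supports_have_distance_one(self):
        D, p = gc.ks_compare(np.arange(10.0), np.arange(100.0, 110.0))
        assert D == 1.0 and p < 1e-4

    def test_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=rng.integers(5, 200))
            b = rng.normal(0.3, 1.2, size=rng.integers(5, 200))
            D, _ = gc.ks_compare(a, b)
            assert abs(D - _ks_brute(a, b)) < 1e-12

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            gc.ks_compare([], [1.0, 2.0])


class TestTissueWiseTests:
    def test_planted_shift_in_one_tissue_is_most_significant(self, small_cohort):
        cohort, _, _ = small_cohort
        rng = np.random.default_rng(0)
        genes = cohort.genes.copy()
        top = cohort.genes.index[:300]
        bottom = cohort.genes.index[300:600]
        shifted = genes.copy()
        shifted.loc[top, "tpm_brain"] = shifted.loc[top, "tpm_brain"] + 50.0
        shifted_cohort = Cohort(genes=shifted, assoc=cohort.assoc, traits=cohort.traits)
        table = gc.tissue_wise_tests(shifted_cohort, top, bottom)
        assert table["p"].idxmin() == "brain"
        assert table["bonferroni_m"].iloc[0] == len(table)
        # flags recompute exactly as p < alpha/m
        assert table["significant"].equals(table["p"] < 0.05 / len(table))

    def test_null_sets_rarely_significant(self, small_cohort):
        cohort, _, _ = small_cohort
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(5):
            ids = rng.permutation(cohort.genes.index.to_numpy())
            table = gc.tissue_wise_tests(cohort, pd.Index(ids[:400]), pd.Index(ids[400:800]))
            rates.append((table["p"] < 0.05).mean())
        assert np.mean(rates) < 0.15  # ~5% nominal, wide guard band


class TestDecileSimilarity:
    def test_selection_from_decile_six_is_similar_to_it(self):
        rng = np.random.default_rng(4)
        values = pd.Series(rng.uniform(size=2000),
                           index=[f"g{i}" for i in range(2000)])
        from polyevo.io_model import assign_deciles
        deciles = pd.Series(assign_deciles(values.to_numpy()), index=values.index)
        members = values.index[deciles == 6][:80]
        z = pd.Series(0.0, index=values.index)
        z[members] = 1.0
        table = gc.decile_similarity(values, z, z_cut=0.5)
        assert bool(table.loc[6, "similar"])
        assert not bool(table.loc[1, "similar"])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(size=1000), index=[f"g{i}" for i in range(1000)])
        z = pd.Series(rng.normal(size=1000), index=values.index)
        t1 = gc.decile_similarity(values, z, z_cut=1.0)
        t2 = gc.decile_similarity(np.exp(values), z, z_cut=1.0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_selection_advises_lower_cut(self):
        values = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        z = pd.Series(0.0, index=values.index)
        with pytest.raises(ValueError, match="z_cut"):
            gc.decile_similarity(values, z, z_cut=5.0)


class TestVarianceCompare:
    def test_identical_samples_give_unit_ratio(self):
        v = np.random.default_rng(0).normal(size=50)
        f, p = gc.variance_compare(v, v)
        assert f == 1.0

    def test_doubling_scale_quarters_the_ratio(self):
        a = np.random.default_rng(1).normal(size=200)
        b = 2.0 * (a - a.mean())
        f, _ = gc.variance_compare(a, b)
        assert abs(f - 0.25) < 1e-12

    def test_p_matches_beta_incomplete_oracle(self):
        from scipy.special import betainc
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=40), rng.normal(size=60)
        f, p = gc.variance_compare(a, b)
        d1, d2 = 39, 59
        cdf = betainc(d1 / 2, d2 / 2, d1 * f / (d1 * f + d2))
        assert abs(p - 2 * min(cdf, 1 - cdf)) < 1e-10

    def test_zero_denominator_variance_raises(self):
        with pytest.raises(ValueError):
            gc.variance_compare([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestDensityModes:
    def test_unimodal_sample_has_one_mode_near_center(self):
        rng = np.random.default_rng(6)
        vals = 10 ** rng.normal(0.2, 0.1, size=1000)
        modes = gc.density_modes(vals)
        assert len(modes) == 1
        assert abs(np.log10(modes[0]) - 0.2) < 0.1

    def test_planted_bimodal_rates_recovered(self):
        # low/high evolutionary-rate regimes around 0.15 and 1.26
        rng = np.random.default_rng(7)
        lo = 10 ** (np.log10(0.15) + 0.08 * rng.normal(size=500))
        hi = 10 ** (np.log10(1.26) + 0.08 * rng.normal(size=500))
        modes = gc.density_modes(np.concatenate([lo, hi]))
        assert len(modes) == 2
        top2 = sorted(modes[:2])
        assert abs(top2[0] - 0.15) / 0.15 < 0.2
        assert abs(top2[1] - 1.26) / 1.26 < 0.2

    def test_constant_vector_is_its_own_mode(self):
        assert gc.density_modes(np.full(50, 0.4)) == [pytest.approx(0.4)]


class TestMonogenicOverlap:
    def _cohort(self, mono_ids, dnds):
        genes = pd.DataFrame({
            "length": 1000, "dnds": dnds,
            "tpm_brain": 1.0,
            "is_monogenic": [g in mono_ids for g in dnds.index],
        }, index=dnds.index)
        assoc = pd.DataFrame({"t": 0.5}, index=dnds.index)
        traits = pd.DataFrame({"domain": ["other"], "n_participants": [1000]},
                              index=pd.Index(["t"], name="trait_id"))
        return Cohort(genes=genes, assoc=assoc, traits=traits)

    def test_disjoint_lists_leave_results_unchanged(self):
        rng = np.random.default_rng(8)
        ids = pd.Index([f"g{i}" for i in range(200)])
        dnds = pd.Series(rng.uniform(0.05, 1.5, 200), index=ids)
        cohort = self._cohort(set(ids[:50]), dnds)
        res = gc.monogenic_overlap(cohort, ids[100:150])
        assert len(res.overlap) == 0
        assert res.rank_sum == res.rank_sum_excluded
        assert res.variance == res.variance_excluded

    def test_contained_list_shrinks_selection_by_its_size(self):
        rng = np.random.default_rng(9)
        ids = pd.Index([f"g{i}" for i in range(200)])
        dnds = pd.Series(rng.uniform(0.05, 1.5, 200), index=ids)
        cohort = self._cohort(set(ids[:20]), dnds)
        selection = ids[:100]
        res = gc.monogenic_overlap(cohort, selection)
        assert len(res.overlap) == 20

    def test_equal_center_inflated_variance_detected(self):
        # mirrors the qualitative finding: no location shift, excess spread
        for seed in (10, 11, 12):
            rng = np.random.default_rng(seed)
            ids = pd.Index([f"g{i}" for i in range(600)])
            dnds = pd.Series(0.0, index=ids, dtype=float)
            dnds.iloc[:300] = rng.normal(0.5, 0.05, 300)       # monogenic-like
            dnds.iloc[300:] = rng.normal(0.5, 0.4, 300)        # top-set-like
            cohort = self._cohort(set(ids[:300]), dnds.clip(lower=0.01))
            res = gc.monogenic_overlap(cohort, ids[300:])
            assert res.rank_sum[1] > 0.05
            assert res.variance[1] < 0.05
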