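import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyevo import selection_signatures as sel
from polyevo.io_model import Cohort


def _cohort_from(dnds, tpm, assoc=None):
    ids = pd.Index([f"g{i}" for i in range(len(dnds))], name="gene_id")
    genes = pd.DataFrame({"length": 1000, "dnds": np.asarray(dnds, dtype=float),
                          "tpm_brain": np.asarray(tpm, dtype=float),
                          "is_monogenic": False}, index=ids)
    if assoc is None:
        assoc = pd.DataFrame({"t": 0.5}, index=ids)
    traits = pd.DataFrame({"domain": ["other"] * assoc.shape[1],
                           "n_participants": 1000},
                          index=pd.Index(assoc.columns, name="trait_id"))
    return Cohort(genes=genes, assoc=assoc, traits=traits)


class TestLoess:
    def test_noiseless_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 3, 500)            # log expression
        dnds = 10 ** (-0.2 - 0.3 * x)         # exact curve, no noise
        cohort = _cohort_from(dnds, 10 ** x - 1)
        res = sel.loess_rate_on_expression(cohort)
        assert np.abs(res["residual"]).max() < 0.02

    def test_constant_rate_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        cohort = _cohort_from(np.full(300, 0.4), rng.uniform(0, 50, 300))
        res = sel.loess_rate_on_expression(cohort)
        assert np.abs(res["residual"]).max() < 1e-10

    def test_residuals_average_to_zero(self, small_cohort):
        cohort, _, _ = small_cohort
        res = sel.loess_rate_on_expression(cohort)
        assert abs(res["residual"].mean()) < 0.01

    def test_planted_offset_subset_recovered(self):
        rng = np.random.default_rng(2)
        n, delta = 4000, 0.3
        x = rng.uniform(0, 3, n)
        log_dnds = -0.2 - 0.3 * x + 0.05 * rng.normal(size=n)
        subset = rng.choice(n, size=n // 20, replace=False)
        log_dnds[subset] += delta
        cohort = _cohort_from(10 ** log_dnds, 10 ** x - 1)
        res = sel.loess_rate_on_expression(cohort)
        got = res["residual"].iloc[subset].mean()
        assert abs(got - delta) / delta < 0.2

    def test_shift_of_all_rates_leaves_residuals_unchanged(self, small_cohort):
        cohort, _, _ = small_cohort
        res1 = sel.loess_rate_on_expression(cohort)
        genes2 = cohort.genes.copy()
        genes2["dnds"] = genes2["dnds"] * 10.0  # +1 on the log10 scale
        cohort2 = Cohort(genes=genes2, assoc=cohort.assoc, traits=cohort.traits)
        res2 = sel.loess_rate_on_expression(cohort2)
        np.testing.assert_allclose(res1["residual"], res2["residual"], atol=1e-8)

    def test_invalid_span_raises(self, small_cohort):
        cohort, _, _ = small_cohort
        with pytest.raises(ValueError, match="span"):
            sel.loess_rate_on_expression(cohort, span=1.5)


class TestTraitMeanResidual:
    def test_uniformly_drawn_set_is_null(self):
        rng = np.random.default_rng(3)
        n = 3000
        x = rng.uniform(0, 3, n)
        dnds = 10 ** (-0.2 - 0.3 * x + 0.2 * rng.normal(size=n))
        p = pd.Series(0.5, index=[f"g{i}" for i in range(n)])
        p.iloc[rng.choice(n, 200, replace=False)] = 1e-9
        cohort = _cohort_from(dnds, 10 ** x - 1, assoc=p.to_frame("t"))
        res = sel.loess_rate_on_expression(cohort)["residual"]
        out = sel.trait_mean_residual(res, cohort, "t")
        se = res.std() / np.sqrt(out["n_genes"])
        assert abs(out["mean_residual"]) < 3 * se

    def test_too_few_genes_skips(self, small_cohort):
        cohort, _, _ = small_cohort
        res = sel.loess_rate_on_expression(cohort)["residual"]
        out = sel.trait_mean_residual(res, cohort, cohort.assoc.columns[0],
                                      p_cut=1e-250, min_genes=50)
        assert out is None

    def test_planted_domains_have_opposite_signs(self, small_cohort):
        """Immune-like traits sit above the loess curve, metabolic below."""
        cohort, _, _ = small_cohort
        table = sel.residual_summary(cohort, min_genes=20)
        by_domain = table.groupby("domain")["mean_residual"].mean()
        assert by_domain["immunological"] > 0 > by_domain["metabolic"]
        assert (table.loc[table["domain"] == "immunological", "p"] < 0.001).mean() > 0.5


class TestPurifyingFraction:
    def test_direct_sum(self):
        assert sel.purifying_fraction([(0.7, 0.1), (0.3, 2.0)]) == pytest.approx(0.7)

    def test_all_purifying_classes(self):
        assert sel.purifying_fraction([(0.5, 0.1), (0.5, 0.9)]) == pytest.approx(1.0)

    def test_random_mixture_matches_masked_sum(self):
        rng = np.random.default_rng(4)
        props = rng.dirichlet(np.ones(5))
        omegas = rng.uniform(0, 2, 5)
        got = sel.purifying_fraction(list(zip(props, omegas)))
        assert got == pytest.approx(props[omegas < 1].sum())

    def test_invariant_to_order_and_splitting(self):
        classes = [(0.6, 0.2), (0.4, 1.5)]
        split = [(0.3, 0.2), (0.3, 0.2), (0.4, 1.5)]
        assert sel.purifying_fraction(classes) == pytest.approx(
            sel.purifying_fraction(classes[::-1]))
        assert sel.purifying_fraction(classes) == pytest.approx(
            sel.purifying_fraction(split))

    def test_malformed_mixture_raises(self):
        with pytest.raises(ValueError):
            sel.purifying_fraction([(0.5, 0.1), (0.3, 2.0)])

    def test_long_table_matches_per_gene_calls(self, small_cohort):
        cohort, _, _ = small_cohort
        frac = sel.purifying_fractions(cohort.site_classes)
        g = cohort.site_classes["gene_id"].iloc[0]
        rows = cohort.site_classes[cohort.site_classes["gene_id"] == g]
        assert frac[g] == pytest.approx(
            sel.purifying_fraction(list(zip(rows["proportion"], rows["omega"]))))


class TestDirectionOfSelection:
    def test_neutral_counts_give_zero(self):
        assert sel.direction_of_selection(2, 2, 2, 2) == 0.0

    def test_extreme_purifying_bound(self):
        assert sel.direction_of_selection(0, 5, 5, 0) == -1.0

    def test_direct_arithmetic(self):
        assert sel.direction_of_selection(10, 5, 2, 8) == pytest.approx(10 / 15 - 2 / 10)

    def test_zero_denominators_are_missing(self):
        assert np.isnan(sel.direction_of_selection(0, 0, 2, 2))
        assert np.isnan(sel.direction_of_selection(2, 2, 0, 0))

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            sel.direction_of_selection(-1, 2, 2, 2)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_antisymmetric_under_divergence_polymorphism_swap(self, counts):
        dn, ds, pn, ps = counts
        a = sel.direction_of_selection(dn, ds, pn, ps)
        b = sel.direction_of_selection(pn, ps, dn, ds)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(-b)


class TestDosTraitRanking:
    def test_immunological_tops_ranking(self, small_cohort):
        cohort, _, _ = small_cohort
        for daf_min in (0.60, 0.30):
            out = sel.dos_trait_ranking(cohort, daf_min=daf_min, top_n=5)
            top = out["scores"].head(5)["trait_id"]
            domains = cohort.traits.loc[top, "domain"]
            assert (domains == "immunological").mean() > 0.5

    def test_degenerate_daf_filter_skips_everything(self, small_cohort):
        cohort, _, _ = small_cohort
        out = sel.dos_trait_ranking(cohort, daf_min=1.0)
        assert len(out["scores"]) == 0
        assert len(out["skipped"]) == len(cohort.assoc.columns)

    def test_all_negative_dos_gives_zero_fractions(self):
        rng = np.random.default_rng(5)
        n = 500
        ids = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
        poly = pd.DataFrame({"Dn": 0, "Ds": 5, "Pn": 5, "Ps": 5,
                             "daf": rng.uniform(0.5, 1.0, n)}, index=ids)
        p = pd.Series(1e-9, index=ids)
        cohort = _cohort_from(np.full(n, 0.3), np.full(n, 5.0), assoc=p.to_frame("t"))
        cohort.polymorphism = poly
        out = sel.dos_trait_ranking(cohort, daf_min=0.3)
        assert (out["scores"]["frac_positive_dos"] == 0).all()


class TestPowerAdjustedEnrichment:
    def test_constant_power_residuals_are_centered(self):
        rng = np.random.default_rng(6)
        idx = pd.Index([f"t{i}" for i in range(40)], name="trait_id")
        prof = pd.DataFrame({"R_exp": rng.normal(0.1, 0.05, 40),
                             "R_rate": rng.normal(-0.1, 0.05, 40),
                             "domain": ["metabolic"] * 20 + ["other"] * 20}, index=idx)
        traits = pd.DataFrame({"n_participants": 100000}, index=idx)
        out = sel.power_adjusted_enrichment(prof, traits, top_n=10)
        np.testing.assert_allclose(out["residuals"]["res_exp"],
                                   prof["R_exp"] - prof["R_exp"].mean(), atol=1e-12)

    def test_power_confounding_is_removed(self):
        # domain X's large R_exp is entirely explained by larger GWASs
        rng = np.random.default_rng(7)
        n = 120
        idx = pd.Index([f"t{i}" for i in range(n)], name="trait_id")
        domain = np.array(["X"] * 60 + ["Y"] * 60)
        power = np.where(domain == "X", 6.0, 4.0) + rng.uniform(-0.2, 0.2, n)
        r_exp = 0.05 + 0.10 * (power - 4.0) + 0.01 * rng.normal(size=n)
        r_rate = 0.02 + 0.05 * (power - 4.0) + 0.01 * rng.normal(size=n)
        prof = pd.DataFrame({"R_exp": r_exp, "R_rate": r_rate, "domain": domain},
                            index=idx)
        traits = pd.DataFrame({"n_participants": (10 ** power).astype(int)}, index=idx)

        naive = prof.assign(score=(prof["R_exp"] * prof["R_rate"]).abs())
        fg = naive.sort_values("score", ascending=False).head(30)
        from polyevo.resampling import domain_enrichment
        unadjusted = domain_enrichment(fg["domain"], prof["domain"])
        adjusted = sel.power_adjusted_enrichment(prof, traits, top_n=30,
                                                 span=0.9)["high_exp_high_rate"]
        assert unadjusted.loc["X", "p"] < 0.01
        assert adjusted.loc["X", "p"] > 0.01
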