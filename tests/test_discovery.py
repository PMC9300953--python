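import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from sighub.discovery import (HubSignature, HubSignatureDiscovery,
                              assign_quartiles, build_hub_signature,
                              category_enrichment, coexpression_list,
                              coexpression_table, contrast_filter,
                              expand_phosphosubstrates, signaling_intersect,
                              stratify_by_seed, survival_filter, top_quartile)
from sighub.errors import DegenerateInputError, ParameterError


def toy_expr(n_samples=12, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.uniform(1, 100, size=(5, n_samples))
    return pd.DataFrame(data, index=[f"g{i}" for i in range(5)],
                        columns=[f"s{i}" for i in range(n_samples)])


class TestStratify:
    def test_510_samples_split_255_each(self):
        expr = toy_expr(510)
        low, high = stratify_by_seed(expr, "g0")
        assert len(low) == len(high) == 255
        assert set(low) | set(high) == set(expr.columns)
        assert not set(low) & set(high)

    def test_five_samples_split_3_2(self):
        low, high = stratify_by_seed(toy_expr(5), "g0")
        assert (len(low), len(high)) == (3, 2)

    def test_constant_seed_rejected(self):
        expr = toy_expr(8)
        expr.loc["g0"] = 1.0
        with pytest.raises(DegenerateInputError):
            stratify_by_seed(expr, "g0")

    def test_absent_seed_rejected(self):
        with pytest.raises(KeyError):
            stratify_by_seed(toy_expr(), "nope")


class TestCoexpression:
    def test_duplicated_seed_row_ranks_first(self):
        expr = toy_expr(20)
        expr.loc["twin"] = expr.loc["g0"]
        rho = coexpression_list(expr, "g0")
        assert rho["twin"] == 1.0
        assert rho.idxmax() == "twin"

    def test_seed_excluded(self):
        rho = coexpression_list(toy_expr(), "g0")
        assert "g0" not in rho.index

    def test_constant_gene_gets_nan_and_is_unranked(self):
        expr = toy_expr(15)
        expr.loc["flat"] = 7.0
        rho = coexpression_list(expr, "g0")
        assert np.isnan(rho["flat"])
        assert assign_quartiles(rho)["flat"] == 0

    def test_planted_partners_outrank_background(self, planted_cohort):
        params, expr, _, _, truth = planted_cohort
        high = sorted(truth.high_samples)
        rho = coexpression_list(expr, params.seed_gene, high)
        top = top_quartile(rho)
        assert truth.partner_genes <= top

    def test_anticorrelated_gene_lands_in_quartile_1(self):
        rng = np.random.default_rng(1)
        n = 100
        seed = rng.normal(size=n)
        rows = {"seed": seed, "anti": -seed + rng.normal(0, 0.1, n)}
        for i in range(30):
            rows[f"bg{i:02d}"] = rng.normal(size=n)
        expr = pd.DataFrame(rows).T
        expr.columns = [f"s{i}" for i in range(n)]
        expr = np.exp(expr)                      # make non-negative
        rho = coexpression_list(expr, "seed")
        assert assign_quartiles(rho)["anti"] == 1


class TestQuartiles:
    @pytest.mark.parametrize("g,top_size", [(20096, 5024), (8, 2), (10, 3)])
    def test_top_quartile_ceil_rule(self, g, top_size):
        rho = pd.Series(np.linspace(1, -1, g),
                        index=[f"g{i:05d}" for i in range(g)])
        q = assign_quartiles(rho)
        assert (q == 4).sum() == top_size

    def test_partition_and_size_balance(self):
        rng = np.random.default_rng(0)
        g = 1003
        rho = pd.Series(rng.normal(size=g),
                        index=[f"g{i:04d}" for i in range(g)])
        q = assign_quartiles(rho)
        sizes = q.value_counts()
        assert set(q) == {1, 2, 3, 4}
        assert sizes.sum() == g
        assert all(abs(sizes[k] - math.ceil(g / 4)) <= 1 for k in (1, 2, 3, 4))

    def test_ties_broken_by_gene_symbol(self):
        rho = pd.Series([0.5, 0.5, 0.5, 0.1], index=["b", "a", "d", "c"])
        q = assign_quartiles(rho)
        assert q["a"] == 4                      # alphabetically first tie

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            assign_quartiles(pd.Series(dtype=float))


class TestFilters:
    def test_signaling_intersect(self):
        anno = {"a": frozenset({"GPCR"}), "b": frozenset({"STK"})}
        assert signaling_intersect({"a", "b", "c"}, anno) == {"a", "b"}
        assert signaling_intersect({"a", "b"}, anno,
                                   categories={"GPCR"}) == {"a"}
        assert signaling_intersect({"x"}, {}) == set()

    def test_category_enrichment_reference_values(self):
        genes = [f"g{i}" for i in range(40)]
        anno = {g: frozenset({"GPCR"}) for g in genes}
        assert category_enrichment(set(genes[:10]), anno, "GPCR", genes) == 1.0
        assert category_enrichment(set(genes), anno, "GPCR", genes) == 4.0
        assert category_enrichment(set(), anno, "GPCR", genes) == 0.0
        with pytest.raises(ParameterError):
            category_enrichment(set(), anno, "RTK", genes)

    @pytest.mark.parametrize("rho_high,rho_low,kept", [
        (0.25, 0.05, True),     # passes threshold and contrast
        (0.15, 0.01, False),    # below the 0.2 floor
        (0.30, 0.35, False),    # not higher in the high group
    ])
    def test_contrast_filter_canonical_cases(self, rho_high, rho_low, kept):
        coexpr = pd.DataFrame({"rho_high": [rho_high], "rho_low": [rho_low],
                               "quartile_high": [4], "quartile_low": [4]},
                              index=["g"])
        assert (("g" in contrast_filter(coexpr)) is kept)

    def test_contrast_filter_requires_top_quartile(self):
        coexpr = pd.DataFrame({"rho_high": [0.4], "rho_low": [0.1],
                               "quartile_high": [3], "quartile_low": [4]},
                              index=["g"])
        assert contrast_filter(coexpr) == set()

    def test_protective_gene_excluded_regardless_of_p(self):
        rng = np.random.default_rng(5)
        n = 300
        protective = rng.normal(size=n)
        # strongly protective: high expression -> much longer survival
        times = np.exp(1.5 * protective) * rng.exponential(1, n)
        clinical = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                                 "os_months": times,
                                 "os_event": np.ones(n, dtype=int)})
        expr = pd.DataFrame([np.exp(protective)], index=["p"],
                            columns=clinical["sample_id"])
        per_gene, kept = survival_filter(expr, clinical, ["p"])
        assert per_gene.loc["p", "logrank_p"] < 0.05
        assert per_gene.loc["p", "direction"] == "better_when_high"
        assert kept == set()

    def test_survival_filter_power_on_planted_cohort(self, planted_cohort):
        params, expr, clinical, _, truth = planted_cohort
        per_gene, kept = survival_filter(expr, clinical,
                                         sorted(truth.partner_genes))
        assert len(kept) >= 0.75 * len(truth.partner_genes)

    def test_expand_phosphosubstrates(self):
        ks = {"K1": {"S1", "S2"}, "K2": {"S1"}, "K3": {"S9"}}
        out = expand_phosphosubstrates({"K1", "K2"}, ks, {"S1", "X"})
        assert out == {"S1": {"K1", "K2"}}
        assert expand_phosphosubstrates(set(), ks, {"S1"}) == {}


class TestBuildSignature:
    def test_recovers_planted_hub(self, planted_cohort):
        params, expr, clinical, annotation, truth = planted_cohort
        sig = build_hub_signature(expr, clinical, annotation,
                                  params.seed_gene)
        found = set(sig.genes)
        assert len(found & truth.partner_genes) >= 9        # of 12
        assert len(found - truth.partner_genes) <= 2
        assert params.seed_gene not in found

    def test_retained_set_is_intersection_of_filters(self, planted_cohort):
        params, expr, clinical, annotation, truth = planted_cohort
        sig = build_hub_signature(expr, clinical, annotation,
                                  params.seed_gene)
        low, high = stratify_by_seed(expr, params.seed_gene)
        coexpr = coexpression_table(expr, params.seed_gene, low, high)
        contrast = contrast_filter(coexpr)
        signaling = signaling_intersect(set(coexpr.index), annotation)
        _, survivors = survival_filter(expr, clinical,
                                       sorted(contrast & signaling))
        assert set(sig.genes) == contrast & signaling & survivors

    def test_threshold_monotonicity(self, planted_cohort):
        params, expr, clinical, annotation, _ = planted_cohort
        base = set(build_hub_signature(expr, clinical, annotation,
                                       params.seed_gene).genes)
        stricter_rho = set(build_hub_signature(
            expr, clinical, annotation, params.seed_gene,
            min_rho_high=0.35).genes)
        stricter_alpha = set(build_hub_signature(
            expr, clinical, annotation, params.seed_gene,
            alpha=0.005).genes)
        assert stricter_rho <= base
        assert stricter_alpha <= base

    def test_empty_result_warns_not_raises(self, planted_cohort):
        params, expr, clinical, annotation, _ = planted_cohort
        with pytest.warns(UserWarning, match="empty signature"):
            sig = build_hub_signature(expr, clinical, annotation,
                                      params.seed_gene, min_rho_high=0.999)
        assert len(sig) == 0
        assert sig.provenance["empty"]

    def test_substrate_expansion_repasses_filters(self, planted_cohort):
        params, expr, clinical, annotation, truth = planted_cohort
        base = build_hub_signature(expr, clinical, annotation,
                                   params.seed_gene)
        # map a retained kinase onto a background gene that fails contrast
        anno = dict(annotation)
        kinase = base.genes[0]
        anno[kinase] = frozenset({"STK"})
        ks = {kinase: {"G000499"}}
        sig = build_hub_signature(expr, clinical, anno, params.seed_gene,
                                  ks_map=ks)
        assert "G000499" not in sig.genes

    def test_signature_tsv_round_trip(self, planted_cohort, tmp_path):
        params, expr, clinical, annotation, _ = planted_cohort
        sig = build_hub_signature(expr, clinical, annotation,
                                  params.seed_gene)
        path = tmp_path / "sig.tsv"
        sig.to_tsv(path)
        back = HubSignature.from_tsv(path)
        assert back.seed_gene == sig.seed_gene
        assert back.genes == sig.genes
        assert back.partners["rho_high"].to_numpy() == pytest.approx(
            sig.partners["rho_high"].to_numpy())


class TestEstimatorApi:
    def test_fit_get_support_and_clone(self, planted_cohort):
        params, expr, clinical, annotation, truth = planted_cohort
        est = HubSignatureDiscovery(seed_gene=params.seed_gene,
                                    annotation=annotation)
        cloned = clone(est)
        assert cloned.get_params()["min_rho_high"] == 0.2
        est.fit(expr.T, clinical)
        assert est.funnel_["after_survival_filter"] == len(est.signature_)
        assert set(est.get_support()) <= set(expr.index)
        assert est.n_features_in_ == expr.shape[0]

    def test_set_params_roundtrip(self):
        est = HubSignatureDiscovery().set_params(alpha=0.01, min_rho_high=0.3)
        assert est.get_params()["alpha"] == 0.01
        assert est.get_params()["min_rho_high"] == 0.3

    def test_fit_without_annotation_rejected(self, planted_cohort):
        _, expr, clinical, _, _ = planted_cohort
        with pytest.raises(ParameterError):
            HubSignatureDiscovery(seed_gene="GSEED").fit(expr.T, clinical)
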