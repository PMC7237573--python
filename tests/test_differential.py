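import numpy as np
import pandas as pd
import pytest

from ienet import (
    AbundanceTable,
    GeneAnnotation,
    SampleDesign,
    alpha_diversity,
    category_abundance_test,
    hypergeometric_enrichment,
    kruskal_wallis_differential,
    pca_embed,
    wilcoxon_differential,
)
from ienet.exceptions import GroupError, MarkerError, NotClosedError


def table_from_rows(rows, samples):
    return AbundanceTable(
        pd.DataFrame(rows, columns=samples,
                     index=[f"f{i}" for i in range(len(rows))]),
        closed=False,
    )


@pytest.fixture()
def design33():
    return SampleDesign(
        pd.Series({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}),
        reference="A",
    )


class TestWilcoxon:
    def test_flat_feature_not_selected(self, design33):
        t = table_from_rows([[1, 1, 1, 1, 1, 1]], list(design33.groups.index))
        res = wilcoxon_differential(t, design33, "A", "B")
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert not res.loc[0, "selected"]

    def test_extreme_separation_exact_p(self, design33):
        # groups (1,2,3) vs (4,5,6): the most extreme of C(6,3)=20 rank splits,
        # two-sided exact p = 2/20 = 0.1
        t = table_from_rows([[1, 2, 3, 4, 5, 6]], list(design33.groups.index))
        res = wilcoxon_differential(t, design33, "A", "B", alpha=0.05)
        assert res.loc[0, "p_value"] == pytest.approx(0.1)
        assert not res.loc[0, "selected"]

    def test_missing_group_rejected(self, design33):
        t = table_from_rows([[1, 2, 3, 4, 5, 6]], list(design33.groups.index))
        with pytest.raises(GroupError):
            wilcoxon_differential(t, design33, "A", "Z")

    def test_null_type_one_error_rate(self):
        # exact 5v5 rank-sum test: rejection region at nominal 0.05 is the
        # 8/252 tail, so the realized size should sit near 0.032
        rng = np.random.default_rng(2024)
        n_feat = 2000
        samples = [f"h{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        design = SampleDesign(
            pd.Series({s: ("H" if s.startswith("h") else "D") for s in samples}),
            reference="H",
        )
        t = table_from_rows(rng.random(size=(n_feat, 10)), samples)
        res = wilcoxon_differential(t, design, "H", "D", alpha=0.05)
        rate = res["selected"].mean()
        assert 0.03 <= rate <= 0.07

    def test_invariant_to_monotone_transform(self, design33):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 2, size=(5, 6))
        t1 = table_from_rows(vals, list(design33.groups.index))
        t2 = table_from_rows(np.exp(vals), list(design33.groups.index))
        r1 = wilcoxon_differential(t1, design33, "A", "B")
        r2 = wilcoxon_differential(t2, design33, "A", "B")
        assert np.allclose(r1["p_value"], r2["p_value"])


class TestKruskalWallis:
    @pytest.fixture()
    def design_3x5(self):
        labels = {}
        for g in "ABC":
            for i in range(5):
                labels[f"{g}{i}"] = g
        return SampleDesign(pd.Series(labels), reference="A")

    def test_exchangeable_null_p_near_one(self, design_3x5):
        t = table_from_rows([[1.0] * 15], list(design_3x5.groups.index))
        res = kruskal_wallis_differential(t, design_3x5)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_disjoint_ranges_reach_analytic_maximum(self, design_3x5):
        # ranks 1-5 / 6-10 / 11-15: H = 12/(15*16) * 5*[(3-8)^2 + 0 + (13-8)^2] = 12.5
        t = table_from_rows([list(range(1, 16))], list(design_3x5.groups.index))
        res = kruskal_wallis_differential(t, design_3x5)
        assert res.loc[0, "statistic"] == pytest.approx(12.5)
        assert res.loc[0, "selected"]

    def test_single_feature_fdr_equals_p(self, design_3x5):
        rng = np.random.default_rng(0)
        t = table_from_rows([rng.uniform(size=15)], list(design_3x5.groups.index))
        res = kruskal_wallis_differential(t, design_3x5)
        assert res.loc[0, "fdr"] == pytest.approx(res.loc[0, "p_value"])

    def test_small_group_rejected(self):
        design = SampleDesign(pd.Series({"a": "A", "b": "B", "c": "B"}), reference="A")
        t = table_from_rows([[1, 2, 3]], ["a", "b", "c"])
        with pytest.raises(GroupError):
            kruskal_wallis_differential(t, design)


class TestEnrichment:
    def test_worked_tail_sum(self):
        # background 20, category 5, selection 5, hits 4:
        # p = [C(5,4)C(15,1) + C(5,5)C(15,0)] / C(20,5) = 76/15504
        background = [f"g{i}" for i in range(20)]
        category = {"cat": background[:5]}
        selected = background[:4] + [background[10]]
        res = hypergeometric_enrichment(selected, background, category)
        assert res.loc[0, "p_value"] == pytest.approx(76 / 15504, rel=1e-12)

    def test_perfect_overlap_is_minimal_p(self):
        background = [f"g{i}" for i in range(12)]
        selected = background[:4]
        res = hypergeometric_enrichment(selected, background, {"cat": selected})
        from math import comb

        assert res.loc[0, "p_value"] == pytest.approx(1 / comb(12, 4))
        assert res.loc[0, "enriched"]

    def test_hits_at_expectation_not_significant(self):
        rng = np.random.default_rng(11)
        background = [f"g{i}" for i in range(1000)]
        category = {"cat": background[:200]}  # K/N = 0.2
        selected = background[:20] + background[500:580]  # 20 hits of 100, at expectation
        res = hypergeometric_enrichment(selected, background, category)
        assert res.loc[0, "p_value"] > 0.05

    def test_selection_outside_background_rejected(self):
        with pytest.raises(MarkerError):
            hypergeometric_enrichment(["x"], ["a", "b"], {"c": ["a"]})


class TestCategoryAbundance:
    def test_extreme_category_selected_with_exact_min_p(self):
        # one category 10x higher in group B across 5v5, no overlap:
        # minimal two-sided exact rank-sum p = 2/252
        samples = [f"h{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        design = SampleDesign(
            pd.Series({s: ("H" if s.startswith("h") else "D") for s in samples}),
            reference="H",
        )
        genes = pd.DataFrame(
            {s: ([0.1, 0.1] if s.startswith("h") else [1.0, 1.1]) for s in samples},
            index=["gA", "gB"],
        ) * (1 + 0.01 * np.arange(10))  # break ties
        annot = GeneAnnotation(
            pd.DataFrame({"species": ["x", "y"], "genus": ["x", "y"],
                          "categories": [["K1"], ["K1"]]}, index=["gA", "gB"])
        )
        res = category_abundance_test(genes, annot, design, "H", "D")
        assert res.loc[0, "p_value"] == pytest.approx(2 / 252, rel=1e-9)
        assert res.loc[0, "selected"]

    def test_flat_category_not_selected(self):
        samples = [f"s{i}" for i in range(10)]
        design = SampleDesign(
            pd.Series({s: ("H" if i < 5 else "D") for i, s in enumerate(samples)}),
            reference="H",
        )
        genes = pd.DataFrame({s: [0.5] for s in samples}, index=["gA"])
        annot = GeneAnnotation(
            pd.DataFrame({"species": ["x"], "genus": ["x"], "categories": [["K1"]]},
                         index=["gA"])
        )
        res = category_abundance_test(genes, annot, design, "H", "D")
        assert not res.loc[0, "selected"]

    def test_partitioning_categories_preserve_closure(self):
        samples = ["s0", "s1"]
        genes = pd.DataFrame({"s0": [0.3, 0.7], "s1": [0.6, 0.4]}, index=["gA", "gB"])
        annot = GeneAnnotation(
            pd.DataFrame({"species": ["x", "y"], "genus": ["x", "y"],
                          "categories": [["K1"], ["K2"]]}, index=["gA", "gB"])
        )
        members = annot.category_members()
        totals = sum(genes.loc[members[c]].sum(axis=0) for c in ("K1", "K2"))
        assert np.allclose(totals, 1.0)


class TestAlphaDiversity:
    def test_uniform_maximises_shannon(self):
        t = AbundanceTable(pd.DataFrame({"s0": [0.25] * 4}))
        assert alpha_diversity(t, "shannon")["s0"] == pytest.approx(np.log(4))

    def test_single_taxon_degenerate(self):
        t = AbundanceTable(pd.DataFrame({"s0": [1.0, 0.0]}))
        assert alpha_diversity(t, "shannon")["s0"] == pytest.approx(0.0)
        assert alpha_diversity(t, "simpson")["s0"] == pytest.approx(0.0)
        assert alpha_diversity(t, "richness")["s0"] == 1

    def test_hand_computed_shannon(self):
        t = AbundanceTable(pd.DataFrame({"s0": [0.5, 0.25, 0.25]}))
        assert alpha_diversity(t, "shannon")["s0"] == pytest.approx(1.5 * np.log(2))

    def test_unclosed_rejected(self):
        t = AbundanceTable(pd.DataFrame({"s0": [0.2, 0.2]}), closed=False)
        with pytest.raises(NotClosedError):
            alpha_diversity(t)


class TestPCA:
    def test_collinear_samples_explained_by_first_component(self):
        base = np.array([0.1, 0.2, 0.3, 0.4])
        data = np.column_stack([base + 0.05 * i * np.array([1, -1, 1, -1]) for i in range(5)])
        t = AbundanceTable(pd.DataFrame(np.abs(data)), closed=False)
        _, evr = pca_embed(t, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_sorted(self, scenario):
        _, evr = pca_embed(scenario.table, n_components=4)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_axes_match_analytic_2d_eigenvectors(self):
        rng = np.random.default_rng(8)
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=500)
        t = AbundanceTable(pd.DataFrame(np.abs(X).T + 1.0), closed=False)
        scores, _ = pca_embed(t, n_components=2)
        M = t.to_samples_matrix().to_numpy()
        emp_cov = np.cov(M, rowvar=False)
        w, v = np.linalg.eigh(emp_cov)
        lead = v[:, np.argmax(w)]
        # score along PC1 must equal projection on the leading eigenvector up to sign
        centered = M - M.mean(axis=0)
        proj = centered @ lead
        corr = np.corrcoef(proj, scores["PC1"])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_component_bounds_enforced(self, toy_table):
        with pytest.raises(ValueError):
            pca_embed(toy_table, n_components=40)
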