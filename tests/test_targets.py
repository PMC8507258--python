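import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mirmark.datatypes import GeneSetCollection
from mirmark.errors import ValidationError
from mirmark.targets import (classify_correlation, correlate_edges, correlate_pair,
                             cross_disease_genes, enrich_genesets, filter_mti,
                             hypergeometric_enrichment_p, mirna_pathway_matrix)


def _edges(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "species", "support_type"])


class TestFilterMti:
    def test_species_and_support_filters(self):
        edges = _edges([
            ("miR-a", "G1", "Homo sapiens", "Functional MTI"),
            ("miR-a", "G2", "Mus musculus", "Functional MTI"),
            ("miR-b", "G3", "Homo sapiens", "Functional MTI (Weak)"),
        ])
        out = filter_mti(edges)
        assert out[["mirna", "gene"]].values.tolist() == [["miR-a", "G1"]]
        # weak rows survive when functional_only is off
        assert len(filter_mti(edges, functional_only=False)) == 2

    def test_duplicate_pairs_collapse(self):
        edges = _edges([
            ("miR-a", "G1", "Homo sapiens", "Functional MTI"),
            ("miR-a", "G1", "Homo sapiens", "Functional MTI"),
        ])
        assert len(filter_mti(edges)) == 1


class TestCrossDiseaseGenes:
    EDGES = _edges([
        ("miR-a", "G1", "Homo sapiens", "Functional MTI"),
        ("miR-a", "G2", "Homo sapiens", "Functional MTI"),
        ("miR-b", "G3", "Homo sapiens", "Functional MTI"),
    ])

    def test_intersection_and_zero_degree_flag(self):
        restricted, degrees = cross_disease_genes(self.EDGES, ["g1"])  # case-insensitive
        assert restricted[["mirna", "gene"]].values.tolist() == [["miR-a", "G1"]]
        assert degrees["miR-a"] == 1
        assert degrees["miR-b"] == 0  # no disease-gene target, still reported

    def test_full_universe_is_identity(self):
        restricted, _ = cross_disease_genes(self.EDGES, ["G1", "G2", "G3"])
        assert len(restricted) == len(self.EDGES)

    def test_empty_disease_list_errors(self):
        with pytest.raises(ValidationError):
            cross_disease_genes(self.EDGES, [])


class TestCorrelatePair:
    def test_perfect_linear_is_pearson_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(8, 1, 30)
        res = correlate_pair(x, 2 * x)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value < 1e-10
        assert res.strength_class == "very_high"

    def test_monotone_nonlinear_goes_to_spearman(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.exponential(1.0, 40))  # skewed -> fails normality
        res = correlate_pair(x, x ** 3)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_forced_spearman_hand_oracle(self):
        # closed form 1 - 6*sum(d^2)/(n(n^2-1)) computed here from ranks
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d = rankdata(x) - rankdata(y)
        expected = 1 - 6 * float((d ** 2).sum()) / (5 * 24)
        res = correlate_pair(x, y, method="spearman")
        assert res.coefficient == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        res = correlate_pair([1.0] * 10, list(range(10)))
        assert np.isnan(res.coefficient)
        assert res.p_value == 1.0
        assert res.note == "constant vector"

    def test_pearson_on_ranks_equals_spearman_tie_free(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        sp = correlate_pair(x, y, method="spearman")
        pe = correlate_pair(rankdata(x), rankdata(y), method="pearson")
        assert sp.coefficient == pytest.approx(pe.coefficient, abs=1e-12)


@pytest.mark.parametrize(
    "coef, expected",
    [
        (-0.478, ("low", "negative")),
        (0.0, ("negligible", "positive")),
        (1.0, ("very_high", "positive")),
        (-0.95, ("very_high", "negative")),
        (0.5, ("moderate", "positive")),
        (0.299, ("negligible", "positive")),
        (0.7, ("high", "positive")),
    ],
)
def test_mukaka_classification(coef, expected):
    assert classify_correlation(coef) == expected


def test_mukaka_out_of_range_errors():
    with pytest.raises(ValidationError):
        classify_correlation(1.2)


class TestEnrichment:
    def test_worked_tail_sum(self):
        # C(5,3)C(15,2) + C(5,4)C(15,1) + C(5,5) over C(20,5)
        assert hypergeometric_enrichment_p(3, 5, 5, 20) == pytest.approx(
            1126 / 15504, abs=1e-12)

    def test_zero_overlap_and_certain_overlap(self):
        assert hypergeometric_enrichment_p(0, 5, 5, 20) == pytest.approx(1.0)
        coll = GeneSetCollection({"ALL": tuple(f"G{i}" for i in range(10))})
        res = enrich_genesets([f"G{i}" for i in range(4)], coll)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)  # set == universe

    def test_ease_correction_is_more_conservative(self):
        plain = hypergeometric_enrichment_p(3, 5, 5, 20)
        ease = hypergeometric_enrichment_p(3, 5, 5, 20, ease=True)
        assert ease > plain

    def test_table_sorted_with_bh(self):
        coll = GeneSetCollection({
            "HIT": ("G1", "G2", "G3"),
            "MISS": ("G8", "G9"),
            "BG": tuple(f"G{i}" for i in range(1, 11)),
        })
        res = enrich_genesets(["G1", "G2", "G3"], coll)
        assert res.loc[0, "set_name"] == "HIT"
        assert (res["p_value"].diff().dropna() >= 0).all()
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()

    def test_genes_outside_universe_warn(self):
        coll = GeneSetCollection({"S": ("G1", "G2")})
        with pytest.warns(UserWarning):
            res = enrich_genesets(["G1", "NOT_THERE"], coll)
        assert res.loc[0, "list_size"] == 1

    def test_empty_universe_errors(self):
        coll = GeneSetCollection({"S": ("G1",)})
        with pytest.raises(ValidationError):
            enrich_genesets(["G1"], coll, universe=[])


class TestPathwayMatrix:
    COLL = GeneSetCollection({
        "P1": ("G1", "G2"), "P2": ("G2",), "P3": ("G3",),
        "P4": ("G1",), "P5": ("G1", "G3"), "P6": ("G2", "G3"),
    })

    def test_row_sums_count_pathways_hit(self):
        edges = _edges([
            ("miR-a", "G1", "Homo sapiens", "Functional MTI"),
            ("miR-a", "G2", "Homo sapiens", "Functional MTI"),
            ("miR-a", "G3", "Homo sapiens", "Functional MTI"),
            ("miR-b", "G9", "Homo sapiens", "Functional MTI"),
        ])
        mat = mirna_pathway_matrix(edges, self.COLL)
        assert mat.loc["miR-a"].sum() == 6  # hits all six pathways
        assert mat.loc["miR-b"].sum() == 0  # row of zeros

    def test_empty_edges_all_zero(self):
        mat = mirna_pathway_matrix(_edges([]), self.COLL)
        assert mat.shape[0] == 0

    def test_unknown_pathway_subset_errors(self):
        with pytest.raises(ValidationError):
            mirna_pathway_matrix(_edges([]), self.COLL, ["NOPE"])


def test_correlate_edges_recovers_planted_relation():
    rng = np.random.default_rng(9)
    samples = [f"s{i}" for i in range(60)]
    x = rng.normal(8, 1, 60)
    mirna_expr = pd.DataFrame([x], index=["miR-a"], columns=samples)
    gene_expr = pd.DataFrame(
        [-0.9 * x + rng.normal(0, 0.3, 60), rng.normal(5, 1, 60)],
        index=["G1", "G2"], columns=samples)
    edges = pd.DataFrame({"mirna": ["miR-a", "miR-a"], "gene": ["G1", "G2"]})
    table = correlate_edges(mirna_expr, gene_expr, edges)
    planted = table.set_index("gene").loc["G1"]
    assert planted["coefficient"] < -0.8
    assert planted["q_value"] < 0.01
    assert "q_value" in table.columns and len(table) == 2
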