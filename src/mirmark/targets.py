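"""miRNA-target networks: interaction filtering, disease-gene crossing,
expression correlation and pathway enrichment.

The interaction table is a validated miRNA->gene edge list (e.g. exported from
a curated MTI database). Edges are filtered to one species and, optionally, to
functional-evidence support before being crossed with a disease-gene list.
Correlation between a miRNA and a target uses Pearson when both vectors pass
Shapiro-Wilk normality and Spearman otherwise, with strength classified on the
Mukaka scale. Gene-set enrichment is the one-sided hypergeometric upper tail
with BH correction across sets (an EASE-style k-1 correction is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .differential import adjust_fdr
from .errors import ValidationError

#: Mukaka (2012) strength bins on the absolute correlation coefficient.
MUKAKA_BINS = (
    (0.90, "very_high"),
    (0.70, "high"),
    (0.50, "moderate"),
    (0.30, "low"),
    (0.00, "negligible"),
)


# ---------------------------------------------------------------------------
# interaction filtering and disease-gene crossing
# ---------------------------------------------------------------------------

def filter_mti(
    edges: pd.DataFrame,
    species: str = "Homo sapiens",
    functional_only: bool = True,
    weak_tag: str = "weak",
) -> pd.DataFrame:
    """Restrict an MTI edge table to one species and functional evidence.

    ``functional_only`` drops support types containing ``weak_tag``
    (case-insensitive), matching the functional vs weak-evidence dichotomy of
    curated MTI databases. (mirna, gene) pairs are deduplicated.
    """
    out = edges[edges["species"] == species]
    if functional_only:
        out = out[~out["support_type"].str.lower().str.contains(weak_tag.lower(), na=False)]
    return out.drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)


def cross_disease_genes(
    edges: pd.DataFrame, disease_genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross MTI edges with a disease-gene list (case-insensitive symbols).

    Returns the restricted bipartite edge list and the per-miRNA interaction
    degree ranking; miRNAs present in the input but with no disease-gene
    target appear with degree 0 so they can be flagged.
    """
    if len(disease_genes) == 0:
        raise ValidationError("disease-gene list is empty (parsing failure?)")
    disease = {g.upper() for g in disease_genes}
    keep = edges["gene"].str.upper().isin(disease)
    restricted = edges[keep].reset_index(drop=True)
    degrees = restricted.groupby("mirna").size()
    degrees = degrees.reindex(sorted(edges["mirna"].unique()), fill_value=0)
    degrees = degrees.sort_values(ascending=False).astype(int)
    degrees.name = "n_disease_targets"
    return restricted, degrees


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    mirna: str
    gene: str
    method: str
    coefficient: float
    p_value: float
    n: int
    strength_class: str | None
    sign: str | None
    note: str | None = None


def classify_correlation(coefficient: float) -> tuple[str, str]:
    """(strength class, sign) of a correlation coefficient on the Mukaka scale."""
    if np.isnan(coefficient) or abs(coefficient) > 1:
        raise ValidationError(f"coefficient out of range: {coefficient}")
    strength = "negligible"
    for cut, name in MUKAKA_BINS:
        if abs(coefficient) >= cut:
            strength = name
            break
    sign = "negative" if coefficient < 0 else "positive"
    return strength, sign


def correlate_pair(
    mirna_values: Sequence[float],
    gene_values: Sequence[float],
    alpha_normality: float = 0.05,
    method: str | None = None,
    mirna: str = "",
    gene: str = "",
) -> CorrelationResult:
    """Correlate paired miRNA/gene expression with normality-driven test choice.

    Pairs with a missing value on either side are dropped; at least 4 complete
    pairs are required. ``method`` forces "pearson" or "spearman" (otherwise
    both vectors must pass Shapiro-Wilk for Pearson). A constant vector makes
    the coefficient undefined: the result is flagged with p = 1.
    """
    x = np.asarray(mirna_values, float)
    y = np.asarray(gene_values, float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValidationError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            mirna, gene, method or "undefined", float("nan"), 1.0, n, None, None,
            note="constant vector",
        )
    if method is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_x = float(stats.shapiro(x).pvalue)
            p_y = float(stats.shapiro(y).pvalue)
        method = "pearson" if (p_x > alpha_normality and p_y > alpha_normality) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    strength, sign = classify_correlation(float(r))
    return CorrelationResult(mirna, gene, method, float(r), float(p), n, strength, sign)


def correlate_edges(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    edges: pd.DataFrame,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """CorrelationResult table for every MTI edge measurable in both matrices.

    ``mirna_expr`` and ``gene_expr`` are feature x sample frames over the same
    (matched) sample columns. Adds BH q-values across all tested pairs.
    """
    common = [s for s in mirna_expr.columns if s in gene_expr.columns]
    if len(common) < 4:
        raise ValidationError("fewer than 4 matched samples between matrices")
    rows = []
    for mirna, gene in edges[["mirna", "gene"]].itertuples(index=False):
        if mirna not in mirna_expr.index or gene not in gene_expr.index:
            continue
        try:
            res = correlate_pair(
                mirna_expr.loc[mirna, common].to_numpy(float),
                gene_expr.loc[gene, common].to_numpy(float),
                alpha_normality=alpha_normality,
                mirna=mirna,
                gene=gene,
            )
        except ValidationError:
            continue
        rows.append(res.__dict__)
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna", "gene", "method", "coefficient", "p_value", "n",
            "strength_class", "sign", "note",
        ],
    )
    if len(table):
        table["q_value"] = adjust_fdr(table["p_value"].to_numpy())
    else:
        table["q_value"] = []
    return table


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment_p(
    k_overlap: int, set_size: int, list_size: int, universe_size: int, ease: bool = False
) -> float:
    """Upper-tail hypergeometric p: P(overlap >= k) drawing ``list_size`` genes
    from a universe containing ``set_size`` set members.

    ``ease=True`` applies the EASE-style correction (score on k-1 successes),
    a conservative variant used by some enrichment web services.
    """
    k = k_overlap - 1 if ease else k_overlap
    return float(stats.hypergeom.sf(k - 1, universe_size, set_size, list_size))


def enrich_genesets(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    Genes outside the universe are dropped with a warning. Returns one row per
    set with the overlap counts, p-value and BH q-value, sorted by p.
    """
    uni = {g.upper() for g in (universe if universe is not None else collection.universe)}
    if not uni:
        raise ValidationError("empty enrichment universe")
    query = {g.upper() for g in gene_list}
    outside = query - uni
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    query &= uni
    rows = []
    for name, members in collection.sets.items():
        in_uni = {g.upper() for g in members} & uni
        overlap = query & in_uni
        p = hypergeometric_enrichment_p(
            len(overlap), len(in_uni), len(query), len(uni), ease=ease
        )
        rows.append(
            {
                "set_name": name,
                "k_overlap": len(overlap),
                "set_size": len(in_uni),
                "list_size": len(query),
                "universe_size": len(uni),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = adjust_fdr(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def mirna_pathway_matrix(
    bipartite_edges: pd.DataFrame,
    collection: GeneSetCollection,
    pathway_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary miRNA x pathway matrix: 1 iff some target of the miRNA is in the
    pathway. Row/column sums are the natural interaction counts."""
    names = list(pathway_subset) if pathway_subset is not None else collection.set_names
    unknown = [n for n in names if n not in collection.sets]
    if unknown:
        raise ValidationError(f"pathways not in collection: {unknown}")
    mirnas = sorted(bipartite_edges["mirna"].unique())
    mat = pd.DataFrame(0, index=mirnas, columns=names, dtype=int)
    targets_by_mirna = {
        m: {g.upper() for g in grp["gene"]}
        for m, grp in bipartite_edges.groupby("mirna")
    }
    for name in names:
        members = {g.upper() for g in collection.sets[name]}
        for m in mirnas:
            if targets_by_mirna[m] & members:
                mat.loc[m, name] = 1
    return mat
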