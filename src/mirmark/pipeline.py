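"""End-to-end orchestration: discovery workflow, validation re-application,
report bundling and provenance.

``run_discovery`` chains the stages on in-memory objects:

    preprocess -> per-cohort differential tests -> cross-cohort consensus ->
    direction filter -> target network (MTI filter, disease crossing,
    correlation, enrichment, miRNA x pathway matrix) -> per-cohort ROC ->
    per-stage survival panel screens.

Target-network, diagnostic and prognostic stages run only when their inputs
are supplied. ``write_discovery`` serializes every intermediate table plus a
manifest (parameter hash, library versions, seed) so a run can be reproduced
bit-identically. ``run_validation`` freezes a miRNA list and recomputes
fold-change direction and AUC in held-out cohorts, reporting a cross-cohort
concordance table; miRNAs absent from a cohort are "absent", not discordant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import STAGES, ClinicalTable, CohortMatrix, GeneSetCollection
from .diagnostics import classify_auc, cohort_roc, compute_auc
from .differential import (cohort_differential, compute_log2fc, consensus_select,
                           consensus_to_tsv_frame, direction_filter)
from .errors import ValidationError
from .io import (read_alias_table, read_clinical, read_expression_matrix,
                 read_gene_list, read_gmt, read_mti, canonicalize_matrix,
                 match_samples)
from .preprocess import preprocess_cohort
from .survival import PanelScreenResult, screen_panels
from .targets import (correlate_edges, cross_disease_genes, enrich_genesets,
                      filter_mti, mirna_pathway_matrix)

logger = logging.getLogger("mirmark")


@dataclass
class AnalysisParams:
    """Every tunable threshold of the workflow, with its conventional default."""

    missing_threshold: float = 0.5
    fence_k: float = 1.5
    alpha: float = 0.05
    q_threshold: float = 0.05
    min_support: int = 2
    min_group: int = 30
    k_min: int = 2
    k_max: int = 5
    policy: str = "conventional"
    fc_mode: str = "diff_of_log_means"
    grouping: str = "concordant"
    endpoints: tuple[str, ...] = ("OS", "RFS")
    stages: tuple[str | None, ...] = STAGES
    species: str = "Homo sapiens"
    functional_only: bool = True
    correlation_tumour_only: bool = True
    compute_hr: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.missing_threshold <= 1):
            raise ValidationError("missing_threshold out of (0, 1]")
        for name in ("alpha", "q_threshold"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} out of (0, 1)")
        if self.min_support < 0 or self.min_group < 1:
            raise ValidationError("min_support/min_group out of range")
        if self.k_min > self.k_max or self.k_min < 1:
            raise ValidationError("bad panel size range")


@dataclass
class DiscoveryResult:
    """Everything the discovery workflow computed, stage by stage."""

    params: AnalysisParams
    reference: str
    processing_counts: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    skipped_mirnas: dict[str, list[str]]
    consensus: pd.DataFrame
    final_table: pd.DataFrame
    final_mirnas: list[str]
    mti_filtered: pd.DataFrame | None = None
    disease_edges: pd.DataFrame | None = None
    disease_degrees: pd.Series | None = None
    correlations: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    pathway_matrix: pd.DataFrame | None = None
    roc_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    panel_screens: dict[tuple[str | None, str], PanelScreenResult] = field(default_factory=dict)


def _stage_log(stage_name: str, **counts) -> None:
    logger.info("%s: %s", stage_name, ", ".join(f"{k}={v}" for k, v in counts.items()))


def run_discovery(
    cohorts: Sequence[CohortMatrix],
    reference: str,
    clinical: ClinicalTable | None = None,
    gene_matrix: CohortMatrix | None = None,
    mti: pd.DataFrame | None = None,
    disease_genes: Sequence[str] | None = None,
    gene_sets: GeneSetCollection | None = None,
    params: AnalysisParams | None = None,
) -> DiscoveryResult:
    """Run the full discovery workflow on in-memory inputs."""
    params = params or AnalysisParams()
    params.validate()
    ids = [c.cohort_id for c in cohorts]
    if reference not in ids:
        raise ValidationError(f"reference cohort {reference!r} not among {ids}")

    # 1. preprocessing, with the per-checkpoint miRNA counts
    counts_rows = []
    cleaned: dict[str, CohortMatrix] = {}
    for cm in cohorts:
        clean, reports = preprocess_cohort(cm, params.missing_threshold, params.fence_k)
        cleaned[cm.cohort_id] = clean
        counts_rows.append(
            {
                "cohort_id": cm.cohort_id,
                "initial": cm.values.shape[0],
                "after_missing_filter": reports[0].n_features_after,
            }
        )
        _stage_log("preprocess", cohort=cm.cohort_id,
                   kept=reports[0].n_features_after,
                   entries_masked=len(reports[1].removed_entries))

    # 2. per-cohort differential testing
    de_tables: dict[str, pd.DataFrame] = {}
    skipped: dict[str, list[str]] = {}
    for row in counts_rows:
        cid = row["cohort_id"]
        table, skip = cohort_differential(
            cleaned[cid], policy=params.policy, fc_mode=params.fc_mode,
            alpha_normality=params.alpha,
        )
        de_tables[cid] = table
        skipped[cid] = skip
        row["tested"] = len(table)
        _stage_log("differential", cohort=cid, tested=len(table),
                   significant=int((table["q_value"] <= params.q_threshold).sum()))
    processing_counts = pd.DataFrame(counts_rows).set_index("cohort_id")

    # 3. consensus + direction filter
    consensus = consensus_select(
        de_tables, reference, min_support=params.min_support,
        q_threshold=params.q_threshold,
    )
    final_table = direction_filter(consensus)
    final_mirnas = sorted(final_table.index)
    _stage_log("consensus", selected=int(consensus["selected"].sum()),
               direction_consistent=len(final_mirnas))

    result = DiscoveryResult(
        params=params,
        reference=reference,
        processing_counts=processing_counts,
        de_tables=de_tables,
        skipped_mirnas=skipped,
        consensus=consensus,
        final_table=final_table,
        final_mirnas=final_mirnas,
    )

    ref_matrix = cleaned[reference]

    # 4. target network
    if mti is not None:
        edges = filter_mti(mti, species=params.species,
                           functional_only=params.functional_only)
        edges = edges[edges["mirna"].isin(final_mirnas)].reset_index(drop=True)
        result.mti_filtered = edges
        if disease_genes is not None and len(edges):
            disease_edges, degrees = cross_disease_genes(edges, disease_genes)
            result.disease_edges = disease_edges
            result.disease_degrees = degrees
            _stage_log("targets", edges=len(edges), disease_edges=len(disease_edges))
            if gene_matrix is not None:
                match = match_samples(ref_matrix.samples, gene_matrix.samples)
                cols = [match.a_ids[k] for k in match.keys]
                gcols = [match.b_ids[k] for k in match.keys]
                if params.correlation_tumour_only:
                    keep = [i for i, c in enumerate(cols)
                            if ref_matrix.sample_labels[c] == "tumour"]
                    cols = [cols[i] for i in keep]
                    gcols = [gcols[i] for i in keep]
                m_expr = ref_matrix.values[cols]
                g_expr = gene_matrix.values[gcols]
                g_expr.columns = m_expr.columns
                result.correlations = correlate_edges(
                    m_expr, g_expr, disease_edges, alpha_normality=params.alpha)
                _stage_log("correlation", pairs=len(result.correlations))
            if gene_sets is not None:
                q_genes = sorted(set(disease_edges["gene"]))
                in_uni = {g.upper() for g in gene_sets.universe}
                q_in = [g for g in q_genes if g.upper() in in_uni]
                if q_in:
                    result.enrichment = enrich_genesets(q_in, gene_sets)
                    sig_sets = result.enrichment.loc[
                        result.enrichment["p_value"] < params.alpha, "set_name"
                    ].tolist()
                    result.pathway_matrix = mirna_pathway_matrix(
                        disease_edges, gene_sets, sig_sets or None)

    # 5. diagnostics
    for cid, cm in cleaned.items():
        result.roc_tables[cid] = cohort_roc(cm, final_mirnas)

    # 6. prognosis on the reference cohort
    if clinical is not None and final_mirnas:
        pool = [m for m in final_mirnas if m in ref_matrix.values.index]
        k_max = min(params.k_max, len(pool))
        for stage in params.stages:
            for endpoint in params.endpoints:
                try:
                    screen = screen_panels(
                        ref_matrix, clinical, stage=stage, endpoint=endpoint,
                        mirnas=pool, k_min=min(params.k_min, k_max), k_max=k_max,
                        min_group=params.min_group, alpha=params.alpha,
                        grouping=params.grouping, compute_hr=params.compute_hr,
                    )
                except ValidationError as exc:
                    logger.warning("panel screen %s/%s failed: %s", stage, endpoint, exc)
                    continue
                result.panel_screens[(stage, endpoint)] = screen
                _stage_log("panels", stage=stage, endpoint=endpoint,
                           tested=int(screen.counts["tested"].sum()) if len(screen.counts) else 0,
                           passing=int(screen.counts["passing"].sum()) if len(screen.counts) else 0)
    return result


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _params_hash(params: AnalysisParams) -> str:
    blob = json.dumps(dataclasses.asdict(params), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_discovery(result: DiscoveryResult, outdir: str | Path) -> dict:
    """Write every table of a discovery run plus a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.processing_counts.to_csv(outdir / "processing_counts.tsv", sep="\t")
    for cid, tab in result.de_tables.items():
        tab.to_csv(outdir / f"de_{cid}.tsv", sep="\t", na_rep="NA")
    consensus_to_tsv_frame(result.consensus).to_csv(
        outdir / "consensus.tsv", sep="\t")
    consensus_to_tsv_frame(result.final_table).to_csv(
        outdir / "final_mirnas.tsv", sep="\t")
    (outdir / "final_mirnas.txt").write_text("\n".join(result.final_mirnas) + "\n")
    optional = {
        "mti_filtered.tsv": result.mti_filtered,
        "disease_edges.tsv": result.disease_edges,
        "correlations.tsv": result.correlations,
        "enrichment.tsv": result.enrichment,
    }
    for name, tab in optional.items():
        if tab is not None:
            tab.to_csv(outdir / name, sep="\t", index=False, na_rep="NA")
    if result.disease_degrees is not None:
        result.disease_degrees.rename_axis("mirna").to_frame().to_csv(
            outdir / "disease_degrees.tsv", sep="\t")
    if result.pathway_matrix is not None:
        result.pathway_matrix.rename_axis("mirna").to_csv(
            outdir / "pathway_matrix.tsv", sep="\t")
    for cid, tab in result.roc_tables.items():
        tab.to_csv(outdir / f"roc_{cid}.tsv", sep="\t", na_rep="NA")
    for (stage, endpoint), screen in result.panel_screens.items():
        tag = f"{stage or 'all'}_{endpoint}"
        tab = screen.results.copy()
        if len(tab):
            tab["panel"] = tab["panel"].map(lambda p: "+".join(p))
        tab.to_csv(outdir / f"panels_{tag}.tsv", sep="\t", index=False, na_rep="NA")
        screen.counts.to_csv(outdir / f"panel_counts_{tag}.tsv", sep="\t", index=False)

    import lifelines, scipy  # noqa: PLC0415

    manifest = {
        "mirmark_version": __version__,
        "params": dataclasses.asdict(result.params),
        "params_hash": _params_hash(result.params),
        "seed": result.params.seed,
        "reference": result.reference,
        "cohorts": sorted(result.de_tables),
        "n_final_mirnas": len(result.final_mirnas),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str) + "\n")
    summary = {
        "processing_counts": result.processing_counts.to_dict("index"),
        "n_selected": int(result.consensus["selected"].sum()),
        "n_final": len(result.final_mirnas),
        "final_mirnas": result.final_mirnas,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    per_cohort: dict[str, pd.DataFrame]
    concordance: pd.DataFrame
    commonly_down: list[str]


def run_validation(
    frozen_mirnas: Sequence[str],
    validation_cohorts: Sequence[CohortMatrix],
    params: AnalysisParams | None = None,
) -> ValidationResult:
    """Re-apply fold-change direction and ROC evaluation to held-out cohorts.

    For every frozen miRNA and cohort: log2FC, direction, orientation-resolved
    AUC and its accuracy class, or status "absent" when the cohort lacks the
    miRNA (absent entries do not count against concordance). The concordance
    table flags miRNAs downregulated in every cohort where they are evaluable.
    """
    if not frozen_mirnas:
        raise ValidationError("frozen miRNA list is empty")
    params = params or AnalysisParams()
    per_cohort: dict[str, pd.DataFrame] = {}
    direction: dict[str, dict[str, str | None]] = {m: {} for m in frozen_mirnas}
    for cm in validation_cohorts:
        clean, _ = preprocess_cohort(cm, params.missing_threshold, params.fence_k)
        rows = []
        for m in frozen_mirnas:
            if m not in clean.values.index:
                rows.append({"mirna": m, "status": "absent", "log2fc": np.nan,
                             "direction": None, "auc": np.nan, "accuracy_class": None})
                direction[m][cm.cohort_id] = None
                continue
            t, n = clean.group_values(m)
            if len(t) == 0 or len(n) == 0:
                rows.append({"mirna": m, "status": "absent", "log2fc": np.nan,
                             "direction": None, "auc": np.nan, "accuracy_class": None})
                direction[m][cm.cohort_id] = None
                continue
            fc = compute_log2fc(t, n, mode=params.fc_mode)
            d = "down" if fc < 0 else "up"
            try:
                roc = compute_auc(clean.values.loc[m].to_numpy(float),
                                  clean.sample_labels.to_numpy(),
                                  mirna=m, cohort_id=cm.cohort_id)
                auc, acc = roc.auc, roc.accuracy_class
            except ValidationError:
                auc, acc = np.nan, None
            rows.append({"mirna": m, "status": "evaluated", "log2fc": fc,
                         "direction": d, "auc": auc, "accuracy_class": acc})
            direction[m][cm.cohort_id] = d
        per_cohort[cm.cohort_id] = pd.DataFrame(rows).set_index("mirna")

    conc_rows = []
    for m in frozen_mirnas:
        dirs = [d for d in direction[m].values() if d is not None]
        conc_rows.append(
            {
                "mirna": m,
                "n_evaluable": len(dirs),
                "n_down": sum(d == "down" for d in dirs),
                "down_in_all_evaluable": bool(dirs) and all(d == "down" for d in dirs),
            }
        )
    concordance = pd.DataFrame(conc_rows).set_index("mirna")
    commonly_down = sorted(concordance.index[concordance["down_in_all_evaluable"]])
    return ValidationResult(per_cohort, concordance, commonly_down)


# ---------------------------------------------------------------------------
# file-driven configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """File-level description of a run: input paths plus AnalysisParams."""

    cohorts: dict[str, dict]          # cohort_id -> {expression, labels, linear_scale?}
    reference: str
    outdir: str
    clinical: str | None = None
    gene_expression: str | None = None
    gene_labels: str | None = None
    mti: str | None = None
    disease_genes: str | None = None
    gene_sets: str | None = None
    alias_table: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        if self.reference not in self.cohorts:
            raise ValidationError(
                f"reference {self.reference!r} not among cohorts {sorted(self.cohorts)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml  # noqa: PLC0415

        raw = yaml.safe_load(Path(path).read_text())
        params = AnalysisParams(**raw.pop("params", {}))
        for key in ("endpoints", "stages"):
            val = getattr(params, key)
            if isinstance(val, list):
                setattr(params, key, tuple(val))
        return cls(params=params, **raw)


def run_from_config(config: PipelineConfig) -> DiscoveryResult:
    """Load every input named in a config, run discovery, write the bundle."""
    alias = read_alias_table(config.alias_table) if config.alias_table else None
    cohorts = []
    for cid, spec in config.cohorts.items():
        cm = read_expression_matrix(
            spec["expression"], spec["labels"], cohort_id=cid,
            linear_scale=bool(spec.get("linear_scale", False)),
            log2_offset=float(spec.get("log2_offset", 1.0)),
        )
        cohorts.append(canonicalize_matrix(cm, alias) if alias else cm)
    clinical = read_clinical(config.clinical) if config.clinical else None
    gene_matrix = None
    if config.gene_expression and config.gene_labels:
        gene_matrix = read_expression_matrix(config.gene_expression, config.gene_labels,
                                             cohort_id="genes")
    mti = read_mti(config.mti) if config.mti else None
    disease = read_gene_list(config.disease_genes) if config.disease_genes else None
    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
    result = run_discovery(cohorts, config.reference, clinical=clinical,
                           gene_matrix=gene_matrix, mti=mti, disease_genes=disease,
                           gene_sets=gene_sets, params=config.params)
    write_discovery(result, config.outdir)
    return result
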