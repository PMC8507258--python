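"""Synthetic multi-cohort miRNA study generator with planted ground truth.

The generator emulates the structure of a multi-cohort tumour/normal miRNA
study: several cohorts with partially overlapping miRNA inventories and
unequal group sizes, log2-scale expression with entry-level missingness and
spike outliers, a planted set of consistently deregulated miRNAs, a gene
expression layer with planted miRNA-target correlations plus decoy
interactions, and exponential survival times whose hazard depends on a planted
miRNA panel. Every quantity is reproducible from the config seed.

Model choices (see docs/methods.md for rationale):

* baseline expression per miRNA ~ Normal(mean ~ U(4, 12) log2 units, sd =
  ``noise_sd``), identical between groups for null miRNAs;
* planted differential miRNAs shift the tumour mean by ``de_shift`` log2 units
  in every cohort that contains them;
* outliers are additive spikes of ±``outlier_magnitude``;
* survival is exponential with log hazard = log(baseline_hazard) +
  ``panel_log_hr`` x panel score, the panel score being the mean of the panel
  miRNAs' standardized tumour expressions; censoring is independent
  exponential, calibrated so the expected censored fraction at the baseline
  hazard equals ``censor_rate``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import NORMAL, STAGES, TUMOUR, ClinicalTable, CohortMatrix, GeneSetCollection
from .errors import ValidationError
from .io import write_clinical, write_expression_matrix, write_gmt


@dataclass
class SurvivalSimConfig:
    """Survival layer of the simulation."""

    baseline_hazard: float = 0.08          # events per year at panel score 0
    panel: tuple[str, ...] = ()            # empty = first 3 planted DE miRNAs
    panel_log_hr: float = math.log(4.0)
    censor_rate: float = 0.5
    stage_probs: tuple[float, float, float, float] = (0.15, 0.35, 0.35, 0.15)
    rfs_hazard_multiplier: float = 1.5     # recurrence happens before death


@dataclass
class SimulationConfig:
    """Study design of the synthetic multi-cohort experiment.

    ``n_tumour``/``n_normal`` may be single ints (same for every cohort) or
    per-cohort sequences. The defaults sketch a four-cohort design with one
    large tumour-heavy reference cohort, a small paired cohort, a mid-size
    tumour-heavy cohort and a normal-heavy cohort.
    """

    n_cohorts: int = 4
    n_tumour: int | Sequence[int] = (40, 9, 25, 20)
    n_normal: int | Sequence[int] = (10, 9, 12, 30)
    n_mirnas: int = 500
    mirna_overlap_fraction: float = 0.6
    n_true_de: int = 25
    de_shift: float = -2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    outlier_magnitude: float = 6.0
    n_genes: int = 300
    n_true_correlated_pairs: int = 40
    target_corr: float = 0.6
    disease_gene_fraction: float = 0.6
    n_gene_sets: int = 6
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    seed: int = 0

    def per_cohort(self, value: int | Sequence[int]) -> list[int]:
        if isinstance(value, (int, np.integer)):
            return [int(value)] * self.n_cohorts
        out = [int(v) for v in value]
        if len(out) != self.n_cohorts:
            raise ValidationError(
                f"per-cohort sizes {out} do not match n_cohorts={self.n_cohorts}"
            )
        return out

    def validate(self) -> None:
        if self.n_cohorts < 2:
            raise ValidationError("need at least 2 cohorts")
        for v in self.per_cohort(self.n_tumour) + self.per_cohort(self.n_normal):
            if v < 1:
                raise ValidationError("group sizes must be positive")
        if self.n_mirnas < 1 or self.n_genes < 1:
            raise ValidationError("feature counts must be positive")
        if not (0 <= self.n_true_de <= self.n_mirnas):
            raise ValidationError("n_true_de must be in [0, n_mirnas]")
        if self.n_true_correlated_pairs > self.n_genes:
            raise ValidationError("n_true_correlated_pairs exceeds n_genes")
        for name in ("mirna_overlap_fraction", "missing_rate", "outlier_rate",
                     "disease_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.target_corr) > 1:
            raise ValidationError("target_corr must lie in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        sv = self.survival
        if sv.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if not (0.0 <= sv.censor_rate < 1.0):
            raise ValidationError("censor_rate must lie in [0, 1)")
        if abs(sum(sv.stage_probs) - 1.0) > 1e-9 or min(sv.stage_probs) < 0:
            raise ValidationError("stage_probs must be a probability simplex")


@dataclass
class GroundTruth:
    """Planted effects the downstream analysis should recover."""

    true_de: dict[str, str]                       # miRNA -> "up"/"down"
    true_pairs: list[tuple[str, str, int]]        # (miRNA, gene, sign)
    prognostic_panel: tuple[str, ...]
    panel_log_hr: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_de": self.true_de,
                "true_pairs": [list(p) for p in self.true_pairs],
                "prognostic_panel": list(self.prognostic_panel),
                "panel_log_hr": self.panel_log_hr,
            },
            indent=2,
        )


def _mirna_names(n: int) -> list[str]:
    return [f"miR-{i + 1:04d}" for i in range(n)]


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def simulate_cohorts(config: SimulationConfig) -> tuple[list[CohortMatrix], GroundTruth]:
    """Generate the per-cohort log2 expression matrices and the ground truth.

    A core inventory of ``round(overlap_fraction * n_mirnas)`` miRNAs (which
    hosts every planted DE miRNA) is present in all cohorts; each remaining
    miRNA enters each cohort independently with probability 1/2, giving the
    cohorts genuinely different inventories. The first cohort ("C1") is the
    intended reference cohort.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    names = np.array(_mirna_names(config.n_mirnas))
    baseline = rng.uniform(4.0, 12.0, size=config.n_mirnas)

    n_core = max(config.n_true_de, int(round(config.mirna_overlap_fraction * config.n_mirnas)))
    n_core = min(max(n_core, 1), config.n_mirnas)
    core_idx = np.arange(n_core)
    de_idx = rng.choice(core_idx, size=config.n_true_de, replace=False) \
        if config.n_true_de else np.array([], dtype=int)
    de_set = set(de_idx.tolist())
    direction = "down" if config.de_shift < 0 else "up"
    true_de = {str(names[i]): direction for i in sorted(de_set)}

    n_t = config.per_cohort(config.n_tumour)
    n_n = config.per_cohort(config.n_normal)
    cohorts: list[CohortMatrix] = []
    for c in range(config.n_cohorts):
        cid = f"C{c + 1}"
        extra = np.nonzero(rng.random(config.n_mirnas - n_core) < 0.5)[0] + n_core
        idx = np.r_[core_idx, extra]
        n_feat = len(idx)
        n_samples = n_t[c] + n_n[c]
        values = rng.normal(baseline[idx][:, None], config.noise_sd,
                            size=(n_feat, n_samples))
        tumour_cols = np.arange(n_t[c])
        de_rows = np.nonzero(np.isin(idx, list(de_set)))[0]
        if len(de_rows) and config.de_shift != 0.0:
            values[np.ix_(de_rows, tumour_cols)] += config.de_shift
        if config.outlier_rate > 0:
            spikes = rng.random(values.shape) < config.outlier_rate
            signs = rng.choice([-1.0, 1.0], size=values.shape)
            values = values + spikes * signs * config.outlier_magnitude
        if config.missing_rate > 0:
            values[rng.random(values.shape) < config.missing_rate] = np.nan
        samples = [f"{cid}-T{i + 1:03d}" for i in range(n_t[c])] + [
            f"{cid}-N{i + 1:03d}" for i in range(n_n[c])
        ]
        labels = pd.Series([TUMOUR] * n_t[c] + [NORMAL] * n_n[c], index=samples)
        frame = pd.DataFrame(values, index=names[idx], columns=samples)
        cohorts.append(CohortMatrix(cid, frame, labels))

    panel = tuple(config.survival.panel) or tuple(sorted(true_de)[: min(3, len(true_de))])
    truth = GroundTruth(
        true_de=true_de,
        true_pairs=[],
        prognostic_panel=panel,
        panel_log_hr=config.survival.panel_log_hr,
    )
    return cohorts, truth


def _standardized_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores with missing entries imputed at the row mean (z = 0)."""
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = frame.sub(mean, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


def simulate_clinical(
    config: SimulationConfig, tumour_matrix: CohortMatrix, truth: GroundTruth
) -> ClinicalTable:
    """Exponential survival times for the tumour patients of one cohort.

    Per patient, the event hazard is ``baseline_hazard * exp(panel_log_hr *
    panel_score)``; recurrence uses the same score with a higher baseline.
    Censoring is independent exponential with rate chosen so that, at the
    baseline hazard, the expected censored fraction equals ``censor_rate``
    (``censor_rate=0`` disables censoring entirely). Stages are i.i.d. from
    ``stage_probs``.
    """
    config.validate()
    sv = config.survival
    panel = tuple(sv.panel) or truth.prognostic_panel
    if not panel and sv.panel_log_hr != 0.0:
        raise ValidationError("empty panel with nonzero panel_log_hr")
    missing = [m for m in panel if m not in tumour_matrix.values.index]
    if missing:
        raise ValidationError(f"panel miRNAs absent from tumour matrix: {missing}")
    rng = np.random.default_rng([config.seed, 1])
    patients = tumour_matrix.tumour_samples
    n = len(patients)
    if panel:
        z = _standardized_rows(tumour_matrix.values.loc[list(panel), patients])
        score = z.mean(axis=0).to_numpy()
    else:
        score = np.zeros(n)

    def draw(base_hazard: float) -> tuple[np.ndarray, np.ndarray]:
        haz = base_hazard * np.exp(sv.panel_log_hr * score)
        event_t = rng.exponential(1.0 / haz)
        if sv.censor_rate > 0:
            lam_c = base_hazard * sv.censor_rate / (1.0 - sv.censor_rate)
            censor_t = rng.exponential(1.0 / lam_c, size=n)
        else:
            censor_t = np.full(n, np.inf)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        return time, event

    os_time, os_event = draw(sv.baseline_hazard)
    rfs_time, rfs_event = draw(sv.baseline_hazard * sv.rfs_hazard_multiplier)
    stage = rng.choice(list(STAGES), size=n, p=list(sv.stage_probs))
    df = pd.DataFrame(
        {
            "stage": stage,
            "os_time": os_time,
            "os_event": os_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return ClinicalTable(df)


def simulate_target_layer(
    config: SimulationConfig,
    reference_matrix: CohortMatrix,
    truth: GroundTruth,
) -> tuple[CohortMatrix, pd.DataFrame, list[str], GeneSetCollection]:
    """Gene expression, MTI edges, disease genes and gene sets for one cohort.

    Planted pairs tie a gene's expression to a miRNA so their correlation is
    ``sign * target_corr`` in expectation; every other gene is independent
    noise. The MTI table holds all planted pairs plus decoy edges (including a
    few non-human and weak-evidence rows so support filters have something to
    drop); the disease-gene list covers ``disease_gene_fraction`` of targeted
    genes plus untargeted padding; gene sets partition a subset of the genes.
    Ground truth pairs are recorded on ``truth.true_pairs`` in place.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    genes = np.array(_gene_names(config.n_genes))
    samples = reference_matrix.samples
    n_s = len(samples)
    gene_base = rng.uniform(4.0, 12.0, size=config.n_genes)
    values = rng.normal(gene_base[:, None], 1.0, size=(config.n_genes, n_s))

    mirnas = np.array(reference_matrix.mirna_ids)
    n_pairs = config.n_true_correlated_pairs
    pair_mirnas = rng.choice(mirnas, size=n_pairs, replace=True) if n_pairs else []
    pair_genes = rng.choice(config.n_genes, size=n_pairs, replace=False) if n_pairs else []
    signs = rng.choice([-1, 1], size=n_pairs)
    rho = abs(config.target_corr)
    z_all = _standardized_rows(reference_matrix.values[samples])
    truth.true_pairs = []
    for m, gi, s in zip(pair_mirnas, pair_genes, signs):
        z = z_all.loc[m].to_numpy()
        eps = rng.normal(size=n_s)
        values[gi] = gene_base[gi] + s * rho * z + math.sqrt(max(0.0, 1 - rho * rho)) * eps
        truth.true_pairs.append((str(m), str(genes[gi]), int(s)))

    gene_frame = pd.DataFrame(values, index=genes, columns=samples)
    gene_matrix = CohortMatrix(
        f"{reference_matrix.cohort_id}-genes", gene_frame,
        reference_matrix.sample_labels.copy(),
    )

    # MTI table: planted pairs + human decoys + rows the filters must drop
    rows = [
        {"mirna": m, "gene": g, "species": "Homo sapiens",
         "support_type": "Functional MTI"}
        for m, g, _ in truth.true_pairs
    ]
    true_set = {(m, g) for m, g, _ in truth.true_pairs}
    n_decoys = min(3 * max(n_pairs, 5), config.n_genes * 2)
    made = 0
    while made < n_decoys:
        m = str(rng.choice(mirnas))
        g = str(genes[rng.integers(config.n_genes)])
        if (m, g) in true_set:
            continue
        true_set.add((m, g))
        rows.append({"mirna": m, "gene": g, "species": "Homo sapiens",
                     "support_type": "Functional MTI"})
        made += 1
    for i in range(2):
        rows.append({"mirna": str(mirnas[i % len(mirnas)]), "gene": str(genes[i]),
                     "species": "Mus musculus", "support_type": "Functional MTI"})
        rows.append({"mirna": str(mirnas[(i + 1) % len(mirnas)]), "gene": str(genes[i]),
                     "species": "Homo sapiens",
                     "support_type": "Functional MTI (Weak)"})
    mti = pd.DataFrame(rows, columns=["mirna", "gene", "species", "support_type"])

    targeted = sorted({g for _, g, _ in truth.true_pairs}
                      | set(mti.loc[mti["species"] == "Homo sapiens", "gene"]))
    n_disease = int(round(config.disease_gene_fraction * len(targeted)))
    disease = sorted(rng.choice(targeted, size=n_disease, replace=False).tolist()) \
        if n_disease else []
    untargeted = [g for g in genes if g not in set(targeted)]
    disease += sorted(rng.choice(untargeted,
                                 size=min(10, len(untargeted)), replace=False).tolist())

    # gene sets partition a shuffled 60% subset of the genes
    subset = rng.permutation(genes)[: max(config.n_gene_sets, int(0.6 * config.n_genes))]
    chunks = np.array_split(subset, config.n_gene_sets)
    sets = {f"PATH{i + 1:02d}": tuple(str(g) for g in chunk)
            for i, chunk in enumerate(chunks) if len(chunk)}
    collection = GeneSetCollection(sets)
    return gene_matrix, mti, disease, collection


def simulate_study(config: SimulationConfig):
    """Full study bundle: cohorts, truth, clinical table and target layer.

    The clinical table and the target layer are generated for the reference
    (first) cohort only, mirroring a design where a single rich cohort carries
    survival follow-up and matched gene expression.
    """
    cohorts, truth = simulate_cohorts(config)
    reference = cohorts[0]
    clinical = simulate_clinical(config, reference, truth)
    gene_matrix, mti, disease, gene_sets = simulate_target_layer(config, reference, truth)
    return cohorts, truth, clinical, gene_matrix, mti, disease, gene_sets


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate a study and write every table in the formats `mirmark.io` reads.

    Returns a manifest of written paths (also dumped to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts, truth, clinical, gene_matrix, mti, disease, gene_sets = simulate_study(config)
    manifest: dict = {"reference": cohorts[0].cohort_id, "cohorts": {}}
    for cm in cohorts:
        expr = outdir / f"{cm.cohort_id}_expression.tsv"
        lab = outdir / f"{cm.cohort_id}_labels.tsv"
        write_expression_matrix(cm, expr, lab)
        manifest["cohorts"][cm.cohort_id] = {"expression": str(expr), "labels": str(lab)}
    write_clinical(clinical, outdir / "clinical.tsv")
    write_expression_matrix(gene_matrix, outdir / "genes_expression.tsv",
                            outdir / "genes_labels.tsv")
    mti.to_csv(outdir / "mti.tsv", sep="\t", index=False)
    (outdir / "disease_genes.txt").write_text("\n".join(disease) + "\n")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    manifest.update(
        clinical=str(outdir / "clinical.tsv"),
        gene_expression=str(outdir / "genes_expression.tsv"),
        gene_labels=str(outdir / "genes_labels.tsv"),
        mti=str(outdir / "mti.tsv"),
        disease_genes=str(outdir / "disease_genes.txt"),
        gene_sets=str(outdir / "gene_sets.gmt"),
        ground_truth=str(outdir / "ground_truth.json"),
        config=dataclasses.asdict(config),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
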