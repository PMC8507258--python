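# mirmark

Multi-cohort miRNA biomarker discovery for tumour/normal expression studies:
cross-cohort differential-expression consensus, miRNA–target network analysis,
per-miRNA diagnostic ROC evaluation, and exhaustive prognostic panel screening
on survival data. The package is aimed at bioinformaticians integrating
several public miRNA expression cohorts (e.g. one large reference cohort with
clinical follow-up plus several smaller supporting cohorts) to nominate
diagnostic and prognostic miRNA biomarkers, and it ships a synthetic study
generator with planted ground truth so the entire workflow is testable
offline.

## What it computes

**Preprocessing.** Per cohort, a miRNA is dropped when more than half of its
values are missing in the tumour group *or* in the normal group (modified
listwise deletion); surviving values outside the per-miRNA, per-group Tukey
fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are masked as missing.

**Differential consensus.** Per miRNA and cohort, Shapiro–Wilk normality
routes the comparison to Levene + Student/Welch *t* or to a two-sided
Mann–Whitney *U* (exact for small tie-free samples); p-values are
Benjamini–Hochberg adjusted within each cohort, and effect size is the log2
fold change `log2FC = mean(tumour) − mean(normal)` (a linear-mean-ratio mode
is available). A miRNA enters the consensus list when q ≤ 0.05 in the
reference cohort **and** in ≥ 2 supporting cohorts, and it survives the
direction filter only if sign(log2FC) agrees in every cohort where it is
significant.

**Target network.** Validated miRNA→gene interactions are filtered to human,
functional-evidence edges, crossed with a disease-gene list, and each
measurable pair is correlated on matched samples (Pearson when both vectors
pass normality, Spearman otherwise) with strength classified on the Mukaka
scale. Gene-set over-representation uses the hypergeometric upper tail
`p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n)` with BH correction across sets, plus a
binary miRNA × pathway crossing matrix.

**Diagnostics.** Per miRNA, AUC from the Mann–Whitney U statistic (ties count
½), orientation-resolved as `max(A, 1−A)` so downregulated markers score
symmetrically, and binned by the Greiner classification (perfect = 1,
highly > 0.9, moderately (0.7, 0.9], less (0.5, 0.7] accurate).

**Prognosis.** Patients are dichotomized at each miRNA's median tumour
expression (strictly above = "higher"); multi-miRNA panels use the
concordant-median rule (same side of the median for every panel member,
discordant patients excluded). All panels of 2–5 miRNAs whose smaller group
has ≥ 30 patients are tested per stage and endpoint (OS/RFS) with the
two-group log-rank test, and the hazard ratio of higher vs lower comes from a
single-covariate Cox proportional-hazards fit (Efron ties, 95% Wald CI).

## Worked example

```python
import mirmark as mm

config = mm.SimulationConfig(n_cohorts=4, n_tumour=(150, 9, 20, 15),
                             n_normal=(10, 9, 10, 20), n_mirnas=60, n_true_de=8,
                             noise_sd=0.5, seed=21)
cohorts, truth, clinical, genes, mti, disease, pathways = mm.simulate_study(config)

params = mm.AnalysisParams(k_min=2, k_max=3, min_group=10,
                           stages=(None,), endpoints=("OS",))
result = mm.run_discovery(cohorts, "C1", clinical=clinical, gene_matrix=genes,
                          mti=mti, disease_genes=disease, gene_sets=pathways,
                          params=params)

planted = set(truth.true_de)
found = set(result.final_mirnas)
print("planted downregulated miRNAs :", len(planted))
print("consensus miRNAs recovered   :", len(found & planted), "of", len(found), "selected")
ref_roc = result.roc_tables["C1"].loc[sorted(found)]
print("median AUC (reference cohort):", round(ref_roc["auc"].median(), 3))
screen = result.panel_screens[(None, "OS")]
best = screen.results.iloc[0]
print("best survival panel          :", "+".join(best["panel"]))
print("  log-rank p = %.4f, HR = %.2f (%d vs %d patients)" % (
    best["logrank_p"], best["hr"], best["n_higher"], best["n_lower"]))
```

prints

```
planted downregulated miRNAs : 8
consensus miRNAs recovered   : 8 of 8 selected
median AUC (reference cohort): 1.0
best survival panel          : miR-0010+miR-0029
  log-rank p = 0.0002, HR = 4.13 (32 vs 33 patients)
```

The generator planted 8 downregulated miRNAs (−2 log2 units) and a 3-miRNA
prognostic panel with hazard-ratio 4 per unit panel score; the consensus
stage recovers all 8 with no false selections, they separate tumour from
normal essentially perfectly in the large reference cohort, and the panel
screen's top hit is a sub-panel of the planted panel (miR-0010 belongs to it)
whose "higher expression" group dies ~4× faster.

The same workflow runs from the shell: `mirmark simulate`, `preprocess`,
`de`, `consensus`, `targets`, `correlate`, `roc`, `survival-panels`,
`validate`, and `run-all --config run.yaml` for the full discovery bundle
(TSV tables + JSON summary + provenance manifest). Real data enter as
TSV expression matrices with a two-column sample-label sidecar, a clinical
TSV, an MTI edge TSV, a disease-gene list and a GMT gene-set file.

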