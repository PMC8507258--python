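"""Two-group differential expression per cohort and cross-cohort consensus.

Per miRNA the test is chosen by a normality/variance decision tree:

* ``policy="conventional"`` (default): Shapiro-Wilk on each group; if both
  groups look normal (p > alpha) run Levene's test (center = mean) and then a
  Student t (equal variances) or Welch t (unequal); otherwise a two-sided
  Mann-Whitney U (exact for small tie-free samples, tie-corrected normal
  approximation otherwise).
* ``policy="paper_literal"``: the branch inverted — normal data go to
  Mann-Whitney and non-normal data to Levene + t. Some published pipelines
  state the rule this way; both readings are reproducible here.

P-values are Benjamini-Hochberg adjusted within each cohort (the adjustment
batch is the set of miRNAs actually tested in that cohort, since cohorts have
different miRNA inventories). Effect size is the log2 fold change, by default
the difference of group means on the log2 scale.

Consensus calling mirrors a discovery design with one large reference cohort
and several supporting cohorts: a miRNA is *selected* when it is significant
(q <= threshold) in the reference cohort and in at least ``min_support`` of
the non-reference cohorts, and it survives the direction filter only if its
fold-change direction agrees in every cohort where it was significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CohortMatrix
from .errors import ValidationError

POLICIES = ("conventional", "paper_literal")
FC_MODES = ("diff_of_log_means", "log_of_linear_mean_ratio")

#: largest combined sample size for which the exact Mann-Whitney null is used
_EXACT_MW_MAX_N = 20


@dataclass
class DifferentialTest:
    """Outcome of the two-group test for one miRNA in one cohort."""

    shapiro_p_tumour: float
    shapiro_p_normal: float
    variance_test_p: float | None
    test_used: str
    p_value: float


def _shapiro_p(x: np.ndarray) -> float:
    # a constant sample is maximally non-normal for routing purposes
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= _EXACT_MW_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def test_differential(
    tumour_values: Sequence[float],
    normal_values: Sequence[float],
    policy: str = "conventional",
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
    force_test: str | None = None,
) -> DifferentialTest:
    """Run the policy-selected two-group test on one miRNA's values.

    Both groups must have at least 3 non-missing values (the Shapiro-Wilk
    minimum). Two zero-variance groups with equal means yield p = 1 by
    convention. ``force_test`` bypasses the selection tree and runs the named
    branch ("mann_whitney", "student_t" or "welch_t") directly.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}")
    t = np.asarray(tumour_values, float)
    n = np.asarray(normal_values, float)
    t, n = t[~np.isnan(t)], n[~np.isnan(n)]
    if len(t) < 3 or len(n) < 3:
        raise ValidationError(
            f"need >= 3 non-missing values per group (got {len(t)}/{len(n)})"
        )
    if np.ptp(t) == 0 and np.ptp(n) == 0 and t[0] == n[0]:
        return DifferentialTest(0.0, 0.0, None, "degenerate", 1.0)

    sp_t, sp_n = _shapiro_p(t), _shapiro_p(n)
    if force_test is not None:
        if force_test == "mann_whitney":
            return DifferentialTest(sp_t, sp_n, None, "mann_whitney",
                                    _mannwhitney_p(t, n))
        if force_test in ("student_t", "welch_t"):
            p = float(stats.ttest_ind(t, n, equal_var=force_test == "student_t").pvalue)
            return DifferentialTest(sp_t, sp_n, None, force_test, p)
        raise ValidationError(f"unknown forced test {force_test!r}")
    both_normal = sp_t > alpha_normality and sp_n > alpha_normality
    use_parametric = both_normal if policy == "conventional" else not both_normal

    if use_parametric:
        lev_p = float(stats.levene(t, n, center="mean").pvalue)
        if lev_p > alpha_variance:
            p = float(stats.ttest_ind(t, n, equal_var=True).pvalue)
            test = "student_t"
        else:
            p = float(stats.ttest_ind(t, n, equal_var=False).pvalue)
            test = "welch_t"
        return DifferentialTest(sp_t, sp_n, lev_p, test, p)

    p = _mannwhitney_p(t, n)
    return DifferentialTest(sp_t, sp_n, None, "mann_whitney", p)


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_log2fc(
    tumour_values: Sequence[float],
    normal_values: Sequence[float],
    mode: str = "diff_of_log_means",
) -> float:
    """Tumour-minus-normal log2 fold change.

    ``diff_of_log_means`` subtracts group means of the (already log2) values;
    ``log_of_linear_mean_ratio`` un-logs, takes the ratio of linear-scale group
    means, and re-logs. The two agree only for degenerate data, so the choice
    is explicit.
    """
    if mode not in FC_MODES:
        raise ValidationError(f"unknown fc mode {mode!r}")
    t = np.asarray(tumour_values, float)
    n = np.asarray(normal_values, float)
    t, n = t[~np.isnan(t)], n[~np.isnan(n)]
    if len(t) == 0 or len(n) == 0:
        raise ValidationError("cannot compute log2FC with an all-missing group")
    if mode == "diff_of_log_means":
        return float(t.mean() - n.mean())
    return float(np.log2(np.mean(2.0 ** t) / np.mean(2.0 ** n)))


def cohort_differential(
    matrix: CohortMatrix,
    policy: str = "conventional",
    fc_mode: str = "diff_of_log_means",
    alpha_normality: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Differential table for every testable miRNA of one cohort.

    Returns the per-miRNA result table (indexed by miRNA, with raw p and BH
    q-values) and the list of miRNAs skipped because a group had fewer than 3
    observed values; skipped miRNAs are excluded from the adjustment batch.
    """
    rows: list[dict] = []
    skipped: list[str] = []
    for mirna in matrix.values.index:
        t, n = matrix.group_values(mirna)
        if len(t) < 3 or len(n) < 3:
            skipped.append(mirna)
            continue
        res = test_differential(t, n, policy=policy, alpha_normality=alpha_normality)
        rows.append(
            {
                "mirna": mirna,
                "cohort_id": matrix.cohort_id,
                "shapiro_p_tumour": res.shapiro_p_tumour,
                "shapiro_p_normal": res.shapiro_p_normal,
                "variance_test_p": res.variance_test_p,
                "test_used": res.test_used,
                "p_value": res.p_value,
                "log2fc": compute_log2fc(t, n, mode=fc_mode),
                "n_tumour": len(t),
                "n_normal": len(n),
            }
        )
    if not rows:
        raise ValidationError(f"{matrix.cohort_id}: no testable miRNAs")
    table = pd.DataFrame(rows).set_index("mirna")
    table["q_value"] = adjust_fdr(table["p_value"].to_numpy())
    return table, skipped


# ---------------------------------------------------------------------------
# cross-cohort consensus
# ---------------------------------------------------------------------------

def consensus_select(
    results: Mapping[str, pd.DataFrame],
    reference_cohort: str,
    min_support: int = 2,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Cross-cohort consensus table over per-cohort differential results.

    A miRNA is selected when significant (q <= threshold) in the reference
    cohort and in at least ``min_support`` supporting cohorts. Directions are
    the fold-change signs recorded in every cohort where the miRNA was
    significant; ``direction_consistent`` requires them all equal.
    """
    if reference_cohort not in results:
        raise ValidationError(f"reference cohort {reference_cohort!r} not among inputs")
    sig: dict[str, pd.DataFrame] = {}
    for cid in sorted(results):
        tab = results[cid]
        sig[cid] = tab[tab["q_value"] <= q_threshold]
    all_mirnas = sorted(set().union(*(set(t.index) for t in results.values())))
    rows = []
    for mirna in all_mirnas:
        cohorts_sig = tuple(c for c in sorted(results) if mirna in sig[c].index)
        directions = {
            c: ("down" if sig[c].loc[mirna, "log2fc"] < 0 else "up") for c in cohorts_sig
        }
        in_reference = reference_cohort in cohorts_sig
        n_support = sum(1 for c in cohorts_sig if c != reference_cohort)
        selected = in_reference and n_support >= min_support
        consistent = len(set(directions.values())) <= 1
        if selected:
            # reference + min_support supporters: a selected miRNA always has
            # directions recorded in >= 1 + min_support cohorts
            assert len(directions) >= 1 + min_support
        rows.append(
            {
                "mirna": mirna,
                "cohorts_significant": cohorts_sig,
                "directions": directions,
                "direction": directions.get(reference_cohort)
                or (next(iter(directions.values())) if directions else None),
                "in_reference": in_reference,
                "n_support": n_support,
                "selected": selected,
                "direction_consistent": consistent,
            }
        )
    return pd.DataFrame(rows).set_index("mirna")


def direction_filter(consensus: pd.DataFrame) -> pd.DataFrame:
    """Restrict a consensus table to selected, direction-consistent miRNAs."""
    keep = consensus["selected"] & consensus["direction_consistent"]
    return consensus[keep].copy()


def consensus_to_tsv_frame(consensus: pd.DataFrame) -> pd.DataFrame:
    """Flatten tuple/dict columns of a consensus table for TSV export."""
    out = consensus.copy()
    out["cohorts_significant"] = out["cohorts_significant"].map(",".join)
    out["directions"] = out["directions"].map(
        lambda d: "|".join(f"{c}:{v}" for c, v in d.items())
    )
    return out
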