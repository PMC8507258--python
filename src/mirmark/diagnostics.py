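"""Per-miRNA ROC analysis for tumour-vs-normal classification.

The AUC is computed from the Mann-Whitney U statistic (ties contribute 1/2),
with the tumour class as positive on ascending score. Because downregulated
markers separate classes just as well as upregulated ones, the reported AUC is
orientation-resolved — ``max(A, 1 - A)`` — with the raw oriented value and the
orientation retained for audit. Accuracy classes follow Greiner's bins:
perfect (AUC = 1), highly accurate (0.9 < AUC < 1), moderately accurate
(0.7 < AUC <= 0.9), less accurate (0.5 < AUC <= 0.7), uninformative otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import TUMOUR, CohortMatrix
from .errors import ValidationError


@dataclass
class RocResult:
    mirna: str
    cohort_id: str
    auc: float
    raw_auc: float
    orientation: str
    n_tumour: int
    n_normal: int
    accuracy_class: str


def classify_auc(auc: float) -> str:
    """Greiner accuracy class of an AUC value."""
    if not (0.0 <= auc <= 1.0):
        raise ValidationError(f"AUC out of range: {auc}")
    if auc == 1.0:
        return "perfect"
    if auc > 0.9:
        return "high"
    if auc > 0.7:
        return "moderate"
    if auc > 0.5:
        return "less"
    return "uninformative"


def compute_auc(scores, labels, mirna: str = "", cohort_id: str = "") -> RocResult:
    """Orientation-resolved AUC of one marker.

    ``labels`` holds "tumour"/"normal" per score; samples with a missing score
    are dropped pairwise. ``raw_auc`` is P(tumour score > normal score) +
    1/2 P(tie); the resolved ``auc`` is ``max(raw, 1 - raw)`` with orientation
    "high_in_tumour" when raw >= 0.5.
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels)
    ok = ~np.isnan(s)
    s, lab = s[ok], lab[ok]
    pos = lab == TUMOUR
    n_t, n_n = int(pos.sum()), int((~pos).sum())
    if n_t == 0 or n_n == 0:
        raise ValidationError("both classes must be present with observed scores")
    ranks = rankdata(s)  # average ranks give the 1/2-per-tie convention
    u = ranks[pos].sum() - n_t * (n_t + 1) / 2.0
    raw = float(u / (n_t * n_n))
    auc = max(raw, 1.0 - raw)
    orientation = "high_in_tumour" if raw >= 0.5 else "low_in_tumour"
    return RocResult(mirna, cohort_id, auc, raw, orientation, n_t, n_n, classify_auc(auc))


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) coordinates of the empirical ROC curve (descending cutoffs)."""
    s = np.asarray(scores, float)
    lab = np.asarray(labels)
    ok = ~np.isnan(s)
    s, pos = s[ok], (lab[ok] == TUMOUR)
    order = np.argsort(-s, kind="mergesort")
    s, pos = s[order], pos[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(pos)[distinct]
    fp = np.cumsum(~pos)[distinct]
    tpr = np.r_[0.0, tp / pos.sum()]
    fpr = np.r_[0.0, fp / (~pos).sum()]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def cohort_roc(matrix: CohortMatrix, mirnas=None) -> pd.DataFrame:
    """ROC table for each (requested) miRNA of a cohort."""
    wanted = list(mirnas) if mirnas is not None else list(matrix.values.index)
    rows = []
    for mirna in wanted:
        if mirna not in matrix.values.index:
            continue
        row = matrix.values.loc[mirna]
        try:
            res = compute_auc(
                row.to_numpy(float),
                matrix.sample_labels.to_numpy(),
                mirna=mirna,
                cohort_id=matrix.cohort_id,
            )
        except ValidationError:
            continue
        rows.append(res.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "cohort_id", "auc", "raw_auc", "orientation",
            "n_tumour", "n_normal", "accuracy_class",
        ],
    ).set_index("mirna")
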