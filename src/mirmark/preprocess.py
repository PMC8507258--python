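"""Per-cohort data cleaning: missingness filtering and boxplot outlier removal.

Two steps, applied in this order:

1. ``filter_missing`` — a modified listwise deletion that drops a miRNA when
   more than half (strictly) of its values are missing in the tumour group or
   in the normal group (per-group denominators).
2. ``remove_outliers`` — per miRNA and per class group, values outside the
   Tukey fences ``[Q1 - k*IQR, Q3 + k*IQR]`` (k = 1.5 by default, quartiles by
   linear interpolation, fences inclusive) are masked to missing. A single
   pass, no re-fencing; groups with fewer than 4 observed values are left
   untouched because their quartiles are unstable.

Outlier removal masks individual entries rather than deleting samples: a value
may be an outlier for one miRNA and perfectly ordinary for another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortMatrix
from .errors import ValidationError


@dataclass
class PreprocessReport:
    """What a preprocessing step changed in one cohort."""

    cohort_id: str
    step: str
    n_features_before: int
    n_features_after: int
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_entries: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "step": self.step,
            "n_features_before": self.n_features_before,
            "n_features_after": self.n_features_after,
            "n_dropped": len(self.dropped),
            "n_entries_removed": len(self.removed_entries),
            "n_warnings": len(self.warnings),
        }


def filter_missing(
    matrix: CohortMatrix, threshold: float = 0.5
) -> tuple[CohortMatrix, PreprocessReport]:
    """Drop miRNAs whose missing fraction exceeds ``threshold`` in either group.

    The inequality is strict ("more than half"): a miRNA missing exactly 50%
    in both groups is retained at the default threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    t_cols = matrix.tumour_samples
    n_cols = matrix.normal_samples
    miss_t = matrix.values[t_cols].isna().mean(axis=1)
    miss_n = matrix.values[n_cols].isna().mean(axis=1)
    drop_mask = (miss_t > threshold) | (miss_n > threshold)
    dropped = pd.DataFrame(
        {
            "mirna": matrix.values.index[drop_mask],
            "missing_frac_tumour": miss_t[drop_mask].to_numpy(),
            "missing_frac_normal": miss_n[drop_mask].to_numpy(),
            "reason": "missingness",
        }
    )
    kept = matrix.values.loc[~drop_mask]
    if kept.shape[0] == 0:
        raise ValidationError(f"{matrix.cohort_id}: all miRNAs dropped by missingness filter")
    report = PreprocessReport(
        cohort_id=matrix.cohort_id,
        step="filter_missing",
        n_features_before=matrix.values.shape[0],
        n_features_after=kept.shape[0],
        dropped=dropped,
    )
    return matrix.with_values(kept.copy()), report


def tukey_fences(values: np.ndarray, fence_k: float = 1.5) -> tuple[float, float]:
    """Closed boxplot fences of a 1-D array of observed (non-NaN) values.

    Quartiles use linear interpolation between order statistics.
    """
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if math.isinf(fence_k):
        return -math.inf, math.inf
    return q1 - fence_k * iqr, q3 + fence_k * iqr


def remove_outliers(
    matrix: CohortMatrix, fence_k: float = 1.5
) -> tuple[CohortMatrix, PreprocessReport]:
    """Mask values outside the per-miRNA, per-group Tukey fences as missing.

    Values exactly at a fence are kept (inclusive bounds); in particular a
    group of identical values (IQR = 0) loses nothing.
    """
    values = matrix.values.copy()
    removed: list[dict] = []
    warnings: list[str] = []
    groups = {
        "tumour": matrix.tumour_samples,
        "normal": matrix.normal_samples,
    }
    for group_name, cols in groups.items():
        block = values[cols]
        arr = block.to_numpy(float)
        for i, mirna in enumerate(block.index):
            row = arr[i]
            observed = row[~np.isnan(row)]
            if observed.size < 4:
                if observed.size > 0:
                    warnings.append(
                        f"{mirna}/{group_name}: only {observed.size} observed values, "
                        "fences skipped"
                    )
                continue
            lo, hi = tukey_fences(observed, fence_k)
            out = (~np.isnan(row)) & ((row < lo) | (row > hi))
            for j in np.nonzero(out)[0]:
                removed.append(
                    {
                        "mirna": mirna,
                        "sample": cols[j],
                        "value": row[j],
                        "group": group_name,
                    }
                )
                values.loc[mirna, cols[j]] = np.nan
    report = PreprocessReport(
        cohort_id=matrix.cohort_id,
        step="remove_outliers",
        n_features_before=matrix.values.shape[0],
        n_features_after=values.shape[0],
        removed_entries=pd.DataFrame(removed, columns=["mirna", "sample", "value", "group"]),
        warnings=warnings,
    )
    return matrix.with_values(values), report


def preprocess_cohort(
    matrix: CohortMatrix, missing_threshold: float = 0.5, fence_k: float = 1.5
) -> tuple[CohortMatrix, list[PreprocessReport]]:
    """Missingness filter followed by single-pass outlier masking."""
    filtered, rep1 = filter_missing(matrix, missing_threshold)
    cleaned, rep2 = remove_outliers(filtered, fence_k)
    return cleaned, [rep1, rep2]
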