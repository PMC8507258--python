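"""Core in-memory containers for cohort expression, clinical and annotation data.

Expression data lives in a :class:`CohortMatrix`: a pandas DataFrame of log2
expression values with miRNAs (or genes) in rows and samples in columns, plus a
tumour/normal label per sample. ``NaN`` entries denote missing measurements;
zeros are valid measurements and are never treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

TUMOUR = "tumour"
NORMAL = "normal"
CLASSES = (TUMOUR, NORMAL)

STAGES = ("I", "II", "III", "IV")


@dataclass
class CohortMatrix:
    """One cohort's log2 expression values with per-sample class labels.

    Parameters
    ----------
    cohort_id : str
        Identifier of the cohort (e.g. a GEO accession).
    values : pandas.DataFrame
        Features in rows, samples in columns, float dtype, NaN = missing.
    sample_labels : pandas.Series
        Class label per sample, values in ``{"tumour", "normal"}``. The index
        must cover every column of ``values``.
    """

    cohort_id: str
    values: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValidationError(f"{self.cohort_id}: empty expression matrix")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"{self.cohort_id}: duplicate sample IDs {dup}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"{self.cohort_id}: duplicate feature IDs {dup}")
        missing = [s for s in self.values.columns if s not in self.sample_labels.index]
        if missing:
            raise ValidationError(
                f"{self.cohort_id}: samples without a class label: {missing[:5]}"
            )
        # align labels to the column order; extra label rows are ignored
        self.sample_labels = self.sample_labels.reindex(self.values.columns)
        bad = sorted(set(self.sample_labels.unique()) - set(CLASSES))
        if bad:
            raise ValidationError(f"{self.cohort_id}: unknown class labels {bad}")
        counts = self.sample_labels.value_counts()
        if counts.get(TUMOUR, 0) == 0 or counts.get(NORMAL, 0) == 0:
            raise ValidationError(
                f"{self.cohort_id}: need at least one tumour and one normal sample "
                f"(got {dict(counts)})"
            )
        self.values = self.values.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumour_samples(self) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == TUMOUR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == NORMAL])

    @property
    def n_tumour(self) -> int:
        return len(self.tumour_samples)

    @property
    def n_normal(self) -> int:
        return len(self.normal_samples)

    def group_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        """Non-missing tumour and normal values for one feature."""
        row = self.values.loc[feature]
        t = row[self.tumour_samples].to_numpy(float)
        n = row[self.normal_samples].to_numpy(float)
        return t[~np.isnan(t)], n[~np.isnan(n)]

    def with_values(self, values: pd.DataFrame) -> "CohortMatrix":
        """A copy of this cohort carrying a new value table (same samples)."""
        return CohortMatrix(self.cohort_id, values, self.sample_labels.copy())

    def subset_features(self, features: Iterable[str]) -> "CohortMatrix":
        keep = [f for f in features if f in self.values.index]
        return self.with_values(self.values.loc[keep])

    def equals(self, other: "CohortMatrix") -> bool:
        return (
            self.cohort_id == other.cohort_id
            and self.values.equals(other.values)
            and self.sample_labels.equals(other.sample_labels)
        )


@dataclass
class ClinicalTable:
    """Per-patient stage and survival endpoints.

    ``data`` is indexed by patient ID with columns ``stage`` (I/II/III/IV or
    ``unknown``), ``os_time`` (years), ``os_event`` (0/1) and optionally
    ``rfs_time``/``rfs_event`` (NaN where recurrence follow-up is absent).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate patient IDs in clinical table")
        for col in ("stage", "os_time", "os_event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        bad_stage = sorted(set(df["stage"].dropna()) - set(STAGES) - {"unknown"})
        if bad_stage:
            raise ValidationError(f"unknown stages {bad_stage}")
        for tcol, ecol in (("os_time", "os_event"), ("rfs_time", "rfs_event")):
            if tcol not in df.columns:
                continue
            t = df[tcol].dropna()
            if (t < 0).any():
                raise ValidationError(f"negative times in {tcol}")
            e = df[ecol].dropna()
            if not set(e.unique()) <= {0, 1, 0.0, 1.0}:
                raise ValidationError(f"{ecol} must be binary")

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, which: str) -> pd.DataFrame:
        """Time/event columns for endpoint 'OS' or 'RFS', NaN rows dropped."""
        which = which.upper()
        if which == "OS":
            cols = ["os_time", "os_event"]
        elif which == "RFS":
            cols = ["rfs_time", "rfs_event"]
        else:
            raise ValidationError(f"unknown endpoint {which!r}")
        for c in cols:
            if c not in self.data.columns:
                raise ValidationError(f"clinical table has no {which} columns")
        out = self.data[cols].dropna()
        out.columns = ["time", "event"]
        return out.astype(float)

    def for_stage(self, stage: str | None) -> "ClinicalTable":
        if stage is None:
            return self
        return ClinicalTable(self.data[self.data["stage"] == stage].copy())


#: Column schema of a miRNA-target interaction (MTI) table.
MTI_COLUMNS = ("mirna", "gene", "species", "support_type")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. pathways from a GMT file) plus the background.

    The enrichment universe is the union of all member genes together with any
    extra background genes supplied at construction.
    """

    sets: Mapping[str, tuple[str, ...]]
    extra_background: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    @property
    def universe(self) -> frozenset[str]:
        genes: set[str] = set(self.extra_background)
        for members in self.sets.values():
            genes.update(members)
        return frozenset(genes)
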