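"""Reading, writing and harmonizing the package's flat-file inputs.

Formats (all plain text):

* expression matrix — TSV, one header row of sample IDs, first column feature
  IDs; missing entries are empty cells or ``NA``;
* sample labels — two-column TSV ``sample_id<TAB>class`` with class in
  ``{tumour, normal}``;
* clinical table — TSV with named columns ``patient_id, stage, os_time,
  os_event[, rfs_time, rfs_event]``;
* miRNA-target interactions — TSV ``mirna, gene, species, support_type``;
* gene sets — standard GMT (set name, description, member genes);
* miRNA alias table — two-column TSV ``old_name<TAB>canonical_name``.

GEO-style linear-scale matrices can be converted on read with
``linear_scale=True``, which applies ``log2(x + offset)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CLASSES, MTI_COLUMNS, ClinicalTable, CohortMatrix, GeneSetCollection
from .errors import CollisionError, ValidationError

SPECIES_PREFIXES = ("hsa-",)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _check_header_duplicates(path: Path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dup = [h for h in header if h in seen or seen.add(h)]  # type: ignore[func-returns-value]
    if dup:
        raise ValidationError(f"{path}: duplicate IDs in header: {sorted(set(dup))[:5]}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id, class`` TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: label file needs two columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")
    bad = sorted(set(ser.unique()) - set(CLASSES))
    if bad:
        raise ValidationError(f"{path}: unknown class labels {bad}")
    return ser


def read_expression_matrix(
    path: str | Path,
    labels: str | Path | pd.Series | Mapping[str, str],
    orientation: str = "features_in_rows",
    cohort_id: str | None = None,
    linear_scale: bool = False,
    log2_offset: float = 1.0,
) -> CohortMatrix:
    """Parse a delimited expression table into a :class:`CohortMatrix`.

    ``orientation="features_in_columns"`` transposes the file so the result is
    always miRNA x sample. Non-numeric cells become missing entries (NaN).
    """
    path = Path(path)
    if orientation not in ("features_in_rows", "features_in_columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    _check_header_duplicates(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate IDs in first column: {dup[:5]}")
    if orientation == "features_in_columns":
        df = df.T
    df = df.apply(pd.to_numeric, errors="coerce")
    if linear_scale:
        df = np.log2(df + log2_offset)
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    elif isinstance(labels, Mapping):
        labels = pd.Series(labels)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CohortMatrix(cohort_id or path.stem, df, labels.astype(str))


def write_expression_matrix(matrix: CohortMatrix, path: str | Path,
                            labels_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="mirna")
    if labels_path is not None:
        lab = matrix.sample_labels.rename("class")
        lab.rename_axis("sample_id").to_frame().to_csv(labels_path, sep="\t")


# ---------------------------------------------------------------------------
# miRNA name canonicalization
# ---------------------------------------------------------------------------

@dataclass
class CanonicalizationResult:
    """Outcome of canonicalizing a list of miRNA names."""

    mapping: dict[str, str]
    unknown: list[str] = field(default_factory=list)

    def apply(self, names: Iterable[str]) -> list[str]:
        return [self.mapping[n] for n in names]


def _strip_species(name: str) -> str:
    for prefix in SPECIES_PREFIXES:
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


def canonicalize_mirna_names(
    names: Sequence[str],
    alias_table: Mapping[str, str] | None = None,
) -> CanonicalizationResult:
    """Map miRNA names to canonical nomenclature.

    Names are looked up in ``alias_table`` (old name -> canonical name), both
    verbatim and after stripping the species prefix; names not in the table
    pass through unchanged and are reported in ``unknown``. The ``hsa-``
    species prefix is stripped from all outputs — human-only analyses report
    names without it. Two inputs mapping to the same canonical name raise
    :class:`CollisionError`.
    """
    alias_table = dict(alias_table or {})
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    owner: dict[str, str] = {}
    for name in names:
        stripped = _strip_species(name)
        if name in alias_table:
            canon = alias_table[name]
        elif stripped in alias_table:
            canon = alias_table[stripped]
        else:
            canon = stripped
            if alias_table:
                unknown.append(name)
        canon = _strip_species(canon)
        if canon in owner and owner[canon] != name:
            raise CollisionError(
                f"both {owner[canon]!r} and {name!r} canonicalize to {canon!r}"
            )
        owner[canon] = name
        mapping[name] = canon
    if unknown:
        warnings.warn(
            f"{len(unknown)} miRNA name(s) not found in alias table; passed through",
            stacklevel=2,
        )
    return CanonicalizationResult(mapping, unknown)


def canonicalize_matrix(matrix: CohortMatrix,
                        alias_table: Mapping[str, str] | None = None) -> CohortMatrix:
    """Rename the features of a cohort matrix to canonical miRNA names."""
    res = canonicalize_mirna_names(list(matrix.values.index), alias_table)
    values = matrix.values.rename(index=res.mapping)
    return matrix.with_values(values)


def read_alias_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: alias table needs two columns")
    if df.iloc[:, 0].duplicated().any():
        raise ValidationError(f"{path}: duplicate old-names in alias table")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# sample matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Paired sample IDs shared by two datasets, in stable sorted order."""

    keys: list[str]
    a_ids: dict[str, str]       # matched key -> original ID on side a
    b_ids: dict[str, str]
    n_unmatched_a: int
    n_unmatched_b: int


def match_samples(
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    key_transform: Callable[[str], str] | None = None,
) -> MatchResult:
    """Intersect two sample-ID lists, optionally after a deterministic key
    transform (e.g. truncating a barcode to its patient prefix)."""
    transform = key_transform or (lambda s: s)

    def keyed(ids: Sequence[str], side: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for i in ids:
            k = transform(i)
            if k in out:
                raise ValidationError(
                    f"key transform maps {out[k]!r} and {i!r} (side {side}) "
                    f"to the same key {k!r}"
                )
            out[k] = i
        return out

    ka, kb = keyed(ids_a, "a"), keyed(ids_b, "b")
    common = sorted(set(ka) & set(kb))
    if not common:
        raise ValidationError("no samples match between the two datasets")
    return MatchResult(
        keys=common,
        a_ids={k: ka[k] for k in common},
        b_ids={k: kb[k] for k in common},
        n_unmatched_a=len(ka) - len(common),
        n_unmatched_b=len(kb) - len(common),
    )


# ---------------------------------------------------------------------------
# clinical, MTI, gene lists, GMT
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValidationError(f"{path}: clinical table needs a patient_id column")
    df = df.set_index("patient_id")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", na_rep="NA", index_label="patient_id")


def read_mti(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = [c for c in MTI_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: MTI table missing columns {missing}")
    return df[list(MTI_COLUMNS)]


def read_gene_list(path: str | Path) -> list[str]:
    genes = [line.strip() for line in open(path) if line.strip()]
    return genes


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValidationError(f"{path}: gene set {name!r} is empty")
            sets[name] = tuple(genes)
    if not sets:
        raise ValidationError(f"{path}: no gene sets parsed")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")
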