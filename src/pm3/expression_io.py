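"""Reading, validating and panel-aligning two-group expression matrices.

The core container is :class:`ExpressionStudy`: a nonnegative gene x sample
matrix of normalized expression values (e.g. TPM) plus a case/control label
per sample.  Validation is strict and errors carry coordinates, because the
downstream metrics silently propagate any bad value into every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gene_model import GeneModel

__all__ = [
    "ExpressionStudy",
    "StudyError",
    "AlignmentReport",
    "read_study",
    "write_study",
    "align",
]

CASE = "case"
CONTROL = "control"

# accepted spellings in the labels file
_GROUP_SYNONYMS = {
    "case": CASE,
    "asd": CASE,
    "control": CONTROL,
    "ctrl": CONTROL,
    "neurotypical": CONTROL,
}


class StudyError(ValueError):
    """Raised for malformed expression matrices or label tables."""


@dataclass(frozen=True)
class AlignmentReport:
    """What :func:`align` kept and dropped relative to a gene model."""

    missing: tuple[str, ...]  # model genes absent from the matrix
    n_extra: int  # matrix genes outside the panel (excluded)

    def __str__(self) -> str:
        return (
            f"{len(self.missing)} panel gene(s) missing "
            f"({', '.join(self.missing) or '-'}); "
            f"{self.n_extra} non-panel gene(s) excluded"
        )


@dataclass(frozen=True)
class ExpressionStudy:
    """A validated two-group expression study.

    Parameters
    ----------
    values
        Gene x sample DataFrame of nonnegative finite reals; index holds
        unique gene symbols, columns hold sample ids.
    labels
        Mapping ``sample_id -> 'case' | 'control'`` covering every column.
    """

    values: pd.DataFrame
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()][0]
            raise StudyError(f"duplicate gene row: {dup}")
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()][0]
            raise StudyError(f"duplicate sample column: {dup}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = np.where(~np.vectorize(_is_number)(arr))
            g, s = vals.index[bad[0][0]], vals.columns[bad[1][0]]
            raise StudyError(f"non-numeric value at gene {g!r}, sample {s!r}")
        if np.isnan(arr).any():
            g, s = _first_coord(vals, np.isnan(arr))
            raise StudyError(f"missing/NA value at gene {g!r}, sample {s!r}")
        if np.isinf(arr).any():
            g, s = _first_coord(vals, np.isinf(arr))
            raise StudyError(f"non-finite value at gene {g!r}, sample {s!r}")
        if (arr < 0).any():
            g, s = _first_coord(vals, arr < 0)
            raise StudyError(
                f"negative expression value at gene {g!r}, sample {s!r}"
            )
        unlabeled = [s for s in vals.columns if s not in self.labels]
        if unlabeled:
            raise StudyError(f"sample(s) missing from labels: {unlabeled}")
        bad_groups = sorted(
            {self.labels[s] for s in vals.columns} - {CASE, CONTROL}
        )
        if bad_groups:
            raise StudyError(f"unknown group label(s): {bad_groups}")
        for group in (CASE, CONTROL):
            if not any(self.labels[s] == group for s in vals.columns):
                raise StudyError(f"group {group!r} has zero samples")

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == group]

    @property
    def case_values(self) -> pd.DataFrame:
        return self.values[self.group_samples(CASE)]

    @property
    def control_values(self) -> pd.DataFrame:
        return self.values[self.group_samples(CONTROL)]

    def transformed(self, transform: str | None) -> "ExpressionStudy":
        """Return a copy with ``log2(x+1)``-transformed values (or self)."""
        if transform is None:
            return self
        if transform != "log2p1":
            raise StudyError(f"unknown transform: {transform!r}")
        return ExpressionStudy(np.log2(self.values + 1.0), dict(self.labels))


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _first_coord(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return df.index[i], df.columns[j]


def read_study(expr_path: str | Path, labels_path: str | Path) -> ExpressionStudy:
    """Read and validate an expression matrix TSV plus a labels TSV.

    The matrix has gene symbols in the first column and sample ids in the
    header; labels have columns ``sample_id`` and ``group`` with group in
    {case, control} (``asd``/``ctrl``/``neurotypical`` accepted as synonyms).
    Samples labelled but absent from the matrix are ignored; matrix samples
    without a label are an error.
    """
    expr_path, labels_path = Path(expr_path), Path(labels_path)
    try:
        values = pd.read_csv(
            expr_path, sep="\t", index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise StudyError(f"cannot parse expression matrix {expr_path}: {exc}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    # pandas will silently coerce 'NA' to NaN; locate it for the error message
    non_numeric = values.select_dtypes(exclude=[np.number])
    if not non_numeric.empty:
        col = non_numeric.columns[0]
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad_gene = values.index[coerced.isna().argmax()]
        raise StudyError(
            f"non-numeric value at gene {bad_gene!r}, sample {col!r}"
        )

    try:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise StudyError(f"cannot parse labels {labels_path}: {exc}")
    if not {"sample_id", "group"} <= set(lab.columns):
        raise StudyError("labels file must have columns sample_id, group")
    labels: dict[str, str] = {}
    for _, row in lab.iterrows():
        raw = str(row["group"]).strip().lower()
        if raw not in _GROUP_SYNONYMS:
            raise StudyError(
                f"sample {row['sample_id']!r}: unknown group {row['group']!r}"
            )
        labels[str(row["sample_id"]).strip()] = _GROUP_SYNONYMS[raw]
    labels = {s: g for s, g in labels.items() if s in values.columns}
    return ExpressionStudy(values, labels)


def write_study(study: ExpressionStudy, expr_path: str | Path, labels_path: str | Path) -> None:
    """Serialize a study at full float precision (round-trip safe)."""
    df = study.values.copy()
    df.index.name = "symbol"
    df.to_csv(expr_path, sep="\t", float_format="%.17g")
    with Path(labels_path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s in study.samples:
            fh.write(f"{s}\t{study.labels[s]}\n")


def align(study: ExpressionStudy, model: GeneModel) -> tuple[ExpressionStudy, AlignmentReport]:
    """Restrict a study to the panel genes, ordered as in the model.

    Missing panel genes are reported, never silently dropped; genes outside
    the panel are excluded and counted.  An empty intersection is an error.
    """
    present = set(study.genes)
    keep = [s for s in model.symbols if s in present]
    missing = tuple(s for s in model.symbols if s not in present)
    if not keep:
        raise StudyError(
            f"no overlap between study genes and model {model.name!r}"
        )
    n_extra = len(present - set(model.symbols))
    restricted = ExpressionStudy(study.values.loc[keep], dict(study.labels))
    return restricted, AlignmentReport(missing=missing, n_extra=n_extra)
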