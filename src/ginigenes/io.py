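"""Reading and writing expression matrices and panel annotations.

The expression format handled here is the tab-separated genes-by-samples
dialect used by the EBI Expression Atlas bulk downloads: optional ``#``
comment lines, a ``Gene ID`` column, an optional ``Gene Name`` column, and
one numeric column per sample.  Abundances are TPM (transcripts per
million) for RNA-seq data, or unit-less relative values for qPCR-derived
matrices.

Blank cells are treated as *missing*, never as zero: a zero is a measured
absence of transcripts, a blank is the absence of a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    DuplicateGeneError,
    MalformedDataError,
    VocabularyError,
)

__all__ = [
    "ExpressionMatrix",
    "PanelAnnotation",
    "PANEL_VOCABULARY",
    "read_expression_tsv",
    "write_expression_tsv",
    "renormalize_tpm",
    "load_panel_annotation",
]

#: Closed vocabulary of reference-gene panels: short code -> canonical name.
PANEL_VOCABULARY: Mapping[str, str] = {
    "GG": "GiniGene",
    "V": "geNorm/Vandesompele",
    "EL": "Eisenberg-Levanon",
    "L": "Lee",
    "C": "Caracausi",
    "ZK": "Zhang-Kriegova",
}
_NAME_TO_CODE = {name: code for code, name in PANEL_VOCABULARY.items()}

_DUPLICATE_POLICIES = ("reject", "keep-max-total", "sum")


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance table.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one float column per
        sample.  ``NaN`` marks a missing measurement; every finite value
        must be non-negative.
    dataset_id
        Free-form label for provenance (e.g. an accession).
    gene_names
        Optional display symbols parallel to the gene index.
    unit
        Abundance unit, ``"TPM"`` for RNA-seq or ``"relative"`` for
        qPCR-derived matrices.
    """

    values: pd.DataFrame
    dataset_id: str = ""
    gene_names: pd.Series | None = None
    unit: str = "TPM"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"duplicate gene identifiers: {dupes}")
        if v.shape[1] < 2:
            raise MalformedDataError(
                f"expression matrix needs at least 2 samples, got {v.shape[1]}"
            )
        arr = v.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            g, s = neg[0]
            raise MalformedDataError(
                f"negative abundance {arr[g, s]} at gene "
                f"{v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.gene_names is not None and len(self.gene_names) != len(v.index):
            raise MalformedDataError("gene_names length does not match gene count")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PanelAnnotation:
    """Mapping gene identifier -> set of panel codes (keys of
    :data:`PANEL_VOCABULARY`)."""

    membership: dict[str, set[str]] = field(default_factory=dict)

    def panels_of(self, gene: str) -> set[str]:
        return self.membership.get(gene, set())

    def label(self, gene: str) -> str:
        """Human-readable, '+'-joined panel names for *gene* ('' if none)."""
        codes = sorted(self.panels_of(gene))
        return "+".join(PANEL_VOCABULARY[c] for c in codes)


def _parse_cell(raw: str, gene: str, column: str) -> float:
    text = raw.strip()
    if text == "" or text.upper() in ("NA", "NAN"):
        return np.nan
    if "," in text:
        raise MalformedDataError(
            f"comma decimal separator in cell {text!r} at gene {gene!r}, "
            f"sample {column!r}; use '.' as the decimal point"
        )
    try:
        value = float(text)
    except ValueError:
        raise MalformedDataError(
            f"non-numeric cell {text!r} at gene {gene!r}, sample {column!r}"
        ) from None
    if value < 0:
        raise MalformedDataError(
            f"negative abundance {value} at gene {gene!r}, sample {column!r}"
        )
    return value


def read_expression_tsv(
    path: str | Path,
    id_column: str | None = None,
    aggregate_duplicates: str = "keep-max-total",
    dataset_id: str | None = None,
    unit: str = "TPM",
) -> ExpressionMatrix:
    """Read an Expression Atlas style TSV into an :class:`ExpressionMatrix`.

    Lines starting with ``#`` are comments.  The identifier column defaults
    to ``Gene ID`` when present (the stable accession), falling back to
    ``Gene Name`` or the first column.  A ``Gene Name`` column, when it is
    not the join key, is kept as display symbols.

    Parameters
    ----------
    aggregate_duplicates
        What to do when the same identifier occurs on several rows:
        ``"reject"`` raises, ``"keep-max-total"`` keeps the row with the
        largest total abundance, ``"sum"`` adds the rows element-wise.
    """
    if aggregate_duplicates not in _DUPLICATE_POLICIES:
        raise ValueError(
            f"aggregate_duplicates must be one of {_DUPLICATE_POLICIES}, "
            f"got {aggregate_duplicates!r}"
        )
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    if raw.shape[0] == 0:
        raise MalformedDataError(f"{path}: no data rows")

    columns = list(raw.columns)
    if id_column is None:
        for candidate in ("Gene ID", "Gene Name"):
            if candidate in columns:
                id_column = candidate
                break
        else:
            id_column = columns[0]
    elif id_column not in columns:
        raise MalformedDataError(f"{path}: identifier column {id_column!r} not found")

    name_column = "Gene Name" if ("Gene Name" in columns and id_column != "Gene Name") else None
    meta_columns = [c for c in (id_column, name_column) if c]
    sample_columns = [c for c in columns if c not in meta_columns]
    if not sample_columns:
        raise MalformedDataError(f"{path}: no sample columns after {meta_columns}")

    gene_ids = raw[id_column].str.strip()
    data = np.empty((len(raw), len(sample_columns)))
    for j, col in enumerate(sample_columns):
        cells = raw[col]
        for i in range(len(raw)):
            data[i, j] = _parse_cell(cells.iat[i], gene_ids.iat[i], col)

    frame = pd.DataFrame(data, index=pd.Index(gene_ids, name=id_column), columns=sample_columns)
    names = (
        pd.Series(raw[name_column].values, index=frame.index)
        if name_column
        else None
    )

    if frame.index.has_duplicates:
        if aggregate_duplicates == "reject":
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"{path}: duplicate gene identifiers {dupes}")
        if aggregate_duplicates == "sum":
            # min_count=1 keeps an all-missing group missing instead of 0
            frame = frame.groupby(level=0, sort=False).sum(min_count=1)
        else:  # keep-max-total: the duplicate row with the greatest total signal
            totals = frame.sum(axis=1, skipna=True).to_numpy()
            order = np.argsort(-totals, kind="stable")
            keep_first = frame.iloc[order]
            keep_first = keep_first[~keep_first.index.duplicated(keep="first")]
            frame = keep_first.reindex(frame.index.unique())
        if names is not None:
            names = names[~names.index.duplicated(keep="first")].reindex(frame.index)

    return ExpressionMatrix(
        values=frame,
        dataset_id=dataset_id if dataset_id is not None else path.stem,
        gene_names=names,
        unit=unit,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write *matrix* in the same dialect :func:`read_expression_tsv` consumes.

    Round-trips values to better than 1e-9 relative (full ``repr``
    precision) and preserves gene/sample order.
    """
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = out.index.name or "Gene ID"
    if matrix.gene_names is not None:
        out.insert(0, "Gene Name", matrix.gene_names.values)
    with open(path, "w") as handle:
        handle.write(f"# dataset: {matrix.dataset_id}\n# unit: {matrix.unit}\n")
        out.to_csv(handle, sep="\t", float_format="%.17g", na_rep="")


def renormalize_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every sample column to sum to 1e6 (TPM convention).

    Within-sample proportions are preserved; missing values are ignored in
    the column total.  Idempotent to floating-point precision.  Opt-in:
    published TPM matrices are normally already on this scale, but the sums
    drift once a matrix is subset to e.g. protein-coding genes.
    """
    sums = matrix.values.sum(axis=0, skipna=True)
    zero = sums[sums <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero total expression: {zero.index.tolist()}"
        )
    scaled = matrix.values * (1e6 / sums)
    return ExpressionMatrix(
        values=scaled,
        dataset_id=matrix.dataset_id,
        gene_names=matrix.gene_names,
        unit=matrix.unit,
    )


def load_panel_annotation(path: str | Path) -> PanelAnnotation:
    """Load a two-column TSV ``gene<TAB>panel-label`` into a
    :class:`PanelAnnotation`.

    Labels may be the short codes (``GG``, ``V``, ``EL``, ``L``, ``C``,
    ``ZK``) or the canonical panel names; anything else raises
    :class:`~ginigenes.errors.VocabularyError`.  A gene listed with several
    labels accumulates all of them.
    """
    membership: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MalformedDataError(
                    f"{path}:{lineno}: expected 'gene<TAB>label', got {line!r}"
                )
            gene, label = (p.strip() for p in parts)
            code = label if label in PANEL_VOCABULARY else _NAME_TO_CODE.get(label)
            if code is None:
                raise VocabularyError(
                    f"{path}:{lineno}: unknown panel label {label!r}; "
                    f"allowed: {sorted(PANEL_VOCABULARY)} or "
                    f"{sorted(PANEL_VOCABULARY.values())}"
                )
            membership.setdefault(gene, set()).add(code)
    return PanelAnnotation(membership)
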