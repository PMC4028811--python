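"""Expression-matrix container and TSV/PCL input/output.

The central data structure is :class:`ExpressionMatrix`: a genes x samples
matrix of log-ratio expression values with an explicit missingness mask
(missing entries are stored as NaN).  Rows are genes and columns are
samples, matching the G x S convention of two-colour microarray software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .exceptions import EmptyResultError, FormatError, ValidationError

logger = logging.getLogger(__name__)

DATASET_TYPES = ("time_series", "non_time_series", "mixed", "unknown")

#: Cell contents (lower-cased, stripped) interpreted as a missing value.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with missing entries as NaN.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, in matrix order.
    sample_ids : sequence of str
        Unique column identifiers, in matrix order.
    values : ndarray of shape (G, S)
        Log-ratio expression values; ``NaN`` marks a missing entry.
    dataset_type : str
        One of ``time_series``, ``non_time_series``, ``mixed``, ``unknown``.
        User-declared metadata; it drives parameter defaults (e.g. the
        sequential-KNN neighbour count), never inference.
    class_labels : mapping sample_id -> group, optional
        Two-class labels used by the differential-expression index.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dataset_type: str = "unknown"
    class_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        G, S = self.values.shape
        if G < 1 or S < 2:
            raise ValidationError(f"matrix must be at least 1 gene x 2 samples, got {G}x{S}")
        if len(self.gene_ids) != G or len(self.sample_ids) != S:
            raise ValidationError("gene_ids / sample_ids lengths do not match values shape")
        if len(set(self.gene_ids)) != G:
            raise ValidationError("duplicate gene IDs")
        if len(set(self.sample_ids)) != S:
            raise ValidationError("duplicate sample IDs")
        if self.dataset_type not in DATASET_TYPES:
            raise ValidationError(f"dataset_type must be one of {DATASET_TYPES}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValidationError("non-finite (infinite) expression values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean G x S array, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            class_labels=dict(self.class_labels) if self.class_labels else None,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """A copy sharing IDs/metadata but carrying ``values``."""
        out = self.copy()
        out.values = np.asarray(values, dtype=float)
        if out.values.shape != self.values.shape:
            raise ValidationError("replacement values have the wrong shape")
        return out

    def equals(self, other: "ExpressionMatrix", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Structural equality: IDs, mask, and values (NaN-aware)."""
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        if rtol == 0.0 and atol == 0.0:
            return bool(np.array_equal(self.values, other.values, equal_nan=True))
        if not np.array_equal(self.missing_mask, other.missing_mask):
            return False
        obs = ~self.missing_mask
        return bool(np.allclose(self.values[obs], other.values[obs], rtol=rtol, atol=atol))


def _parse_cell(token: str, row_label: str, row_no: int, col_id: str) -> float:
    t = token.strip()
    if t.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(t)
    except ValueError:
        raise FormatError(
            f"unparseable cell {token!r} at data row {row_no} (gene {row_label!r}), "
            f"column {col_id!r}"
        ) from None


def read_matrix(
    path,
    dialect: str = "tsv",
    dataset_type: str = "unknown",
    class_labels: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    ``tsv``: first column gene IDs, header row sample IDs.  ``pcl``: the
    Stanford PCL flavour — an optional NAME and GWEIGHT column and an
    optional EWEIGHT row are skipped.  Blank, ``NA``, ``NaN`` and ``null``
    cells (case-insensitive) become missing values.
    """
    if dialect not in ("tsv", "pcl"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")

    header = lines[0].split("\t")
    skip_cols: set[int] = set()
    if dialect == "pcl":
        for j, name in enumerate(header[1:], start=1):
            if name.strip().upper() in ("NAME", "GWEIGHT"):
                skip_cols.add(j)
    sample_ids = [h.strip() for j, h in enumerate(header[1:], start=1) if j not in skip_cols]

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    row_no = 0
    for ln in lines[1:]:
        cells = ln.split("\t")
        gid = cells[0].strip()
        if dialect == "pcl" and gid.upper() == "EWEIGHT":
            continue
        row_no += 1
        body = [c for j, c in enumerate(cells[1:], start=1) if j not in skip_cols]
        if len(body) != len(sample_ids):
            raise FormatError(
                f"{path}: data row {row_no} (gene {gid!r}) has {len(body)} cells, "
                f"expected {len(sample_ids)}"
            )
        gene_ids.append(gid)
        rows.append(
            [_parse_cell(tok, gid, row_no, sample_ids[j]) for j, tok in enumerate(body)]
        )

    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dups = []
        for g in gene_ids:
            if g in seen:
                dups.append(g)
            seen.add(g)
        raise ValidationError(f"{path}: duplicate gene IDs {sorted(set(dups))[:5]}")

    m = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        dataset_type=dataset_type,
        class_labels=dict(class_labels) if class_labels else None,
    )
    logger.info("read %s: %d genes x %d samples, %d missing entries",
                path, m.n_genes, m.n_samples, m.n_missing)
    return m


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Write ``m`` as TSV: gene IDs in column 1, sample IDs in the header.

    Missing entries become empty cells.  Numeric cells use ``repr`` so the
    written value round-trips bit-exactly through :func:`read_matrix`.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["GENE"] + m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([gid] + cells) + "\n")


def filter_complete(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every gene with one or more missing entries, preserving order.

    This is how benchmark ground truth is prepared: the surviving complete
    submatrix is the answer key that masking simulation perturbs.
    """
    keep = ~m.missing_mask.any(axis=1)
    if not keep.any():
        raise EmptyResultError("no complete genes remain; benchmarking is impossible")
    out = ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        values=m.values[keep],
        dataset_type=m.dataset_type,
        class_labels=dict(m.class_labels) if m.class_labels else None,
    )
    logger.info("filter_complete: %d -> %d genes", m.n_genes, out.n_genes)
    return out


def read_class_labels(path) -> dict[str, str]:
    """Read a two-column sidecar file (sample_id <TAB> group)."""
    labels: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected two tab-separated columns, got {ln!r}")
            sid, grp = parts[0].strip(), parts[1].strip()
            if sid in labels:
                raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
            labels[sid] = grp
    groups = set(labels.values())
    if len(groups) != 2:
        raise ValidationError(f"{path}: need exactly two groups, found {sorted(groups)}")
    return labels
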