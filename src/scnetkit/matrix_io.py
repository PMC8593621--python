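"""Reading and writing expression matrices and cell-annotation categories.

Expression matrices arrive as MatrixMarket triples: a ``.mtx`` coordinate
file (genes x cells) plus two sidecars, ``.mtx_rows`` (gene identifiers,
optionally with a second gene-symbol column) and ``.mtx_cols`` (cell
barcodes).  The triple may sit in a directory or inside a zip / tar.gz /
tgz archive, the layout used by the EMBL-EBI Single Cell Expression Atlas
("GXA") bulk downloads.

Category tables come in two orientations:

* GXA clusters dialect -- one clustering resolution per row, header
  ``sel.K, K, <cell ids...>``, read with ``transpose=False``;
* cell-metadata tables -- one cell per row, one annotation per column,
  read with ``transpose=True``.

MatrixMarket coordinate entries are 1-based on disk and 0-based in memory;
scipy handles the conversion.  Matrices are kept sparse throughout.
"""

from __future__ import annotations

import csv
import io
import tarfile
import warnings
import zipfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import ConsistencyError, EmptyCategoryError, FormatError

__all__ = [
    "ExpressionExperiment",
    "Category",
    "CategoryRow",
    "read_mtx_triple",
    "read_category_csv",
    "select_default_row",
    "write_mtx_triple",
    "write_clusters_csv",
]

_MTX_SUFFIXES = (".mtx", ".mtx_rows", ".mtx_cols")


@dataclass
class CategoryRow:
    """One grouping of cells: every cell barcode maps to a group label.

    For clustering categories ``row_label`` is the K value (number of
    clusters) and ``is_default`` mirrors the GXA ``sel.K`` flag marking the
    resolution the atlas recommends.  Labels are opaque strings; "NA" marks
    cells excluded from downstream comparisons.
    """

    row_label: str
    is_default: bool
    assignments: dict[str, str]

    def groups(self) -> list[str]:
        """Distinct non-"NA" group labels, sorted."""
        return sorted({g for g in self.assignments.values() if g != "NA"})


@dataclass
class Category:
    """A named cell annotation holding one or more :class:`CategoryRow`."""

    name: str
    rows: list[CategoryRow]
    selected_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyCategoryError(f"category {self.name!r} has no rows")
        if not 0 <= self.selected_row < len(self.rows):
            raise ValueError(
                f"selected_row {self.selected_row} out of range for "
                f"{len(self.rows)} rows"
            )


@dataclass
class ExpressionExperiment:
    """A sparse genes x cells expression matrix with identifiers.

    ``matrix`` holds normalized expression values (non-negative unless a
    transform stage such as unit-variance scaling has run, flagged by
    ``transformed``).  Duplicate gene ids are preserved -- rows are never
    merged -- but flagged with a warning so downstream statistics stay
    per-row.
    """

    matrix: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    species: str = ""
    accession: str = ""
    source: str = "file"  # one of "GXA", "HCA", "file"
    gene_symbols: list[str] | None = None
    categories: dict[str, Category] = field(default_factory=dict)
    transformed: bool = False

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if not self.gene_ids or not self.cell_ids:
            raise ValueError("gene_ids and cell_ids must be non-empty")
        n_genes, n_cells = self.matrix.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ConsistencyError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if not self.transformed and self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("expression matrix has negative entries")
        dupes = [g for g, c in Counter(self.gene_ids).items() if c > 1]
        if dupes:
            warnings.warn(
                f"{len(dupes)} duplicate gene id(s) kept as separate rows: "
                + ", ".join(sorted(dupes)[:10]),
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self) -> dict[str, int]:
        """First-occurrence index per gene id."""
        idx: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            idx.setdefault(g, i)
        return idx


# ---------------------------------------------------------------------------
# MatrixMarket triple
# ---------------------------------------------------------------------------


def _collect_members(path: Path) -> dict[str, bytes]:
    """Return {suffix: payload} for the three triple members at ``path``.

    ``path`` may be a directory, a zip archive, or a (possibly gzipped)
    tar archive.
    """
    found: dict[str, list[tuple[str, bytes]]] = {s: [] for s in _MTX_SUFFIXES}

    def offer(name: str, loader) -> None:
        base = name.rsplit("/", 1)[-1]
        for suffix in _MTX_SUFFIXES:
            if base.endswith(suffix):
                found[suffix].append((name, loader()))
                return

    if path.is_dir():
        for child in sorted(path.iterdir()):
            if child.is_file():
                offer(child.name, child.read_bytes)
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                if not info.is_dir():
                    offer(info.filename, lambda i=info: zf.read(i))
    else:
        try:
            with tarfile.open(path, mode="r:*") as tf:
                for member in tf.getmembers():
                    if member.isfile():
                        fobj = tf.extractfile(member)
                        assert fobj is not None
                        offer(member.name, fobj.read)
        except tarfile.ReadError as exc:
            raise FormatError(
                f"{path} is neither a directory, zip, nor tar archive"
            ) from exc

    members: dict[str, bytes] = {}
    for suffix in _MTX_SUFFIXES:
        hits = [(n, b) for n, b in found[suffix] if suffix != ".mtx" or not any(
            n.endswith(other) for other in (".mtx_rows", ".mtx_cols"))]
        if not hits:
            raise FormatError(f"no {suffix} member found in {path}")
        if len(hits) > 1:
            raise FormatError(
                f"multiple {suffix} members found in {path}: "
                + ", ".join(n for n, _ in hits)
            )
        members[suffix] = hits[0][1]
    return members


def _parse_id_file(payload: bytes) -> tuple[list[str], list[str] | None]:
    """Parse a .mtx_rows/.mtx_cols sidecar: one id per line, optional 2nd column."""
    ids: list[str] = []
    seconds: list[str] = []
    has_second = False
    for raw in payload.decode("utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        ids.append(parts[0].strip())
        if len(parts) > 1:
            has_second = True
            seconds.append(parts[1].strip())
        else:
            seconds.append(parts[0].strip())
    return ids, (seconds if has_second else None)


def read_mtx_triple(
    path: str | Path,
    species: str = "",
    accession: str = "",
    source: str = "file",
) -> ExpressionExperiment:
    """Read a MatrixMarket triple (directory or archive) into an experiment.

    Raises :class:`FormatError` when a member is missing and
    :class:`ConsistencyError` when the ``.mtx`` header disagrees with the
    sidecar lengths.  Sparse storage is preserved end to end.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    members = _collect_members(path)

    matrix = scipy.io.mmread(io.BytesIO(members[".mtx"]))
    matrix = sp.csr_matrix(matrix)
    gene_ids, gene_symbols = _parse_id_file(members[".mtx_rows"])
    cell_ids, _ = _parse_id_file(members[".mtx_cols"])

    if matrix.shape != (len(gene_ids), len(cell_ids)):
        raise ConsistencyError(
            f".mtx header declares {matrix.shape} but sidecars list "
            f"{len(gene_ids)} genes and {len(cell_ids)} cells"
        )
    return ExpressionExperiment(
        matrix=matrix,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        species=species,
        accession=accession,
        source=source,
        gene_symbols=gene_symbols,
    )


def write_mtx_triple(exp: ExpressionExperiment, directory: str | Path,
                     stem: str | None = None) -> list[Path]:
    """Write the three triple files into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or (exp.accession or "experiment")
    mtx = directory / f"{stem}.mtx"
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(exp.matrix))
    # mmwrite appends .mtx when missing; normalize the name
    if not mtx.exists() and mtx.with_suffix(".mtx.mtx").exists():
        mtx.with_suffix(".mtx.mtx").rename(mtx)
    rows = directory / f"{stem}.mtx_rows"
    symbols = exp.gene_symbols or exp.gene_ids
    rows.write_text(
        "".join(f"{g}\t{s}\n" for g, s in zip(exp.gene_ids, symbols))
    )
    cols = directory / f"{stem}.mtx_cols"
    cols.write_text("".join(f"{c}\n" for c in exp.cell_ids))
    return [mtx, rows, cols]


# ---------------------------------------------------------------------------
# Category tables
# ---------------------------------------------------------------------------


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def _read_table(path: Path) -> list[list[str]]:
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path} is empty")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, header has {width}"
            )
    return rows


def _is_clusters_dialect(header: list[str]) -> bool:
    return (
        len(header) >= 3
        and header[0].strip().lower() == "sel.k"
        and header[1].strip().lower() == "k"
    )


def read_category_csv(path: str | Path, transpose: bool, name: str) -> Category:
    """Read a CSV/TSV category file (delimiter sniffed from the header).

    ``transpose=False`` treats file rows as :class:`CategoryRow` (cells in
    columns; the GXA clusters orientation, where columns ``sel.K`` and ``K``
    precede the cell ids).  ``transpose=True`` transposes first: cells in
    rows, one CategoryRow per metadata column.
    """
    path = Path(path)
    rows = _read_table(path)
    header, data = rows[0], rows[1:]
    if not data:
        raise EmptyCategoryError(f"{path} has a header but no data rows")

    if transpose:
        # cells in rows; first column is the cell id
        cell_ids = [r[0] for r in data]
        cat_rows = [
            CategoryRow(
                row_label=header[j],
                is_default=False,
                assignments={r[0]: r[j] for r in data},
            )
            for j in range(1, len(header))
        ]
        if not cat_rows:
            raise EmptyCategoryError(f"{path} has no annotation columns")
        return Category(name=name, rows=cat_rows)

    if _is_clusters_dialect(header):
        cell_ids = [h.strip() for h in header[2:]]
        cat_rows = [
            CategoryRow(
                row_label=r[1].strip(),
                is_default=r[0].strip().upper() == "TRUE",
                assignments=dict(zip(cell_ids, (v.strip() for v in r[2:]))),
            )
            for r in data
        ]
    else:
        cell_ids = [h.strip() for h in header[1:]]
        cat_rows = [
            CategoryRow(
                row_label=r[0].strip(),
                is_default=False,
                assignments=dict(zip(cell_ids, (v.strip() for v in r[1:]))),
            )
            for r in data
        ]
    category = Category(name=name, rows=cat_rows)
    category.selected_row = select_default_row(category)
    return category


def select_default_row(category: Category) -> int:
    """Index of the first row flagged as default (``sel.K`` TRUE); 0 otherwise.

    Emits a warning when no row carries the flag.
    """
    for i, row in enumerate(category.rows):
        if row.is_default:
            return i
    warnings.warn(
        f"category {category.name!r} has no default-flagged row; using row 0",
        stacklevel=2,
    )
    return 0


def write_clusters_csv(category: Category, path: str | Path,
                       cell_ids: list[str] | None = None) -> Path:
    """Write a category in the GXA clusters dialect (``sel.K,K,<cells...>``)."""
    path = Path(path)
    if cell_ids is None:
        cell_ids = sorted(category.rows[0].assignments)
    lines = ["sel.K,K," + ",".join(cell_ids)]
    for row in category.rows:
        flag = "TRUE" if row.is_default else "FALSE"
        labels = ",".join(row.assignments.get(c, "NA") for c in cell_ids)
        lines.append(f"{flag},{row.row_label},{labels}")
    path.write_text("\n".join(lines) + "\n")
    return path


def attach_category(exp: ExpressionExperiment, category: Category) -> None:
    """Attach a category to an experiment, reconciling cell id mismatches.

    Cells present in the category but absent from the matrix are dropped
    with a warning; matrix cells missing from a row get the label "NA"
    (excluded from differential expression).
    """
    matrix_cells = set(exp.cell_ids)
    for row in category.rows:
        extra = set(row.assignments) - matrix_cells
        if extra:
            warnings.warn(
                f"category {category.name!r} row {row.row_label!r}: dropping "
                f"{len(extra)} cell(s) absent from the matrix",
                stacklevel=2,
            )
            for c in extra:
                del row.assignments[c]
        for c in exp.cell_ids:
            row.assignments.setdefault(c, "NA")
    exp.categories[category.name] = category
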