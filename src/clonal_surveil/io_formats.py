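"""Readers and writers for the standard formats the pipeline touches.

Expression matrices travel as 10x-style MatrixMarket directories (matrix in
coordinate form, one gene per row of ``genes.tsv``, one barcode per row of
``barcodes.tsv``).  Immune-repertoire rearrangements travel as AIRR
Rearrangement TSV.  Germline segments are plain FASTA with ``key=value``
annotations in the description line.  Result tables are CSV; run summaries
are JSON.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "Rearrangement",
    "GermlineSegment",
    "FormatError",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_airr",
    "write_airr",
    "read_gene_set",
    "write_gene_set",
    "write_scores",
    "read_annotation",
    "write_annotation",
    "read_germline_fasta",
    "parse_isotype",
    "KNOWN_ISOTYPES",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A cells x genes count (or log-normalized) matrix.

    ``counts`` is stored sparse with cells as rows, matching the in-memory
    convention of AnnData; on disk the matrix is written genes x cells as 10x
    does.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative entries in expression matrix")
        if self.layer not in ("raw", "lognorm"):
            raise FormatError(f"unknown layer tag {self.layer!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, symbol: str) -> int:
        try:
            return self.genes.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[idx],
            layer=self.layer,
        )

    def to_anndata(self):
        """View as an AnnData object (cells as obs, genes as var)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=self.cells),
            var=pd.DataFrame(index=self.genes),
        )


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} has duplicates")


#: Isotypes recognized from AIRR ``c_call`` values (heavy chain, mouse).
KNOWN_ISOTYPES = ["IgM", "IgD", "IgG1", "IgG2b", "IgG2c", "IgG3", "IgA", "IgE"]

_ISOTYPE_PREFIXES = [
    ("IGHG2B", "IgG2b"),
    ("IGHG2C", "IgG2c"),
    ("IGHG1", "IgG1"),
    ("IGHG3", "IgG3"),
    ("IGHM", "IgM"),
    ("IGHD", "IgD"),
    ("IGHA", "IgA"),
    ("IGHE", "IgE"),
]


def parse_isotype(c_call: str) -> str:
    """Map an AIRR ``c_call`` (e.g. ``IGHG1*01``) to a canonical isotype.

    Prefix matching; unknown or empty calls map to ``"unknown"``.
    """
    call = (c_call or "").strip().upper()
    for prefix, isotype in _ISOTYPE_PREFIXES:
        if call.startswith(prefix):
            return isotype
    # accept already-canonical names like "IgG2b"
    for isotype in KNOWN_ISOTYPES:
        if call == isotype.upper():
            return isotype
    return "unknown"


@dataclass
class Rearrangement:
    """One cell's heavy-chain rearrangement record."""

    cell_id: str
    v_call: str
    j_call: str
    c_call: str
    cdr3_aa: str
    v_seq_aligned: str = ""
    germline_v_aligned: str = ""
    sample_id: str | None = None

    @property
    def isotype(self) -> str:
        return parse_isotype(self.c_call)


@dataclass
class GermlineSegment:
    name: str
    seq: str
    annotations: dict = field(default_factory=dict)

    @property
    def cdr1_aa_start(self) -> int | None:
        v = self.annotations.get("cdr1_aa_start")
        return int(v) if v is not None else None

    @property
    def cdr1_aa_len(self) -> int:
        return int(self.annotations.get("cdr1_aa_len", 8))


# ---------------------------------------------------------------------------
# MTX directories
# ---------------------------------------------------------------------------

def _read_column(path: Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[-1])
    return out


def read_mtx_dir(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a 10x-style MTX directory (matrix.mtx + genes.tsv + barcodes.tsv).

    The MatrixMarket file is genes x cells; the returned matrix is
    cells x genes in file order.  Raises :class:`FormatError` on dimension
    mismatches or negative / non-integer raw entries.
    """
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    genes_file = path / "genes.tsv"
    if not genes_file.exists():
        genes_file = path / "features.tsv"
    barcodes_file = path / "barcodes.tsv"
    for f in (mtx_file, genes_file, barcodes_file):
        if not f.exists():
            raise FormatError(f"missing expected file {f}")
    mat = sp.coo_matrix(scipy.io.mmread(mtx_file))
    genes = _read_column(genes_file)
    cells = _read_column(barcodes_file)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"matrix header declares {mat.shape[0]} genes but gene list has {len(genes)}"
        )
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"matrix header declares {mat.shape[1]} cells but barcode list has {len(cells)}"
        )
    if mat.nnz:
        if mat.data.min() < 0:
            raise FormatError("negative entries in count matrix")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError("non-integer entries in raw count matrix")
    counts = sp.csr_matrix(mat.T)
    counts.data = counts.data.astype(np.int64)
    return ExpressionMatrix(genes=genes, cells=cells, counts=counts, layer="raw")


def write_mtx_dir(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write an :class:`ExpressionMatrix` as a 10x-style MTX directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = sp.coo_matrix(matrix.counts.T)
    if matrix.layer == "raw":
        m = m.astype(np.int64)
    scipy.io.mmwrite(path / "matrix.mtx", m)
    with open(path / "genes.tsv", "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\n")
    with open(path / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(matrix.cells) + "\n")


# ---------------------------------------------------------------------------
# AIRR rearrangement TSV
# ---------------------------------------------------------------------------

_ALIGNED_SEQ_COLS = ["v_sequence_alignment", "sequence_alignment"]
_ALIGNED_GERM_COLS = ["v_germline_alignment", "germline_alignment"]


def read_airr(path: str | os.PathLike) -> tuple[list[Rearrangement], list[tuple[int, str]]]:
    """Read an AIRR Rearrangement TSV.

    Returns ``(records, rejected)`` where *rejected* pairs the 0-based data
    row index with the reason the row was unusable (e.g. ``"missing CDR3"``).
    Rows are never silently dropped: ``len(records) + len(rejected)`` equals
    the number of data rows.

    Both ``cdr3_aa`` and ``junction_aa`` dialects are accepted; the CDR3 is
    derived from a junction by trimming the two flanking conserved residues.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    missing = [c for c in ("cell_id", "v_call", "j_call") if c not in cols]
    if "cdr3_aa" not in cols and "junction_aa" not in cols:
        missing.append("cdr3_aa (or junction_aa)")
    if missing:
        raise FormatError(f"AIRR file missing mandatory columns: {', '.join(missing)}")

    seq_col = next((c for c in _ALIGNED_SEQ_COLS if c in cols), None)
    germ_col = next((c for c in _ALIGNED_GERM_COLS if c in cols), None)

    records: list[Rearrangement] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        cdr3 = row.get("cdr3_aa", "").strip()
        if not cdr3 and row.get("junction_aa", "").strip():
            junction = row["junction_aa"].strip()
            cdr3 = junction[1:-1] if len(junction) > 2 else ""
        if not cdr3:
            rejected.append((i, "missing CDR3"))
            continue
        if not row.get("v_call", "").strip():
            rejected.append((i, "missing v_call"))
            continue
        if not row.get("j_call", "").strip():
            rejected.append((i, "missing j_call"))
            continue
        records.append(
            Rearrangement(
                cell_id=row["cell_id"],
                v_call=row["v_call"].strip(),
                j_call=row["j_call"].strip(),
                c_call=row.get("c_call", "").strip(),
                cdr3_aa=cdr3,
                v_seq_aligned=row.get(seq_col, "") if seq_col else "",
                germline_v_aligned=row.get(germ_col, "") if germ_col else "",
                sample_id=row.get("sample_id") or None,
            )
        )
    return records, rejected


def write_airr(records: list[Rearrangement], path: str | os.PathLike) -> None:
    """Write rearrangements as AIRR TSV (standard column names)."""
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "sample_id": [r.sample_id or "" for r in records],
            "v_call": [r.v_call for r in records],
            "j_call": [r.j_call for r in records],
            "c_call": [r.c_call for r in records],
            "cdr3_aa": [r.cdr3_aa for r in records],
            "v_sequence_alignment": [r.v_seq_aligned for r in records],
            "v_germline_alignment": [r.germline_v_aligned for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets, score tables, annotations, germlines
# ---------------------------------------------------------------------------

def read_gene_set(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line, ``#`` comments allowed.

    Order preserving; duplicates are dropped with a warning.  Symbols are
    matched case-sensitively after whitespace strip.
    """
    path = Path(path)
    genes: list[str] = []
    seen = set()
    n_dup = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line in seen:
                n_dup += 1
                continue
            seen.add(line)
            genes.append(line)
    if n_dup:
        logger.warning("gene set %s: dropped %d duplicate entries", path, n_dup)
    if not genes:
        raise FormatError(f"gene set file {path} is empty")
    return GeneSet(name=name or path.stem, genes=genes)


def write_gene_set(gene_set: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gene set: {gene_set.name}\n")
        fh.write("\n".join(gene_set.genes) + "\n")


def write_scores(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-cell score table to CSV (header row, one row per cell)."""
    table.to_csv(path, index=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-cell annotation table (cell_id, sample_id, group[, cell_type])."""
    df = pd.read_csv(path)
    missing = [c for c in ("cell_id", "sample_id", "group") if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {', '.join(missing)}")
    if df["cell_id"].duplicated().any():
        raise FormatError("annotation has duplicate cell_id values")
    bad = set(df["group"]) - {"treated", "untreated"}
    if bad:
        raise FormatError(f"annotation group values outside treated/untreated: {bad}")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    annotation.to_csv(path, index=False)


def read_germline_fasta(path: str | os.PathLike) -> dict[str, GermlineSegment]:
    """Read germline segments from FASTA; ``key=value`` description tokens
    become annotations (e.g. the CDR1 window coordinates)."""
    segments: dict[str, GermlineSegment] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ann = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                ann[k] = v
        segments[rec.id] = GermlineSegment(name=rec.id, seq=str(rec.seq), annotations=ann)
    if not segments:
        raise FormatError(f"no sequences in germline FASTA {path}")
    return segments
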