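"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions, applied uniformly:

* intervals (BED, bedgraph, peaks, chromatin states) are 0-based half-open;
* transcription start sites (TSS) are single 1-based positions, following the
  GTF convention; conversion happens at read time only;
* Hi-C maps are keyed by bin index ``floor(position / resolution)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

ANNOT_COLUMNS = ["gene_id", "chrom", "tss", "strand", "biotype"]
INTERVAL_COLUMNS = ["chrom", "start", "end"]

#: store a matrix sparse when its density is below this fraction
SPARSE_DENSITY_THRESHOLD = 0.5


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene chromosome, TSS (1-based), strand and biotype.

    The table anchors all cis-window and interval logic downstream.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["gene_id"].duplicated().any():
            dups = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].tolist()
            raise FormatError(f"duplicate gene_id(s): {sorted(set(dups))}")
        bad_strand = ~self.df["strand"].isin(["+", "-"])
        if bad_strand.any():
            rows = (self.df.index[bad_strand] + 1).tolist()
            raise FormatError(f"invalid strand at record(s) {rows}; must be + or -")
        if (self.df["tss"] < 1).any():
            raise FormatError("tss must be >= 1 (1-based coordinate)")
        self.df["tss"] = self.df["tss"].astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.df["gene_id"].to_numpy()

    def subset(self, gene_ids) -> "GeneAnnotation":
        keep = self.df[self.df["gene_id"].isin(set(gene_ids))]
        return GeneAnnotation(keep.copy())

    def tss_of(self, gene_id: str) -> int:
        row = self.df.loc[self.df["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return int(row["tss"].iloc[0])


def _tss_from_interval(start_1based: int, end_1based: int, strand: str) -> int:
    # + strand transcribes left to right: TSS is the interval start
    return start_1based if strand == "+" else end_1based


def read_gene_annotation(path, format: str | None = None) -> GeneAnnotation:
    """Read gene annotation from GTF or a BED-like/columnar TSV.

    ``format`` is ``"gtf"`` or ``"tsv"``; inferred from the extension when
    omitted.  In interval-style records the TSS is the start for + strand
    genes and the end for - strand genes.
    """
    path = str(path)
    if format is None:
        format = "gtf" if path.endswith((".gtf", ".gtf.gz")) else "tsv"
    if format == "gtf":
        return _read_annotation_gtf(path)
    if format == "tsv":
        return _read_annotation_tsv(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def _read_annotation_gtf(path: str) -> GeneAnnotation:
    import pyranges

    gr = pyranges.read_gtf(path)
    df = gr.df
    df = df[df["Feature"] == "gene"].copy()
    if df.empty:
        raise FormatError(f"no gene records in {path}")
    biotype_col = next(
        (c for c in ("gene_biotype", "gene_type") if c in df.columns), None
    )
    if biotype_col is None:
        raise FormatError("GTF gene records lack gene_biotype/gene_type attribute")
    # pyranges converts to 0-based half-open; GTF 1-based start = Start + 1
    start_1b = df["Start"].to_numpy() + 1
    end_1b = df["End"].to_numpy()
    strand = df["Strand"].astype(str).to_numpy()
    tss = np.where(strand == "+", start_1b, end_1b)
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str).to_numpy(),
            "chrom": df["Chromosome"].astype(str).to_numpy(),
            "tss": tss,
            "strand": strand,
            "biotype": df[biotype_col].astype(str).to_numpy(),
        }
    )
    return GeneAnnotation(out)


def _read_annotation_tsv(path: str) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    if "tss" in df.columns:
        return GeneAnnotation(df[ANNOT_COLUMNS].copy())
    # interval-style table: gene_id chrom start end strand biotype (1-based)
    required = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"annotation TSV needs either a 'tss' column or interval columns; "
            f"missing {missing}"
        )
    tss = [
        _tss_from_interval(int(s), int(e), str(st))
        for s, e, st in zip(df["start"], df["end"], df["strand"])
    ]
    out = df[["gene_id", "chrom"]].copy()
    out["tss"] = tss
    out["strand"] = df["strand"]
    out["biotype"] = df["biotype"]
    return GeneAnnotation(out)


def write_gene_annotation(annot: GeneAnnotation, path) -> None:
    annot.df[ANNOT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell / sample matrices
# ---------------------------------------------------------------------------

@dataclass
class CellMatrix:
    """Genes (or enhancers/peaks) x cells (or samples) matrix.

    ``kind`` is one of ``counts``, ``normalized`` or ``binary``.  Values are
    kept sparse (CSR) when density is below 50%, dense otherwise.
    """

    row_ids: np.ndarray
    col_ids: np.ndarray
    X: "sp.spmatrix | np.ndarray"
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.row_ids = np.asarray(self.row_ids, dtype=object)
        self.col_ids = np.asarray(self.col_ids, dtype=object)
        if self.kind not in ("counts", "normalized", "binary"):
            raise ValueError(f"unknown matrix kind: {self.kind!r}")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("row_ids not unique")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise FormatError("col_ids not unique")
        if self.X.shape != (len(self.row_ids), len(self.col_ids)):
            raise FormatError(
                f"matrix shape {self.X.shape} inconsistent with id lists "
                f"({len(self.row_ids)} x {len(self.col_ids)})"
            )
        if self.kind == "binary":
            data = self.X.data if sp.issparse(self.X) else self.X
            vals = np.unique(np.asarray(data))
            if not np.isin(vals, [0, 1]).all():
                raise FormatError("binary matrix contains values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.X):
            return np.asarray(self.X.todense(), dtype=float)
        return np.asarray(self.X, dtype=float)

    def row(self, row_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.row_ids == row_id)
        if idx.size == 0:
            raise KeyError(row_id)
        r = self.X[idx[0]]
        return np.asarray(r.todense()).ravel() if sp.issparse(self.X) else np.asarray(r).ravel()

    def value(self, row_id: str, col_id: str) -> float:
        j = np.flatnonzero(self.col_ids == col_id)
        if j.size == 0:
            raise KeyError(col_id)
        return float(self.row(row_id)[j[0]])

    def subset_rows(self, row_ids) -> "CellMatrix":
        order = {r: i for i, r in enumerate(self.row_ids)}
        idx = [order[r] for r in row_ids]
        return CellMatrix(np.asarray(list(row_ids), dtype=object), self.col_ids,
                          self.X[idx], self.kind)

    def subset_cols(self, col_ids) -> "CellMatrix":
        order = {c: i for i, c in enumerate(self.col_ids)}
        idx = [order[c] for c in col_ids]
        X = self.X[:, idx] if not sp.issparse(self.X) else self.X.tocsc()[:, idx].tocsr()
        return CellMatrix(self.row_ids, np.asarray(list(col_ids), dtype=object), X, self.kind)


def _pack(X: np.ndarray) -> "sp.spmatrix | np.ndarray":
    """Choose sparse vs dense storage by density."""
    X = np.asarray(X)
    density = np.count_nonzero(X) / max(X.size, 1)
    return sp.csr_matrix(X) if density < SPARSE_DENSITY_THRESHOLD else X


def make_cell_matrix(row_ids, col_ids, X, kind: str = "counts") -> CellMatrix:
    """Build a :class:`CellMatrix`, picking sparse or dense storage."""
    if sp.issparse(X):
        density = X.nnz / max(X.shape[0] * X.shape[1], 1)
        X = X.tocsr() if density < SPARSE_DENSITY_THRESHOLD else np.asarray(X.todense())
    else:
        X = _pack(X)
    return CellMatrix(np.asarray(row_ids, dtype=object),
                      np.asarray(col_ids, dtype=object), X, kind)


def read_cell_matrix(matrix_path, row_path, col_path, kind: str = "counts") -> CellMatrix:
    """Read a MatrixMarket triplet matrix plus row/column id text files.

    MTX triplets are 1-based; absent triplets are zeros. Dense TSV input
    (genes in rows, first column = ids, header = column ids) is accepted when
    ``matrix_path`` ends in ``.tsv``.
    """
    matrix_path = str(matrix_path)
    if matrix_path.endswith(".tsv"):
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        return make_cell_matrix(df.index.to_numpy(dtype=object),
                                df.columns.to_numpy(dtype=object),
                                df.to_numpy(dtype=float), kind)
    row_ids = _read_id_file(row_path)
    col_ids = _read_id_file(col_path)
    try:
        M = scipy.io.mmread(matrix_path)
    except ValueError as exc:
        raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    if M.shape != (len(row_ids), len(col_ids)):
        raise FormatError(
            f"MTX dimension header {M.shape} does not match id files "
            f"({len(row_ids)} rows, {len(col_ids)} cols)"
        )
    return make_cell_matrix(row_ids, col_ids, sp.csr_matrix(M), kind)


def _read_id_file(path) -> np.ndarray:
    with open(path) as fh:
        ids = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def write_cell_matrix(mat: CellMatrix, matrix_path, row_path, col_path) -> None:
    X = mat.X if sp.issparse(mat.X) else sp.csr_matrix(np.asarray(mat.X))
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(X))
    for path, ids in ((row_path, mat.row_ids), (col_path, mat.col_ids)):
        with open(path, "w") as fh:
            fh.write("\n".join(str(i) for i in ids) + "\n")


# ---------------------------------------------------------------------------
# intervals (BED / bedgraph / chromatin states)
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """0-based half-open genomic intervals, sorted by (chrom, start).

    Optional columns beyond chrom/start/end (``id``, ``value``, ``strand``)
    are preserved; BED column 4 maps to ``id``, column 5 to ``value``,
    column 6 to ``strand``.  Bedgraph column 4 maps to ``value``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INTERVAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"interval table missing columns: {missing}")
        df = self.df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            first = df[bad].iloc[0]
            raise FormatError(
                f"interval with start >= end: {first['chrom']}:{first['start']}-{first['end']}"
            )
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


def read_intervals(path, value_col: str | None = None) -> IntervalSet:
    """Read >=3-column whitespace-separated BED-like intervals.

    ``value_col='value'`` forces bedgraph interpretation (column 4 numeric).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least 3 columns")
    out = pd.DataFrame({"chrom": df[0].astype(str), "start": df[1], "end": df[2]})
    if df.shape[1] >= 4:
        col4 = df[3]
        if value_col == "value" or pd.api.types.is_numeric_dtype(col4):
            out["value"] = pd.to_numeric(col4)
        else:
            out["id"] = col4.astype(str)
    if df.shape[1] >= 5 and "value" not in out.columns:
        out["value"] = pd.to_numeric(df[4], errors="coerce")
    # strand is whichever trailing column holds only +/- (BED col 6, or col 5
    # in the value-bearing 5-column stranded-track layout)
    for col in (5, 4):
        if df.shape[1] > col and "strand" not in out.columns:
            vals = df[col].astype(str)
            if vals.isin(["+", "-"]).all():
                out["strand"] = vals
    return IntervalSet(out)


def write_intervals(ivals: IntervalSet, path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("id", "value", "strand"):
        if extra in ivals.df.columns:
            cols.append(extra)
    ivals.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, strand: str | None = None) -> IntervalSet:
    """Read a 4-column bedgraph; attach a constant strand when given."""
    ivals = read_intervals(path, value_col="value")
    if "value" not in ivals.df.columns:
        raise FormatError(f"{path}: bedgraph needs a numeric 4th column")
    if strand is not None:
        df = ivals.df.copy()
        df["strand"] = strand
        return IntervalSet(df)
    return ivals


# ---------------------------------------------------------------------------
# Hi-C contact maps
# ---------------------------------------------------------------------------

@dataclass
class HiCMap:
    """Sparse per-chromosome bin-pair -> normalized contact at a resolution.

    Keys are ``(chrom, i, j)`` with ``i <= j``; lookup is symmetric and an
    absent pair returns the missing marker (None).
    """

    resolution: int
    contacts: dict = field(default_factory=dict)

    def _key(self, chrom: str, i: int, j: int) -> tuple:
        return (chrom, i, j) if i <= j else (chrom, j, i)

    def set(self, chrom: str, i: int, j: int, value: float) -> None:
        if value < 0:
            raise FormatError(f"negative Hi-C contact at {chrom}:{i},{j}: {value}")
        self.contacts[self._key(chrom, i, j)] = float(value)

    def get(self, chrom: str, i: int, j: int):
        """Normalized contact for a bin pair, or None when absent."""
        return self.contacts.get(self._key(chrom, i, j))

    def bin_of(self, position: int) -> int:
        return int(position) // self.resolution

    def __len__(self) -> int:
        return len(self.contacts)


def read_hic(path, resolution: int, chrom: str | None = None,
             keyed: str = "position") -> HiCMap:
    """Read Hi-C triplet text ``[chrom] key_i key_j value``.

    ``keyed='position'``: keys are bp positions, multiples of the resolution
    (dialect A).  ``keyed='bin'``: keys are bin indices (dialect B).  A
    3-column file needs ``chrom``; a 4-column file carries it per line.
    """
    if keyed not in ("position", "bin"):
        raise ValueError("keyed must be 'position' or 'bin'")
    hic = HiCMap(resolution=int(resolution))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) == 4:
                c, a, b, v = parts
            elif len(parts) == 3:
                if chrom is None:
                    raise FormatError(
                        f"{path}:{lineno}: 3-column Hi-C file requires a chrom argument"
                    )
                c, (a, b, v) = chrom, parts
            else:
                raise FormatError(f"{path}:{lineno}: expected 3 or 4 columns")
            a, b, v = int(a), int(b), float(v)
            if keyed == "position":
                if a % resolution or b % resolution:
                    raise FormatError(
                        f"{path}:{lineno}: position {a},{b} not a multiple of "
                        f"resolution {resolution}"
                    )
                a, b = a // resolution, b // resolution
            hic.set(c, a, b, v)
    return hic


def write_hic(hic: HiCMap, path, keyed: str = "position") -> None:
    with open(path, "w") as fh:
        for (chrom, i, j), v in sorted(hic.contacts.items()):
            if keyed == "position":
                i, j = i * hic.resolution, j * hic.resolution
            fh.write(f"{chrom}\t{i}\t{j}\t{v:.10g}\n")
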