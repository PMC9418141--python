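"""Expression normalization and gene filtering applied before co-expression
detection.

The continuous path is: library-size scaling -> log1p -> per-gene rank
inverse-normal transform -> (bulk only) regression of top principal
components.  The binary path for sparse single-cell regimes is plain
binarization of the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import ndtri
from scipy.stats import rankdata

from .genome_io import CellMatrix, GeneAnnotation, make_cell_matrix

#: hg19 MHC region excluded by default in the human analyses
DEFAULT_EXCLUDE_REGION = ("chr6", 29_500_000, 33_600_000)


@dataclass
class FilterConfig:
    """Gene filters applied before co-expression testing.

    ``exclude_region`` is tested by TSS membership (half-open on bp).
    ``min_cells_expressed`` counts cells with a nonzero raw count.
    """

    autosomes_only: bool = True
    coding_only: bool = True
    exclude_region: tuple | None = DEFAULT_EXCLUDE_REGION
    min_cells_expressed: int = 0
    drop_zero_variance: bool = True

    def __post_init__(self) -> None:
        if self.min_cells_expressed < 0:
            raise ValueError("min_cells_expressed must be >= 0")


_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles of their ranks: Phi^-1((r - 0.5)/n).

    Ties receive average ranks.  An all-equal vector maps to all zeros with a
    warning (the zero-variance filter removes such genes downstream).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("rank_inverse_normal needs length >= 2")
    if np.all(values == values[0]):
        warnings.warn("all-equal input to rank_inverse_normal; returning zeros")
        return np.zeros_like(values)
    ranks = rankdata(values, method="average")
    return ndtri((ranks - 0.5) / values.size)


def rank_inverse_normal_rows(mat: CellMatrix) -> CellMatrix:
    """Apply the rank inverse-normal transform to every row."""
    X = mat.to_dense()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = np.vstack([rank_inverse_normal(row) for row in X])
    return CellMatrix(mat.row_ids, mat.col_ids, out, "normalized")


def library_size_normalize(mat: CellMatrix) -> CellMatrix:
    """Scale counts per median library size and log1p-transform.

    A simple size-factor scheme: column sums define library sizes, each
    column is scaled to the median library, then log1p.  Downstream
    correlations are rank-driven (rank-INT follows), so the choice of
    size-factor estimator has little leverage.
    """
    if mat.kind != "counts":
        raise ValueError("library_size_normalize expects a counts matrix")
    X = mat.to_dense()
    lib = X.sum(axis=0)
    lib[lib == 0] = 1.0
    scaled = X * (np.median(lib) / lib)[None, :]
    return CellMatrix(mat.row_ids, mat.col_ids, np.log1p(scaled), "normalized")


def binarize(mat: CellMatrix) -> CellMatrix:
    """Binarize counts: any positive value becomes 1, zero stays 0."""
    if sp.issparse(mat.X):
        X = mat.X.copy()
        X.data = (X.data > 0).astype(np.int8)
        X.eliminate_zeros()
    else:
        X = (np.asarray(mat.X) > 0).astype(np.int8)
    return CellMatrix(mat.row_ids, mat.col_ids, X, "binary")


def filter_genes(mat: CellMatrix, annot: GeneAnnotation, cfg: FilterConfig,
                 raw_counts: CellMatrix | None = None) -> CellMatrix:
    """Drop matrix rows failing any enabled filter; log removal reasons.

    For ``min_cells_expressed`` on a normalized matrix, pass the raw count
    matrix as ``raw_counts`` so expression presence is judged on counts.
    """
    ann = annot.df.set_index("gene_id")
    unannotated = [g for g in mat.row_ids if g not in ann.index]
    if unannotated:
        raise KeyError(f"rows without annotation: {unannotated}")

    count_source = raw_counts if raw_counts is not None else mat
    if not np.array_equal(count_source.row_ids, mat.row_ids):
        count_source = count_source.subset_rows(list(mat.row_ids))
    counts = count_source.to_dense()
    X = mat.to_dense()

    keep, reasons = [], {}
    n_expressed = (counts > 0).sum(axis=1)
    variances = X.var(axis=1)
    for i, gene in enumerate(mat.row_ids):
        rec = ann.loc[gene]
        why = None
        if cfg.autosomes_only and str(rec["chrom"]) not in _AUTOSOMES:
            why = f"non-autosomal chromosome {rec['chrom']}"
        elif cfg.coding_only and rec["biotype"] != "protein_coding":
            why = f"biotype {rec['biotype']}"
        elif cfg.exclude_region is not None and _tss_in_region(rec, cfg.exclude_region):
            why = "TSS in excluded region"
        elif n_expressed[i] < cfg.min_cells_expressed:
            why = f"expressed in {n_expressed[i]} < {cfg.min_cells_expressed} cells"
        elif cfg.drop_zero_variance and variances[i] == 0:
            why = "zero variance"
        if why is None:
            keep.append(i)
        else:
            reasons[gene] = why
    out = CellMatrix(mat.row_ids[keep], mat.col_ids,
                     mat.X[keep] if not sp.issparse(mat.X) else mat.X[keep],
                     mat.kind)
    out.removal_reasons = reasons
    return out


def _tss_in_region(rec, region) -> bool:
    chrom, start, end = region
    return str(rec["chrom"]) == str(chrom) and start <= int(rec["tss"]) < end


def regress_principal_components(mat: CellMatrix, k: int) -> CellMatrix:
    """Replace each gene's vector by its OLS residual on the top-k
    sample-space principal components of the centered matrix.

    With k = 0 this is plain gene-centering.  Used on bulk matrices to
    remove broad confounders before co-expression testing.
    """
    if mat.kind != "normalized":
        raise ValueError("regress_principal_components expects a normalized matrix")
    X = mat.to_dense()
    n_genes, n_samples = X.shape
    if k >= min(n_genes, n_samples):
        raise ValueError(f"k={k} must be < min(dimensions)={min(n_genes, n_samples)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    if k > 0:
        # rows of Vt are the sample-space principal axes
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
        if k > rank:
            raise ValueError(f"k={k} exceeds matrix rank {rank}")
        V = Vt[:k].T  # (samples, k), orthonormal
        Xc = Xc - (Xc @ V) @ V.T
    return CellMatrix(mat.row_ids, mat.col_ids, Xc, "normalized")
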