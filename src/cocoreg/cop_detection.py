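"""Detection of locally co-expressed gene pairs (COPs).

For every gene, all other genes with a TSS within a cis window (default
1 Mb) are tested for higher-than-expected Pearson correlation across cells
(single-cell mode) or samples (bulk mode).  Significance comes from a
per-focal-gene max-statistic permutation null: the focal gene's expression
vector is shuffled across cells, and for each shuffle the *maximum*
correlation over all of the focal gene's cis partners is recorded.  Because
the null distribution of the maximum grows with the number of cis partners,
empirical p-values are comparable between genes in dense and sparse
neighbourhoods.  Benjamini-Hochberg correction is applied over all tests in
a run; a pair is called a COP when either of its two focal-direction tests
is significant and the correlation passes the positivity / ceiling /
cross-mappability filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CellMatrix, GeneAnnotation


@dataclass
class CopParams:
    """Parameters of a COP detection run.

    ``min_rho`` is used in the binary (sparse single-cell) regime, where a
    correlation floor of 0.2 is required on top of statistical significance;
    leave it ``None`` in the continuous regime.
    """

    window_bp: int = 1_000_000
    n_perm: int = 1000
    fdr: float = 0.05
    min_rho: float | None = None
    max_rho: float = 0.99
    crossmap_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")


@dataclass
class CopSet:
    """Significant co-expressed pairs from one run, with provenance.

    ``pairs`` has one row per unordered pair: gene_a, gene_b, chrom,
    tss_distance, rho, p_emp, q, plus provenance columns.  ``tests`` keeps
    the full per-direction test table (two rows per candidate pair) and is
    the input for building the non-COP pool.
    """

    pairs: pd.DataFrame
    individual: str | None = None
    experiment: str | None = None
    n_cells: int = 0
    tests: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> set:
        return set(zip(self.pairs["gene_a"], self.pairs["gene_b"]))


PAIR_COLUMNS = ["gene_a", "gene_b", "chrom", "tss_distance", "rho", "p_emp", "q"]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def enumerate_cis_pairs(annot: GeneAnnotation, window_bp: int) -> pd.DataFrame:
    """All unordered same-chromosome gene pairs with |TSS distance| <= window.

    The window boundary is inclusive.  Returns columns gene_a, gene_b
    (lexicographically ordered), chrom, tss_distance.
    """
    if len(annot) == 0:
        raise ValueError("empty annotation")
    rows = []
    for chrom, grp in annot.df.groupby("chrom", sort=False):
        ids = grp["gene_id"].to_numpy()
        tss = grp["tss"].to_numpy()
        order = np.argsort(tss, kind="mergesort")
        ids, tss = ids[order], tss[order]
        for i in range(len(ids)):
            # genes are TSS-sorted: partners form a contiguous right slice
            j_hi = np.searchsorted(tss, tss[i] + window_bp, side="right")
            for j in range(i + 1, j_hi):
                a, b = _pair_key(ids[i], ids[j])
                rows.append((a, b, chrom, int(tss[j] - tss[i])))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "chrom", "tss_distance"])


def correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN when either side is constant.

    On binary vectors this equals the phi coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("correlate needs equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _zscore_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean, unit norm; second output flags constant rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    constant = norms == 0
    norms[constant] = 1.0
    return Xc / norms[:, None], constant


def _perm_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def null_max_correlations(mat: CellMatrix, focal: str, partners: list[str],
                          n_perm: int, seed: int) -> np.ndarray:
    """Permutation null of the maximum cis correlation for one focal gene.

    Each permutation shuffles the focal gene's vector across cells and
    records the maximum Pearson correlation over all partners.
    """
    if not partners:
        raise ValueError("partners must be nonempty")
    X = mat.to_dense()
    idx = {g: i for i, g in enumerate(mat.row_ids)}
    Z, _ = _zscore_rows(X[[idx[focal]] + [idx[p] for p in partners]])
    rng = np.random.default_rng(seed)
    perms = _perm_indices(rng, n_perm, X.shape[1])
    null_r = Z[0][perms] @ Z[1:].T  # (n_perm, n_partners)
    return null_r.max(axis=1)


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Permutation p-value with the add-one estimator: (1 + #{null >= obs}) / (n + 1)."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null must be nonempty")
    return (1 + int((null >= observed).sum())) / (null.size + 1)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving by index."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_cop_tests(mat: CellMatrix, annot: GeneAnnotation, params: CopParams) -> pd.DataFrame:
    """Per-direction permutation tests for every cis pair.

    Returns two rows per unordered pair (one per focal gene) with columns
    focal_gene, partner_gene, gene_a, gene_b, chrom, tss_distance, rho,
    p_emp, q.  BH correction is applied jointly over all rows.
    """
    gene_set = set(mat.row_ids)
    missing = [g for g in mat.row_ids if g not in set(annot.gene_ids)]
    if missing:
        raise KeyError(f"matrix rows without annotation: {missing}")
    sub = annot.subset(gene_set)
    pairs = enumerate_cis_pairs(sub, params.window_bp)
    if pairs.empty:
        warnings.warn("no testable cis pairs")
        return pd.DataFrame(columns=["focal_gene", "partner_gene", "gene_a", "gene_b",
                                     "chrom", "tss_distance", "rho", "p_emp", "q"])

    X = mat.to_dense()
    idx = {g: i for i, g in enumerate(mat.row_ids)}
    Z, constant = _zscore_rows(X)
    n_cells = X.shape[1]

    partners_of: dict[str, list[str]] = {}
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        partners_of.setdefault(a, []).append(b)
        partners_of.setdefault(b, []).append(a)

    genes = sorted(partners_of)  # fixed order -> reproducible child seeds
    seeds = np.random.SeedSequence(params.seed).spawn(len(genes))

    pair_info = {
        (a, b): (c, d)
        for a, b, c, d in zip(pairs["gene_a"], pairs["gene_b"],
                              pairs["chrom"], pairs["tss_distance"])
    }
    records = []
    for gene, seed_seq in zip(genes, seeds):
        fi = idx[gene]
        part = partners_of[gene]
        pi = np.array([idx[p] for p in part])
        obs = Z[fi] @ Z[pi].T
        if constant[fi]:
            obs[:] = np.nan
        obs[constant[pi]] = np.nan
        rng = np.random.default_rng(seed_seq)
        perms = _perm_indices(rng, params.n_perm, n_cells)
        null_max = np.sort((Z[fi][perms] @ Z[pi].T).max(axis=1))
        # exceedance count via binary search on the sorted null
        n_ge = params.n_perm - np.searchsorted(null_max, np.nan_to_num(obs, nan=np.inf), side="left")
        p_emp = (1 + n_ge) / (params.n_perm + 1)
        for p_gene, r, pe in zip(part, obs, p_emp):
            if np.isnan(r):
                continue  # zero-variance member: pair skipped in this direction
            a, b = _pair_key(gene, p_gene)
            chrom, dist = pair_info[(a, b)]
            records.append((gene, p_gene, a, b, chrom, int(dist), float(r), float(pe)))
    tests = pd.DataFrame(records, columns=["focal_gene", "partner_gene", "gene_a",
                                           "gene_b", "chrom", "tss_distance",
                                           "rho", "p_emp"])
    tests["q"] = bh_fdr(tests["p_emp"].to_numpy()) if len(tests) else []
    return tests


def filter_crossmap(pairs: pd.DataFrame, scores: pd.DataFrame | None,
                    threshold: float = 10.0) -> pd.DataFrame:
    """Remove pairs whose cross-mappability score exceeds the threshold.

    ``scores`` has columns gene_a, gene_b, score; lookup is symmetric and a
    missing pair passes (no evidence of mapping artifact).
    """
    if scores is None or pairs.empty:
        return pairs
    lut = {}
    for a, b, s in zip(scores["gene_a"], scores["gene_b"], scores["score"]):
        lut[_pair_key(a, b)] = float(s)
    keep = np.array([lut.get(_pair_key(a, b), 0.0) <= threshold
                     for a, b in zip(pairs["gene_a"], pairs["gene_b"])], dtype=bool)
    return pairs.loc[keep].reset_index(drop=True)


def detect_cops(mat: CellMatrix, annot: GeneAnnotation, params: CopParams,
                crossmap: pd.DataFrame | None = None,
                individual: str | None = None,
                experiment: str | None = None) -> CopSet:
    """Full COP call on one preprocessed matrix.

    A pair is a COP when any of its two focal-direction tests has q < fdr,
    rho > 0, rho <= max_rho, rho >= min_rho (when set), and its
    cross-mappability score is <= crossmap_max (missing score passes).
    The returned :class:`CopSet` keeps the full test table in ``.tests``.
    """
    tests = run_cop_tests(mat, annot, params)
    if tests.empty:
        warnings.warn("no testable pairs; returning empty CopSet")
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        return CopSet(empty, individual, experiment, mat.shape[1], tests)

    best = (tests.sort_values(["q", "p_emp"], kind="mergesort")
                 .groupby(["gene_a", "gene_b"], as_index=False, sort=False).first())
    sig = best[(best["q"] < params.fdr) & (best["rho"] > 0) & (best["rho"] <= params.max_rho)]
    if params.min_rho is not None:
        sig = sig[sig["rho"] >= params.min_rho]
    sig = filter_crossmap(sig.reset_index(drop=True), crossmap, params.crossmap_max)
    pairs = sig[PAIR_COLUMNS].reset_index(drop=True)
    return CopSet(pairs, individual, experiment, mat.shape[1], tests)


def drop_outlier_experiments(stats: list[tuple[str, int, int]]) -> list[str]:
    """Keep experiments whose COPs-per-cell ratio is not an extreme outlier.

    An experiment is dropped when its ratio exceeds Q75 + 3 * IQR of the
    ratios (linear-interpolation quantiles).  With fewer than 4 experiments
    nothing is dropped.
    """
    for _, _, n_cells in stats:
        if n_cells <= 0:
            raise ValueError("n_cells must be > 0")
    if len(stats) < 4:
        if stats:
            warnings.warn("fewer than 4 experiments; outlier rule skipped")
        return [s[0] for s in stats]
    ratios = np.array([n_cops / n_cells for _, n_cops, n_cells in stats])
    q25, q75 = np.percentile(ratios, [25, 75])
    cutoff = q75 + 3 * (q75 - q25)
    return [s[0] for s, r in zip(stats, ratios) if r <= cutoff]


def union_cops(sets: list[CopSet]) -> CopSet:
    """Union of COP sets from experiments of the same individual.

    Duplicated pairs keep their most significant (smallest q) statistics;
    provenance lists the contributing experiments per pair.
    """
    if not sets:
        return CopSet(pd.DataFrame(columns=PAIR_COLUMNS + ["experiments"]))
    individuals = {s.individual for s in sets}
    if len(individuals) > 1:
        raise ValueError(f"union_cops requires a single individual, got {individuals}")
    frames = []
    for s in sets:
        df = s.pairs.copy()
        df["experiments"] = s.experiment if s.experiment is not None else ""
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True)
    if allp.empty:
        return CopSet(allp, next(iter(individuals)), None, max(s.n_cells for s in sets))
    exps = (allp.groupby(["gene_a", "gene_b"])["experiments"]
                .apply(lambda v: ",".join(sorted(set(map(str, v))))))
    best = (allp.sort_values(["q", "p_emp"], kind="mergesort")
                .groupby(["gene_a", "gene_b"], as_index=False, sort=True).first())
    best["experiments"] = best.set_index(["gene_a", "gene_b"]).index.map(exps)
    return CopSet(best.reset_index(drop=True), next(iter(individuals)), None,
                  max(s.n_cells for s in sets))
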