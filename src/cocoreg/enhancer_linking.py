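"""Gene-enhancer association from paired expression / accessibility matrices.

Enhancer regions are built by merging book-ended enhancer-state intervals;
accessibility peaks are assigned to regions when at least half the peak
overlaps; a region is "active" in a cell when any assigned peak is open.
Each gene is then tested against every region whose midpoint lies within a
cis window of its TSS by Spearman correlation across cells, with an
empirical p-value from shuffling the gene's expression vector (the shuffle
is drawn once per permutation and reused against all of that gene's
enhancers), BH correction over all tests, and a correlation floor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata, spearmanr

from .cop_detection import CopParams, _pair_key, _perm_indices, _zscore_rows, bh_fdr
from .genome_io import CellMatrix, GeneAnnotation, IntervalSet

#: chromatin-state labels treated as enhancers (genic + active enhancer states)
DEFAULT_ENHANCER_LABELS = frozenset({"EnhG1", "EnhG2", "EnhA1", "EnhA2"})

ASSOC_COLUMNS = ["gene_id", "enhancer_id", "chrom", "tss", "enh_mid",
                 "tss_to_midpoint", "rho", "p_emp", "q", "significant"]


def merge_bookended(states: IntervalSet, keep_labels=DEFAULT_ENHANCER_LABELS) -> pd.DataFrame:
    """Merge overlapping-or-adjacent (book-ended) enhancer-state intervals.

    Intervals whose ``id`` (state label) is in ``keep_labels`` are kept and
    runs with no gap between them are merged into single enhancer regions.
    Returns columns id, chrom, start, end, midpoint.
    """
    df = states.df
    if "id" in df.columns and keep_labels is not None:
        df = df[df["id"].isin(set(keep_labels))]
    regions = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or book-ended (s == cur_e)
                cur_e = max(cur_e, e)
            else:
                regions.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            regions.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    out.insert(0, "id", [f"enh_{i}" for i in range(len(out))])
    out["midpoint"] = (out["start"] + out["end"]) // 2
    return out


def assign_peaks(peaks: IntervalSet, enhancers: pd.DataFrame,
                 min_frac: float = 0.5) -> dict:
    """Assign each peak to every enhancer covering >= min_frac of the peak.

    Returns peak id -> list of enhancer ids.  Peaks without an ``id`` column
    get positional ids ``chrom:start-end``.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    pdf = peaks.df.copy()
    if "id" not in pdf.columns:
        pdf["id"] = [f"{c}:{s}-{e}" for c, s, e in zip(pdf["chrom"], pdf["start"], pdf["end"])]
    assignment: dict = {}
    enh_by_chrom = {c: g.sort_values("start") for c, g in enhancers.groupby("chrom")}
    for chrom, grp in pdf.groupby("chrom"):
        enh = enh_by_chrom.get(chrom)
        if enh is None:
            continue
        es, ee, eid = (enh["start"].to_numpy(), enh["end"].to_numpy(),
                       enh["id"].to_numpy())
        for pid, ps, pe in zip(grp["id"], grp["start"], grp["end"]):
            overlap = np.minimum(ee, pe) - np.maximum(es, ps)
            hits = eid[overlap >= min_frac * (pe - ps)]
            if hits.size:
                assignment[pid] = list(hits)
    return assignment


def enhancer_activity(peak_matrix: CellMatrix, assignment: dict) -> CellMatrix:
    """Binary enhancer x cell activity: OR over each region's assigned peaks.

    Enhancers with no assigned peak are absent from the output.
    """
    if peak_matrix.kind != "binary":
        raise ValueError("peak matrix must be binary")
    by_enh: dict = {}
    for pid, enh_ids in assignment.items():
        for eid in enh_ids:
            by_enh.setdefault(eid, []).append(pid)
    pidx = {p: i for i, p in enumerate(peak_matrix.row_ids)}
    X = peak_matrix.to_dense()
    rows, ids = [], []
    for eid in sorted(by_enh):
        members = [pidx[p] for p in by_enh[eid] if p in pidx]
        if not members:
            continue
        rows.append((X[members].sum(axis=0) > 0).astype(np.int8))
        ids.append(eid)
    if not rows:
        return CellMatrix(np.array([], dtype=object), peak_matrix.col_ids,
                          np.zeros((0, peak_matrix.shape[1]), dtype=np.int8), "binary")
    return CellMatrix(np.array(ids, dtype=object), peak_matrix.col_ids,
                      np.vstack(rows), "binary")


def _rank_zscore_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows replaced by zero-mean unit-norm average ranks (Spearman device)."""
    R = np.vstack([rankdata(row, method="average") for row in X])
    return _zscore_rows(R)


def detect_associations(expr: CellMatrix, activity: CellMatrix,
                        annot: GeneAnnotation, enhancers: pd.DataFrame,
                        params: CopParams | None = None,
                        rho_min: float = 0.05) -> pd.DataFrame:
    """Test every gene x in-window enhancer for Spearman association.

    The null shuffles each gene's expression vector ``n_perm`` times; each
    shuffle is scored against all of that gene's enhancers (per-test
    exceedance counts).  BH runs over all tests jointly; a test is
    significant when q < fdr and rho > rho_min.
    """
    if params is None:
        params = CopParams()
    shared = [c for c in expr.col_ids if c in set(activity.col_ids)]
    if not shared:
        raise ValueError("expression and activity matrices share no cells")
    E = expr.subset_cols(shared)
    A = activity.subset_cols(shared)
    n_cells = len(shared)

    Ze, const_e = _rank_zscore_rows(E.to_dense())
    Za, const_a = _rank_zscore_rows(A.to_dense())

    ann = annot.df.set_index("gene_id")
    enh_by_chrom = {c: g for c, g in enhancers.groupby("chrom")}
    eidx = {e: i for i, e in enumerate(A.row_ids)}

    genes = [g for g in E.row_ids if g in ann.index]
    seeds = np.random.SeedSequence(params.seed).spawn(len(genes))
    records = []
    for gi, (gene, seed_seq) in enumerate(zip(genes, seeds)):
        if const_e[np.flatnonzero(E.row_ids == gene)[0]]:
            continue
        tss = int(ann.loc[gene, "tss"])
        chrom = str(ann.loc[gene, "chrom"])
        enh = enh_by_chrom.get(chrom)
        if enh is None:
            continue
        inwin = enh[(enh["midpoint"] - tss).abs() <= params.window_bp]
        cols = [(eid, mid) for eid, mid in zip(inwin["id"], inwin["midpoint"])
                if eid in eidx and not const_a[eidx[eid]]]
        if not cols:
            continue
        ai = np.array([eidx[eid] for eid, _ in cols])
        zg = Ze[np.flatnonzero(E.row_ids == gene)[0]]
        obs = zg @ Za[ai].T
        rng = np.random.default_rng(seed_seq)
        perms = _perm_indices(rng, params.n_perm, n_cells)
        null = zg[perms] @ Za[ai].T  # (n_perm, n_enh)
        n_ge = (null >= obs[None, :]).sum(axis=0)
        p_emp = (1 + n_ge) / (params.n_perm + 1)
        for (eid, mid), r, pe in zip(cols, obs, p_emp):
            records.append((gene, eid, chrom, tss, int(mid), int(mid) - tss,
                            float(r), float(pe)))
    tests = pd.DataFrame(records, columns=ASSOC_COLUMNS[:8])
    if tests.empty:
        warnings.warn("no gene-enhancer tests performed")
        tests["q"] = []
        tests["significant"] = []
        return tests
    tests["q"] = bh_fdr(tests["p_emp"].to_numpy())
    tests["significant"] = (tests["q"] < params.fdr) & (tests["rho"] > rho_min)
    return tests


def shared_enhancers(pairs: pd.DataFrame, tests: pd.DataFrame) -> pd.DataFrame:
    """Enhancers significantly associated with both genes of each pair.

    Also reports the number of enhancers *tested* for both genes, so the
    sharing comparison can be checked for testing-opportunity bias.
    Returns gene_a, gene_b, shared_ids (comma-joined), n_shared, n_tested_both.
    """
    sig_by_gene = (tests[tests["significant"]]
                   .groupby("gene_id")["enhancer_id"].apply(set).to_dict())
    tested_by_gene = tests.groupby("gene_id")["enhancer_id"].apply(set).to_dict()
    rows = []
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        shared = sig_by_gene.get(a, set()) & sig_by_gene.get(b, set())
        tested = tested_by_gene.get(a, set()) & tested_by_gene.get(b, set())
        rows.append((a, b, ",".join(sorted(shared)), len(shared), len(tested)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "shared_ids",
                                       "n_shared", "n_tested_both"])


def score_concordance(tests_a: pd.DataFrame, tests_b: pd.DataFrame) -> tuple[float, int]:
    """Spearman correlation between two gene-enhancer score tables.

    Records are matched by gene id plus enhancer interval overlap (tables
    must carry chrom/start/end for the enhancer, or share enhancer_id).
    Returns (rho, n matched).
    """
    if {"start", "end"} <= set(tests_a.columns) and {"start", "end"} <= set(tests_b.columns):
        matched_a, matched_b = [], []
        b_by_gene = {g: t for g, t in tests_b.groupby("gene_id")}
        for g, ta in tests_a.groupby("gene_id"):
            tb = b_by_gene.get(g)
            if tb is None:
                continue
            bs, be, brho = tb["start"].to_numpy(), tb["end"].to_numpy(), tb["rho"].to_numpy()
            for s, e, r in zip(ta["start"], ta["end"], ta["rho"]):
                hit = np.flatnonzero((np.minimum(be, e) - np.maximum(bs, s)) > 0)
                if hit.size:
                    matched_a.append(r)
                    matched_b.append(brho[hit[0]])
    else:
        merged = tests_a.merge(tests_b, on=["gene_id", "enhancer_id"],
                               suffixes=("_a", "_b"))
        matched_a, matched_b = merged["rho_a"], merged["rho_b"]
    if len(matched_a) == 0:
        raise ValueError("no matched gene-enhancer records between tables")
    rho = spearmanr(matched_a, matched_b).statistic
    return float(rho), len(matched_a)
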