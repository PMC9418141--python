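"""Distance-matched non-co-expressed control pairs ("non-COPs").

Every downstream comparison (enrichment, Hi-C support, GRO-seq and
proteomics concordance) contrasts COPs with control pairs that were tested
but not significant and whose TSS distance matches the COP's within a small
tolerance (default 100 bp), sampled without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cop_detection import CopSet, _pair_key


@dataclass
class MatchedPairSet:
    """COP -> control pair matching result.

    ``records`` columns: gene_a, gene_b (COP), control_a, control_b,
    cop_distance, control_distance.  COPs with no eligible candidate are in
    ``unmatched``.
    """

    records: pd.DataFrame
    unmatched: list = field(default_factory=list)
    tolerance_bp: int = 100

    def __len__(self) -> int:
        return len(self.records)

    def max_distance_error(self) -> int:
        if self.records.empty:
            return 0
        return int((self.records["cop_distance"] - self.records["control_distance"])
                   .abs().max())

    def control_pairs(self) -> pd.DataFrame:
        out = self.records[["control_a", "control_b", "control_distance"]].copy()
        return out.rename(columns={"control_a": "gene_a", "control_b": "gene_b",
                                   "control_distance": "tss_distance"})


def build_noncop_pool(tests: pd.DataFrame, mode: str, fdr: float = 0.05,
                      cop_pairs: set | None = None) -> pd.DataFrame:
    """Pool of tested pairs eligible as controls.

    Binary mode keeps pairs with rho < 0.2 AND q > fdr; continuous mode
    keeps pairs with q > fdr.  Pairs that are COPs in any set of the run
    (``cop_pairs``, unordered keys) are excluded.  One row per unordered
    pair with its best (smallest q) statistics.
    """
    if mode not in ("continuous", "binary"):
        raise ValueError("mode must be 'continuous' or 'binary'")
    if tests.empty:
        raise ValueError("empty test table")
    best = (tests.sort_values(["q", "p_emp"], kind="mergesort")
                 .groupby(["gene_a", "gene_b"], as_index=False, sort=True).first())
    mask = best["q"] > fdr
    if mode == "binary":
        mask &= best["rho"] < 0.2
    pool = best[mask]
    if cop_pairs:
        keys = [_pair_key(a, b) for a, b in zip(pool["gene_a"], pool["gene_b"])]
        pool = pool.loc[np.array([k not in cop_pairs for k in keys], dtype=bool)]
    pool = pool[["gene_a", "gene_b", "chrom", "tss_distance", "rho", "q"]].reset_index(drop=True)
    if pool.empty:
        raise ValueError("non-COP pool is empty")
    return pool


def sample_distance_matched(cops: CopSet | pd.DataFrame, pool: pd.DataFrame,
                            tolerance_bp: int = 100, seed: int = 0) -> MatchedPairSet:
    """Draw one distance-matched control per COP, without replacement.

    COPs are processed in a seeded shuffled order to avoid systematic
    exhaustion bias; for each, a candidate with |pool distance - COP
    distance| <= tolerance is drawn uniformly among unused pool pairs.
    COPs with no remaining candidate are reported as unmatched.
    """
    cop_df = cops.pairs if isinstance(cops, CopSet) else cops
    rng = np.random.default_rng(seed)

    pool_d = pool["tss_distance"].to_numpy()
    order = np.argsort(pool_d, kind="mergesort")
    pool_sorted = pool.iloc[order].reset_index(drop=True)
    d_sorted = pool_d[order]
    used = np.zeros(len(pool_sorted), dtype=bool)

    cop_order = rng.permutation(len(cop_df))
    matches, unmatched = [], []
    for ci in cop_order:
        cop = cop_df.iloc[ci]
        d = int(cop["tss_distance"])
        lo = np.searchsorted(d_sorted, d - tolerance_bp, side="left")
        hi = np.searchsorted(d_sorted, d + tolerance_bp, side="right")
        candidates = np.flatnonzero(~used[lo:hi]) + lo
        if candidates.size == 0:
            unmatched.append((cop["gene_a"], cop["gene_b"]))
            continue
        pick = int(rng.choice(candidates))
        used[pick] = True
        ctrl = pool_sorted.iloc[pick]
        matches.append((cop["gene_a"], cop["gene_b"], ctrl["gene_a"], ctrl["gene_b"],
                        d, int(ctrl["tss_distance"])))
    records = pd.DataFrame(matches, columns=["gene_a", "gene_b", "control_a",
                                             "control_b", "cop_distance",
                                             "control_distance"])
    # restore the COP table order for stable output
    if not records.empty:
        key = {(a, b): i for i, (a, b) in enumerate(zip(cop_df["gene_a"], cop_df["gene_b"]))}
        records = (records
                   .assign(_o=[key[(a, b)] for a, b in zip(records["gene_a"], records["gene_b"])])
                   .sort_values("_o").drop(columns="_o").reset_index(drop=True))
    return MatchedPairSet(records, unmatched, tolerance_bp)
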