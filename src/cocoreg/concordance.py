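"""Concordance of co-expressed pairs with orthogonal molecular readouts.

Two readouts are supported: nascent transcription at TSSs from stranded
signal tracks (GRO-seq style), and protein intensities summed over isoforms
(proteomics style).  In both cases the readout values of the two genes of
each pair are correlated across pairs (Spearman), for COPs and for their
distance-matched controls, with a label-shuffle as an additional negative
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genome_io import GeneAnnotation, IntervalSet


@dataclass
class PairCorrelation:
    """Result of correlating pair-member values across pairs."""

    rho: float | None
    p: float | None
    n_used: int
    reason: str | None = None  # set when the correlation was not computed


def tss_read_counts(track: IntervalSet, annot: GeneAnnotation) -> dict:
    """Per gene, the strand-matched track value covering the TSS base.

    The track carries ``value`` and ``strand`` columns (typically built
    from one bedgraph per strand).  The 1-based TSS maps to 0-based base
    tss - 1; intervals are half-open, so a TSS at an interval's ``end`` is
    not covered.  Genes without strand-matched coverage are absent.
    """
    df = track.df
    if "value" not in df.columns or "strand" not in df.columns:
        raise ValueError("signal track needs value and strand columns")
    out: dict = {}
    by_key = {k: g.sort_values("start") for k, g in df.groupby(["chrom", "strand"])}
    for gene, chrom, tss, strand in zip(annot.df["gene_id"], annot.df["chrom"],
                                        annot.df["tss"], annot.df["strand"]):
        grp = by_key.get((str(chrom), strand))
        if grp is None:
            continue
        pos = int(tss) - 1  # 0-based TSS base
        starts = grp["start"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and grp["end"].iloc[i] > pos:
            out[gene] = float(grp["value"].iloc[i])
    return out


def pair_value_correlation(pairs: pd.DataFrame, values: dict,
                           min_pairs: int = 11) -> PairCorrelation:
    """Spearman correlation of (value of gene_a, value of gene_b) across pairs.

    Pairs with a missing value for either gene are dropped.  When fewer
    than ``min_pairs`` usable pairs remain the correlation is not computed
    and the reason is reported instead.
    """
    xs, ys = [], []
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        if a in values and b in values and not (pd.isna(values[a]) or pd.isna(values[b])):
            xs.append(values[a])
            ys.append(values[b])
    n = len(xs)
    if n < min_pairs:
        return PairCorrelation(None, None, n,
                               f"only {n} usable pairs (min {min_pairs})")
    res = spearmanr(xs, ys)
    return PairCorrelation(float(res.statistic), float(res.pvalue), n)


def gene_intensities(isoforms: pd.DataFrame) -> pd.DataFrame:
    """Sum isoform intensities to gene-level intensities per sample.

    Input columns: isoform, gene, sample, intensity.  A gene-sample with
    all isoform intensities missing stays missing (NaN), not 0.  Returns a
    gene x sample table.
    """
    required = {"gene", "sample", "intensity"}
    if not required <= set(isoforms.columns):
        raise ValueError(f"isoform table needs columns {sorted(required)}")
    summed = (isoforms.groupby(["gene", "sample"])["intensity"]
              .sum(min_count=1))  # min_count keeps all-NaN groups as NaN
    return summed.unstack("sample")


def shuffle_pair_labels(pairs: pd.DataFrame, seed: int = 0,
                        max_tries: int = 1000) -> pd.DataFrame:
    """Permute second-position genes across pairs, avoiding original pairs.

    The permutation is a derangement at the pair level: no output pair
    equals an input pair (unordered comparison).  The multiset of genes is
    preserved.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to shuffle")
    a = pairs["gene_a"].to_numpy()
    b = pairs["gene_b"].to_numpy()
    original = {frozenset(p) for p in zip(a, b)}
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(len(b))
        nb = b[perm]
        if all(frozenset((x, y)) not in original for x, y in zip(a, nb)):
            out = pairs.copy()
            out["gene_b"] = nb
            return out.reset_index(drop=True)
    # deterministic fallback: rotate second genes by one position
    nb = np.roll(b, 1)
    if any(frozenset((x, y)) in original for x, y in zip(a, nb)):
        raise RuntimeError("could not find a pair-level derangement")
    out = pairs.copy()
    out["gene_b"] = nb
    return out.reset_index(drop=True)


def subset_cells_by_phase(col_ids, phase_labels: dict, phase: str) -> list:
    """Cell ids of one cell-cycle phase, for phase-stratified detection.

    ``phase_labels`` maps cell id -> phase (e.g. G1/S/G2M); phase labels
    are an input, not predicted here.
    """
    return [c for c in col_ids if phase_labels.get(c) == phase]
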