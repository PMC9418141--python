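"""Fisher's exact enrichment of pair sets in functionally-related-pair labels.

A pair is "labeled" when both genes share at least one gene set (pathway,
protein complex) or when the pair belongs to an explicit reference pair set.
Enrichment contrasts a query pair list (e.g. COPs) against a background of
all tested pairs via a 2x2 Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

from .cop_detection import _pair_key


@dataclass
class PairLabeler:
    """Symmetric labeling of gene pairs.

    Either ``gene_sets`` (set name -> set of gene ids; a pair is labeled
    when both genes co-occur in >= 1 set) or ``reference_pairs`` (explicit
    unordered pair set).
    """

    gene_sets: dict | None = None
    reference_pairs: set | None = None

    def __post_init__(self) -> None:
        if (self.gene_sets is None) == (self.reference_pairs is None):
            raise ValueError("provide exactly one of gene_sets or reference_pairs")
        if self.gene_sets is not None:
            self._membership: dict = {}
            for set_id, genes in self.gene_sets.items():
                for g in genes:
                    self._membership.setdefault(g, set()).add(set_id)
        if self.reference_pairs is not None:
            self.reference_pairs = {_pair_key(a, b) for a, b in self.reference_pairs}

    def label(self, gene_a: str, gene_b: str) -> bool:
        if self.reference_pairs is not None:
            return _pair_key(gene_a, gene_b) in self.reference_pairs
        sets_a = self._membership.get(gene_a)
        sets_b = self._membership.get(gene_b)
        return bool(sets_a and sets_b and (sets_a & sets_b))


@dataclass
class EnrichmentResult:
    """2x2 contingency counts with sample odds ratio, Woolf CI and exact p.

    Table layout: a = labeled query, b = unlabeled query, c = labeled
    non-query background, d = unlabeled non-query background.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    sidedness: str


def read_gene_sets(path) -> dict:
    """Two-column TSV (set_id, gene_id) -> {set_id: set of gene ids}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene_id"],
                     dtype=str, comment="#")
    return {s: set(g) for s, g in df.groupby("set_id")["gene_id"]}


def label_pairs(pairs: pd.DataFrame, labeler: PairLabeler) -> np.ndarray:
    """Boolean vector: pair labeled (both genes share >= 1 set / in reference)."""
    return np.array([labeler.label(a, b)
                     for a, b in zip(pairs["gene_a"], pairs["gene_b"])], dtype=bool)


def fisher_enrichment(query: pd.DataFrame, background: pd.DataFrame,
                      labeler: PairLabeler, sidedness: str = "greater") -> EnrichmentResult:
    """Fisher's exact enrichment of the query pair set within the background.

    The background must contain every query pair (it is the union of all
    pairs tested across the compared runs).  The odds ratio is the sample
    cross-product (ad)/(bc) with Haldane 0.5 correction when any cell is
    zero; the 95% CI is Woolf's on the log odds ratio.
    """
    if sidedness not in ("greater", "two-sided", "less"):
        raise ValueError(f"unsupported sidedness: {sidedness!r}")
    qkeys = {_pair_key(a, b) for a, b in zip(query["gene_a"], query["gene_b"])}
    bkeys = {_pair_key(a, b) for a, b in zip(background["gene_a"], background["gene_b"])}
    if not qkeys <= bkeys:
        raise ValueError("query pairs must be a subset of the background")

    labeled = {k for k in bkeys if labeler.label(*k)}
    a = len(qkeys & labeled)
    b = len(qkeys) - a
    c = len(labeled - qkeys)
    d = len(bkeys) - len(qkeys) - c

    table = np.array([[a, b], [c, d]], dtype=float)
    if (table == 0).any():
        table = table + 0.5  # Haldane correction for the estimate/CI only
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    se = np.sqrt((1.0 / table).sum())
    z = norm.ppf(0.975)
    ci_low, ci_high = np.exp(np.log(odds) - z * se), np.exp(np.log(odds) + z * se)
    _, p = fisher_exact([[a, b], [c, d]], alternative=sidedness)
    return EnrichmentResult(a, b, c, d, float(odds), float(ci_low), float(ci_high),
                            float(p), sidedness)
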