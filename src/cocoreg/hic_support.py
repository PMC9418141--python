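"""Chromatin-contact (Hi-C) support of gene-enhancer and pair-enhancer links.

Contacts are looked up for the bins containing the gene TSS and the
enhancer midpoint, log2(1 + x)-transformed, with missing bin pairs scored
as 0.  Each association gets a mirrored control: the enhancer position
reflected through the TSS, which preserves genomic distance.  An
association is "supported" when its contact exceeds the 75th percentile of
contacts over all tested associations; a gene pair is supported when at
least one shared enhancer has above-threshold contact with both TSSs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .genome_io import HiCMap

CONTACT_COLUMNS = ["gene_id", "enhancer_id", "chrom", "contact",
                   "control_contact", "supported"]


def lookup_contact(hic: HiCMap, chrom: str, pos_a: int, pos_b: int) -> float:
    """log2(1 + normalized contact) for the bins containing two positions.

    Symmetric in the positions; an unstored bin pair scores 0 (missing
    data is treated as no contact).
    """
    if pos_a < 0 or pos_b < 0:
        raise ValueError("positions must be >= 0")
    raw = hic.get(chrom, hic.bin_of(pos_a), hic.bin_of(pos_b))
    return 0.0 if raw is None else float(np.log2(1.0 + raw))


def mirror_control(tss: int, enh_mid: int) -> int:
    """Enhancer position reflected through the TSS (distance-preserving),
    floored at 0."""
    return max(2 * int(tss) - int(enh_mid), 0)


def support_threshold(contacts: np.ndarray) -> float:
    """75th percentile (linear interpolation) of the tested contacts."""
    contacts = np.asarray(contacts, dtype=float)
    if contacts.size == 0:
        raise ValueError("support_threshold needs a nonempty vector")
    return float(np.percentile(contacts, 75))


def flag_supported(tests: pd.DataFrame, hic: HiCMap):
    """Score every association for Hi-C support.

    ``tests`` must carry gene_id, enhancer_id, chrom, tss, enh_mid (the
    association table from enhancer linking).  Returns ``(records,
    threshold, rho)`` where records adds contact, control_contact and the
    supported flag, threshold is the 75th-percentile cutoff over all tested
    pairs, and rho is the Spearman correlation of association strength vs
    contact (None when degenerate).
    """
    contacts, controls = [], []
    for chrom, tss, mid in zip(tests["chrom"], tests["tss"], tests["enh_mid"]):
        contacts.append(lookup_contact(hic, chrom, int(tss), int(mid)))
        controls.append(lookup_contact(hic, chrom, int(tss), mirror_control(tss, mid)))
    contacts = np.asarray(contacts)
    threshold = support_threshold(contacts)
    out = tests.copy()
    out["contact"] = contacts
    out["control_contact"] = controls
    out["supported"] = contacts > threshold
    rho = None
    if "rho" in tests.columns and len(tests) >= 3:
        if np.ptp(contacts) > 0 and np.ptp(tests["rho"].to_numpy()) > 0:
            rho = float(spearmanr(tests["rho"], contacts).statistic)
    return out, threshold, rho


def cop_hic_support(shared: pd.DataFrame, tests: pd.DataFrame, hic: HiCMap,
                    threshold: float) -> pd.DataFrame:
    """Flag gene pairs with >= 1 shared enhancer contacting both TSSs.

    A pair is supported when some single shared enhancer has
    contact(TSS_a, midpoint) > threshold AND contact(TSS_b, midpoint) >
    threshold.  Pairs without shared enhancers are unsupported.
    """
    tss_of = {}
    mid_of, chrom_of = {}, {}
    for g, e, c, t, m in zip(tests["gene_id"], tests["enhancer_id"], tests["chrom"],
                             tests["tss"], tests["enh_mid"]):
        tss_of[g] = int(t)
        mid_of[e] = int(m)
        chrom_of[e] = c
    rows = []
    for a, b, ids in zip(shared["gene_a"], shared["gene_b"], shared["shared_ids"]):
        supported = False
        enh_ids = [e for e in str(ids).split(",") if e] if isinstance(ids, str) else list(ids)
        for e in enh_ids:
            if e not in mid_of or a not in tss_of or b not in tss_of:
                continue
            ca = lookup_contact(hic, chrom_of[e], tss_of[a], mid_of[e])
            cb = lookup_contact(hic, chrom_of[e], tss_of[b], mid_of[e])
            if ca > threshold and cb > threshold:
                supported = True
                break
        rows.append((a, b, supported))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "hic_supported"])
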