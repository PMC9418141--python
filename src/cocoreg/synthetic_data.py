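"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the two single-cell regimes the pipeline targets —
a "smartseq"-like continuous count regime (moderate depth, overdispersed
negative-binomial counts, dropout) and a "shareseq"-like sparse binary
multiome regime (paired binary expression / accessibility) — plus
distance-decaying Hi-C contacts, isoform-level protein intensities and
stranded TSS signal tracks derived from the same expression truth.

Co-expression is planted through shared latent Gaussian factors (a Gaussian
copula), which controls the latent correlation while preserving marginal
count distributions.  Planted pairs are gene-disjoint so that "true pair"
is unambiguous in false-discovery accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CellMatrix, GeneAnnotation, HiCMap, IntervalSet, make_cell_matrix

#: default regime presets mirroring the two processing branches
PRESETS = {
    "smartseq": dict(n_cells=500, mean_log=1.0, dispersion=0.5, dropout=0.3),
    "shareseq": dict(n_cells=5000, baseline_on=0.2, gene_baseline=0.3),
}


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    ``planted_cop_pairs``: (gene_a, gene_b, target latent rho);
    ``planted_links``: (enhancer midpoint bp, gene id, activation effect);
    ``planted_shared``: (enhancer midpoint bp, gene_a, gene_b);
    ``expr_means``: per-gene mean expression level on the linear scale,
    shared by the members of a planted pair (the cross-pair concordance
    signal the proteomics / TSS-signal generators inherit).
    """

    planted_cop_pairs: list = field(default_factory=list)
    planted_links: list = field(default_factory=list)
    planted_shared: list = field(default_factory=list)
    expr_means: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def cop_pair_keys(self) -> set:
        return {tuple(sorted((a, b))) for a, b, *_ in self.planted_cop_pairs}


def simulate_annotation(n_genes: int, n_chrom: int = 1, spacing_bp: int = 100_000,
                        jitter_bp: int = 0, seed: int = 0,
                        start_bp: int = 100_000) -> GeneAnnotation:
    """Evenly spaced genes with optional uniform TSS jitter.

    Genes are split into ``n_chrom`` equal blocks, strands alternate, and
    all biotypes are protein_coding.
    """
    if spacing_bp <= 0:
        raise ValueError("spacing_bp must be > 0")
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_genes / n_chrom))
    rows = []
    for g in range(n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        pos_in_chrom = g % per_chrom
        tss = start_bp + pos_in_chrom * spacing_bp
        if jitter_bp > 0:
            tss += int(rng.integers(-jitter_bp, jitter_bp + 1))
        rows.append((f"g{g:04d}", chrom, max(tss, 1), "+" if g % 2 == 0 else "-",
                     "protein_coding"))
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss",
                                                      "strand", "biotype"]))


def adjacent_planted_pairs(annot: GeneAnnotation, n_pairs: int) -> list:
    """First ``n_pairs`` disjoint pairs of genomically adjacent genes."""
    df = annot.df.sort_values(["chrom", "tss"])
    pairs = []
    for _, grp in df.groupby("chrom", sort=False):
        ids = grp["gene_id"].tolist()
        for i in range(0, len(ids) - 1, 2):
            pairs.append((ids[i], ids[i + 1]))
            if len(pairs) == n_pairs:
                return pairs
    if len(pairs) < n_pairs:
        raise ValueError(f"annotation supports only {len(pairs)} disjoint adjacent pairs")
    return pairs


def _check_planted(annot: GeneAnnotation, planted: list, window_bp: int) -> None:
    seen: set = set()
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    chrom = dict(zip(annot.df["gene_id"], annot.df["chrom"]))
    for a, b in planted:
        if a in seen or b in seen or a == b:
            raise ValueError(f"gene reused across planted pairs: ({a}, {b})")
        seen.update((a, b))
        if chrom[a] != chrom[b] or abs(tss[a] - tss[b]) > window_bp:
            raise ValueError(f"planted pair ({a}, {b}) outside the cis window")


def simulate_expression(annot: GeneAnnotation, n_cells: int, planted: list,
                        rho: float = 0.6, mean_log: float = 1.0,
                        dispersion: float = 0.5, dropout: float = 0.3,
                        gene_mean_sd: float = 0.5, window_bp: int = 1_000_000,
                        seed: int = 0) -> tuple[CellMatrix, SimTruth]:
    """Overdispersed sparse counts with planted correlated cis gene pairs.

    A Gaussian copula: per gene and cell a latent standard normal, with
    the members of a planted pair sharing a latent factor with weight
    sqrt(rho) (latent correlation ``rho``); counts are the
    negative-binomial quantile transform of the latent's normal CDF
    (``dispersion`` = alpha in var = mu + alpha mu^2), so marginal count
    distributions are exactly NB while rank correlation tracks the latent,
    attenuated only by count ties and dropout.  Bernoulli dropout zeroes
    entries independently.  Members of a planted pair also share their
    per-gene mean, so planted pairs carry a cross-pair concordance signal
    usable by the proteomics / TSS-signal generators.
    """
    from scipy.stats import nbinom, norm, poisson

    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    _check_planted(annot, planted, window_bp)
    rng = np.random.default_rng(seed)
    genes = list(annot.gene_ids)
    n_genes = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}

    # per-gene mean on the log scale; planted partners share theirs
    base_log = mean_log + gene_mean_sd * rng.standard_normal(n_genes)
    for a, b in planted:
        base_log[gidx[b]] = base_log[gidx[a]]

    Z = rng.standard_normal((n_genes, n_cells))
    for a, b in planted:
        w = rng.standard_normal(n_cells)
        for g in (a, b):
            Z[gidx[g]] = np.sqrt(rho) * w + np.sqrt(1 - rho) * rng.standard_normal(n_cells)

    mu = np.exp(base_log)[:, None]
    u = norm.cdf(Z)
    if dispersion > 0:
        size = 1.0 / dispersion
        counts = nbinom.ppf(u, size, size / (size + mu))
    else:
        counts = poisson.ppf(u, mu)
    if dropout > 0:
        counts = np.where(rng.random(counts.shape) < dropout, 0, counts)

    cells = [f"cell{i:05d}" for i in range(n_cells)]
    truth = SimTruth(
        planted_cop_pairs=[(a, b, rho) for a, b in planted],
        expr_means={g: float(np.exp(base_log[i])) for i, g in enumerate(genes)},
        params=dict(n_cells=n_cells, rho=rho, mean_log=mean_log,
                    dispersion=dispersion, dropout=dropout,
                    gene_mean_sd=gene_mean_sd),
        seed=seed,
    )
    return make_cell_matrix(genes, cells, counts.astype(np.int64), "counts"), truth


def simulate_multiome(annot: GeneAnnotation, n_cells: int, links: list,
                      shared: list | None = None, baseline_on: float = 0.2,
                      gene_baseline: float = 0.3, n_decoy_enhancers: int = 0,
                      n_decoy_peaks: int = 0, enhancer_width: int = 1000,
                      peak_width: int = 400,
                      seed: int = 0):
    """Paired binary expression / accessibility with planted enhancer links.

    ``links``: (enhancer midpoint bp, gene id, effect) — the gene's on
    probability rises by ``effect`` in cells where the enhancer is open.
    ``shared``: (enhancer midpoint bp, gene_a, gene_b, effect) — one
    enhancer drives both genes, inducing gene-gene co-expression.  Decoy
    enhancers get peaks and activity but no target; decoy peaks overlap no
    enhancer state and are dropped by region assignment downstream.

    Returns (expr, peak matrix, peak intervals, state intervals, truth).
    """
    rng = np.random.default_rng(seed)
    shared = shared or []
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    chrom_of = dict(zip(annot.df["gene_id"], annot.df["chrom"]))

    enh_records = []  # (mid, chrom, targets=[(gene, effect), ...])
    for mid, gene, effect in links:
        if abs(mid - tss[gene]) > 1_000_000:
            raise ValueError(f"enhancer at {mid} outside +/-1 Mb of {gene} TSS")
        enh_records.append((int(mid), chrom_of[gene], [(gene, float(effect))]))
    for mid, ga, gb, effect in shared:
        for g in (ga, gb):
            if abs(mid - tss[g]) > 1_000_000:
                raise ValueError(f"shared enhancer at {mid} outside +/-1 Mb of {g} TSS")
        enh_records.append((int(mid), chrom_of[ga],
                            [(ga, float(effect)), (gb, float(effect))]))

    chroms = sorted(set(annot.df["chrom"]))
    span_hi = int(annot.df["tss"].max()) + 500_000
    taken = {(c, m) for m, c, _ in enh_records}
    while len(enh_records) < len(links) + len(shared) + n_decoy_enhancers:
        c = chroms[int(rng.integers(len(chroms)))]
        m = int(rng.integers(100_000, span_hi))
        # keep decoys clear of true enhancers so merged regions stay 1:1
        if all(abs(m - m2) > 2 * enhancer_width for m2, c2, _ in enh_records if c2 == c):
            enh_records.append((m, c, []))
            taken.add((c, m))

    n_enh = len(enh_records)
    E_on = (rng.random((n_enh, n_cells)) < baseline_on).astype(np.int8)

    genes = list(annot.gene_ids)
    gidx = {g: i for i, g in enumerate(genes)}
    p_on = np.full((len(genes), n_cells), gene_baseline)
    for ei, (_, _, targets) in enumerate(enh_records):
        for gene, effect in targets:
            p_on[gidx[gene]] += effect * E_on[ei]
    expr = (rng.random(p_on.shape) < np.clip(p_on, 0, 1)).astype(np.int8)

    # one peak per enhancer, centred on it (fully inside its state interval)
    peak_rows, state_rows, peak_ids = [], [], []
    for ei, (mid, chrom, _) in enumerate(enh_records):
        peak_ids.append(f"peak_t{ei:04d}")
        peak_rows.append((chrom, mid - peak_width // 2, mid + peak_width // 2,
                          peak_ids[-1]))
        state_rows.append((chrom, mid - enhancer_width // 2,
                           mid + enhancer_width // 2, "EnhA1"))
    P = E_on.copy()
    for di in range(n_decoy_peaks):
        c = chroms[int(rng.integers(len(chroms)))]
        while True:
            m = int(rng.integers(100_000, span_hi))
            if all(abs(m - m2) > 2 * enhancer_width for m2, c2, _ in enh_records if c2 == c):
                break
        pid = f"peak_d{di:04d}"
        peak_ids.append(pid)
        peak_rows.append((c, m - peak_width // 2, m + peak_width // 2, pid))
        P = np.vstack([P, (rng.random(n_cells) < baseline_on).astype(np.int8)])

    cells = [f"cell{i:05d}" for i in range(n_cells)]
    expr_mat = make_cell_matrix(genes, cells, expr, "binary")
    peak_mat = make_cell_matrix(peak_ids, cells, P, "binary")
    peak_iv = IntervalSet(pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "id"]))
    state_iv = IntervalSet(pd.DataFrame(state_rows, columns=["chrom", "start", "end", "id"]))
    truth = SimTruth(
        planted_links=[(int(m), g, float(e)) for m, g, e in links]
        + [(int(m), g, float(e)) for m, ga, gb, e in shared for g in (ga, gb)],
        planted_shared=[(int(m), ga, gb) for m, ga, gb, _ in shared],
        params=dict(n_cells=n_cells, baseline_on=baseline_on,
                    gene_baseline=gene_baseline), seed=seed,
    )
    return expr_mat, peak_mat, peak_iv, state_iv, truth


def link_is_planted(tests: pd.DataFrame, enhancers: pd.DataFrame,
                    truth: SimTruth) -> np.ndarray:
    """Boolean vector: association table row matches a planted link.

    A detected (gene, enhancer region) pair is "planted" when the region
    interval contains the midpoint of a planted enhancer linked to that
    gene.
    """
    bounds = {e: (c, s, t) for e, c, s, t in zip(enhancers["id"], enhancers["chrom"],
                                                 enhancers["start"], enhancers["end"])}
    out = []
    for gene, eid in zip(tests["gene_id"], tests["enhancer_id"]):
        chrom, s, t = bounds[eid]
        out.append(any(g == gene and s <= m < t for m, g, _ in truth.planted_links))
    return np.asarray(out, dtype=bool)


def simulate_hic(annot: GeneAnnotation, links: list, resolution: int = 5000,
                 decay_exp: float = 1.0, boost: float = 4.0,
                 noise_sd: float = 0.3, base: float = 10.0,
                 max_span_bp: int = 1_200_000, seed: int = 0) -> HiCMap:
    """Distance-decaying contacts with boosted true gene-enhancer bin pairs.

    contact(i, j) = base * (1 + |i - j|)^(-decay_exp) * lognormal noise,
    multiplied by ``boost`` when the bin pair joins a planted link's TSS
    and enhancer midpoint.  ``links`` is (enhancer midpoint, gene id, ...).
    """
    if decay_exp <= 0:
        raise ValueError("decay_exp must be > 0")
    if boost < 1:
        raise ValueError("boost must be >= 1")
    rng = np.random.default_rng(seed)
    hic = HiCMap(resolution=int(resolution))
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    chrom_of = dict(zip(annot.df["gene_id"], annot.df["chrom"]))
    boosted = set()
    for mid, gene, *_ in links:
        c = chrom_of[gene]
        bi, bj = sorted((int(tss[gene]) // resolution, int(mid) // resolution))
        boosted.add((c, bi, bj))
    max_bins = max_span_bp // resolution
    for chrom, grp in annot.df.groupby("chrom"):
        lo = max(int(grp["tss"].min()) - 200_000, 0) // resolution
        hi = (int(grp["tss"].max()) + 200_000) // resolution
        for i in range(lo, hi + 1):
            for j in range(i, min(i + max_bins, hi) + 1):
                val = base * (1 + j - i) ** (-decay_exp)
                if (chrom, i, j) in boosted:
                    val *= boost
                val *= float(np.exp(noise_sd * rng.standard_normal()))
                hic.set(chrom, i, j, val)
    return hic


def simulate_proteomics(truth: SimTruth, expr_means: dict, n_samples: int,
                        noise_sd: float = 0.2, missing_rate: float = 0.1,
                        n_isoforms_max: int = 3, pair_corr: float = 0.8,
                        seed: int = 0) -> pd.DataFrame:
    """Isoform-level protein intensities tracking the expression truth.

    Gene-level intensity per sample = expr_means[gene] + noise, where the
    noise of a planted pair's members shares a common factor (weight
    sqrt(pair_corr)); the intensity is split over 1..n_isoforms_max
    isoforms and entries are removed at ``missing_rate``.  With zero noise
    and zero missingness, summing isoforms recovers expr_means.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(expr_means)
    pair_of = {}
    for pi, (a, b, *_) in enumerate(truth.planted_cop_pairs):
        pair_of[a] = pi
        pair_of[b] = pi
    factors = rng.standard_normal((len(truth.planted_cop_pairs), n_samples))
    rows = []
    for g in genes:
        k = int(rng.integers(1, n_isoforms_max + 1))
        fracs = rng.dirichlet(np.ones(k))
        if g in pair_of:
            e = (np.sqrt(pair_corr) * factors[pair_of[g]]
                 + np.sqrt(1 - pair_corr) * rng.standard_normal(n_samples))
        else:
            e = rng.standard_normal(n_samples)
        intensity = np.clip(expr_means[g] + noise_sd * e, 0, None)
        for iso in range(k):
            for s in range(n_samples):
                if rng.random() < missing_rate:
                    continue
                rows.append((f"{g}_iso{iso}", g, f"sample{s:03d}",
                             float(fracs[iso] * intensity[s])))
    return pd.DataFrame(rows, columns=["isoform", "gene", "sample", "intensity"])


def simulate_groseq(annot: GeneAnnotation, expr_means: dict, seed: int = 0,
                    width: int = 200, scale: float = 10.0,
                    decoy_rate: float = 0.3) -> IntervalSet:
    """Stranded TSS-covering signal track derived from expression means.

    Each gene gets an interval of ``width`` bp around its TSS on its own
    strand with value Poisson(scale * expr_means); decoy intervals on the
    opposite strand are added at ``decoy_rate`` and must not be picked up
    by strand-matched TSS lookup.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, chrom, tss, strand in zip(annot.df["gene_id"], annot.df["chrom"],
                                        annot.df["tss"], annot.df["strand"]):
        pos = int(tss) - 1
        start = max(pos - width // 2, 0)
        value = int(rng.poisson(scale * expr_means.get(gene, 1.0)))
        rows.append((chrom, start, start + width, float(value), strand))
        if rng.random() < decoy_rate:
            other = "-" if strand == "+" else "+"
            rows.append((chrom, start, start + width,
                         float(rng.poisson(scale)), other))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "strand"])
    return IntervalSet(df)
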