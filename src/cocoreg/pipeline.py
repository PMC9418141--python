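"""End-to-end orchestration: simulate -> preprocess -> COPs -> controls ->
enrichment -> enhancer linking -> sharing -> Hi-C support -> concordance.

The pipeline runs on synthetic data with planted ground truth and exercises
both processing branches: the continuous branch (overdispersed counts,
library-size + rank inverse-normal normalization, continuous COP calls,
proteomics and TSS-signal concordance) and the binary branch (paired binary
expression/accessibility, binary COP calls with a 0.2 correlation floor,
gene-enhancer linking, enhancer sharing, Hi-C support).

Every run writes stage TSVs, a summary JSON, and the resolved configuration
next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import pair_value_correlation, shuffle_pair_labels, tss_read_counts
from .cop_detection import CopParams, detect_cops
from .enhancer_linking import (assign_peaks, detect_associations, enhancer_activity,
                               merge_bookended, shared_enhancers)
from .enrichment import PairLabeler, fisher_enrichment
from .genome_io import write_cell_matrix, write_gene_annotation, write_hic, write_intervals
from .hic_support import cop_hic_support, flag_supported
from .matched_controls import build_noncop_pool, sample_distance_matched
from .preprocess import FilterConfig, filter_genes, library_size_normalize, rank_inverse_normal_rows
from .concordance import gene_intensities
from .synthetic_data import (adjacent_planted_pairs, simulate_annotation,
                             simulate_expression, simulate_groseq, simulate_hic,
                             simulate_multiome, simulate_proteomics)

log = logging.getLogger("cocoreg")


@dataclass
class RunConfig:
    """Full parameterization of an end-to-end synthetic run."""

    seed: int = 1
    outdir: str = "cocoreg_run"
    # genome
    n_genes: int = 200
    n_chrom: int = 1
    spacing_bp: int = 150_000
    # continuous (smartseq-like) branch
    n_cells_sc: int = 500
    n_planted_pairs: int = 40
    planted_rho: float = 0.6
    mean_log: float = 1.0
    dispersion: float = 0.5
    dropout: float = 0.3
    # binary (shareseq-like) multiome branch
    n_cells_multiome: int = 1500
    n_links: int = 20
    n_shared: int = 30
    link_effect: float = 0.4
    shared_effect: float = 0.6
    baseline_on: float = 0.2
    gene_baseline: float = 0.3
    n_decoy_enhancers: int = 20
    n_decoy_peaks: int = 10
    # detection
    window_bp: int = 1_000_000
    n_perm: int = 1000
    fdr: float = 0.05
    min_rho_binary: float = 0.2
    max_rho: float = 0.99
    rho_min_assoc: float = 0.05
    tolerance_bp: int = 100
    # hic
    hic_resolution: int = 5000
    hic_decay_exp: float = 1.0
    hic_boost: float = 4.0
    hic_noise_sd: float = 0.3
    # concordance
    n_protein_samples: int = 30
    protein_noise_sd: float = 0.2
    protein_missing_rate: float = 0.1

    def validate(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.n_genes < 2 * (self.n_planted_pairs + self.n_shared) + self.n_links:
            raise ValueError("n_genes too small for the requested planted structures")

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f'{f.name} = "{v}"' if isinstance(v, str) else f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Raises on any stage failure; outputs of completed stages remain.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    (outdir / "config.toml").write_text(config.to_toml())
    (outdir / "VERSION").write_text(__version__ + "\n")
    rng = np.random.SeedSequence(config.seed)
    seeds = iter(rng.generate_state(20))
    summary: dict = {"version": __version__, "seed": config.seed}

    # ------------------------------------------------------------------ simulate
    log.info("simulating genome and datasets")
    annot = simulate_annotation(config.n_genes, config.n_chrom, config.spacing_bp,
                                seed=int(next(seeds)))
    write_gene_annotation(annot, outdir / "annotation.tsv")
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    genes = list(annot.gene_ids)

    planted = adjacent_planted_pairs(annot, config.n_planted_pairs)
    counts, truth_sc = simulate_expression(
        annot, config.n_cells_sc, planted, rho=config.planted_rho,
        mean_log=config.mean_log, dispersion=config.dispersion,
        dropout=config.dropout, seed=int(next(seeds)))
    write_cell_matrix(counts, outdir / "counts.mtx", outdir / "counts.rows.txt",
                      outdir / "counts.cols.txt")

    used = {g for p in planted for g in p}
    free = [g for g in genes if g not in used]
    link_genes = free[: config.n_links]
    shared_gene_pairs = [(free[config.n_links + 2 * i], free[config.n_links + 2 * i + 1])
                         for i in range(config.n_shared)]
    links = [(tss[g] + 30_000, g, config.link_effect) for g in link_genes]
    shared = [((tss[a] + tss[b]) // 2 + 10_000, a, b, config.shared_effect)
              for a, b in shared_gene_pairs]
    expr_b, peak_mat, peak_iv, state_iv, truth_mm = simulate_multiome(
        annot, config.n_cells_multiome, links, shared,
        baseline_on=config.baseline_on, gene_baseline=config.gene_baseline,
        n_decoy_enhancers=config.n_decoy_enhancers,
        n_decoy_peaks=config.n_decoy_peaks, seed=int(next(seeds)))
    write_intervals(peak_iv, outdir / "peaks.bed")
    write_intervals(state_iv, outdir / "states.bed")
    write_cell_matrix(expr_b, outdir / "expr_binary.mtx",
                      outdir / "expr_binary.rows.txt", outdir / "expr_binary.cols.txt")
    write_cell_matrix(peak_mat, outdir / "peaks.mtx",
                      outdir / "peaks.rows.txt", outdir / "peaks.cols.txt")

    hic = simulate_hic(annot, truth_mm.planted_links, resolution=config.hic_resolution,
                       decay_exp=config.hic_decay_exp, boost=config.hic_boost,
                       noise_sd=config.hic_noise_sd, seed=int(next(seeds)))
    write_hic(hic, outdir / "hic.txt")

    # ---------------------------------------------------------------- continuous
    log.info("continuous branch: preprocess + COP detection")
    cfg = FilterConfig(min_cells_expressed=0)
    normed = rank_inverse_normal_rows(library_size_normalize(counts))
    normed = filter_genes(normed, annot, cfg, raw_counts=counts)
    params_c = CopParams(window_bp=config.window_bp, n_perm=config.n_perm,
                         fdr=config.fdr, max_rho=config.max_rho,
                         seed=int(next(seeds)))
    cops_c = detect_cops(normed, annot, params_c, individual="sim1", experiment="exp1")
    cops_c.pairs.to_csv(outdir / "cops.tsv", sep="\t", index=False)
    cops_c.tests.to_csv(outdir / "cop_tests.tsv", sep="\t", index=False)
    summary["n_cops_continuous"] = len(cops_c)

    pool_c = build_noncop_pool(cops_c.tests, "continuous", config.fdr,
                               cops_c.pair_keys())
    matched_c = sample_distance_matched(cops_c, pool_c, config.tolerance_bp,
                                        seed=int(next(seeds)))
    matched_c.records.to_csv(outdir / "noncops.tsv", sep="\t", index=False)
    summary["n_noncops"] = len(matched_c)
    summary["n_unmatched_cops"] = len(matched_c.unmatched)

    log.info("enrichment of COPs in planted truth pairs")
    labeler = PairLabeler(reference_pairs={(a, b) for a, b in planted})
    background = cops_c.tests[["gene_a", "gene_b"]].drop_duplicates()
    enr = fisher_enrichment(cops_c.pairs, background, labeler, "greater")
    pd.DataFrame([dataclasses.asdict(enr)]).to_csv(outdir / "enrichment.tsv",
                                                   sep="\t", index=False)
    summary["enrichment_odds_ratio"] = enr.odds_ratio
    summary["enrichment_p"] = enr.p

    # -------------------------------------------------------------------- binary
    log.info("binary branch: COPs, enhancer linking, sharing")
    params_b = CopParams(window_bp=config.window_bp, n_perm=config.n_perm,
                         fdr=config.fdr, min_rho=config.min_rho_binary,
                         max_rho=config.max_rho, seed=int(next(seeds)))
    cops_b = detect_cops(expr_b, annot, params_b, individual="sim1",
                         experiment="multiome")
    cops_b.pairs.to_csv(outdir / "cops_binary.tsv", sep="\t", index=False)
    summary["n_cops_binary"] = len(cops_b)

    pool_b = build_noncop_pool(cops_b.tests, "binary", config.fdr, cops_b.pair_keys())
    matched_b = sample_distance_matched(cops_b, pool_b, config.tolerance_bp,
                                        seed=int(next(seeds)))

    regions = merge_bookended(state_iv)
    assignment = assign_peaks(peak_iv, regions)
    activity = enhancer_activity(peak_mat, assignment)
    params_l = CopParams(window_bp=config.window_bp, n_perm=config.n_perm,
                         fdr=config.fdr, seed=int(next(seeds)))
    assoc = detect_associations(expr_b, activity, annot, regions, params_l,
                                rho_min=config.rho_min_assoc)
    assoc.to_csv(outdir / "links.tsv", sep="\t", index=False)
    summary["n_associations"] = int(assoc["significant"].sum())
    summary["n_association_tests"] = len(assoc)

    shared_cops = shared_enhancers(cops_b.pairs, assoc)
    shared_cops.to_csv(outdir / "shared_cops.tsv", sep="\t", index=False)
    shared_ctrl = shared_enhancers(matched_b.control_pairs(), assoc)
    shared_ctrl.to_csv(outdir / "shared_noncops.tsv", sep="\t", index=False)
    frac = lambda df: float((df["n_shared"] >= 1).mean()) if len(df) else 0.0
    summary["pct_cops_sharing_enhancer"] = 100 * frac(shared_cops)
    summary["pct_noncops_sharing_enhancer"] = 100 * frac(shared_ctrl)

    # --------------------------------------------------------------- hic support
    log.info("Hi-C support")
    # the support threshold is the 75th percentile over ALL tested pairs
    flagged, threshold, rho_contact = flag_supported(assoc, hic)
    flagged.to_csv(outdir / "hic_support.tsv", sep="\t", index=False)
    summary["hic_threshold"] = threshold
    summary["hic_rho_vs_association"] = rho_contact
    sig_flagged = flagged[flagged["significant"]]
    summary["pct_associations_hic_supported"] = (
        100 * float(sig_flagged["supported"].mean()) if len(sig_flagged) else 0.0)
    cop_support = cop_hic_support(shared_cops, assoc, hic, threshold)
    cop_support.to_csv(outdir / "cop_hic_support.tsv", sep="\t", index=False)
    summary["pct_cops_hic_supported"] = (
        100 * float(cop_support["hic_supported"].mean()) if len(cop_support) else 0.0)

    # --------------------------------------------------------------- concordance
    log.info("concordance: TSS signal and proteomics")
    track = simulate_groseq(annot, truth_sc.expr_means, seed=int(next(seeds)))
    write_intervals(track, outdir / "groseq.bedgraph")
    reads = tss_read_counts(track, annot)
    res_cop = pair_value_correlation(cops_c.pairs, reads)
    res_ctrl = pair_value_correlation(matched_c.control_pairs(), reads)
    summary["groseq_rho_cops"] = res_cop.rho
    summary["groseq_rho_noncops"] = res_ctrl.rho

    iso = simulate_proteomics(truth_sc, truth_sc.expr_means, config.n_protein_samples,
                              noise_sd=config.protein_noise_sd,
                              missing_rate=config.protein_missing_rate,
                              seed=int(next(seeds)))
    iso.to_csv(outdir / "proteomics_isoforms.tsv", sep="\t", index=False)
    intensities = gene_intensities(iso)

    def mean_pair_rho(pairs_df):
        rhos = []
        for col in intensities.columns:
            res = pair_value_correlation(pairs_df, intensities[col].to_dict())
            if res.rho is not None:
                rhos.append(res.rho)
        return float(np.mean(rhos)) if rhos else None

    summary["proteomics_mean_rho_cops"] = mean_pair_rho(cops_c.pairs)
    summary["proteomics_mean_rho_noncops"] = mean_pair_rho(matched_c.control_pairs())
    if len(cops_c.pairs) >= 2:
        shuffled = shuffle_pair_labels(cops_c.pairs, seed=int(next(seeds)))
        summary["proteomics_mean_rho_shuffled"] = mean_pair_rho(shuffled)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("pipeline complete: %s", outdir)
    return outdir
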