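import numpy as np
import pandas as pd
import pytest

from cocoreg import (
    adjacent_planted_pairs,
    enumerate_cis_pairs,
    gene_intensities,
    lookup_contact,
    mirror_control,
    simulate_annotation,
    simulate_expression,
    simulate_groseq,
    simulate_hic,
    simulate_multiome,
    simulate_proteomics,
    tss_read_counts,
)
from cocoreg.preprocess import library_size_normalize, rank_inverse_normal_rows


# ---------------------------------------------------------------- annotation

def test_annotation_spacing_gives_expected_cis_partners():
    annot = simulate_annotation(41, spacing_bp=100_000, jitter_bp=0, seed=0)
    pairs = enumerate_cis_pairs(annot, 1_000_000)
    central = "g0020"
    n_partners = ((pairs["gene_a"] == central) | (pairs["gene_b"] == central)).sum()
    assert n_partners == 20  # 10 per side at 100 kb spacing within 1 Mb


def test_annotation_multiple_chromosomes_isolate_cis():
    annot = simulate_annotation(20, n_chrom=2, spacing_bp=100_000, seed=0)
    pairs = enumerate_cis_pairs(annot, 1_000_000)
    chrom_of = dict(zip(annot.df["gene_id"], annot.df["chrom"]))
    assert all(chrom_of[a] == chrom_of[b]
               for a, b in zip(pairs["gene_a"], pairs["gene_b"]))
    assert set(annot.df["chrom"]) == {"chr1", "chr2"}


def test_annotation_deterministic():
    a = simulate_annotation(15, jitter_bp=5000, seed=9)
    b = simulate_annotation(15, jitter_bp=5000, seed=9)
    pd.testing.assert_frame_equal(a.df, b.df)


# ---------------------------------------------------------------- expression

def test_planted_rho_recovered_on_rank_scale():
    """With few ties (no dropout, high mean) the count-scale rank correlation
    approaches the Gaussian-copula value for latent rho 0.8."""
    annot = simulate_annotation(6, spacing_bp=100_000, seed=0)
    from scipy.stats import spearmanr

    counts, truth = simulate_expression(annot, 1000, [("g0000", "g0001")],
                                        rho=0.8, mean_log=3.0, dropout=0.0,
                                        dispersion=0.2, seed=1)
    X = counts.to_dense()
    idx = {g: i for i, g in enumerate(counts.row_ids)}
    r = spearmanr(X[idx["g0000"]], X[idx["g0001"]]).statistic
    assert r == pytest.approx(0.8, abs=0.1)


def test_null_simulation_has_no_strong_pairs():
    annot = simulate_annotation(40, spacing_bp=100_000, seed=1)
    counts, _ = simulate_expression(annot, 500, [], seed=2)
    X = rank_inverse_normal_rows(library_size_normalize(counts)).to_dense()
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 0.0)
    assert np.nanmax(np.abs(corr)) < 0.2


def test_dropout_one_gives_all_zero():
    annot = simulate_annotation(4, seed=0)
    counts, _ = simulate_expression(annot, 50, [], dropout=1.0, seed=3)
    assert counts.to_dense().sum() == 0


def test_gene_reuse_across_planted_pairs_rejected():
    annot = simulate_annotation(6, seed=0)
    with pytest.raises(ValueError, match="reused"):
        simulate_expression(annot, 50, [("g0000", "g0001"), ("g0001", "g0002")])


def test_expression_deterministic_and_pair_means_shared():
    annot = simulate_annotation(8, seed=0)
    planted = adjacent_planted_pairs(annot, 2)
    c1, t1 = simulate_expression(annot, 100, planted, seed=5)
    c2, t2 = simulate_expression(annot, 100, planted, seed=5)
    np.testing.assert_array_equal(c1.to_dense(), c2.to_dense())
    for a, b in planted:
        assert t1.expr_means[a] == t1.expr_means[b]


# ------------------------------------------------------------------ multiome

def test_shared_enhancer_induces_coexpression():
    annot = simulate_annotation(6, spacing_bp=150_000, seed=0)
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    shared = [((tss["g0002"] + tss["g0003"]) // 2, "g0002", "g0003", 0.4)]
    expr, *_ = simulate_multiome(annot, 5000, [], shared, seed=4)
    X = expr.to_dense()
    idx = {g: i for i, g in enumerate(expr.row_ids)}
    phi = np.corrcoef(X[idx["g0002"]], X[idx["g0003"]])[0, 1]
    assert phi > 0.05


def test_zero_effect_leaves_expression_independent():
    annot = simulate_annotation(4, spacing_bp=150_000, seed=0)
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    links = [(tss["g0001"] + 20_000, "g0001", 0.0)]
    expr, peaks, *_ = simulate_multiome(annot, 5000, links, seed=5)
    g = expr.to_dense()[1]
    e = peaks.to_dense()[0]
    assert abs(np.corrcoef(g, e)[0, 1]) < 0.05


def test_decoy_peaks_overlap_no_state():
    from cocoreg import assign_peaks, merge_bookended

    annot = simulate_annotation(6, spacing_bp=150_000, seed=0)
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    links = [(tss["g0001"] + 20_000, "g0001", 0.4)]
    _, _, peak_iv, state_iv, _ = simulate_multiome(
        annot, 100, links, n_decoy_peaks=5, seed=6)
    regions = merge_bookended(state_iv)
    assignment = assign_peaks(peak_iv, regions)
    decoys = [p for p in peak_iv.df["id"] if p.startswith("peak_d")]
    assert decoys and all(d not in assignment for d in decoys)


# ----------------------------------------------------------------------- hic

def test_hic_contacts_decay_with_distance():
    annot = simulate_annotation(5, spacing_bp=100_000, seed=0)
    hic = simulate_hic(annot, [], noise_sd=0.0, seed=7)
    by_sep: dict = {}
    for (chrom, i, j), v in hic.contacts.items():
        by_sep.setdefault(j - i, []).append(v)
    means = [np.mean(by_sep[s]) for s in sorted(by_sep)]
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_hic_boosted_links_beat_mirrored_controls():
    annot = simulate_annotation(8, spacing_bp=150_000, seed=0)
    tss = dict(zip(annot.df["gene_id"], annot.df["tss"]))
    links = [(tss[g] + 40_000, g, 0.4) for g in annot.gene_ids[:4]]
    wins = 0
    for rep in range(10):
        hic = simulate_hic(annot, links, boost=4.0, seed=100 + rep)
        for mid, g, _ in links:
            true_c = lookup_contact(hic, "chr1", tss[g], mid)
            ctrl_c = lookup_contact(hic, "chr1", tss[g], mirror_control(tss[g], mid))
            wins += true_c > ctrl_c
    assert wins / (10 * len(links)) >= 0.8


def test_hic_symmetric_storage():
    annot = simulate_annotation(3, seed=0)
    hic = simulate_hic(annot, [], seed=1)
    for (chrom, i, j) in list(hic.contacts)[:20]:
        assert hic.get(chrom, j, i) == hic.get(chrom, i, j)


# ----------------------------------------------------------- proteomics etc.

def test_proteomics_noiseless_roundtrip():
    annot = simulate_annotation(6, seed=0)
    counts, truth = simulate_expression(annot, 50, [("g0000", "g0001")], seed=1)
    iso = simulate_proteomics(truth, truth.expr_means, n_samples=4,
                              noise_sd=0.0, missing_rate=0.0, seed=2)
    intensities = gene_intensities(iso)
    for g, mean in truth.expr_means.items():
        np.testing.assert_allclose(intensities.loc[g], mean, rtol=1e-9)


def test_proteomics_full_missingness_empty():
    annot = simulate_annotation(3, seed=0)
    counts, truth = simulate_expression(annot, 20, [], seed=1)
    iso = simulate_proteomics(truth, truth.expr_means, 3, missing_rate=1.0, seed=2)
    assert iso.empty


def test_groseq_strand_decoys_invisible():
    annot = simulate_annotation(30, seed=0)
    counts, truth = simulate_expression(annot, 20, [], seed=1)
    track = simulate_groseq(annot, truth.expr_means, seed=3, decoy_rate=1.0)
    # every gene has a decoy on the opposite strand; lookup must match strand
    reads = tss_read_counts(track, annot)
    flipped = annot.df.copy()
    flipped["strand"] = flipped["strand"].map({"+": "-", "-": "+"})
    from cocoreg.genome_io import GeneAnnotation

    reads_flipped = tss_read_counts(track, GeneAnnotation(flipped))
    # same positions, opposite strand: values come from the decoy track
    assert set(reads) == set(annot.gene_ids)
    assert any(reads[g] != reads_flipped.get(g) for g in reads)
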