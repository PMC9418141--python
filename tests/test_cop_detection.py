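import numpy as np
import pandas as pd
import pytest

from cocoreg import (
    CopParams,
    CopSet,
    adjacent_planted_pairs,
    bh_fdr,
    correlate,
    detect_cops,
    drop_outlier_experiments,
    empirical_p,
    enumerate_cis_pairs,
    filter_crossmap,
    library_size_normalize,
    make_cell_matrix,
    null_max_correlations,
    rank_inverse_normal_rows,
    simulate_annotation,
    simulate_expression,
    union_cops,
)
from cocoreg.genome_io import GeneAnnotation


# ----------------------------------------------------------------- cis pairs

def _annot_at(tss_list, chroms=None):
    n = len(tss_list)
    chroms = chroms or ["chr1"] * n
    return GeneAnnotation(pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": chroms,
        "tss": tss_list,
        "strand": ["+"] * n,
        "biotype": ["protein_coding"] * n,
    }))


def test_cis_pairs_distance_cutoff():
    annot = _annot_at([1, 500_001, 1_200_001])
    pairs = enumerate_cis_pairs(annot, 1_000_000)
    keys = set(zip(pairs["gene_a"], pairs["gene_b"]))
    assert keys == {("g0", "g1"), ("g1", "g2")}  # g0-g2 spans 1.2 Mb


def test_cis_pairs_exact_window_inclusive():
    annot = _annot_at([1, 1_000_001])
    pairs = enumerate_cis_pairs(annot, 1_000_000)
    assert len(pairs) == 1
    assert pairs["tss_distance"].iloc[0] == 1_000_000


def test_cis_pairs_never_cross_chromosomes():
    annot = _annot_at([100, 200], chroms=["chr1", "chr2"])
    assert enumerate_cis_pairs(annot, 1_000_000).empty


# --------------------------------------------------------------- correlation

@pytest.mark.parametrize("x, y, expected", [
    ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
    ([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], 9 / np.sqrt(84)),
    ([0.0, 1.0], [1.0, 0.0], -1.0),
])
def test_pearson_closed_form(x, y, expected):
    assert correlate(np.array(x), np.array(y)) == pytest.approx(expected)


def test_correlate_zero_variance_is_nan():
    assert np.isnan(correlate(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])))


# ------------------------------------------------------------------ null max

@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(3, 40))
    return make_cell_matrix(["f", "p1", "p2"], [f"c{i}" for i in range(40)],
                            X, "normalized")


def test_null_entries_bounded(small_matrix):
    null = null_max_correlations(small_matrix, "f", ["p1", "p2"], 200, seed=1)
    assert null.shape == (200,)
    assert np.all(null >= -1) and np.all(null <= 1)


def test_null_max_monotone_in_partners(small_matrix):
    """With identical shuffles, adding a partner can only raise the maximum."""
    one = null_max_correlations(small_matrix, "f", ["p1"], 100, seed=9)
    two = null_max_correlations(small_matrix, "f", ["p1", "p2"], 100, seed=9)
    assert np.all(two >= one - 1e-12)


def test_null_reproducible_under_seed(small_matrix):
    a = null_max_correlations(small_matrix, "f", ["p1", "p2"], 50, seed=3)
    b = null_max_correlations(small_matrix, "f", ["p1", "p2"], 50, seed=3)
    np.testing.assert_array_equal(a, b)


# --------------------------------------------------------------- empirical p

@pytest.mark.parametrize("observed, null, expected", [
    (0.9, np.full(1000, 0.1), 1 / 1001),
    (0.25, np.array([0.1, 0.2, 0.3, 0.4]), 0.6),
    (-0.5, np.array([0.0, 0.1, 0.2]), 1.0),
])
def test_empirical_p_exceedance(observed, null, expected):
    assert empirical_p(observed, null) == pytest.approx(expected)


# ------------------------------------------------------------------------ BH

def test_bh_stepup_hand_example():
    np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_single_test_identity():
    np.testing.assert_allclose(bh_fdr(np.array([0.5])), [0.5])


def test_bh_is_index_preserving_under_permutation():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.001, 1, 50)
    q = bh_fdr(p)
    perm = rng.permutation(50)
    np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(1e-6, 1, 200)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)


# --------------------------------------------------------------- detect_cops

def _preprocessed(annot, n_cells, planted, rho, seed, **kw):
    counts, truth = simulate_expression(annot, n_cells, planted, rho=rho,
                                        seed=seed, **kw)
    return rank_inverse_normal_rows(library_size_normalize(counts)), truth


def test_detect_recovers_strong_planted_pair():
    annot = simulate_annotation(8, spacing_bp=100_000, seed=0)
    planted = [("g0000", "g0001")]
    # a well-expressed pair: high latent correlation survives counting noise;
    # with so few genes library-size scaling is meaningless, so rank-INT directly
    counts, truth = simulate_expression(annot, 500, planted, rho=0.9, seed=2,
                                        mean_log=2.0, dispersion=0.3, dropout=0.1)
    mat = rank_inverse_normal_rows(counts)
    cops = detect_cops(mat, annot, CopParams(seed=4))
    assert truth.cop_pair_keys() <= cops.pair_keys()


def test_detect_excludes_near_perfect_duplicates():
    """A duplicated gene row (rho = 1) is removed by the correlation ceiling."""
    annot = simulate_annotation(6, spacing_bp=100_000, seed=0)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 200))
    X[1] = X[0]  # duplicate row: rho exactly 1
    mat = make_cell_matrix(annot.gene_ids, [f"c{i}" for i in range(200)], X,
                           "normalized")
    cops = detect_cops(mat, annot, CopParams(seed=1))
    assert ("g0000", "g0001") not in cops.pair_keys()
    row = cops.tests[(cops.tests["gene_a"] == "g0000")
                     & (cops.tests["gene_b"] == "g0001")]
    assert (row["rho"] > 0.99).all()


def test_detect_null_matrix_yields_no_calls():
    annot = simulate_annotation(20, spacing_bp=100_000, seed=1)
    mat, _ = _preprocessed(annot, 300, [], rho=0.0, seed=3)
    cops = detect_cops(mat, annot, CopParams(seed=5))
    assert len(cops) == 0


def test_detect_bit_reproducible():
    annot = simulate_annotation(10, spacing_bp=100_000, seed=2)
    mat, _ = _preprocessed(annot, 100, [("g0000", "g0001")], rho=0.8, seed=4)
    a = detect_cops(mat, annot, CopParams(n_perm=200, seed=7))
    b = detect_cops(mat, annot, CopParams(n_perm=200, seed=7))
    pd.testing.assert_frame_equal(a.tests, b.tests)
    pd.testing.assert_frame_equal(a.pairs, b.pairs)


def test_rho_symmetric_across_focal_directions():
    annot = simulate_annotation(8, spacing_bp=200_000, seed=3)
    mat, _ = _preprocessed(annot, 80, [], rho=0.0, seed=6)
    tests = detect_cops(mat, annot, CopParams(n_perm=100, seed=8)).tests
    both = tests.groupby(["gene_a", "gene_b"])["rho"].agg(["min", "max", "count"])
    two_sided = both[both["count"] == 2]
    assert len(two_sided) > 0
    np.testing.assert_allclose(two_sided["min"], two_sided["max"], atol=1e-12)


def test_binary_min_rho_floor_applied():
    """In binary mode a significant pair below the 0.2 floor is not a COP."""
    annot = simulate_annotation(8, spacing_bp=100_000, seed=4)
    rng = np.random.default_rng(10)
    # weak but significant dependence: phi around 0.12
    e = rng.random(4000) < 0.2
    X = (rng.random((8, 4000)) < 0.3).astype(np.int8)
    X[0] = (rng.random(4000) < np.where(e, 0.55, 0.25)).astype(np.int8)
    X[1] = (rng.random(4000) < np.where(e, 0.55, 0.25)).astype(np.int8)
    mat = make_cell_matrix(annot.gene_ids, [f"c{i}" for i in range(4000)], X, "binary")
    with_floor = detect_cops(mat, annot, CopParams(min_rho=0.2, seed=1))
    without = detect_cops(mat, annot, CopParams(seed=1))
    assert ("g0000", "g0001") in without.pair_keys()
    assert ("g0000", "g0001") not in with_floor.pair_keys()


# -------------------------------------------------------------- crossmap

def test_crossmap_threshold_and_missing():
    pairs = pd.DataFrame({"gene_a": ["a", "c", "e"], "gene_b": ["b", "d", "f"]})
    scores = pd.DataFrame({"gene_a": ["b", "d"], "gene_b": ["a", "c"],
                           "score": [11.0, 10.0]})  # reversed order: symmetric lookup
    out = filter_crossmap(pairs, scores, 10.0)
    keys = set(zip(out["gene_a"], out["gene_b"]))
    assert keys == {("c", "d"), ("e", "f")}  # 11 removed, 10 kept, missing kept


# ----------------------------------------------------------------- outliers

def test_outlier_rule_drops_extreme_ratio():
    stats = [(f"e{i}", 10, 100) for i in range(4)] + [("e4", 500, 100)]
    assert drop_outlier_experiments(stats) == ["e0", "e1", "e2", "e3"]


def test_outlier_rule_equal_ratios_keep_all():
    stats = [(f"e{i}", 10, 100) for i in range(5)]
    assert drop_outlier_experiments(stats) == [f"e{i}" for i in range(5)]


def test_outlier_rule_few_experiments_guard():
    with pytest.warns(UserWarning, match="fewer than 4"):
        assert drop_outlier_experiments([("only", 99, 10)]) == ["only"]


# -------------------------------------------------------------------- union

def _copset(pairs, individual="i1", experiment="e1", qs=None):
    qs = qs or [0.01] * len(pairs)
    df = pd.DataFrame({
        "gene_a": [p[0] for p in pairs], "gene_b": [p[1] for p in pairs],
        "chrom": "chr1", "tss_distance": 1000,
        "rho": 0.5, "p_emp": [q / 2 for q in qs], "q": qs,
    })
    return CopSet(df, individual, experiment, 100)


def test_union_is_set_union_with_best_stats():
    s1 = _copset([("A", "B")], experiment="e1", qs=[0.04])
    s2 = _copset([("A", "B"), ("C", "D")], experiment="e2", qs=[0.01, 0.02])
    u = union_cops([s1, s2])
    assert u.pair_keys() == {("A", "B"), ("C", "D")}
    ab = u.pairs[(u.pairs["gene_a"] == "A")]
    assert ab["q"].iloc[0] == 0.01  # most significant retained
    assert ab["experiments"].iloc[0] == "e1,e2"


def test_union_empty_input():
    assert len(union_cops([])) == 0


def test_union_rejects_mixed_individuals():
    with pytest.raises(ValueError, match="individual"):
        union_cops([_copset([("A", "B")], individual="i1"),
                    _copset([("C", "D")], individual="i2")])
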