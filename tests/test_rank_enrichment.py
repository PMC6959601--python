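"""Enrichment scores, permutation nulls, gene-set construction, patient rankings."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cistromeshift.intervals import GenomeLayout, GenomicInterval, PeakSet, TssTable
from cistromeshift.rank_enrichment import (
    GeneSet,
    RankedList,
    UnstableNullWarning,
    adjust_batch,
    chip_gene_set,
    de_ranked_list,
    enrichment_score,
    paired_ranking,
    permutation_test,
    read_gmt,
    write_gmt,
)
from oracles import running_sum_es


def ranked_from(pairs):
    return RankedList.from_scores(dict(pairs))


FOUR = ranked_from([("g1", 2.0), ("g2", 1.0), ("g3", -1.0), ("g4", -2.0)])


def test_es_hand_examples():
    """Top pair {g1,g2} reaches +1; the bottom gene alone reaches -1."""
    es, curve = enrichment_score(FOUR, GeneSet("top", {"g1", "g2"}))
    assert es == pytest.approx(1.0, abs=1e-12)
    assert curve.tolist() == pytest.approx([2 / 3, 1.0, 0.5, 0.0], abs=1e-12)
    es_bottom, _ = enrichment_score(FOUR, GeneSet("bottom", {"g4"}))
    assert es_bottom == pytest.approx(-1.0, abs=1e-12)


def test_es_degenerate_sets_rejected():
    with pytest.raises(ValueError, match="no genes"):
        enrichment_score(FOUR, GeneSet("x", {"zz"}))
    with pytest.raises(ValueError, match="entire"):
        enrichment_score(FOUR, GeneSet("x", {"g1", "g2", "g3", "g4"}))


def test_reversing_a_symmetric_list_negates_es():
    gene_set = GeneSet("s", {"g1", "g3"})
    es, _ = enrichment_score(FOUR, gene_set)
    es_rev, _ = enrichment_score(FOUR.reversed(), gene_set)
    assert es_rev == pytest.approx(-es, abs=1e-12)


def test_es_matches_running_sum_oracle():
    rng = np.random.default_rng(23)
    for _ in range(400):
        n = int(rng.integers(4, 60))
        genes = [f"g{i:03d}" for i in range(n)]
        scores = np.round(rng.normal(0, 2, n), 3)
        ranked = RankedList.from_scores(dict(zip(genes, scores)))
        k = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=k, replace=False))
        weight = float(rng.choice([0.0, 1.0, 1.5]))
        es, _ = enrichment_score(ranked, GeneSet("s", members), weight=weight)
        oracle = running_sum_es(ranked.genes, ranked.scores, members, weight)
        assert es == pytest.approx(oracle, abs=1e-12)


def test_ranked_list_rejects_duplicates_and_bad_order():
    with pytest.raises(ValueError, match="unique"):
        RankedList(("a", "a"), np.array([2.0, 1.0]))
    with pytest.raises(ValueError, match="descending"):
        RankedList(("a", "b"), np.array([1.0, 2.0]))


# -- permutation test --------------------------------------------------------

def exact_singleton_p(ranked, member):
    """Exhaustive null over all singleton sets (independent enumeration)."""
    es_obs, _ = enrichment_score(ranked, GeneSet("s", {member}))
    nulls = [
        enrichment_score(ranked, GeneSet("n", {g}))[0] for g in ranked.genes
    ]
    same = [e for e in nulls if (e >= 0) == (es_obs >= 0)]
    extreme = sum(abs(e) >= abs(es_obs) for e in same)
    return (1 + extreme) / (1 + len(same))


def test_exhaustive_null_matches_exact_enumeration_n4():
    for member in FOUR.genes:
        res = permutation_test(FOUR, GeneSet("s", {member}), n_perm=100, seed=1)
        assert res.n_perm == 4  # C(4,1) fully enumerated
        assert res.p_perm == pytest.approx(exact_singleton_p(FOUR, member))


def test_exhaustive_null_matches_combinatorial_enumeration_small_n():
    rng = np.random.default_rng(31)
    genes = [f"g{i}" for i in range(9)]
    ranked = RankedList.from_scores(dict(zip(genes, rng.normal(0, 1, 9))))
    for k in (1, 2, 3):
        members = set(rng.choice(genes, size=k, replace=False))
        res = permutation_test(ranked, GeneSet("s", members), n_perm=1000, seed=2)
        assert res.n_perm == math.comb(9, k)
        es_obs, _ = enrichment_score(ranked, GeneSet("s", members))
        nulls = [
            enrichment_score(ranked, GeneSet("n", set(c)))[0]
            for c in itertools.combinations(genes, k)
        ]
        same = [e for e in nulls if (e >= 0) == (es_obs >= 0)]
        extreme = sum(abs(e) >= abs(es_obs) for e in same)
        assert res.p_perm == pytest.approx((1 + extreme) / (1 + len(same)), abs=1e-12)


def test_same_seed_reproduces_identical_result():
    rng = np.random.default_rng(5)
    genes = [f"g{i:03d}" for i in range(300)]
    ranked = RankedList.from_scores(dict(zip(genes, rng.normal(0, 1, 300))))
    gene_set = GeneSet("s", set(genes[:20]))
    a = permutation_test(ranked, gene_set, n_perm=2000, seed=9)
    b = permutation_test(ranked, gene_set, n_perm=2000, seed=9)
    assert (a.es, a.nes, a.p_perm) == (b.es, b.nes, b.p_perm)
    assert a.leading_edge == b.leading_edge


def test_sign_consistency_and_leading_edge_membership():
    rng = np.random.default_rng(7)
    genes = [f"g{i:03d}" for i in range(200)]
    ranked = RankedList.from_scores(dict(zip(genes, rng.normal(0, 1, 200))))
    top = GeneSet("top", set(ranked.genes[:15]))
    res = permutation_test(ranked, top, n_perm=1000, seed=0)
    assert res.es > 0 and np.sign(res.nes) == np.sign(res.es)
    assert 0 < res.p_perm <= 1
    assert set(res.leading_edge) <= top.members
    assert len(res.leading_edge) > 0


def test_tiny_null_space_warns_unstable():
    genes = ["a", "b", "c", "d", "e"]
    ranked = RankedList.from_scores(dict(zip(genes, [3.0, 2.0, 1.0, -1.0, -2.0])))
    with pytest.warns(UnstableNullWarning):
        res = permutation_test(ranked, GeneSet("s", {"a"}), n_perm=100, seed=0)
    assert res.unstable_null


def test_adjust_batch_is_bh_over_batch():
    rng = np.random.default_rng(11)
    genes = [f"g{i:03d}" for i in range(100)]
    ranked = RankedList.from_scores(dict(zip(genes, rng.normal(0, 1, 100))))
    results = [
        permutation_test(ranked, GeneSet(f"s{j}", set(rng.choice(genes, 8, replace=False))),
                         n_perm=500, seed=j)
        for j in range(4)
    ]
    adjusted = adjust_batch(results)
    from cistromeshift.differential import bh_adjust

    assert [r.padj for r in adjusted] == pytest.approx(
        bh_adjust([r.p_perm for r in results]).tolist()
    )


# -- ChIP gene sets ----------------------------------------------------------

def _tss(rows):
    return TssTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "position", "strand"]))


def test_chip_gene_set_distance_rule():
    layout = GenomeLayout({"chr1": 1_000_000})
    tss = _tss([("gNear", "chr1", 10_000, "+"), ("gFar", "chr1", 500_000, "+")])
    peaks = PeakSet(
        "p", [GenomicInterval("chr1", 10_400, 10_601, name="x")], layout
    )  # summit 10500: 500 bp from gNear
    assert chip_gene_set(peaks, tss, 10_000).members == {"gNear"}
    far_peaks = PeakSet("p", [GenomicInterval("chr1", 520_000, 520_200)], layout)
    assert chip_gene_set(far_peaks, tss, 10_000).members == set()
    assert chip_gene_set(PeakSet("e", []), tss, 10_000).members == set()


# -- ranked lists from DE tables --------------------------------------------

def test_de_ranked_list_scores_and_tie_break():
    de = pd.DataFrame(
        {
            "gene": ["g2", "g1", "g3"],
            "log2FC": [1.0, 2.0, -3.0],
            "p": [0.01, 0.01, 1e-6],
        }
    )
    ranked = de_ranked_list(de)
    # g1 and g2 tie at score 2; id ascending; g3 scores -6 at the bottom
    assert ranked.genes == ("g1", "g2", "g3")
    assert ranked.scores[2] == pytest.approx(-6.0)


def test_de_ranked_list_matches_sort_oracle():
    rng = np.random.default_rng(3)
    n = 300
    de = pd.DataFrame(
        {
            "gene": [f"g{i:03d}" for i in range(n)],
            "log2FC": rng.normal(0, 1, n),
            "p": rng.uniform(1e-8, 1, n),
        }
    )
    ranked = de_ranked_list(de)
    scores = dict(zip(de["gene"], np.sign(de["log2FC"]) * -np.log10(de["p"])))
    expected = [g for g, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]
    assert list(ranked.genes) == expected


def test_de_ranked_list_validation():
    with pytest.raises(ValueError, match="duplicate"):
        de_ranked_list(pd.DataFrame({"gene": ["a", "a"], "log2FC": [1, 2], "p": [0.1, 0.2]}))
    with pytest.raises(ValueError, match="0, 1"):
        de_ranked_list(pd.DataFrame({"gene": ["a"], "log2FC": [1.0], "p": [0.0]}))


# -- paired primary/metastasis ranking --------------------------------------

def _pairs_frame(n_pairs):
    rows = []
    for i in range(n_pairs):
        rows.append({"sample": f"X{i}_P", "pair_id": f"X{i}", "tissue": "primary"})
        rows.append({"sample": f"X{i}_M", "pair_id": f"X{i}", "tissue": "metastasis"})
    return pd.DataFrame(rows)


def test_paired_ranking_identical_counts_score_zero():
    rng = np.random.default_rng(2)
    base = rng.poisson(100, size=(50, 1))
    counts = pd.DataFrame(
        np.repeat(base, 6, axis=1),
        index=[f"g{i}" for i in range(50)],
        columns=[s for i in range(3) for s in (f"X{i}_P", f"X{i}_M")],
    )
    ranked = paired_ranking(counts, _pairs_frame(3), mode="replicates")
    assert np.allclose(ranked.scores, 0.0)


def test_paired_ranking_label_swap_negates_scores():
    rng = np.random.default_rng(4)
    counts = pd.DataFrame(
        rng.poisson(80, size=(100, 6)) + 1,
        index=[f"g{i:03d}" for i in range(100)],
        columns=[s for i in range(3) for s in (f"X{i}_P", f"X{i}_M")],
    )
    pairs = _pairs_frame(3)
    fwd = paired_ranking(counts, pairs, mode="replicates")
    swapped = pairs.copy()
    swapped["tissue"] = swapped["tissue"].map(
        {"primary": "metastasis", "metastasis": "primary"}
    )
    rev = paired_ranking(counts, swapped, mode="replicates")
    fwd_scores = dict(zip(fwd.genes, fwd.scores))
    rev_scores = dict(zip(rev.genes, rev.scores))
    for g in fwd.genes:
        assert rev_scores[g] == pytest.approx(-fwd_scores[g], abs=1e-9)


def test_paired_ranking_single_pair_mode_validation():
    rng = np.random.default_rng(6)
    counts = pd.DataFrame(
        rng.poisson(80, size=(20, 4)) + 1,
        index=[f"g{i}" for i in range(20)],
        columns=["X0_P", "X0_M", "X1_P", "X1_M"],
    )
    with pytest.raises(ValueError, match="target_pair"):
        paired_ranking(counts, _pairs_frame(2), mode="single_pair")
    ranked = paired_ranking(counts, _pairs_frame(2), mode="single_pair", target_pair="X1")
    assert len(ranked) == 20


def test_planted_signature_rises_to_top_and_enriches():
    """4-fold up signature genes in metastases occupy top ranks and give a
    strongly positive enrichment in replicates mode."""
    from cistromeshift.simulate import _nb1

    for seed in (0, 1):
        rng = np.random.default_rng(seed)
        n, n_pairs, k = 300, 5, 30
        genes = [f"g{i:03d}" for i in range(n)]
        sig = set(genes[:k])
        cols = {}
        base = 100 * np.exp(rng.normal(0, 0.4, n))
        for i in range(n_pairs):
            cols[f"X{i}_P"] = _nb1(rng, base, 0.1)
            met_mean = base * np.where(np.isin(genes, list(sig)), 4.0, 1.0)
            cols[f"X{i}_M"] = _nb1(rng, met_mean, 0.1)
        counts = pd.DataFrame(cols, index=genes)
        ranked = paired_ranking(counts, _pairs_frame(n_pairs), mode="replicates")
        top_k = set(ranked.genes[:k])
        assert len(top_k & sig) / k > 0.9
        res = permutation_test(ranked, GeneSet("sig", sig), n_perm=1000, seed=seed)
        assert res.nes > 0 and res.p_perm < 0.01


# -- GMT I/O -----------------------------------------------------------------

def test_gmt_roundtrip(tmp_path):
    sets = [GeneSet("a", {"g1", "g2"}), GeneSet("b", {"g3"})]
    path = tmp_path / "s.gmt"
    write_gmt(sets, path)
    back = read_gmt(path)
    assert {(s.name, s.members) for s in back} == {(s.name, s.members) for s in sets}
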