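"""Interval algebra, format round-trips, consensus calling, TSS annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cistromeshift.intervals import (
    BedParseError,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    TssTable,
    classify_region,
    consensus_peaks,
    merge_intervals,
    overlap_membership,
    read_bed,
    read_chrom_sizes,
    read_narrowpeak,
    tss_distance,
    tss_distances,
    write_bed,
    write_chrom_sizes,
)
from conftest import make_peaks
from oracles import consensus_by_base_counting, nearest_tss_exhaustive, overlap_all_pairs


# -- GenomicInterval / PeakSet invariants -----------------------------------

def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 200, summit=100)  # offset == width
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -5, 100)


def test_peakset_sorted_and_layout_checked(small_layout):
    ps = make_peaks("p", [("chr2", 10, 20), ("chr1", 50, 60), ("chr1", 5, 15)], small_layout)
    assert [(iv.chrom, iv.start) for iv in ps] == [("chr1", 5), ("chr1", 50), ("chr2", 10)]
    with pytest.raises(ValueError):
        make_peaks("q", [("chr1", 0, 200_000)], small_layout)
    with pytest.raises(ValueError):
        make_peaks("q", [("chrX", 0, 100)], small_layout)


def test_summit_pos_defaults_to_midpoint():
    assert GenomicInterval("chr1", 100, 201).summit_pos == 150
    assert GenomicInterval("chr1", 100, 200, summit=25).summit_pos == 125


# -- narrowPeak / BED I/O ----------------------------------------------------

def test_narrowpeak_summit_column(tmp_path):
    path = tmp_path / "a.narrowPeak"
    path.write_text(
        "chr1\t100\t200\tp1\t0\t.\t5\t4\t3\t25\n"
        "chr1\t300\t400\tp2\t0\t.\t5\t4\t3\t-1\n"
    )
    ps = read_narrowpeak(path)
    assert ps[0].summit == 25 and ps[0].summit_pos == 125
    assert ps[1].summit is None and ps[1].summit_pos == 350  # midpoint rule


def test_narrowpeak_parse_errors_carry_line_numbers(tmp_path):
    path = tmp_path / "bad.narrowPeak"
    path.write_text("chr1\t100\t200\tp\t0\t.\t1\t1\t1\t0\nchr1\t200\t100\tp\t0\t.\t1\t1\t1\t0\n")
    with pytest.raises(BedParseError, match=":2:"):
        read_narrowpeak(path)
    path.write_text("chr1\t100\n")
    with pytest.raises(BedParseError, match="columns"):
        read_narrowpeak(path)


def test_interval_outside_layout_rejected(tmp_path, small_layout):
    path = tmp_path / "a.narrowPeak"
    path.write_text("chr1\t99990\t100200\tp\t0\t.\t1\t1\t1\t-1\n")
    with pytest.raises(ValueError, match="past chromosome end"):
        read_narrowpeak(path, small_layout)


@st.composite
def peaksets(draw):
    n = draw(st.integers(0, 30))
    ivs = []
    for i in range(n):
        chrom = draw(st.sampled_from(["chr1", "chr2"]))
        start = draw(st.integers(0, 9_000))
        width = draw(st.integers(1, 500))
        ivs.append(GenomicInterval(chrom, start, start + width, name=f"p{i}"))
    return PeakSet("rand", ivs)


@settings(max_examples=100, deadline=None)
@given(peaksets())
def test_bed_roundtrip_is_identity(tmp_path_factory, ps):
    """write_bed then read_bed preserves coordinates and order bit-exactly."""
    path = tmp_path_factory.mktemp("rt") / "p.bed"
    write_bed(ps, path)
    back = read_bed(path)
    assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
        (iv.chrom, iv.start, iv.end) for iv in ps
    ]


def test_bed_roundtrip_empty_and_sort_order(tmp_path):
    path = tmp_path / "e.bed"
    write_bed(PeakSet("empty", []), path)
    assert path.read_text() == ""
    ps = make_peaks("p", [("chr2", 0, 10), ("chr1", 5, 15)])
    write_bed(ps, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("chr1\t") and lines[1].startswith("chr2\t")


def test_chrom_sizes_roundtrip(tmp_path, small_layout):
    path = tmp_path / "c.sizes"
    write_chrom_sizes(small_layout, path)
    assert read_chrom_sizes(path).lengths == dict(small_layout.lengths)


# -- merge ------------------------------------------------------------------

@pytest.mark.parametrize(
    "triples,gap,expected",
    [
        ([("chr1", 100, 200), ("chr1", 150, 250)], 0, [(100, 250)]),
        ([("chr1", 100, 200), ("chr1", 200, 300)], 0, [(100, 300)]),  # bookended
        ([("chr1", 100, 200), ("chr1", 210, 300)], 5, [(100, 200), (210, 300)]),
        ([("chr1", 100, 200), ("chr1", 210, 300)], 10, [(100, 300)]),
    ],
)
def test_merge_intervals(triples, gap, expected):
    merged = merge_intervals(make_peaks("m", triples), gap=gap)
    assert [(iv.start, iv.end) for iv in merged] == expected


@settings(max_examples=50, deadline=None)
@given(peaksets(), st.integers(0, 100))
def test_merge_is_idempotent(ps, gap):
    once = merge_intervals(ps, gap)
    twice = merge_intervals(once, gap)
    assert once == twice


# -- consensus ---------------------------------------------------------------

def test_consensus_partial_overlap_support_run(small_layout):
    reps = [
        make_peaks("r1", [("chr1", 100, 200)], small_layout),
        make_peaks("r2", [("chr1", 150, 250)], small_layout),
        make_peaks("r3", [("chr1", 180, 220)], small_layout),
        make_peaks("r4", [], small_layout),
    ]
    cons = consensus_peaks(reps, 3)
    assert [(iv.start, iv.end) for iv in cons] == [(180, 200)]
    assert cons[0].summit_pos == 190


def test_consensus_three_of_four_rule(small_layout):
    """A peak present in all 4 replicates survives; one in only 2 does not."""
    shared = ("chr1", 500, 700)
    pair_only = ("chr1", 2000, 2200)
    reps = [
        make_peaks("r1", [shared, pair_only], small_layout),
        make_peaks("r2", [shared, pair_only], small_layout),
        make_peaks("r3", [shared], small_layout),
        make_peaks("r4", [shared], small_layout),
    ]
    cons = consensus_peaks(reps, 3)
    assert [(iv.start, iv.end) for iv in cons] == [(500, 700)]


def test_consensus_min_support_bounds(small_layout):
    reps = [make_peaks("r", [("chr1", 0, 10)], small_layout)] * 2
    with pytest.raises(ValueError):
        consensus_peaks(reps, 3)
    with pytest.raises(ValueError):
        consensus_peaks(reps, 0)


def _random_replicates(rng, n_reps, chrom_lengths):
    reps = []
    for r in range(n_reps):
        ivs = []
        for _ in range(rng.integers(0, 15)):
            chrom = rng.choice(list(chrom_lengths))
            start = int(rng.integers(0, chrom_lengths[chrom] - 1))
            end = int(rng.integers(start + 1, min(start + 800, chrom_lengths[chrom]) + 1))
            ivs.append(GenomicInterval(chrom, start, end))
        reps.append(PeakSet(f"r{r}", ivs))
    return reps


def test_consensus_matches_per_base_oracle():
    """Sweep output equals an independent per-base support count, exactly."""
    rng = np.random.default_rng(42)
    chrom_lengths = {"chrA": 8_000, "chrB": 5_000}
    for _ in range(60):
        n_reps = int(rng.integers(1, 7))
        reps = _random_replicates(rng, n_reps, chrom_lengths)
        k = int(rng.integers(1, n_reps + 1))
        got = [(iv.chrom, iv.start, iv.end) for iv in consensus_peaks(reps, k)]
        assert got == consensus_by_base_counting(reps, k, chrom_lengths)


def test_consensus_replicate_order_invariant():
    rng = np.random.default_rng(7)
    reps = _random_replicates(rng, 4, {"chrA": 8_000})
    base = consensus_peaks(reps, 3)
    for _ in range(5):
        perm = list(rng.permutation(4))
        assert consensus_peaks([reps[i] for i in perm], 3) == base


# -- overlap membership ------------------------------------------------------

def test_overlap_membership_half_open_boundary():
    q = make_peaks("q", [("chr1", 100, 200)])
    touching = make_peaks("t1", [("chr1", 199, 300)])
    bookended = make_peaks("t2", [("chr1", 200, 300)])
    m = overlap_membership(q, [touching, bookended])
    assert m.tolist() == [[True, False]]


def test_overlap_membership_matches_all_pairs_scan():
    rng = np.random.default_rng(3)
    def random_set(n):
        ivs = []
        for _ in range(n):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 5000))
            ivs.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 400))))
        return PeakSet("x", ivs)

    for _ in range(10):
        q = random_set(50)
        tracks = [random_set(int(rng.integers(0, 30))) for _ in range(3)]
        assert np.array_equal(
            overlap_membership(q, tracks), overlap_all_pairs(q, tracks)
        )


# -- TSS distance and region classes ----------------------------------------

def _tss(rows):
    return TssTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "position", "strand"]))


def test_tss_distance_sign_convention():
    tss = _tss([("gA", "chr1", 1000, "+"), ("gB", "chr2", 1000, "-")])
    iv_plus = GenomicInterval("chr1", 1400, 1601)  # summit 1500
    iv_minus = GenomicInterval("chr2", 1400, 1601)
    assert tss_distance(iv_plus, tss) == ("gA", 500)
    assert tss_distance(iv_minus, tss) == ("gB", -500)


def test_tss_distance_tie_breaks_to_smallest_gene_id():
    tss = _tss([("gB", "chr1", 2000, "+"), ("gA", "chr1", 1000, "+")])
    iv = GenomicInterval("chr1", 1400, 1601)  # summit 1500: equidistant
    assert tss_distance(iv, tss)[0] == "gA"


def test_tss_distance_missing_chrom_raises():
    tss = _tss([("gA", "chr1", 1000, "+")])
    with pytest.raises(LookupError):
        tss_distance(GenomicInterval("chr9", 0, 100), tss)


def test_tss_distance_matches_exhaustive_search():
    rng = np.random.default_rng(11)
    rows = [
        (f"g{i:02d}", rng.choice(["chr1", "chr2"]), int(rng.integers(0, 50_000)), rng.choice(["+", "-"]))
        for i in range(20)
    ]
    tss = _tss(rows)
    table = tss.table
    peaks = []
    for _ in range(100):
        chrom = rng.choice(["chr1", "chr2"])
        s = int(rng.integers(0, 49_000))
        peaks.append(GenomicInterval(chrom, s, s + 201))
    got = tss_distances(PeakSet("q", peaks), tss)
    # PeakSet sorts; recompute expectation in sorted order
    for iv, res in zip(PeakSet("q", peaks), got):
        assert res == nearest_tss_exhaustive(iv.chrom, iv.summit_pos, table)


@pytest.mark.parametrize(
    "distance,label",
    [
        (800, "promoter_<=1kb"),
        (-800, "promoter_<=1kb"),
        (1000, "promoter_<=1kb"),
        (-1500, "promoter_1-2kb"),
        (-2500, "promoter_2-3kb"),
        (50_000, "distal"),
    ],
)
def test_classify_region_bins(distance, label):
    assert classify_region(distance) == label
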