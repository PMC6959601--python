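"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is deliberately naive: per-base counting, all-pairs scans,
pure-Python running sums, exhaustive hypergeometric enumeration. None of it
shares code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def consensus_by_base_counting(replicates, min_support, chrom_lengths):
    """Per-base support-depth sweep: returns [(chrom, start, end), ...]."""
    out = []
    for chrom in sorted(chrom_lengths):
        depth = np.zeros(chrom_lengths[chrom], dtype=int)
        for rep in replicates:
            covered = np.zeros(chrom_lengths[chrom], dtype=bool)
            for iv in rep:
                if iv.chrom == chrom:
                    covered[iv.start : iv.end] = True
            depth += covered
        above = depth >= min_support
        # extract maximal runs
        padded = np.concatenate([[False], above, [False]])
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(changes[::2], changes[1::2]):
            out.append((chrom, int(s), int(e)))
    return out


def overlap_all_pairs(query, tracks):
    """Naive O(n*m) membership scan."""
    out = np.zeros((len(query), len(tracks)), dtype=bool)
    for i, q in enumerate(query):
        for j, track in enumerate(tracks):
            out[i, j] = any(
                q.chrom == t.chrom and q.start < t.end and t.start < q.end
                for t in track
            )
    return out


def nearest_tss_exhaustive(summit_chrom, summit_pos, tss_table):
    """Exhaustive nearest search with smallest-gene-id tie-break."""
    best = None
    for row in tss_table.itertuples():
        if row.chrom != summit_chrom:
            continue
        d = abs(int(row.position) - summit_pos)
        key = (d, str(row.gene_id))
        if best is None or key < best[0]:
            signed = summit_pos - int(row.position)
            if row.strand == "-":
                signed = -signed
            best = (key, (str(row.gene_id), signed))
    if best is None:
        raise LookupError("no TSS on chromosome")
    return best[1]


def bh_step_up(pvals):
    """Independent Benjamini-Hochberg step-up (textbook formulation)."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


def fisher_two_sided_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by enumerating every table with the margins.

    Hypergeometric probabilities from integer binomials; the p-value sums the
    probabilities of all tables no more probable than the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    pmf = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom
        for k in range(k_min, k_max + 1)
    }
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def running_sum_es(genes, scores, members, weight=1.0):
    """Single-pass pure-Python enrichment score oracle."""
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    w = [abs(s) ** weight for s in scores]
    wsum = sum(wi for wi, h in zip(w, hits) if h)
    miss_step = 1.0 / (n - n_hit)
    total = 0.0
    best = 0.0
    for i in range(n):
        if hits[i]:
            total += (w[i] / wsum) if wsum > 0 else 1.0 / n_hit
        else:
            total -= miss_step
        if abs(total) > abs(best) or (abs(total) == abs(best) and total > best):
            best = total
    return best


def combination_tally(rows, factors):
    """Dictionary tally of exact membership patterns."""
    tally = {}
    for row in rows:
        combo = tuple(f for f, present in zip(factors, row) if present)
        tally[combo] = tally.get(combo, 0) + 1
    return tally
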