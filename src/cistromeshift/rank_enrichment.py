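"""Weighted Kolmogorov-Smirnov rank enrichment with permutation nulls.

The running sum over a ranked gene list increments by |score|^weight
(normalized over set members) at each set member and decrements by 1/(N-|S|)
at each non-member; the enrichment score (ES) is the extreme deviation, sign
kept. The null distribution comes from random gene sets of the same size drawn
without replacement; the p-value uses the add-one estimator over same-sign
permutations and NES divides ES by the mean |null ES| of the same sign. When
the number of distinct sets of size |S| is no larger than the permutation
budget, the null is enumerated exhaustively and the p-value is exact.

Gene sets can be built from ChIP peaks (any summit within a distance of a
gene's TSS) and ranked lists from differential-expression tables or from
paired primary/metastasis count tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import bh_adjust, size_factors
from .intervals import PeakSet, TssTable

__all__ = [
    "EnrichmentResult",
    "GeneSet",
    "RankedList",
    "UnstableNullWarning",
    "chip_gene_set",
    "de_ranked_list",
    "enrichment_score",
    "paired_ranking",
    "permutation_test",
    "read_gmt",
    "write_gmt",
]


class UnstableNullWarning(UserWarning):
    """Fewer than 10 same-sign permutations support the p-value."""


@dataclass(frozen=True)
class RankedList:
    """Gene ids ordered by descending score; equal scores order by gene id."""

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        order_ok = all(
            (scores[i] > scores[i + 1])
            or (scores[i] == scores[i + 1] and self.genes[i] < self.genes[i + 1])
            for i in range(len(scores) - 1)
        )
        if not order_ok:
            raise ValueError("scores must be descending with gene-id tie-break")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: dict[str, float] | pd.Series) -> "RankedList":
        items = sorted(dict(scores).items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(tuple(g for g, _ in items), np.array([s for _, s in items]))

    def reversed(self) -> "RankedList":
        return RankedList.from_scores({g: -s for g, s in zip(self.genes, self.scores)})

    def to_rnk(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g, s in zip(self.genes, self.scores):
                fh.write(f"{g}\t{s:.10g}\n")

    @classmethod
    def from_rnk(cls, path: str | Path) -> "RankedList":
        scores = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                g, s = line.rstrip("\n").split("\t")
                scores[g] = float(s)
        return cls.from_scores(scores)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    """ES/NES with permutation p, optional batch-adjusted p, and edge genes."""

    set_name: str
    es: float
    nes: float
    p_perm: float
    padj: float | None
    leading_edge: tuple[str, ...]
    trailing_edge: tuple[str, ...]
    n_perm: int
    n_same_sign: int
    unstable_null: bool = False


def _hit_deltas(ranked: RankedList, members: frozenset[str], weight: float):
    hit = np.array([g in members for g in ranked.genes])
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError(f"gene set shares no genes with the ranked list")
    if n_hit == len(ranked):
        raise ValueError("gene set equals the entire ranked list (degenerate)")
    w = np.abs(ranked.scores) ** weight
    wsum = w[hit].sum()
    if wsum == 0:
        # all member scores are exactly 0: fall back to unweighted increments
        deltas = np.where(hit, 1.0 / n_hit, -1.0 / (len(ranked) - n_hit))
    else:
        deltas = np.where(hit, w / wsum, -1.0 / (len(ranked) - n_hit))
    return hit, deltas


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES (extreme running-sum deviation, sign kept) and the full curve."""
    hit, deltas = _hit_deltas(ranked, gene_set.members, weight)
    curve = np.cumsum(deltas)
    hi, lo = float(curve.max()), float(curve.min())
    es = hi if abs(hi) >= abs(lo) else lo
    return es, curve


def _edges(
    ranked: RankedList, hit: np.ndarray, curve: np.ndarray, es: float
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Leading edge: members driving the ES extreme; trailing edge: members
    beyond the opposite extreme of the curve."""
    genes = np.array(ranked.genes)
    i_max = int(curve.argmax())
    i_min = int(curve.argmin())
    if es >= 0:
        leading = genes[: i_max + 1][hit[: i_max + 1]]
        trailing = genes[i_min + 1 :][hit[i_min + 1 :]] if curve[i_min] < 0 else np.array([])
    else:
        leading = genes[i_min + 1 :][hit[i_min + 1 :]]
        trailing = genes[: i_max + 1][hit[: i_max + 1]] if curve[i_max] > 0 else np.array([])
    return tuple(leading), tuple(trailing)


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """ES for each row of sorted hit positions (vectorized over permutations).

    ``pos`` has shape (n_perm, k) with ascending 0-based ranks; ``w`` is the
    |score|^weight vector of the full list.
    """
    n_perm, k = pos.shape
    miss_step = 1.0 / (n - k)
    wk = w[pos]
    wsum = wk.sum(axis=1, keepdims=True)
    # guard all-zero member weights (classic ES fallback)
    zero = wsum[:, 0] == 0
    cum = np.cumsum(wk, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.where(wsum > 0, cum / wsum, (np.arange(1, k + 1) / k)[None, :])
    misses_before = pos - np.arange(k)[None, :]
    after_hit = cum - misses_before * miss_step
    before_hit = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1
    ) - misses_before * miss_step
    hi = after_hit.max(axis=1)
    lo = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def _null_positions(
    n: int, k: int, n_perm: int, rng: np.random.Generator, exhaustive_cap: int
) -> tuple[np.ndarray, bool]:
    n_comb = math.comb(n, k)
    if n_comb <= min(n_perm, exhaustive_cap):
        combos = np.array(list(itertools.combinations(range(n), k)), dtype=np.int64)
        return combos, True
    out = np.empty((n_perm, k), dtype=np.int64)
    chunk = max(1, min(n_perm, int(4e6 / max(n, 1)) or 1))
    filled = 0
    while filled < n_perm:
        c = min(chunk, n_perm - filled)
        u = rng.random((c, n))
        part = np.argpartition(u, k - 1, axis=1)[:, :k]
        out[filled : filled + c] = np.sort(part, axis=1)
        filled += c
    return out, False


def permutation_test(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 100_000,
    seed: int | None = None,
    weight: float = 1.0,
    exhaustive_cap: int = 200_000,
) -> EnrichmentResult:
    """Gene-set permutation test of the enrichment score.

    The null draws random sets of size |S| without replacement from the ranked
    genes (enumerated exhaustively when feasible). p = (1 + #same-sign null ES
    with |ES_null| >= |ES|) / (1 + #same-sign permutations); NES = ES divided
    by the mean |null ES| of the same sign. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    hit, _ = _hit_deltas(ranked, gene_set.members, weight)
    es, curve = enrichment_score(ranked, gene_set, weight)
    leading, trailing = _edges(ranked, hit, curve, es)
    n, k = len(ranked), int(hit.sum())
    rng = np.random.default_rng(seed)
    pos, _ = _null_positions(n, k, n_perm, rng, exhaustive_cap)
    w = np.abs(ranked.scores) ** weight
    null_es = _es_from_positions(pos, w, n)
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    unstable = n_same < 10
    if unstable:
        warnings.warn(
            f"only {n_same} same-sign permutations; p-value unstable",
            UnstableNullWarning,
            stacklevel=2,
        )
    n_extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1 + n_extreme) / (1 + n_same)
    mean_abs = float(np.abs(null_es[same_sign]).mean()) if n_same else np.nan
    nes = es / mean_abs if n_same and mean_abs > 0 else np.nan
    return EnrichmentResult(
        gene_set.name, float(es), float(nes), float(p), None, leading, trailing,
        len(pos), n_same, unstable,
    )


def adjust_batch(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg adjustment of permutation p-values across a batch."""
    q = bh_adjust([r.p_perm for r in results])
    return [replace(r, padj=float(qi)) for r, qi in zip(results, q)]


def chip_gene_set(
    peaks: PeakSet, tss: TssTable, max_distance: int = 10_000, name: str = "chip"
) -> GeneSet:
    """Genes with any peak summit within ``max_distance`` bp of their TSS."""
    summits: dict[str, np.ndarray] = {}
    for chrom, ivs in peaks.by_chrom().items():
        summits[chrom] = np.array(sorted(iv.summit_pos for iv in ivs))
    members = []
    for row in tss.table.itertuples():
        pos = summits.get(row.chrom)
        if pos is None or len(pos) == 0:
            continue
        i = int(np.searchsorted(pos, row.position))
        near = min(
            abs(int(pos[j]) - int(row.position))
            for j in range(max(0, i - 1), min(len(pos), i + 1))
        )
        if near <= max_distance:
            members.append(str(row.gene_id))
    return GeneSet(name, frozenset(members))


def de_ranked_list(de_table: pd.DataFrame) -> RankedList:
    """Rank genes by sign(log2FC) * -log10(p), descending.

    ``de_table`` needs columns gene, log2FC, p with unique genes and p in (0, 1].
    """
    if de_table["gene"].duplicated().any():
        dup = de_table.loc[de_table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene {dup!r} in DE table")
    p = de_table["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    score = np.sign(de_table["log2FC"].to_numpy(dtype=float)) * (-np.log10(p))
    return RankedList.from_scores(dict(zip(de_table["gene"].astype(str), score)))


def paired_ranking(
    counts: pd.DataFrame,
    pairs: pd.DataFrame,
    mode: str = "replicates",
    target_pair: str | None = None,
    d0: float = 4.0,
    pseudocount: float = 0.5,
) -> RankedList:
    """Rank genes by moderated metastasis/primary log2 fold change.

    ``counts`` is genes x samples; ``pairs`` has columns sample, pair_id,
    tissue in {primary, metastasis}. Counts are median-of-ratios normalized,
    then each pair yields a per-gene log2 ratio with pseudo-count 0.5. In
    ``replicates`` mode the score is the mean ratio over pairs divided by a
    moderated standard error; in ``single_pair`` mode one pair's ratio is
    scored against a dispersion estimated from the remaining pairs.
    """
    if mode not in ("replicates", "single_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    pair_ids = list(dict.fromkeys(pairs["pair_id"]))
    if mode == "single_pair":
        if target_pair is None or target_pair not in pair_ids:
            raise ValueError(f"target_pair {target_pair!r} not among {pair_ids}")
        if len(pair_ids) < 2:
            raise ValueError("single_pair mode needs >= 2 pairs")
    sample_order = list(pairs["sample"])
    sf = size_factors(counts[sample_order])
    norm = counts[sample_order].to_numpy(dtype=float) / sf
    norm = pd.DataFrame(norm, index=counts.index, columns=sample_order)
    ratios = {}
    for pid in pair_ids:
        sub = pairs[pairs["pair_id"] == pid]
        prim = sub.loc[sub["tissue"] == "primary", "sample"].iloc[0]
        met = sub.loc[sub["tissue"] == "metastasis", "sample"].iloc[0]
        ratios[pid] = np.log2(
            (norm[met] + pseudocount) / (norm[prim] + pseudocount)
        )
    ratio_mat = pd.DataFrame(ratios)  # genes x pairs
    if mode == "replicates":
        n = len(pair_ids)
        mean_l = ratio_mat.mean(axis=1).to_numpy()
        if n < 2:
            score = mean_l
        else:
            v = ratio_mat.var(axis=1, ddof=1).to_numpy()
            vmod = (d0 * v.mean() + (n - 1) * v) / (d0 + n - 1)
            score = mean_l / np.sqrt(vmod / n + 1e-12)
    else:
        others = [p for p in pair_ids if p != target_pair]
        v = ratio_mat[others].var(axis=1, ddof=1).to_numpy() if len(others) > 1 else (
            ratio_mat[others].to_numpy() ** 2
        ).mean(axis=1)
        vmod = (d0 * v.mean() + len(others) * v) / (d0 + len(others))
        score = ratio_mat[target_pair].to_numpy() / np.sqrt(vmod + 1e-12)
    return RankedList.from_scores(dict(zip(counts.index.astype(str), score)))


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(s.name + "\tna\t" + "\t".join(sorted(s.members)) + "\n")
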