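"""Genomic interval algebra and standard-format I/O.

All coordinates are 0-based half-open (BED convention). A peak's summit is
stored as an offset from the interval start, matching the tenth column of the
ENCODE narrowPeak format; when no summit was called, the interval midpoint
(floored) is used. Peaks are unstranded; only transcription start sites carry
strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BedParseError",
    "GenomeLayout",
    "GenomicInterval",
    "PeakSet",
    "TssTable",
    "classify_region",
    "consensus_peaks",
    "merge_intervals",
    "overlap_membership",
    "read_bed",
    "read_chrom_sizes",
    "read_narrowpeak",
    "tss_distance",
    "tss_distances",
    "write_bed",
    "write_chrom_sizes",
    "write_narrowpeak",
]


class BedParseError(ValueError):
    """A malformed line in a BED-family file, annotated with its line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of the working genome assembly."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally with a summit offset and score.

    ``summit`` is an offset from ``start`` in ``[0, end - start)``; ``summit_pos``
    resolves it to an absolute coordinate, defaulting to the floored midpoint.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if not self.start < self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise ValueError(
                f"summit offset {self.summit} outside interval of length "
                f"{self.end - self.start}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate; interval midpoint when no summit was called."""
        offset = self.summit if self.summit is not None else self.width // 2
        return self.start + offset

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered collection of intervals: one cistrome, track, or region set.

    Intervals are kept sorted by (chrom, start, end). If a :class:`GenomeLayout`
    is supplied, every interval is checked to lie within it.
    """

    def __init__(
        self,
        name: str,
        intervals: Iterable[GenomicInterval],
        layout: GenomeLayout | None = None,
    ) -> None:
        self.name = name
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=GenomicInterval.sort_key)
        )
        if layout is not None:
            for iv in self.intervals:
                if iv.chrom not in layout:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > layout.length(iv.chrom):
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                        f"chromosome end {layout.length(iv.chrom)}"
                    )
        self.layout = layout

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.name!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def with_name(self, name: str) -> "PeakSet":
        return PeakSet(name, self.intervals, self.layout)


@dataclass
class TssTable:
    """Stranded transcription start sites, one point per gene."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("gene_id", "chrom", "position", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"TSS table missing columns {missing}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in TSS table")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("TSS strand must be '+' or '-'")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_bed(cls, path: str | Path) -> "TssTable":
        """Read a BED6 file of TSS points (gene id in the name column)."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise BedParseError(
                        f"{path}:{lineno}: TSS BED needs 6 columns, got {len(parts)}"
                    )
                rows.append(
                    {
                        "gene_id": parts[3],
                        "chrom": parts[0],
                        "position": int(parts[1]),
                        "strand": parts[5],
                    }
                )
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            t = self.table.sort_values(["chrom", "position", "gene_id"])
            for row in t.itertuples():
                fh.write(
                    f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                    f"{row.gene_id}\t0\t{row.strand}\n"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a 2-column ``chrom<TAB>length`` file into a :class:`GenomeLayout`."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            lengths[parts[0]] = int(parts[1])
    return GenomeLayout(lengths)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_narrowpeak(
    path: str | Path, layout: GenomeLayout | None = None, name: str | None = None
) -> PeakSet:
    """Read an ENCODE narrowPeak (or BED6+) file.

    A 10th column >= 0 is taken as the summit offset from the interval start; a
    value of -1, or fewer than 10 columns, falls back to the floored midpoint.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if not 6 <= len(parts) <= 10:
                raise BedParseError(
                    f"{path}:{lineno}: expected 6-10 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                peak_name = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
                summit: int | None = None
                if len(parts) == 10:
                    raw = int(parts[9])
                    summit = raw if raw >= 0 else None
                interval = GenomicInterval(
                    chrom, start, end, summit=summit, score=score, name=peak_name
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(interval)
    return PeakSet(name or Path(path).stem, intervals, layout)


def read_bed(
    path: str | Path, layout: GenomeLayout | None = None, name: str | None = None
) -> PeakSet:
    """Read a BED3-6 file into a :class:`PeakSet` (summits default to midpoints)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                interval = GenomicInterval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    name=parts[3] if len(parts) > 3 else ".",
                    score=float(parts[4])
                    if len(parts) > 4 and parts[4] != "."
                    else None,
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(interval)
    return PeakSet(name or Path(path).stem, intervals, layout)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as sorted BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = 0 if iv.score is None else iv.score
            score_str = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score_str}\t.\n")


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 10-column narrowPeak; absent summits become -1."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = 0 if iv.score is None else iv.score
            score_str = str(int(score)) if float(score).is_integer() else repr(score)
            summit = -1 if iv.summit is None else iv.summit
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score_str}\t.\t"
                f"0\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Merge intervals closer than ``gap`` bp; bookended intervals merge at gap 0.

    Summits of merged intervals are reset to their midpoints.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    cur: list | None = None  # [chrom, start, end]
    for iv in peaks:
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2] + gap:
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return PeakSet(peaks.name, merged, peaks.layout)


def consensus_peaks(replicates: Sequence[PeakSet], min_support: int) -> PeakSet:
    """Maximal runs of base pairs covered by >= ``min_support`` replicates.

    Each replicate contributes per-base coverage at most once (its intervals are
    unioned first), so a replicate with overlapping peaks does not double-count.
    Output summits are midpoints; names are ``consensus_<i>``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(replicates):
        raise ValueError(
            f"min_support {min_support} exceeds number of replicates {len(replicates)}"
        )
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicates:
        for iv in merge_intervals(rep, gap=0):
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    idx = 0
    layout = next((r.layout for r in replicates if r.layout is not None), None)
    for chrom in sorted(events):
        evts = sorted(events[chrom])
        depth = 0
        run_start: int | None = None
        i = 0
        while i < len(evts):
            pos = evts[i][0]
            while i < len(evts) and evts[i][0] == pos:
                depth += evts[i][1]
                i += 1
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                out.append(
                    GenomicInterval(chrom, run_start, pos, name=f"consensus_{idx}")
                )
                idx += 1
                run_start = None
    return PeakSet("consensus", out, layout)


def _merged_arrays(track: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in merge_intervals(track, gap=0).by_chrom().items():
        arrays[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    return arrays


def overlap_membership(query: PeakSet, tracks: Sequence[PeakSet]) -> np.ndarray:
    """Boolean matrix: cell (i, j) is True iff query interval i overlaps >=1 bp
    of any interval in track j. Overlap is half-open: [100,200) and [200,300)
    do not touch."""
    out = np.zeros((len(query), len(tracks)), dtype=bool)
    for j, track in enumerate(tracks):
        arrays = _merged_arrays(track)
        for i, iv in enumerate(query):
            if iv.chrom not in arrays:
                continue
            starts, ends = arrays[iv.chrom]
            # the only merged interval that can overlap [start, end) is the
            # rightmost one with start < iv.end (merged intervals are disjoint)
            k = int(np.searchsorted(starts, iv.end, side="left")) - 1
            if k >= 0 and ends[k] > iv.start:
                out[i, j] = True
    return out


def tss_distance(
    interval: GenomicInterval, tss: TssTable
) -> tuple[str, int]:
    """Nearest TSS to the interval's summit and the signed, strand-aware distance.

    Positive distance means the summit lies downstream of the TSS in the gene's
    orientation. Ties on absolute distance resolve to the smallest gene_id.
    """
    return tss_distances(PeakSet("_q", [interval]), tss)[0]


def tss_distances(peaks: PeakSet, tss: TssTable) -> list[tuple[str, int]]:
    """Vectorised nearest-TSS lookup for every interval of a PeakSet."""
    if len(tss) == 0:
        raise LookupError("TSS table is empty")
    per_chrom: dict[str, pd.DataFrame] = {
        chrom: grp.sort_values(["position", "gene_id"]).reset_index(drop=True)
        for chrom, grp in tss.table.groupby("chrom")
    }
    results: list[tuple[str, int]] = []
    for iv in peaks:
        grp = per_chrom.get(iv.chrom)
        if grp is None:
            raise LookupError(f"no TSS on chromosome {iv.chrom!r}")
        pos = grp["position"].to_numpy()
        summit = iv.summit_pos
        k = int(np.searchsorted(pos, summit))
        candidates = range(max(0, k - 1), min(len(pos), k + 1))
        best_dist = min(abs(int(pos[c]) - summit) for c in candidates)
        # all TSS at exactly the best distance (either side), smallest gene_id wins
        at_best = np.abs(pos - summit) == best_dist
        sub = grp.loc[at_best].sort_values("gene_id").iloc[0]
        signed = summit - int(sub["position"])
        if sub["strand"] == "-":
            signed = -signed
        results.append((str(sub["gene_id"]), signed))
    return results


PROMOTER_BINS: tuple[int, int, int] = (1000, 2000, 3000)
REGION_LABELS: tuple[str, ...] = (
    "promoter_<=1kb",
    "promoter_1-2kb",
    "promoter_2-3kb",
    "distal",
)


def classify_region(
    distance: int, bins: tuple[int, int, int] = PROMOTER_BINS
) -> str:
    """Bin a signed TSS distance into promoter distance classes or 'distal'."""
    d = abs(int(distance))
    for edge, label in zip(bins, REGION_LABELS):
        if d <= edge:
            return label
    return REGION_LABELS[-1]
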