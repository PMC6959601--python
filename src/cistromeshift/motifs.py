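"""PWM scanning and positional centrality of motif hits around peak summits.

Scores are log2 odds of the motif model against a background base composition.
Centrality profiles follow the CentriMo idea: the best hit per peak within a
window around the summit, binned by offset, with all curves in a profile set
normalized jointly so their grand total is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = [
    "CentralityProfile",
    "MotifHit",
    "Pwm",
    "PresenceRate",
    "log_odds_scan",
    "motif_presence_rate",
    "positional_distribution",
    "read_meme",
    "write_meme",
]

_BASES = "ACGT"
_CODES = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
ZERO_SMOOTH = 1e-4  # pseudo-probability replacing exact zeros before log-odds


@dataclass(frozen=True)
class Pwm:
    """A position probability matrix over ACGT with a background composition."""

    name: str
    probs: np.ndarray  # shape (w, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # shape (4,)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probabilities must have shape (w, 4)")
        if probs.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """5-row log2-odds matrix indexed by base code; row 4 (N) scores 0."""
        probs = self.probs.copy()
        probs[probs == 0] = ZERO_SMOOTH
        probs /= probs.sum(axis=1, keepdims=True)
        lo = np.log2(probs / self.background)
        return np.hstack([lo, np.zeros((self.width, 1))])

    @property
    def max_score(self) -> float:
        """Maximum achievable log2-odds score (best base at every position)."""
        return float(self.log_odds()[:, :4].max(axis=1).sum())

    def default_threshold(self, fraction: float = 0.6) -> float:
        """Relative score threshold: ``fraction`` of the maximum achievable score."""
        return fraction * self.max_score

    def reverse_complement(self) -> "Pwm":
        rc = self.probs[::-1, [3, 2, 1, 0]]
        return Pwm(self.name + "_rc", rc, self.background)


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to base codes; anything not ACGT becomes N (code 4)."""
    table = np.full(256, 4, dtype=np.int8)
    for base, code in _CODES.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


class MotifHit(NamedTuple):
    offset: int
    strand: str
    score: float


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    n = len(codes) - w + 1
    scores = np.zeros(n)
    for j in range(w):
        scores += lo[j, codes[j : j + n]]
    return scores


def log_odds_scan(sequence: str, pwm: Pwm) -> MotifHit:
    """Best log2-odds hit over both strands and all offsets.

    Ties resolve to the leftmost offset, then to the + strand. N bases
    contribute a score of 0 (they match the background by construction).
    """
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif width {pwm.width}"
        )
    codes = encode(sequence)
    fwd = _window_scores(codes, pwm.log_odds())
    rev = _window_scores(codes, pwm.reverse_complement().log_odds())
    i_f, i_r = int(fwd.argmax()), int(rev.argmax())
    best_f, best_r = float(fwd[i_f]), float(rev[i_r])
    if best_r > best_f or (best_r == best_f and i_r < i_f):
        return MotifHit(i_r, "-", best_r)
    return MotifHit(i_f, "+", best_f)


# ---------------------------------------------------------------------------
# Genome access: pyfaidx Fasta, plain dict of strings, or any Mapping
# ---------------------------------------------------------------------------

def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) from a pyfaidx Fasta or a mapping of strings."""
    if isinstance(genome, Mapping):
        try:
            seq = genome[chrom]
        except KeyError:
            raise LookupError(f"chromosome {chrom!r} missing from genome") from None
        return seq[start:end]
    try:
        record = genome[chrom]
    except KeyError:
        raise LookupError(f"chromosome {chrom!r} missing from FASTA") from None
    return str(record[start:end])


def _chrom_length(genome, chrom: str) -> int:
    if isinstance(genome, Mapping):
        return len(genome[chrom])
    return len(genome[chrom])


@dataclass
class CentralityProfile:
    """Probability mass of best motif hits per offset bin around peak summits."""

    motif: str
    bin_centers: np.ndarray
    mass: np.ndarray
    n_hits: int

    @property
    def empty(self) -> bool:
        """True when no hit passed the score threshold for this motif."""
        return self.n_hits == 0

    def total(self) -> float:
        return float(self.mass.sum())


def positional_distribution(
    peaks: PeakSet,
    genome,
    pwms: Sequence[Pwm],
    half_window: int = 250,
    score_min: float | None = None,
    bin_width: int = 10,
    joint_normalization: bool = True,
) -> list[CentralityProfile]:
    """Offset distribution of best motif hits within +-half_window of summits.

    For each peak and each PWM the single best-scoring hit in the window is
    kept if it reaches ``score_min`` (default: 60% of that PWM's maximum
    achievable score). Offsets are hit centers relative to the summit. With
    ``joint_normalization`` all curves share one normalization so the grand
    total over every curve is 1 (per-curve normalization otherwise); a profile
    with no passing hits has total 0 and ``empty=True``.
    """
    if half_window <= 0 or bin_width <= 0:
        raise ValueError("half_window and bin_width must be positive")
    edges = np.arange(-half_window, half_window + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hits = np.zeros((len(pwms), len(centers)))
    thresholds = [
        pwm.default_threshold() if score_min is None else score_min for pwm in pwms
    ]
    los = [(pwm.log_odds(), pwm.reverse_complement().log_odds()) for pwm in pwms]
    for iv in peaks:
        clen = _chrom_length(genome, iv.chrom)
        summit = iv.summit_pos
        ws = max(0, summit - half_window)
        we = min(clen, summit + half_window + 1)
        seq = fetch_sequence(genome, iv.chrom, ws, we)
        codes = encode(seq)
        for m, pwm in enumerate(pwms):
            if len(codes) < pwm.width:
                continue
            fwd = _window_scores(codes, los[m][0])
            rev = _window_scores(codes, los[m][1])
            both = np.maximum(fwd, rev)
            best = int(both.argmax())
            if both[best] < thresholds[m]:
                continue
            offset = ws + best + pwm.width // 2 - summit
            k = int(np.searchsorted(edges, offset, side="right")) - 1
            if 0 <= k < len(centers):
                hits[m, k] += 1
    profiles = []
    grand_total = hits.sum()
    for m, pwm in enumerate(pwms):
        mass = hits[m].copy()
        denom = grand_total if joint_normalization else mass.sum()
        if denom > 0:
            mass = mass / denom
        profiles.append(
            CentralityProfile(pwm.name, centers.copy(), mass, int(hits[m].sum()))
        )
    return profiles


def profiles_to_frame(profiles: Sequence[CentralityProfile]) -> pd.DataFrame:
    rows = [
        {"offset_bin": float(c), "motif": p.motif, "mass": float(v)}
        for p in profiles
        for c, v in zip(p.bin_centers, p.mass)
    ]
    return pd.DataFrame(rows, columns=["offset_bin", "motif", "mass"])


class PresenceRate(NamedTuple):
    n_with_hit: int
    n_peaks: int
    fraction: float


def motif_presence_rate(
    peaks: PeakSet, genome, pwm: Pwm, score_min: float | None = None
) -> PresenceRate:
    """Fraction of peaks whose sequence contains a hit scoring >= score_min."""
    if len(peaks) == 0:
        raise ValueError("empty PeakSet")
    threshold = pwm.default_threshold() if score_min is None else score_min
    n_hit = 0
    for iv in peaks:
        seq = fetch_sequence(genome, iv.chrom, iv.start, iv.end)
        if len(seq) < pwm.width:
            continue
        if log_odds_scan(seq, pwm).score >= threshold:
            n_hit += 1
    return PresenceRate(n_hit, len(peaks), n_hit / len(peaks))


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme(path: str | Path) -> list[Pwm]:
    """Parse MEME minimal motif format into a list of PWMs."""
    pwms: list[Pwm] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in _BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()])
            pwms.append(Pwm(name, np.array(rows), background))
            i += w
        i += 1
    return pwms


def write_meme(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
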