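"""Synthetic genomes, cistromes, counts, and expression with planted ground truth.

The generator emulates the statistical structure of an induced-binding study:
replicate ChIP peak sets with imperfect reproducibility, negative-binomial
region counts with planted gained/lost regions between an induced and a
vehicle condition, MIR-like repeats carrying an embedded ETS motif with a
planted per-peak enrichment odds ratio, differential expression coupled to
gained binding sites within 10 kb of a TSS, and matched primary/metastasis
patient count tables in which a subset of pairs is responsive.

Negative-binomial counts use the linear-variance (NB1) parametrization:
``var = mu * (1 + dispersion)``, so dispersion -> 0 recovers Poisson-like
variance. Randomness is hierarchical: one child stream per artifact, spawned
from the master seed, so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cobinding import BindingMatrix
from .differential import CountMatrix
from .intervals import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    TssTable,
    consensus_peaks,
    write_bed,
    write_chrom_sizes,
    write_narrowpeak,
)
from .motifs import Pwm, write_meme

__all__ = [
    "GroundTruth",
    "SimConfig",
    "SimulatedGenome",
    "SimulatedPeaks",
    "default_ets_pwm",
    "simulate_all",
    "simulate_binding_matrix",
    "simulate_counts",
    "simulate_de",
    "simulate_genome",
    "simulate_patient_pairs",
    "simulate_peaks",
]

_BASES = np.array(list("ACGT"))
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")

FACTORS = ("ELF5", "FOXA1", "ER")
CONDITIONS = ("induced", "vehicle")


def default_ets_pwm(informativeness: float = 0.85) -> Pwm:
    """A sharply informative ETS-family PWM with the canonical GGAA core."""
    consensus = "ACCGGAAGT"
    probs = np.full((len(consensus), 4), (1 - informativeness) / 3)
    for i, base in enumerate(consensus):
        probs[i, "ACGT".index(base)] = informativeness
    return Pwm("ETS", probs, np.full(4, 0.25))


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the shipped study conditions."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_000_000}
    )
    n_genes: int = 400
    n_base_peaks: int = 300  # per factor
    n_universe_peaks: int = 2000
    n_replicates: int = 4
    replicate_reproducibility: float = 0.85  # rho: P(replicate keeps a base peak)
    peak_width: int = 200
    peak_jitter_sd: float = 10.0
    gained_fraction: float = 0.10
    lost_fraction: float = 0.05
    gained_log2_effect: float = 1.0
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1  # NB1: var = mu * (1 + dispersion)
    repeat_density: float = 150.0  # repeats per Mb
    repeat_length: int = 180
    repeat_enrichment_or: float = 2.0  # planted per-peak odds ratio at focus peaks
    cobind_rate: float = 0.6  # P(FOXA1/ER base peak placed at an ELF5 site)
    de_coupling: float = 1.5  # mean log2FC of genes near gained sites
    de_sd: float = 0.5  # sd of emitted log2FC around its mean
    motif_at_peak_rate: float = 0.8  # P(ETS instance planted at an ELF5 summit)
    motif_at_gained_rate: float = 0.7  # P(instance at a gained-region summit)
    motif_at_lost_rate: float = 0.1  # P(instance at a lost-region summit)
    n_patient_pairs: int = 7
    n_responsive_pairs: int = 3
    signature_effect: float = 1.5  # log2 fold change of signature genes in responsive metastases
    patient_nb_dispersion: float = 0.2
    # planted co-binding block (binding-compendium emulation)
    n_binding_loci: int = 500
    n_block_cofactors: int = 4
    n_background_factors: int = 10
    block_prob: float = 0.35
    in_block_rate: float = 0.9
    background_bind_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.replicate_reproducibility <= 1:
            raise ValueError("replicate_reproducibility must be in (0, 1]")
        if not 0 <= self.gained_fraction < 1:
            raise ValueError("gained_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.repeat_density < 0:
            raise ValueError("rates and dispersions must be positive")

    def streams(self) -> dict[str, np.random.Generator]:
        """One named child generator per artifact, spawned from the master seed."""
        names = ["genome", "peaks", "counts", "de", "patients", "binding", "plant"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream caller."""

    gained_ids: list[str] = field(default_factory=list)
    lost_ids: list[str] = field(default_factory=list)
    gained_regions: PeakSet | None = None
    lost_regions: PeakSet | None = None
    repeat_peak_flags: dict[str, bool] = field(default_factory=dict)
    motif_positions: dict[str, int] = field(default_factory=dict)
    coupled_genes: list[str] = field(default_factory=list)
    responsive_pairs: list[str] = field(default_factory=list)
    block_cofactors: list[str] = field(default_factory=list)


@dataclass
class SimulatedGenome:
    layout: GenomeLayout
    sequences: dict[str, str]
    tss: TssTable
    repeats: PeakSet
    tracks: dict[str, PeakSet]
    ets_pwm: Pwm


@dataclass
class SimulatedPeaks:
    base_peaks: dict[str, PeakSet]
    replicates: dict[tuple[str, str, int], PeakSet]  # (factor, condition, rep)
    universe: PeakSet


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _sample_motif_instance(
    rng: np.random.Generator, pwm: Pwm, max_tries: int = 20
) -> np.ndarray:
    """Sample a motif instance from the PWM that still scores above the
    default detection threshold (rejection sampling; consensus fallback)."""
    lo = pwm.log_odds()
    threshold = pwm.default_threshold()
    for _ in range(max_tries):
        inst = np.array(
            [rng.choice(4, p=pwm.probs[j]) for j in range(pwm.width)], dtype=np.int8
        )
        if lo[np.arange(pwm.width), inst].sum() >= threshold:
            return inst
    return pwm.probs.argmax(axis=1).astype(np.int8)


def _place_disjoint(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n: int,
    width: int,
    occupied: dict[str, list[tuple[int, int]]],
    max_tries: int = 50,
) -> list[GenomicInterval]:
    """Place ``n`` width-``width`` intervals avoiding already-occupied spans."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed = []
    for _ in range(n):
        for _try in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, chrom_lengths[chrom] - width))
            end = start + width
            clash = any(s < end and start < e for s, e in occupied.get(chrom, []))
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(GenomicInterval(chrom, start, end))
                break
    return placed


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """I.i.d. background sequence with planted repeats, annotation tracks, TSS."""
    rng = rng if rng is not None else config.streams()["genome"]
    for chrom, length in config.chrom_lengths.items():
        if length < 10 * max(config.repeat_length, config.peak_width, 5000):
            raise ValueError(f"chromosome {chrom} too short for requested features")
    layout = GenomeLayout(dict(config.chrom_lengths))
    seq_codes = {c: _random_sequence(rng, n) for c, n in config.chrom_lengths.items()}
    pwm = default_ets_pwm()

    occupied: dict[str, list[tuple[int, int]]] = {}
    # MIR-like repeats, each with one embedded motif instance at its center
    total_mb = sum(config.chrom_lengths.values()) / 1e6
    n_repeats = int(round(config.repeat_density * total_mb))
    repeat_ivs = _place_disjoint(
        rng, config.chrom_lengths, n_repeats, config.repeat_length, occupied
    )
    w = pwm.width
    motif_positions: dict[str, int] = {}
    for idx, iv in enumerate(repeat_ivs):
        motif_start = iv.start + (iv.width - w) // 2
        inst = _sample_motif_instance(rng, pwm)
        seq_codes[iv.chrom][motif_start : motif_start + w] = inst
        motif_positions[f"repeat_{idx}"] = motif_start
    repeats = PeakSet(
        "MIR",
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"repeat_{i}")
            for i, iv in enumerate(repeat_ivs)
        ],
        layout,
    )

    track_spec = {
        "enhancer": (40, 1000),
        "super_enhancer": (10, 5000),
        "HOT": (20, 2000),
        "DNase_open": (80, 800),
    }
    tracks: dict[str, PeakSet] = {}
    track_occupied: dict[str, list[tuple[int, int]]] = {}
    for label, (n, width) in track_spec.items():
        ivs = _place_disjoint(rng, config.chrom_lengths, n, width, track_occupied)
        tracks[label] = PeakSet(
            label,
            [
                GenomicInterval(iv.chrom, iv.start, iv.end, name=f"{label}_{i}")
                for i, iv in enumerate(ivs)
            ],
            layout,
        )

    rows = []
    for g in range(config.n_genes):
        chroms = list(config.chrom_lengths)
        weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        rows.append(
            {
                "gene_id": f"g{g:04d}",
                "chrom": chrom,
                "position": int(rng.integers(1000, config.chrom_lengths[chrom] - 1000)),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    tss = TssTable(pd.DataFrame(rows))

    sequences = {c: _codes_to_str(codes) for c, codes in seq_codes.items()}
    return SimulatedGenome(layout, sequences, tss, repeats, tracks, pwm)


def simulate_peaks(
    config: SimConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> SimulatedPeaks:
    """Replicate peak sets per factor/condition plus a uniform universe set.

    ELF5 base peaks sit on planted repeats with the probability that yields the
    configured per-peak enrichment odds ratio against the universe; FOXA1/ER
    base peaks co-locate with ELF5 sites at ``cobind_rate``. Each replicate
    keeps a base peak with probability rho and jitters its boundaries.
    """
    rng = rng if rng is not None else config.streams()["peaks"]
    truth = truth if truth is not None else GroundTruth()
    layout = genome.layout
    width = config.peak_width

    def uniform_peak(name: str) -> GenomicInterval:
        chroms = layout.chroms
        weights = np.array([layout.length(c) for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        start = int(rng.integers(0, layout.length(chrom) - width))
        return GenomicInterval(chrom, start, start + width, summit=width // 2, name=name)

    universe = PeakSet(
        "universe", [uniform_peak(f"u{i}") for i in range(config.n_universe_peaks)], layout
    )

    # background repeat-overlap rate of a uniform peak, estimated on the universe
    from .intervals import overlap_membership

    r0 = float(overlap_membership(universe, [genome.repeats])[:, 0].mean())
    r0 = min(max(r0, 1e-6), 0.5)
    odds0 = r0 / (1 - r0)
    target = config.repeat_enrichment_or * odds0
    p_hit = target / (1 + target)
    p_repeat = min(max((p_hit - r0) / (1 - r0), 0.0), 1.0)

    repeat_ivs = list(genome.repeats)
    base_peaks: dict[str, PeakSet] = {}
    for factor in FACTORS:
        ivs = []
        for i in range(config.n_base_peaks):
            name = f"{factor}_base_{i}"
            if factor == "ELF5" and repeat_ivs and rng.random() < p_repeat:
                rep = repeat_ivs[int(rng.integers(len(repeat_ivs)))]
                center = (rep.start + rep.end) // 2
                start = max(0, center - width // 2)
                end = min(layout.length(rep.chrom), start + width)
                iv = GenomicInterval(
                    rep.chrom, start, end, summit=center - start, name=name
                )
                truth.repeat_peak_flags[name] = True
            elif factor != "ELF5" and "ELF5" in base_peaks and rng.random() < config.cobind_rate:
                anchor = base_peaks["ELF5"][int(rng.integers(len(base_peaks["ELF5"])))]
                shift = int(rng.integers(-50, 51))
                start = max(0, anchor.summit_pos + shift - width // 2)
                end = min(layout.length(anchor.chrom), start + width)
                iv = GenomicInterval(anchor.chrom, start, end, summit=width // 2, name=name)
            else:
                iv = uniform_peak(name)
                if factor == "ELF5":
                    truth.repeat_peak_flags[name] = False
            ivs.append(iv)
        base_peaks[factor] = PeakSet(f"{factor}_base", ivs, layout)

    replicates: dict[tuple[str, str, int], PeakSet] = {}
    rho = config.replicate_reproducibility
    for factor in FACTORS:
        for condition in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                ivs = []
                for iv in base_peaks[factor]:
                    if rng.random() > rho:
                        continue
                    jitter = rng.normal(0.0, config.peak_jitter_sd, size=2)
                    start = max(0, iv.start + int(round(jitter[0])))
                    end = min(layout.length(iv.chrom), iv.end + int(round(jitter[1])))
                    if end - start < 10:
                        continue
                    summit = min(max(iv.summit_pos - start, 0), end - start - 1)
                    ivs.append(
                        GenomicInterval(
                            iv.chrom, start, end, summit=summit,
                            score=float(np.round(rng.uniform(100, 1000), 2)),
                            name=f"{iv.name}_r{rep}",
                        )
                    )
                replicates[(factor, condition, rep)] = PeakSet(
                    f"{factor}_{condition}_rep{rep}", ivs, layout
                )
    return SimulatedPeaks(base_peaks, replicates, universe)


def _nb1(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB1 draws: var = mean * (1 + dispersion), via size = mean / dispersion."""
    mean = np.asarray(mean, dtype=float)
    size = np.maximum(mean / dispersion, 1e-8)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: SimConfig,
    consensus: PeakSet,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Region x sample NB counts with planted gained/lost regions.

    Gained regions get mean x 2^gained_log2_effect in the induced samples
    (lost regions the inverse); sample library sizes vary around 1.
    """
    rng = rng if rng is not None else config.streams()["counts"]
    n = len(consensus)
    region_ids = [iv.name for iv in consensus]
    n_gained = int(round(config.gained_fraction * n))
    n_lost = int(round(config.lost_fraction * n))
    chosen = rng.choice(n, size=n_gained + n_lost, replace=False)
    gained_idx = set(chosen[:n_gained].tolist())
    lost_idx = set(chosen[n_gained:].tolist())
    truth.gained_ids = [region_ids[i] for i in sorted(gained_idx)]
    truth.lost_ids = [region_ids[i] for i in sorted(lost_idx)]
    truth.gained_regions = PeakSet(
        "true_gained", [consensus[i] for i in sorted(gained_idx)], consensus.layout
    )
    truth.lost_regions = PeakSet(
        "true_lost", [consensus[i] for i in sorted(lost_idx)], consensus.layout
    )

    base_mean = config.nb_mean * np.exp(rng.normal(0.0, 0.3, size=n))
    effect = np.ones(n)
    effect[list(gained_idx)] = 2.0 ** config.gained_log2_effect
    effect[list(lost_idx)] = 2.0 ** (-config.gained_log2_effect)

    samples = []
    counts: dict[str, np.ndarray] = {}
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            name = f"{condition}_{rep}"
            lib = rng.uniform(0.8, 1.25)
            mean = base_mean * lib * (effect if condition == "induced" else 1.0)
            counts[name] = _nb1(rng, mean, config.nb_dispersion)
            samples.append({"sample": name, "condition": condition, "replicate": rep})
    counts_df = pd.DataFrame(counts, index=pd.Index(region_ids, name="region_id"))
    regions = pd.DataFrame(
        {
            "region_id": region_ids,
            "chrom": [iv.chrom for iv in consensus],
            "start": [iv.start for iv in consensus],
            "end": [iv.end for iv in consensus],
        }
    )
    return CountMatrix(counts_df, regions, pd.DataFrame(samples))


def simulate_de(
    config: SimConfig,
    genome: SimulatedGenome,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    max_distance: int = 10_000,
) -> pd.DataFrame:
    """DE table (gene, log2FC, p, FDR) coupled to planted gained binding sites.

    Genes with a planted gained region within ``max_distance`` of their TSS
    draw log2FC around ``de_coupling``; all others around 0. The p-value is
    the two-sided normal tail of log2FC / de_sd, so null p-values are uniform
    and effect sizes and p-values are mutually consistent.
    """
    rng = rng if rng is not None else config.streams()["de"]
    from .rank_enrichment import chip_gene_set

    if truth.gained_regions is not None and len(truth.gained_regions) > 0:
        coupled = chip_gene_set(truth.gained_regions, genome.tss, max_distance).members
    else:
        coupled = frozenset()
    truth.coupled_genes = sorted(coupled)
    genes = genome.tss.table["gene_id"].tolist()
    mu = np.array([config.de_coupling if g in coupled else 0.0 for g in genes])
    lfc = mu + rng.normal(0.0, config.de_sd, size=len(genes))
    p = np.clip(2.0 * stats.norm.sf(np.abs(lfc) / config.de_sd), 1e-300, 1.0)
    from .differential import bh_adjust

    return pd.DataFrame(
        {"gene": genes, "log2FC": lfc, "p": p, "FDR": bh_adjust(p)}
    )


def simulate_patient_pairs(
    config: SimConfig,
    genome: SimulatedGenome,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched primary/metastasis NB count tables with responsive pairs.

    In responsive pairs the signature genes (the planted coupled genes) get
    mean x 2^signature_effect in the metastasis sample. Returns (counts genes
    x samples, pairs sample sheet with pair_id and tissue).
    """
    if config.n_patient_pairs < 2:
        raise ValueError("need >= 2 patient pairs")
    rng = rng if rng is not None else config.streams()["patients"]
    genes = genome.tss.table["gene_id"].tolist()
    signature = set(truth.coupled_genes)
    responsive = [f"X{i + 1}" for i in range(config.n_responsive_pairs)]
    all_pairs = [f"X{i + 1}" for i in range(config.n_patient_pairs)]
    truth.responsive_pairs = responsive
    base_mean = config.nb_mean * np.exp(rng.normal(0.0, 0.6, size=len(genes)))
    sig_mask = np.array([g in signature for g in genes])
    counts: dict[str, np.ndarray] = {}
    rows = []
    for pid in all_pairs:
        for tissue in ("primary", "metastasis"):
            sample = f"{pid}_{tissue[0].upper()}"
            lib = rng.uniform(0.8, 1.25)
            mean = base_mean * lib
            if tissue == "metastasis" and pid in responsive:
                mean = mean * np.where(sig_mask, 2.0 ** config.signature_effect, 1.0)
            counts[sample] = _nb1(rng, mean, config.patient_nb_dispersion)
            rows.append({"sample": sample, "pair_id": pid, "tissue": tissue})
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))
    return counts_df, pd.DataFrame(rows)


def plant_motifs(
    config: SimConfig,
    genome: SimulatedGenome,
    peaks: SimulatedPeaks,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> None:
    """Embed detectable ETS instances at ELF5 base-peak summits and, at the
    configured rates, at the summits of planted gained and lost regions.

    Mutates ``genome.sequences`` in place; gained sites end up carrying the
    motif more often than lost sites, mirroring induced-binding biology.
    """
    rng = rng if rng is not None else config.streams()["plant"]
    pwm = genome.ets_pwm
    w = pwm.width
    codes = {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.sequences.items()}
    lookup = np.zeros(256, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    arr = {c: lookup[v].copy() for c, v in codes.items()}

    def plant_at(iv: GenomicInterval) -> None:
        start = iv.summit_pos - w // 2
        clen = genome.layout.length(iv.chrom)
        start = min(max(start, 0), clen - w)
        arr[iv.chrom][start : start + w] = _sample_motif_instance(rng, pwm)
        truth.motif_positions[iv.name] = start

    for iv in peaks.base_peaks.get("ELF5", []):
        if rng.random() < config.motif_at_peak_rate:
            plant_at(iv)
    for regions, rate in (
        (truth.gained_regions, config.motif_at_gained_rate),
        (truth.lost_regions, config.motif_at_lost_rate),
    ):
        if regions is None:
            continue
        for iv in regions:
            if rng.random() < rate:
                plant_at(iv)
    genome.sequences.update({c: _codes_to_str(v) for c, v in arr.items()})


def simulate_binding_matrix(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
    target: str = "ELF5",
) -> BindingMatrix:
    """A multi-factor binding compendium with a planted co-binding block.

    The target factor and ``n_block_cofactors`` partners co-occur through a
    latent per-locus state; the remaining factors bind independently.
    """
    rng = rng if rng is not None else config.streams()["binding"]
    block = [f"CO{i + 1}" for i in range(config.n_block_cofactors)]
    background = [f"BG{i + 1}" for i in range(config.n_background_factors)]
    if truth is not None:
        truth.block_cofactors = block
    n = config.n_binding_loci
    z = rng.random(n) < config.block_prob
    cols: dict[str, np.ndarray] = {}
    for f in [target] + block:
        p = np.where(z, config.in_block_rate, 0.05)
        cols[f] = (rng.random(n) < p).astype(int)
    for f in background:
        cols[f] = (rng.random(n) < config.background_bind_rate).astype(int)
    classes = rng.choice(
        ["DE_promoter", "enhancer", "super_enhancer", "other"],
        size=n,
        p=[0.15, 0.40, 0.10, 0.35],
    )
    table = pd.DataFrame(
        {
            "locus_id": [f"locus_{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 200,
            "class": classes,
        }
    )
    for f, v in cols.items():
        table[f] = v
    return BindingMatrix(table, tuple([target] + block + background))


# ---------------------------------------------------------------------------
# Full dataset emission
# ---------------------------------------------------------------------------

def _write_fasta(sequences: dict[str, str], path: Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_all(config: SimConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input under ``outdir`` and return the manifest.

    Emits FASTA + chrom sizes, TSS BED, annotation BEDs, replicate narrowPeaks,
    a universe BED, the region count matrix with its sample sheet, the DE
    table, patient pair counts, the binding compendium, the ETS motif, and
    ground-truth sidecar TSVs, plus ``manifest.json`` with checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = config.streams()
    truth = GroundTruth()

    genome = simulate_genome(config, streams["genome"])
    peaks = simulate_peaks(config, genome, streams["peaks"], truth)

    # decide the planted gained/lost regions first so motif planting can favor
    # gained sites; counts are drawn over the FOXA1 consensus (the contrast window)
    foxa1_reps = [
        peaks.replicates[("FOXA1", cond, r)]
        for cond in CONDITIONS
        for r in range(1, config.n_replicates + 1)
    ]
    contrast_consensus = consensus_peaks(foxa1_reps, min_support=3)
    matrix = simulate_counts(config, contrast_consensus, truth, streams["counts"])
    plant_motifs(config, genome, peaks, truth, streams["plant"])

    paths: dict[str, str] = {}

    def emit(key: str, filename: str, writer) -> Path:
        path = outdir / filename
        writer(path)
        paths[key] = filename
        return path

    emit("fasta", "genome.fa", lambda p: _write_fasta(genome.sequences, p))
    emit("chrom_sizes", "chrom.sizes", lambda p: write_chrom_sizes(genome.layout, p))
    emit("tss", "tss.bed", genome.tss.to_bed)
    emit("repeats", "repeats_MIR.bed", lambda p: write_bed(genome.repeats, p))
    for label, track in genome.tracks.items():
        emit(f"track_{label}", f"{label}.bed", lambda p, t=track: write_bed(t, p))
    emit("universe", "universe.bed", lambda p: write_bed(peaks.universe, p))
    emit("motifs", "motifs.meme", lambda p: write_meme([genome.ets_pwm], p))

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (factor, condition, rep), pset in peaks.replicates.items():
        fname = f"peaks/{factor}_{condition}_rep{rep}.narrowPeak"
        emit(f"peaks_{factor}_{condition}_{rep}", fname,
             lambda p, s=pset: write_narrowpeak(s, p))

    matrix.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    paths["counts"] = "counts.tsv"
    paths["samples"] = "samples.tsv"

    de = simulate_de(config, genome, truth, streams["de"])
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    paths["de_table"] = "de_table.tsv"

    patient_counts, pairs = simulate_patient_pairs(
        config, genome, truth, streams["patients"]
    )
    patient_counts.to_csv(outdir / "patient_counts.tsv", sep="\t")
    pairs.to_csv(outdir / "patient_pairs.tsv", sep="\t", index=False)
    paths["patient_counts"] = "patient_counts.tsv"
    paths["patient_pairs"] = "patient_pairs.tsv"

    binding = simulate_binding_matrix(config, streams["binding"], truth)
    binding.to_tsv(outdir / "binding_matrix.tsv")
    paths["binding_matrix"] = "binding_matrix.tsv"

    # ground-truth sidecars
    pd.DataFrame({"region_id": truth.gained_ids}).to_csv(
        outdir / "truth_gained.tsv", sep="\t", index=False
    )
    pd.DataFrame({"region_id": truth.lost_ids}).to_csv(
        outdir / "truth_lost.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": truth.coupled_genes}).to_csv(
        outdir / "truth_coupled_genes.tsv", sep="\t", index=False
    )
    pd.DataFrame({"pair_id": truth.responsive_pairs}).to_csv(
        outdir / "truth_responsive_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.repeat_peak_flags.items()),
        columns=["peak_id", "on_repeat"],
    ).to_csv(outdir / "truth_repeat_peaks.tsv", sep="\t", index=False)
    for key in (
        "truth_gained", "truth_lost", "truth_coupled_genes",
        "truth_responsive_pairs", "truth_repeat_peaks",
    ):
        paths[key] = key + ".tsv"

    manifest = {
        "schema_version": 1,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "files": {
            key: {"path": rel, "sha256": _sha256(outdir / rel)}
            for key, rel in sorted(paths.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
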