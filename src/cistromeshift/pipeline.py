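"""End-to-end orchestration: consensus -> differential binding -> motif ->
context enrichment -> co-binding -> rank enrichment, with per-stage TSV
outputs and a versioned summary JSON."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cobinding as cb
from . import context as ctx
from . import differential as diff
from . import motifs as mo
from . import rank_enrichment as re_
from .intervals import (
    PeakSet,
    consensus_peaks,
    read_bed,
    read_chrom_sizes,
    read_narrowpeak,
    TssTable,
    write_bed,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("cistromeshift")

SUMMARY_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input locations and the decision thresholds of the analysis.

    Defaults mirror the study's printed thresholds: consensus 3-of-4, FDR
    alpha 0.05, fold-change cut 1.5, the 10 kb TSS rule for ChIP gene sets,
    and gene-set permutation testing.
    """

    input_dir: Path
    output_dir: Path
    min_support: int = 3
    alpha: float = 0.05
    fold_change: float = 1.5
    tss_distance: int = 10_000
    motif_half_window: int = 250
    n_perm: int = 10_000
    seed: int = 0
    factors: tuple[str, ...] = ("ELF5", "FOXA1", "ER")
    conditions: tuple[str, ...] = ("induced", "vehicle")
    n_replicates: int = 4

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"missing input: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the files under ``config.input_dir``.

    Writes per-stage TSVs, gained/lost BEDs, and ``summary.json`` under
    ``config.output_dir``; returns the summary dict.
    """
    ind = config.input_dir
    out = config.output_dir
    # validate all inputs before any stage runs
    layout = read_chrom_sizes(_require(ind / "chrom.sizes"))
    for name in (
        "genome.fa", "tss.bed", "repeats_MIR.bed", "DNase_open.bed", "universe.bed",
        "motifs.meme", "counts.tsv", "samples.tsv", "de_table.tsv",
        "patient_counts.tsv", "patient_pairs.tsv", "binding_matrix.tsv",
    ):
        _require(ind / name)
    out.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "thresholds": {
            "min_support": config.min_support,
            "alpha": config.alpha,
            "fold_change": config.fold_change,
            "tss_distance": config.tss_distance,
            "n_perm": config.n_perm,
        },
    }

    stage = "consensus"
    try:
        logger.info("stage=%s status=start", stage)
        consensus: dict[str, PeakSet] = {}
        for factor in config.factors:
            reps = [
                read_narrowpeak(
                    _require(ind / "peaks" / f"{factor}_induced_rep{r}.narrowPeak"),
                    layout,
                )
                for r in range(1, config.n_replicates + 1)
            ]
            cons = consensus_peaks(reps, config.min_support)
            consensus[factor] = cons
            write_bed(cons, out / f"consensus_{factor}.bed")
        summary["consensus"] = {f: len(p) for f, p in consensus.items()}

        stage = "diffbind"
        logger.info("stage=%s status=start", stage)
        matrix = diff.CountMatrix.from_tsv(ind / "counts.tsv", ind / "samples.tsv")
        records = diff.test_region_differential(matrix)
        gained, lost = diff.classify_sites(records, alpha=config.alpha)
        records.to_csv(out / "differential_binding.tsv", sep="\t", index=False)
        write_bed(gained, out / "gained.bed")
        write_bed(lost, out / "lost.bed")
        summary["differential_binding"] = {
            "n_tested": len(records),
            "n_gained": len(gained),
            "n_lost": len(lost),
        }

        stage = "motif"
        logger.info("stage=%s status=start", stage)
        import pyfaidx

        genome = pyfaidx.Fasta(str(ind / "genome.fa"))
        pwms = mo.read_meme(ind / "motifs.meme")
        profiles = mo.positional_distribution(
            consensus["ELF5"], genome, pwms, half_window=config.motif_half_window
        )
        mo.profiles_to_frame(profiles).to_csv(
            out / "motif_centrality.tsv", sep="\t", index=False
        )
        rates = {}
        for name, pset in (("gained", gained), ("lost", lost)):
            if len(pset) > 0:
                rate = mo.motif_presence_rate(pset, genome, pwms[0])
                rates[name] = {
                    "n_with_hit": rate.n_with_hit,
                    "n_peaks": rate.n_peaks,
                    "fraction": rate.fraction,
                }
        summary["motif"] = {
            "profile_total": sum(p.total() for p in profiles),
            "presence_rates": rates,
        }

        stage = "context"
        logger.info("stage=%s status=start", stage)
        repeats = ctx.AnnotationTrack("MIR", read_bed(ind / "repeats_MIR.bed", layout))
        open_chromatin = ctx.AnnotationTrack(
            "DNase_open", read_bed(ind / "DNase_open.bed", layout)
        )
        universe = read_bed(ind / "universe.bed", layout)
        or_result = ctx.odds_ratio_overlap(consensus["ELF5"], repeats, universe)
        ctx.results_to_frame([or_result]).to_csv(
            out / "context_enrichment.tsv", sep="\t", index=False
        )
        context_summary = {
            "repeat_odds_ratio": or_result.odds_ratio,
            "repeat_p": or_result.p_value,
        }
        if len(gained) > 0:
            frac = ctx.fraction_overlapping(gained, open_chromatin)
            context_summary["gained_open_chromatin"] = {
                "numerator": frac.numerator,
                "denominator": frac.denominator,
                "percent": frac.percent_rounded,
            }
        summary["context"] = context_summary

        stage = "cobind"
        logger.info("stage=%s status=start", stage)
        binding = cb.BindingMatrix.from_tsv(ind / "binding_matrix.tsv")
        phi = cb.phi_correlation(binding)
        phi.to_csv(out / "cobinding_phi.tsv", sep="\t")
        cofactors = cb.select_cofactors(binding, "ELF5")
        combos = []
        for cls in sorted(set(binding.table["class"])):
            for combo, count in cb.combination_counts_by_class(binding, cls):
                combos.append(
                    {"class": cls, "combination": "+".join(combo) or "(none)", "count": count}
                )
        pd.DataFrame(combos).to_csv(out / "cobinding_combinations.tsv", sep="\t", index=False)
        summary["cobinding"] = {"elf5_cofactors": cofactors}

        stage = "gsea"
        logger.info("stage=%s status=start", stage)
        de = pd.read_csv(ind / "de_table.tsv", sep="\t")
        ranked = re_.de_ranked_list(de)
        tss = TssTable.from_bed(ind / "tss.bed")
        results = []
        for name, pset in (("gained_sites", gained), ("lost_sites", lost)):
            if len(pset) == 0:
                continue
            gene_set = re_.chip_gene_set(pset, tss, config.tss_distance, name=name)
            if not gene_set.members or len(gene_set) >= len(ranked):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", re_.UnstableNullWarning)
                results.append(
                    re_.permutation_test(
                        ranked, gene_set, n_perm=config.n_perm, seed=config.seed
                    )
                )
        results = re_.adjust_batch(results)
        pd.DataFrame(
            [
                {
                    "set": r.set_name, "es": r.es, "nes": r.nes,
                    "p": r.p_perm, "padj": r.padj,
                    "leading_edge": "|".join(r.leading_edge),
                }
                for r in results
            ]
        ).to_csv(out / "rank_enrichment.tsv", sep="\t", index=False)
        summary["rank_enrichment"] = {
            r.set_name: {"es": r.es, "nes": r.nes, "p": r.p_perm, "padj": r.padj}
            for r in results
        }

        stage = "patients"
        logger.info("stage=%s status=start", stage)
        pcounts = pd.read_csv(ind / "patient_counts.tsv", sep="\t", index_col=0)
        pairs = pd.read_csv(ind / "patient_pairs.tsv", sep="\t")
        signature = re_.GeneSet(
            "de_signature",
            frozenset(de.loc[(de["FDR"] < config.alpha) & (de["log2FC"] > 0), "gene"]),
        )
        per_pair = {}
        if signature.members:
            for pid in dict.fromkeys(pairs["pair_id"]):
                ranked_pair = re_.paired_ranking(
                    pcounts, pairs, mode="single_pair", target_pair=pid
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", re_.UnstableNullWarning)
                    r = re_.permutation_test(
                        ranked_pair, signature, n_perm=max(1000, config.n_perm // 10),
                        seed=config.seed,
                    )
                per_pair[pid] = {"es": r.es, "nes": r.nes, "p": r.p_perm}
        summary["patients"] = per_pair
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("stage=%s status=failed error=%s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline status=done")
    return summary
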