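"""Shared fixtures: a session-scoped synthetic dataset and its pipeline run."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cistromeshift.intervals import GenomeLayout, GenomicInterval, PeakSet
from cistromeshift.pipeline import PipelineConfig, run_pipeline
from cistromeshift.simulate import SimConfig, simulate_all

SESSION_SEED = 0


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, sim_config) -> Path:
    """A full synthetic input bundle at the shipped configuration."""
    out = tmp_path_factory.mktemp("simdata")
    simulate_all(sim_config, out)
    return out


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, sim_dir):
    """(summary dict, output dir) of one full pipeline run on the bundle."""
    out = tmp_path_factory.mktemp("pipeline_out")
    summary = run_pipeline(
        PipelineConfig(input_dir=sim_dir, output_dir=out, seed=SESSION_SEED)
    )
    return summary, out


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


def make_peaks(name, triples, layout=None, summits=None):
    """Helper: PeakSet from (chrom, start, end) triples."""
    ivs = [
        GenomicInterval(
            c, s, e, summit=None if summits is None else summits[i], name=f"{name}_{i}"
        )
        for i, (c, s, e) in enumerate(triples)
    ]
    return PeakSet(name, ivs, layout)
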