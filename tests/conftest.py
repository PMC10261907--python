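"""Shared fixtures: toy genes/genomes and simulated scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from fusionscope.contig import GeneModel, build_fusion_contig
from fusionscope.simulate import (
    Depths,
    SimulationConfig,
    simulate_scenario,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(n: int, seed: int = 42) -> str:
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    return {"chr1": random_seq(10_000, seed=42)}


@pytest.fixture(scope="session")
def gene_a() -> GeneModel:
    return GeneModel(
        gene_id="GA",
        chrom="chr1",
        strand="+",
        transcripts={"GA.t1": [(1000, 1200), (1500, 1700), (2200, 2400)]},
    )


@pytest.fixture(scope="session")
def gene_b_minus() -> GeneModel:
    return GeneModel(
        gene_id="GB",
        chrom="chr1",
        strand="-",
        transcripts={"GB.t1": [(5000, 5200), (5700, 5900), (6900, 7100)]},
    )


@pytest.fixture(scope="session")
def toy_contig(gene_a, gene_b_minus, toy_genome):
    return build_fusion_contig(gene_a, gene_b_minus, toy_genome)


@pytest.fixture(scope="session")
def basic_scenario(tmp_path_factory):
    """One REF_SPLICE fusion with counters and background, zero error."""
    out = tmp_path_factory.mktemp("scenario_basic")
    cfg = SimulationConfig(seed=7, n_genes=4)
    return simulate_scenario(
        out,
        cfg,
        [
            {
                "gene_a": "G1",
                "gene_b": "G2",
                "mode": "REF_SPLICE",
                "depths": Depths(8, 10, 5, 3),
                "n_background": 20,
            }
        ],
        extra_candidates=[("G3", "G4")],
    )
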