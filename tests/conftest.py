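"""Shared fixtures: hand-built gene models and seeded simulated data sets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lrfusion.annotation import GeneModel, GeneModelSet
from lrfusion.simulate import SimSpec, simulate

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def mini_genome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    return {chrom: random_dna(rng, 12_000) for chrom in ("t1", "t2", "t3")}


@pytest.fixture(scope="session")
def mini_gms() -> GeneModelSet:
    """Small hand-built annotation used across unit tests.

    GA (+, t1) and GB (+, t2) are a clean fusion pair on different
    chromosomes; GC (-, t2) exercises minus-strand handling; GH (t3) has a
    5 kb and an 800 b intron for contig shrinking; GOV1/GOV2 overlap on t1.
    """
    return GeneModelSet(
        [
            GeneModel("GA", "GA", "t1", "+", {"GA.t1": [(1000, 1200), (1400, 1600), (2100, 2300)]}),
            GeneModel("GB", "GB", "t2", "+", {"GB.t1": [(1000, 1150), (1500, 1700)]}),
            GeneModel("GC", "GC", "t2", "-", {"GC.t1": [(5000, 5200), (5800, 6000)]}),
            GeneModel("GH", "GH", "t3", "+", {"GH.t1": [(100, 300), (5300, 5500), (6300, 6500)]}),
            GeneModel("GOV1", "GOV1", "t1", "+", {"GOV1.t1": [(8000, 8500)]}),
            GeneModel("GOV2", "GOV2", "t1", "+", {"GOV2.t1": [(8300, 9000)]}),
        ]
    )


# The reference study conditions for the end-to-end runs: a 20-gene toy
# genome, 5 planned fusions with at least 3 supporting reads each at
# consensus exon junctions, 200 background reads (10 per gene).
E2E_SPEC = dict(
    seed=11,
    n_genes=20,
    genes_per_chrom=5,
    n_fusions=5,
    fusion_reads=(3, 8),
    background_reads_per_gene=10,
)


@pytest.fixture(scope="session")
def sim_e2e():
    """End-to-end data set with 1% substitution error."""
    return simulate(SimSpec(sub_rate=0.01, **E2E_SPEC))


@pytest.fixture(scope="session")
def sim_clean():
    """Same study conditions with zero sequencing error."""
    return simulate(SimSpec(**E2E_SPEC))


def truth_as_predictions(dataset):
    from lrfusion.benchmark import PredictedFusion, parse_breakpoint

    return [
        PredictedFusion(
            method="truth",
            sample=t["sample"],
            gene5=t["gene5"],
            gene3=t["gene3"],
            breakpoint5=parse_breakpoint(t["breakpoint5"]),
            breakpoint3=parse_breakpoint(t["breakpoint3"]),
            read_support=t["num_reads"],
        )
        for t in dataset.truth
    ]
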