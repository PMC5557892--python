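"""Shared fixtures: every dataset is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from chimeramap.annotation import AnnotationIndex
from chimeramap.catalog import MiRNA, MiRNACatalog
from chimeramap.chimeras import GenomeMapper, Read, call_chimeras
from chimeramap.simulate import SimulationConfig, simulate_study

# mature bovine miRNA sequences (miRBase nomenclature): miR-17-5p and
# the 3p arm of miR-224
MIR17 = "CAAAGTGCTTACAGTGCAGGTAGT"
MIR224 = "CAAAATGGTACCCTAGTGACT"


@pytest.fixture(scope="session")
def small_catalog() -> MiRNACatalog:
    return MiRNACatalog(
        [
            MiRNA("bta-miR-17-5p", MIR17),
            MiRNA("bta-miR-224-3p", MIR224),
            MiRNA("bta-miR-15a", "TAGCAGCACATAATGGTTTGTG"),
            MiRNA("bta-miR-15b", "TAGCAGCACATCATGGTTTACA"),
        ]
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """Small full study used by several pipeline-level tests."""
    cfg = SimulationConfig(rng_seed=11, total_reads=20_000)
    reference, catalog, truth, reads, counts = simulate_study(cfg)
    return cfg, reference, catalog, truth, reads, counts


@pytest.fixture(scope="session")
def sim_called(sim_bundle):
    """Chimera calls for the shared study bundle."""
    cfg, reference, catalog, truth, reads, counts = sim_bundle
    mapper = GenomeMapper(reference.genome_sequences())
    ann = AnnotationIndex(reference.genes.values())
    B = cfg.barcode_length
    read_objs = [
        Read(rid, s[B:], s[:B], rep)
        for rep, rep_reads in reads.items()
        for rid, s in rep_reads
    ]
    counters: dict = {}
    called = call_chimeras(
        read_objs, catalog, mapper,
        [hp.locus for hp in reference.hairpins], ann, counters,
    )
    return called, counters, mapper, ann, read_objs


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
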