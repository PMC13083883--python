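"""Shared fixtures: a hand-built toy genome and a seeded simulated dataset."""

import numpy as np
import pandas as pd
import pytest

from b2gate.genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    SequenceStore,
    TEInstance,
)
from b2gate.lace import TagSet
from b2gate.simulate import SimulationConfig, simulate_genome, simulate_tags


@pytest.fixture(scope="session")
def toy_annotation():
    """Two genes (one per strand) and two TE copies on a 10 kb contig."""
    genes = [
        GeneModel(
            "geneA",
            GenomicInterval("chr1", 1000, 3000, "+"),
            exons=[
                GenomicInterval("chr1", 1000, 1500, "+"),
                GenomicInterval("chr1", 2200, 3000, "+"),
            ],
        ),
        GeneModel(
            "geneB",
            GenomicInterval("chr1", 5000, 7000, "-"),
            exons=[
                GenomicInterval("chr1", 5000, 5600, "-"),
                GenomicInterval("chr1", 6400, 7000, "-"),
            ],
        ),
    ]
    tes = [
        TEInstance(GenomicInterval("chr1", 1200, 1380, "+"), "B2_Mm1a", "SINE"),
        TEInstance(GenomicInterval("chr1", 8000, 8500, "+"), "MERVL-int", "LTR"),
    ]
    return GenomeAnnotation(contig_lengths={"chr1": 10_000}, genes=genes, tes=tes)


@pytest.fixture()
def tagset_factory():
    def make(positions, strand="+", contig="chr1", sample_id="s", condition="control"):
        tags = pd.DataFrame(
            {"contig": contig, "pos": list(positions), "strand": strand}
        )
        return TagSet(sample_id=sample_id, condition=condition, tags=tags)

    return make


@pytest.fixture(scope="session")
def sim_bundle():
    """Default-scale simulated dataset at seed 1, shared across tests."""
    cfg = SimulationConfig(seed=1)
    store, ann, truth = simulate_genome(cfg)
    tags = simulate_tags(cfg, truth, ann.contig_lengths)
    return {"cfg": cfg, "store": store, "ann": ann, "truth": truth, "tags": tags}


@pytest.fixture(scope="session")
def sim_clusters(sim_bundle):
    from b2gate.lace import call_binding_sites

    return call_binding_sites(
        sim_bundle["tags"]["control"],
        sim_bundle["tags"]["inhibitor"],
        sim_bundle["store"],
    )
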