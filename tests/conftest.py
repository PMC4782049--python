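import numpy as np
import pandas as pd
import pytest

from srexport.annotation import GenomeAnnotation, TranscriptModel
from srexport.simulate import (
    ProteinSpec, SimulationConfig, simulate_genome, simulate_iclip,
)


@pytest.fixture(scope="session")
def tiny_annotation() -> GenomeAnnotation:
    """Hand-built two-gene annotation covering both strands and a CDS."""
    t1 = TranscriptModel(
        "tA.1", "gA", "chr1", "+",
        exons=[(100, 200), (300, 400), (500, 650)], cds=(150, 560))
    t2 = TranscriptModel(
        "tB.1", "gB", "chr1", "-",
        exons=[(1000, 1150), (1300, 1400)], cds=(1050, 1380))
    t3 = TranscriptModel("tC.1", "gC", "chr1", "+", exons=[(2000, 2400)])
    return GenomeAnnotation([t1, t2, t3])


@pytest.fixture(scope="session")
def small_sim():
    """A small planted simulation shared by several test modules."""
    cfg = SimulationConfig(seed=101)
    cfg.genome.n_genes = 40
    cfg.genome.n_tandem = 5
    cfg.genome.n_ale = 3
    cfg.proteins = [
        ProteinSpec("SRSF3", ["TCATCATC"], enrichment=12.0,
                    background_rate=0.6,
                    plant={"cds": 1.0, "three_prime_utr": 1.0}),
        ProteinSpec("CTRL", [], enrichment=1.0, background_rate=0.3),
    ]
    cfg.nxf1.utr3_site_rate = 1.0
    genome = simulate_genome(cfg)
    libraries = simulate_iclip(cfg, genome)
    return cfg, genome, libraries
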