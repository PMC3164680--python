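import numpy as np
import pytest

from igsfootprint.genome import GeneFeature, GenomeAnnotation
from igsfootprint.simulate import SimulationConfig, build_synthetic_genomes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genome(taxon, genes, length=1000, seq=None):
    """Helper: genome with features given as (id, start, end, strand, kind)."""
    seq = seq or ("A" * length)
    feats = [
        GeneFeature(fid, "chr", s, e, strand, kind, ortholog_id=fid)
        for fid, s, e, strand, kind in genes
    ]
    return GenomeAnnotation(taxon, {"chr": seq}, feats)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One shared synthetic 4-taxon genome set with planted truth."""
    cfg = SimulationConfig(seed=7)
    genomes, omap, truth = build_synthetic_genomes(
        cfg,
        n_genes=10,
        sd_fraction=0.8,
        terminator_fraction=0.5,
        inactivations=[(3, "Ua", "frameshift"), (5, "AkAp", "stop")],
    )
    return cfg, genomes, omap, truth
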