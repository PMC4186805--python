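import numpy as np
import pytest

from mitocomp.io import AnnotatedGenome, GeneFeature
from mitocomp.simulate import SimulationConfig, simulate_genomes


@pytest.fixture(scope="session")
def sim5():
    """Five simulated taxa at reduced scale plus ground truth."""
    cfg = SimulationConfig(n_taxa=5, seed=11, scale=0.3)
    genomes, truth = simulate_genomes(cfg)
    return genomes, truth, cfg


@pytest.fixture(scope="session")
def sim5_genomes(sim5):
    return sim5[0]


@pytest.fixture()
def toy_genome():
    """Hand-built mini genome: rrnS, AT-rich gap, trnI, one PCG per strand."""
    # layout (1-based):  rrnS 1-12 (N) | gap 13-24 | trnI 25-32 (J)
    #                    | cox1 33-50 (J) | nad1 51-68 (N)
    cox1 = "ATGAAATTTCCCGGGTAA"          # 6 codons, complete stop
    nad1 = "ATGCATCATTGTTGTTAA"          # as coding (N strand)
    seq = ("GGGGCCCCAAAA" + "TTTTATTATATA" + "AAGGCCTT"
           + cox1 + _rc(nad1))
    feats = [
        GeneFeature("rrnS", "rRNA", 1, 12, "N"),
        GeneFeature("trnI", "tRNA", 25, 32, "J"),
        GeneFeature("cox1", "PCG", 33, 50, "J"),
        GeneFeature("nad1", "PCG", 51, 68, "N"),
    ]
    return AnnotatedGenome("toy", seq, True, feats, taxon="toy taxon")


def _rc(s: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return s.translate(comp)[::-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
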