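import numpy as np
import pytest

from retrochron.io import Sequence
from retrochron.simulate import SimConfig, SubfamilySpec, simulate_history
from retrochron.trees import read_newick

CROC_TREE = (
    "((Alligator:3,(Crocodylus:2,Gavialis:2)Longirostres:1)Crocodylia:2,"
    "Gallus:5)RootNode;"
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng: np.random.Generator, seq: str, frac: float) -> str:
    out = list(seq)
    k = int(round(frac * len(out)))
    for i in rng.choice(len(out), size=k, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def croc_host_tree():
    return read_newick(CROC_TREE)


@pytest.fixture(scope="session")
def small_sim(croc_host_tree):
    """A modest four-taxon history shared by several test modules."""
    specs = [
        SubfamilySpec("CR1-old", mu=1.0, sigma=1.0, rate=25, element_length=800),
        SubfamilySpec("CR1-young", mu=4.0, sigma=0.8, rate=25, element_length=600),
    ]
    cfg = SimConfig(
        host_tree=croc_host_tree,
        subfamilies=specs,
        ancestral_genome_length=40_000,
        subst_rate=0.005,
        seed=3,
    )
    return simulate_history(cfg)
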