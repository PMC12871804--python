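import numpy as np
import pytest

from ipastrace import synthetic_data as sd
from ipastrace.longread_classify import ExonChain, IsoformModel


@pytest.fixture(scope="session")
def primate_tree():
    return sd.load_primate_tree()


@pytest.fixture(scope="session")
def primate_characters():
    return sd.load_primate_characters()


@pytest.fixture(scope="session")
def isoform_models():
    """A nine-exon canonical model and a five-exon truncated model whose
    last exon reads into the following intron (shared junctions J1-J4)."""
    canonical = IsoformModel(
        "canonical",
        ExonChain("chrS", "+", [(200 + 500 * i, 320 + 500 * i) for i in range(9)], "canonical"),
    )
    short = IsoformModel(
        "short",
        ExonChain(
            "chrS",
            "+",
            [(200 + 500 * i, 320 + 500 * i) for i in range(4)] + [(2200, 2560)],
            "short",
        ),
    )
    return [canonical, short]


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary topology by iterative pair-joining (for oracles)."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:{rng.uniform(0.5, 2):.2f},{b}:{rng.uniform(0.5, 2):.2f})")
    return nodes[0] + ";"
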