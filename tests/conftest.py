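import random

import pytest

from glycomer.glycan_model import GlycanNode, GlycanTree, Residue

_IDENTITIES = ["Man", "Gal", "Glc", "GlcNAc", "Fuc", "Hex", "HexNAc", "dHex"]
_LINK_POS = ["2", "3", "4", "6", "?"]
_ANOM = ["a", "b", "?"]


def random_tree(rng: random.Random, max_residues: int = 8) -> GlycanTree:
    """A random well-formed glycan tree (root carries no linkage)."""
    n = rng.randint(1, max_residues)
    root = GlycanNode(Residue("GlcNAc", "?", "none", rng.randint(0, 2)))
    nodes = [root]
    for _ in range(n - 1):
        parent = rng.choice(nodes)
        child = GlycanNode(
            Residue(
                rng.choice(_IDENTITIES),
                rng.choice(_ANOM),
                f"1-{rng.choice(_LINK_POS)}",
                rng.randint(0, 2),
            )
        )
        parent.children.append(child)
        nodes.append(child)
    return GlycanTree(root, rng.choice(["permethylated", "native", "twoAB"]))


@pytest.fixture
def tree_corpus():
    """120 seeded random trees for round-trip / additivity properties."""
    rng = random.Random(20240917)
    return [random_tree(rng) for _ in range(120)]
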