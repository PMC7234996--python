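import numpy as np
import pandas as pd
import pytest

from pikw.phylo import Node, TimeTree, parse_newick


@pytest.fixture
def three_tip_tree() -> TimeTree:
    """((A:1,B:1):1,C:2); — ultrametric, depths all 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


def star_tree(n_tips: int, depth: float) -> TimeTree:
    """A star phylogeny: no shared internal edges, exchangeable tips."""
    root = Node(0.0, None, [Node(depth, f"s{i:03d}") for i in range(n_tips)])
    return TimeTree(root)


@pytest.fixture
def trait_sources():
    """Small three-source cohort input with one unmatched species."""
    bmr = pd.DataFrame(
        {
            "species": ["Gallus gallus", "Struthio camelus", "Corvus corax",
                        "Apteryx australis"],
            "mass": [2000.0, 100000.0, 1200.0, 2500.0],
            "bmr": [20.0, 300.0, 18.0, 15.0],
        }
    )
    lifespan = pd.DataFrame(
        {
            "species": ["gallus_gallus", "Struthio camelus", "Corvus corax"],
            "lifespan": [30.0, 40.0, 25.0],
            "quality": ["high", "acceptable", "questionable"],
        }
    )
    factor = pd.DataFrame(
        {
            "species": ["Gallus gallus", "Struthio camelus", "Corvus corax"],
            "keap1": [1, 1, 0],
        }
    )
    return bmr, lifespan, factor
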