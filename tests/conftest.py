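import numpy as np
import pytest

from binaudit.taxonomy import TaxonomyTree


@pytest.fixture
def two_level_tree() -> TaxonomyTree:
    """root -> {A -> {A1, A2}, B}; A and B are phyla, A1/A2/B1 species."""
    parent = {"root": "root", "A": "root", "B": "root",
              "A1": "A", "A2": "A", "B1": "B"}
    rank = {"root": "root", "A": "phylum", "B": "phylum",
            "A1": "species", "A2": "species", "B1": "species"}
    return TaxonomyTree(parent, rank)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230916)


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i's parent is uniform among nodes < i."""
    parent = {"n0": "n0"}
    for i in range(1, n_nodes):
        parent[f"n{i}"] = f"n{int(rng.integers(0, i))}"
    rank = {t: "node" for t in parent}
    rank["n0"] = "root"
    return TaxonomyTree(parent, rank)
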