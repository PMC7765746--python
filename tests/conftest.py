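import numpy as np
import pytest
from hypothesis import settings

from mitochar.data import olepturum_gene_table
from mitochar.phylo import DistanceMatrix, PhyloNode, PhyloTree, patristic_distances
from mitochar.synth import generate_genome, olepturum_spec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_table():
    """The packaged reference mitogenome annotation (38 features)."""
    return olepturum_gene_table()


@pytest.fixture(scope="session")
def synth_record():
    """A self-consistent synthetic genome with the reference layout."""
    return generate_genome(olepturum_spec(seed=1))


def random_unrooted_tree(rng: np.random.Generator, n_taxa: int,
                         min_branch: float = 0.05, max_branch: float = 1.0) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths.

    Built by random cluster agglomeration down to a final trifurcation, the
    shape NJ itself emits.
    """
    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    clusters = [PhyloNode(name=f"t{i}") for i in range(n_taxa)]
    while len(clusters) > 3:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        clusters.append(PhyloNode(children=[(a, blen()), (b, blen())]))
    root = PhyloNode(children=[(c, blen()) for c in clusters])
    return PhyloTree(root)


def random_additive_matrix(rng: np.random.Generator, n_taxa: int) -> tuple[PhyloTree, DistanceMatrix]:
    tree = random_unrooted_tree(rng, n_taxa)
    return tree, patristic_distances(tree)
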