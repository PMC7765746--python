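"""K2P distances, neighbor-joining and bootstrap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitochar.phylo import (
    Alignment,
    DistanceMatrix,
    IncomparablePairError,
    SaturationError,
    bootstrap_support,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    patristic_distances,
    pq_proportions,
)
from mitochar.synth import SimSpec, simulate_alignment

from conftest import random_additive_matrix


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("AAAA", "AAAA", (0.0, 0.0, 4)),
        ("AG", "GA", (1.0, 0.0, 2)),       # both purine<->purine
        ("ACGT", "ATGT", (0.25, 0.0, 4)),  # one C<->T transition
        ("AAAA", "ACCA", (0.0, 0.5, 4)),
        ("A-GN", "AAGA", (0.0, 0.0, 2)),   # pairwise deletion
    ],
)
def test_pq_proportions(a, b, expected):
    assert pq_proportions(a, b) == expected


def test_pq_proportions_no_usable_sites():
    with pytest.raises(IncomparablePairError):
        pq_proportions("NN--", "AC-G")


@given(st.integers(0, 2**31 - 1))
def test_pq_matches_per_site_classification(seed):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list("ACGTN-"), size=80))
    b = "".join(rng.choice(list("ACGTN-"), size=80))
    usable = ts = tv = 0
    purines = {"A", "G"}
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        usable += 1
        if x != y:
            if (x in purines) == (y in purines):
                ts += 1
            else:
                tv += 1
    if usable == 0:
        return
    P, Q, n = pq_proportions(a, b)
    assert (P, Q, n) == (ts / usable, tv / usable, usable)


def test_k2p_distance_closed_form():
    assert k2p_distance(0.0, 0.0) == 0.0
    # -1/2 ln(0.75 * sqrt(0.9)), evaluated independently
    assert k2p_distance(0.1, 0.05) == pytest.approx(0.1701812, abs=1e-6)


def test_k2p_distance_series_limit():
    """d ~ P + Q to second order for small proportions."""
    P, Q = 1e-4, 5e-5
    assert k2p_distance(P, Q) == pytest.approx(P + Q, rel=1e-3)


def test_k2p_distance_saturation():
    with pytest.raises(SaturationError):
        k2p_distance(0.4, 0.3)
    with pytest.raises(SaturationError):
        k2p_distance(0.0, 0.5)


@given(st.floats(0.0, 0.3), st.floats(0.0, 0.2),
       st.floats(1e-4, 0.05), st.floats(1e-4, 0.05))
def test_k2p_distance_monotone_in_p_and_q(P, Q, dp, dq):
    if 1 - 2 * (P + dp) - (Q + dq) <= 0 or 1 - 2 * (Q + dq) <= 0:
        return
    d = k2p_distance(P, Q)
    assert k2p_distance(P + dp, Q) > d
    assert k2p_distance(P, Q + dq) > d


def test_nj_recovers_known_four_taxon_tree():
    """Additive matrix of ((A:1,B:2):1,(C:3,D:4)) comes back exactly."""
    taxa = ["A", "B", "C", "D"]
    path = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    m = np.zeros((4, 4))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                m[i, j] = path[tuple(sorted((a, b)))]
    tree = nj_tree(DistanceMatrix(taxa, m))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    back = patristic_distances(tree)
    assert np.allclose(back.values, m)


def test_nj_three_taxa_closed_form():
    m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
    got = {c.name: l for c, l in tree.root.children}
    assert got["a"] == pytest.approx(0.1)
    assert got["b"] == pytest.approx(0.2)
    assert got["c"] == pytest.approx(0.4)


def test_nj_rejects_asymmetric_matrix():
    m = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b", "c"], m)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_exact_on_random_additive_matrices(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(20):
        true_tree, dm = random_additive_matrix(rng, n_taxa)
        est = nj_tree(dm)
        assert est.bipartitions() == true_tree.bipartitions()
        assert np.allclose(patristic_distances(est).values, dm.values,
                           atol=1e-9)


def test_nj_topology_agrees_with_independent_implementation():
    """On noisy (non-additive) matrices our NJ and dendropy's NJ pick the
    same unrooted topology."""
    import io

    dendropy = pytest.importorskip("dendropy")
    for seed in range(5):
        rng = np.random.default_rng(200 + seed)
        _, dm = random_additive_matrix(rng, 4 + seed)
        noise = rng.uniform(0.0, 0.02, size=dm.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        vals = dm.values + noise
        mine = nj_tree(DistanceMatrix(dm.taxa, vals))

        csv = "," + ",".join(dm.taxa) + "\n" + "\n".join(
            t + "," + ",".join(str(v) for v in vals[i])
            for i, t in enumerate(dm.taxa)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        ref, allt = min(dm.taxa), frozenset(dm.taxa)
        theirs = set()
        for e in pdm.nj_tree().preorder_edge_iter():
            if e.head_node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            if ref in side:
                side = allt - side
            if 1 < len(side) < len(allt) - 1:
                theirs.add(side)
        assert mine.bipartitions() == theirs


def test_nj_ultrametric_matrix_matches_clustering_topology():
    # ultrametric: ((a:1,b:1):1,(c:1,d:1):1) heights -> additive too
    taxa = ["a", "b", "c", "d"]
    m = np.array([
        [0.0, 2.0, 4.0, 4.0],
        [2.0, 0.0, 4.0, 4.0],
        [4.0, 4.0, 0.0, 2.0],
        [4.0, 4.0, 2.0, 0.0],
    ])
    tree = nj_tree(DistanceMatrix(taxa, m))
    assert tree.bipartitions() == {frozenset({"c", "d"})}


def test_k2p_nj_pipeline_on_simulated_alignment():
    spec = SimSpec(
        newick="((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1);",
        length=5000, seed=42,
    )
    aln = simulate_alignment(spec)
    tree = nj_tree(k2p_matrix(aln))
    assert tree.bipartitions() == {frozenset({"C", "D"})} or \
        tree.bipartitions() == {frozenset({"A", "B"})}


def test_bootstrap_high_support_for_clean_split():
    spec = SimSpec(
        newick="((A:0.05,B:0.05):0.15,(C:0.05,D:0.05):0.15);",
        length=5000, seed=7,
    )
    tree = bootstrap_support(simulate_alignment(spec), replicates=100, seed=1)
    internal = [n for n, _ in _internal_nodes(tree)]
    assert internal and all(n.support >= 95 for n in internal)


def _internal_nodes(tree):
    out = []

    def walk(node):
        for child, l in node.children:
            if not child.is_leaf:
                out.append((child, l))
                walk(child)

    walk(tree.root)
    return out


def test_bootstrap_deterministic_given_seed():
    spec = SimSpec(newick="((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
                   length=800, seed=5)
    aln = simulate_alignment(spec)
    t1 = bootstrap_support(aln, replicates=50, seed=9)
    t2 = bootstrap_support(aln, replicates=50, seed=9)
    assert t1.newick() == t2.newick()


def test_identical_sequences_degenerate_tree_warns():
    aln = Alignment(["a", "b", "c", "d"], ["ACGT" * 10] * 4)
    with pytest.warns(UserWarning, match="degenerate|bipartition"):
        tree = bootstrap_support(aln, replicates=5, seed=0)
    assert all(l == pytest.approx(0.0) for _, l in _leaf_edges(tree))


def _leaf_edges(tree):
    out = []

    def walk(node):
        for child, l in node.children:
            if child.is_leaf:
                out.append((child, l))
            else:
                walk(child)

    walk(tree.root)
    return out
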