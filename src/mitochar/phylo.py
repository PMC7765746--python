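"""Kimura 2-parameter distances, neighbor-joining, and bootstrap supports.

The K2P model separates the two classes of nucleotide substitution:
transitions (A<->G, C<->T, observed proportion P) and transversions
(proportion Q). The corrected number of substitutions per site between two
aligned sequences is

    d = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap or an ambiguity are excluded
pairwise (pairwise deletion). Trees are built from the distance matrix with
the Saitou-Nei neighbor-joining algorithm, which recovers any additive
distance matrix exactly; node supports come from the nonparametric
bootstrap (column resampling).

All randomness is driven by an explicit seed; ties in the NJ criterion are
broken on the lexicographically smallest label pair, so the whole pipeline
is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PhyloNode",
    "PhyloTree",
    "SaturationError",
    "IncomparablePairError",
    "pq_proportions",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_support",
    "patristic_distances",
]


class SaturationError(ValueError):
    """Observed divergence too high for the K2P correction to be defined."""


class IncomparablePairError(ValueError):
    """No usable (ungapped, unambiguous) sites shared by a sequence pair."""


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,N,-}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_sequences(cls, seqs) -> "Alignment":
        """Build from a list of NucleotideSequence of equal length."""
        return cls([s.id for s in seqs], [s.residues for s in seqs])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self.ncols, size=self.ncols)
        arr = np.array([list(r) for r in self.rows])
        return Alignment(list(self.taxa), ["".join(row) for row in arr[:, idx]])


def pq_proportions(row_a: str, row_b: str) -> tuple[float, float, int]:
    """Transition (P) and transversion (Q) proportions for one pair.

    Sites where either row is not a plain A/C/G/T (gap or ambiguity) are
    excluded from numerator and denominator (pairwise deletion). Returns
    (P, Q, usable_sites).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    usable = transitions = transversions = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        usable += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        raise IncomparablePairError("no usable sites shared by the pair")
    return transitions / usable, transversions / usable, usable


def k2p_distance(P: float, Q: float) -> float:
    """K2P-corrected substitutions per site from the P, Q proportions.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)); requires 1 - 2P - Q > 0 and
    1 - 2Q > 0, otherwise the pair is saturated and a
    :class:`SaturationError` is raised.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} outside the K2P domain"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    """All pairwise K2P distances of an alignment (pairwise deletion)."""
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            P, Q, _ = pq_proportions(aln.rows[i], aln.rows[j])
            try:
                d[i, j] = d[j, i] = k2p_distance(P, Q)
            except SaturationError as exc:
                raise SaturationError(
                    f"{aln.taxa[i]} vs {aln.taxa[j]}: {exc}"
                ) from None
    return DistanceMatrix(list(aln.taxa), d)


@dataclass
class PhyloNode:
    """A node of an (un)rooted tree; children carry their branch lengths."""

    name: str = ""
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)
    support: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


_NEWICK_RESERVED = set("(),:;'\" \t")


def _quote(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class PhyloTree:
    """Unrooted tree from NJ: the root is the final degree-3 junction.

    Leaves are taxa; internal edges may carry integer bootstrap supports,
    serialized as internal-node labels in Newick.
    """

    root: PhyloNode

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self) -> str:
        def fmt(node: PhyloNode, length: Optional[float]) -> str:
            if node.is_leaf:
                body = _quote(node.name)
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = "" if node.support is None else str(node.support)
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, canonicalized as the side not
        containing the alphabetically first taxon."""
        all_taxa = frozenset(self.root.leaves())
        ref = min(all_taxa)
        out: set[frozenset] = set()
        for node, below in self._edges():
            side = frozenset(below)
            if ref in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side)
        return out

    def _edges(self):
        """Yield (child_node, leaf set below the edge above it)."""
        def walk(node: PhyloNode):
            for child, _ in node.children:
                yield child, child.leaves()
                yield from walk(child)

        yield from walk(self.root)

    def set_supports(self, supports: dict[frozenset, int]) -> None:
        all_taxa = frozenset(self.root.leaves())
        ref = min(all_taxa)
        for node, below in self._edges():
            if node.is_leaf:
                continue
            side = frozenset(below)
            if ref in side:
                side = all_taxa - side
            if side in supports:
                node.support = supports[side]


def nj_tree(dm: DistanceMatrix, allow_negative_branches: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor-joining on a distance matrix.

    Deterministic: ties in the rate-corrected criterion are broken on the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf). Negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch (the
    behavior of the common distance-phylogenetics tools), unless
    ``allow_negative_branches``.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if np.allclose(dm.values, 0.0):
        warnings.warn(
            "all pairwise distances are zero; tree is degenerate "
            "(topology decided by tie-breaking only)"
        )

    # active clusters: label -> (node, representative label for tie-break)
    nodes = {t: PhyloNode(name=t) for t in dm.taxa}
    labels = list(dm.taxa)
    d = {frozenset((a, b)): dm.get(a, b) for a in labels for b in labels if a != b}

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(labels) > 3:
        m = len(labels)
        r = {a: sum(dist(a, b) for b in labels if b != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if not allow_negative_branches:
            la, lb = _clamp_pair(la, lb)
        new_label = min(a, b)
        parent = PhyloNode(children=[(nodes[a], la), (nodes[b], lb)])
        for c in labels:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        labels = [c for c in labels if c not in (a, b)] + [new_label]
        nodes.pop(a), nodes.pop(b)
        nodes[new_label] = parent

    a, b, c = sorted(labels)
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    if not allow_negative_branches:
        la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    root = PhyloNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb = max(0.0, lb + la)
        la = 0.0
    elif lb < 0:
        la = max(0.0, la + lb)
        lb = 0.0
    return la, lb


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree.

    The tree metric: for an additive input matrix, NJ output satisfies
    ``patristic_distances(nj_tree(dm)) == dm`` exactly, which makes this
    the natural oracle for tree-reconstruction checks.
    """
    def leaf_dists(node: PhyloNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        out: dict[str, float] = {}
        groups = []
        for child, length in node.children:
            d = {k: v + length for k, v in leaf_dists(child).items()}
            groups.append(d)
            out.update(d)
        # record cross-pair distances through this node
        for i, gi in enumerate(groups):
            for gj in groups[i + 1:]:
                for a, da in gi.items():
                    for b, db in gj.items():
                        _cross[frozenset((a, b))] = da + db
        return out

    _cross: dict[frozenset, float] = {}
    leaf_dists(tree.root)
    taxa = sorted(tree.root.leaves())
    n = len(taxa)
    m = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _cross[frozenset((a, taxa[j]))]
    return DistanceMatrix(taxa, m)


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    allow_negative_branches: bool = False,
) -> PhyloTree:
    """K2P + NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; each
    replicate alignment is run through the same K2P + NJ pipeline, and the
    support of every internal bipartition of the original tree is the
    percentage of completed replicates containing it. Replicates whose
    distance matrix is saturated are skipped with a warning and supports
    are normalized by the number of completed replicates.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    tree = nj_tree(k2p_matrix(aln), allow_negative_branches)
    original = tree.bipartitions()
    if not original:
        warnings.warn("tree has no internal bipartitions (degenerate or <4 taxa)")
    rng = np.random.default_rng(seed)
    hits = {bp: 0 for bp in original}
    completed = 0
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = nj_tree(k2p_matrix(rep), allow_negative_branches)
        except (SaturationError, IncomparablePairError) as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        completed += 1
        rep_bps = rep_tree.bipartitions()
        for bp in original:
            if bp in rep_bps:
                hits[bp] += 1
    if completed == 0:
        raise SaturationError("all bootstrap replicates failed")
    supports = {
        bp: int(round(100.0 * h / completed)) for bp, h in hits.items()
    }
    tree.set_supports(supports)
    return tree
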