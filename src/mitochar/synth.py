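"""Deterministic generators for synthetic mitogenomes and alignments.

Real mitogenome records cannot be redistributed or fetched at test time, so
this module builds self-consistent stand-ins:

* :func:`generate_genome` plants an annotated gene layout into a random
  circular sequence — protein-coding genes get their requested start codon,
  their requested stop (a complete ``TAA``/``TAG`` triplet or a literal
  ``T``/``TA`` tail for incomplete stops) and no internal stop codons, with
  L-strand genes planted as reverse complements and the remaining positions
  drawn from a target base composition. The output always passes
  :func:`mitochar.core.validate_table` with zero findings.
* :func:`simulate_alignment` evolves a root sequence down a given tree
  under a two-rate (transition/transversion) continuous-time model — the
  generating process that the K2P distance inverts exactly.

Everything is reproducible from the spec's seed.

What these generators deliberately do not model: codon usage bias beyond
the base composition, tRNA secondary structure, tandem repeats or
heteroplasmy in the control region, and among-site rate variation in the
simulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .codons import VERTEBRATE_MITO
from .core import (
    GeneFeature,
    GeneTable,
    NucleotideSequence,
    feature_length,
    junction_gaps,
)
from .data import OLEPTURUM_BASE_FRACTIONS, olepturum_gene_table
from .io import ParsedRecord
from .phylo import Alignment

__all__ = [
    "GenomeSpec",
    "FeaturePlan",
    "SimSpec",
    "SpecError",
    "generate_genome",
    "simulate_alignment",
    "olepturum_spec",
]


class SpecError(ValueError):
    """A generator spec is internally inconsistent (detected before generation)."""


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = "ACGT"


@dataclass
class FeaturePlan:
    """One feature of a genome layout, with desired codon labels for PCGs."""

    locus: str
    category: str
    strand: str
    start: int
    stop: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None


@dataclass
class GenomeSpec:
    """Layout + composition targets + seed for one synthetic genome."""

    genome_length: int
    features: list[FeaturePlan]
    base_fractions: dict[str, float] = field(
        default_factory=lambda: dict(OLEPTURUM_BASE_FRACTIONS)
    )
    seed: int = 0
    taxon: str = "synthetic"

    @classmethod
    def from_gene_table(
        cls,
        table: GeneTable,
        seed: int = 0,
        fix_inconsistent_stops: bool = True,
        base_fractions: Optional[dict[str, float]] = None,
        taxon: Optional[str] = None,
    ) -> "GenomeSpec":
        """Derive a layout from an annotation table.

        A declared stop label incompatible with the gene's length mod 3
        (possible in published tables) cannot be planted; with
        ``fix_inconsistent_stops`` it is replaced by the length-consistent
        label (``T-``, ``TA-``, or ``TAA``), otherwise a :class:`SpecError`
        is raised.
        """
        plans = []
        for f in table.features:
            stop_codon = f.declared_stop_codon
            if f.category == "PCG" and stop_codon is not None:
                tail = feature_length(f, table.genome_length) % 3
                expected = {"T-": 1, "TA-": 2}.get(stop_codon, 0)
                if tail != expected:
                    if not fix_inconsistent_stops:
                        raise SpecError(
                            f"{f.locus}: stop {stop_codon!r} incompatible with "
                            f"length mod 3 == {tail}"
                        )
                    stop_codon = {0: "TAA", 1: "T-", 2: "TA-"}[tail]
            plans.append(FeaturePlan(
                f.locus, f.category, f.strand, f.start, f.stop,
                f.declared_start_codon if f.category == "PCG" else None,
                stop_codon if f.category == "PCG" else None,
                f.anticodon,
            ))
        return cls(
            genome_length=table.genome_length,
            features=plans,
            base_fractions=base_fractions or dict(OLEPTURUM_BASE_FRACTIONS),
            seed=seed,
            taxon=taxon if taxon is not None else (table.taxon or "synthetic"),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        return cls(
            genome_length=int(d["genome_length"]),
            features=[FeaturePlan(**f) for f in d["features"]],
            base_fractions=d.get("base_fractions") or dict(OLEPTURUM_BASE_FRACTIONS),
            seed=int(d.get("seed", 0)),
            taxon=d.get("taxon", "synthetic"),
        )

    @classmethod
    def from_json(cls, path) -> "GenomeSpec":
        return cls.from_dict(json.loads(open(path, encoding="utf-8").read()))


def olepturum_spec(seed: int = 0) -> GenomeSpec:
    """The packaged reference layout as a generator spec.

    Uses the published coordinates, strands and codon labels, with the one
    length-inconsistent stop label replaced by its length-consistent form
    so that the generated genome is self-consistent.
    """
    return GenomeSpec.from_gene_table(olepturum_gene_table(), seed=seed)


def _positions(plan: FeaturePlan, L: int) -> "np.ndarray":
    """Genome indices (0-based) of the feature's coding positions, 5'->3'."""
    flen = (plan.stop - plan.start + 1) if plan.stop >= plan.start \
        else (L - plan.start + 1) + plan.stop
    h = (plan.start - 1 + np.arange(flen)) % L
    return h if plan.strand == "H" else h[::-1]


def _validate_spec(spec: GenomeSpec) -> None:
    for p in spec.features:
        if p.category != "PCG":
            continue
        flen = len(_positions(p, spec.genome_length))
        if p.start_codon is not None and flen < 6:
            raise SpecError(f"{p.locus}: PCG of {flen} nt cannot hold start+stop")
        if p.stop_codon is not None:
            expected = {"T-": 1, "TA-": 2}.get(p.stop_codon, 0)
            if expected == 0 and p.stop_codon not in VERTEBRATE_MITO.stop_codons:
                raise SpecError(f"{p.locus}: {p.stop_codon!r} is not a stop label")
            if flen % 3 != expected:
                raise SpecError(
                    f"{p.locus}: stop {p.stop_codon!r} needs length % 3 == "
                    f"{expected}, got {flen % 3}"
                )


def generate_genome(spec: GenomeSpec) -> ParsedRecord:
    """Generate a self-consistent annotated circular genome from a spec.

    Start and stop codons (including literal ``T``/``TA`` tails) are
    planted as hard constraints; overlapping genes must agree on any shared
    constrained position or the spec is rejected. All other positions are
    drawn from the target base composition, then an iterative repair pass
    resamples unconstrained bases until no protein-coding gene contains an
    in-frame internal stop codon (overlapping reading frames are re-checked
    against each other until fixation). Deterministic given the seed.
    """
    _validate_spec(spec)
    L = spec.genome_length
    rng = np.random.default_rng(spec.seed)
    fracs = np.array([spec.base_fractions.get(b, 0.0) for b in _BASES])
    fracs = fracs / fracs.sum()
    genome = list("".join(rng.choice(list(_BASES), size=L, p=fracs)))

    def coded(plan: FeaturePlan, pos: int, base: str) -> str:
        return base if plan.strand == "H" else _COMP[base]

    # hard constraints on the reference strand, from planted codon labels
    hard: dict[int, str] = {}
    pcg_positions: dict[str, np.ndarray] = {}
    for p in spec.features:
        if p.category != "PCG":
            continue
        idx = _positions(p, L)
        pcg_positions[p.locus] = idx
        wanted: list[tuple[int, str]] = []
        if p.start_codon:
            wanted += list(zip(idx[:3], p.start_codon))
        if p.stop_codon:
            tail = {"T-": "T", "TA-": "TA"}.get(p.stop_codon, p.stop_codon)
            wanted += list(zip(idx[-len(tail):], tail))
        for pos, base in wanted:
            ref_base = coded(p, pos, base)
            if hard.get(pos, ref_base) != ref_base:
                raise SpecError(
                    f"{p.locus}: planted codon conflicts with an overlapping "
                    f"gene at position {pos + 1}"
                )
            hard[pos] = ref_base
    for pos, base in hard.items():
        genome[pos] = base

    stops = VERTEBRATE_MITO.stop_codons

    def codon_at(plan_idx: np.ndarray, strand: str, ci: int) -> tuple[str, list[int]]:
        pos3 = [int(plan_idx[3 * ci + k]) for k in range(3)]
        codon = "".join(
            genome[p] if strand == "H" else _COMP[genome[p]] for p in pos3
        )
        return codon, pos3

    pcgs = [p for p in spec.features if p.category == "PCG"]
    for _ in range(500):
        violations = []
        for p in pcgs:
            idx = pcg_positions[p.locus]
            ncod, tail = len(idx) // 3, len(idx) % 3
            for ci in range(ncod):
                codon, _ = codon_at(idx, p.strand, ci)
                is_terminator = tail == 0 and ci == ncod - 1
                if codon in stops and not is_terminator:
                    violations.append((p, ci))
        if not violations:
            break
        for p, ci in violations:
            idx = pcg_positions[p.locus]
            codon, pos3 = codon_at(idx, p.strand, ci)
            free = [pos for pos in pos3 if pos not in hard]
            if not free:
                raise SpecError(
                    f"{p.locus}: internal stop forced by overlapping constraints"
                )
            for _attempt in range(100):
                pos = free[int(rng.integers(len(free)))]
                genome[pos] = _BASES[int(rng.integers(4))]
                codon, _ = codon_at(idx, p.strand, ci)
                if codon not in stops:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise SpecError(f"{p.locus}: could not clear internal stop")
    else:  # pragma: no cover
        raise SpecError("internal-stop repair did not converge")

    sequence = NucleotideSequence("".join(genome), "circular", spec.taxon)
    features = []
    for p in spec.features:
        flen = len(_positions(p, L))
        features.append(GeneFeature(
            locus=p.locus,
            category=p.category,
            strand=p.strand,
            start=p.start,
            stop=p.stop,
            anticodon=p.anticodon,
            declared_start_codon=p.start_codon,
            declared_stop_codon=p.stop_codon,
            declared_size=flen,
        ))
    table = GeneTable(
        features=features,
        genome_length=L,
        circular=True,
        taxon=spec.taxon,
    )
    # declared intergenic values mirror the coordinate arithmetic so the
    # generated record validates cleanly
    if len(features) >= 2:
        for f, j in zip(features[1:], junction_gaps(table).junctions):
            f.declared_intergenic = j.gap
    return ParsedRecord(
        sequence, table, provenance=f"synthetic generate_genome(seed={spec.seed})"
    )


@dataclass
class SimSpec:
    """Tree + rates + length + seed for a simulated alignment.

    With the default rates (transition 0.5, per-transversion 0.25) the
    total substitution rate is 1, so branch lengths in the tree are in
    expected substitutions per site.
    """

    newick: str
    length: int
    transition_rate: float = 0.5
    transversion_rate: float = 0.25
    seed: int = 0
    root_fractions: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.transition_rate <= 0 or self.transversion_rate <= 0:
            raise SpecError("substitution rates must be positive")
        if self.length < 1:
            raise SpecError("alignment length must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        return cls(
            newick=d["newick"],
            length=int(d["length"]),
            transition_rate=float(d.get("transition_rate", 0.5)),
            transversion_rate=float(d.get("transversion_rate", 0.25)),
            seed=int(d.get("seed", 0)),
            root_fractions=d.get("root_fractions"),
        )

    @classmethod
    def from_json(cls, path) -> "SimSpec":
        return cls.from_dict(json.loads(open(path, encoding="utf-8").read()))


# encoding: A=0, G=1 (purines), C=2, T=3 (pyrimidines); the transition
# partner of i is i ^ 1, the transversion partners are the other class.
_ENC = {"A": 0, "G": 1, "C": 2, "T": 3}
_DEC = np.array(["A", "G", "C", "T"])


def _evolve(seq: np.ndarray, t: float, alpha: float, beta: float,
            rng: np.random.Generator) -> np.ndarray:
    """One branch of the two-rate model, via its exact transition kernel.

    P(same)          = 1/4 + 1/4 e^{-4 beta t} + 1/2 e^{-2 (alpha+beta) t}
    P(transition)    = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2 (alpha+beta) t}
    P(each transv.)  = 1/4 - 1/4 e^{-4 beta t}
    """
    if t <= 0:
        return seq.copy()
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    u = rng.random(seq.shape)
    out = seq.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = seq[ts_mask] ^ 1
    other_first = np.where(seq < 2, 2, 0)  # first base of the other class
    out[tv1_mask] = other_first[tv1_mask]
    out[tv2_mask] = other_first[tv2_mask] + 1
    return out


def simulate_alignment(spec: SimSpec) -> Alignment:
    """Evolve a root sequence down the spec's tree; leaves become rows.

    The generating process is exactly the two-rate model whose pairwise
    divergence the K2P distance estimates: for two leaves at total path
    length t, E[d_K2P] -> (transition_rate + 2 * transversion_rate) * t as
    the alignment grows.
    """
    tree = dendropy.Tree.get(data=spec.newick, schema="newick")
    rng = np.random.default_rng(spec.seed)
    fracs_map = spec.root_fractions or {b: 0.25 for b in _BASES}
    fracs = np.array([fracs_map.get(b, 0.0) for b in "AGCT"])
    fracs = fracs / fracs.sum()
    root_seq = rng.choice(4, size=spec.length, p=fracs)

    taxa: list[str] = []
    rows: list[str] = []

    def walk(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = _evolve(
                seq, t, spec.transition_rate, spec.transversion_rate, rng
            )
            if child.is_leaf():
                taxa.append(child.taxon.label)
                rows.append("".join(_DEC[child_seq]))
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root_seq)
    if not taxa:
        raise SpecError("tree has no leaves")
    return Alignment(taxa, rows)
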