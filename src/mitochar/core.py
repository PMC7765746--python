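"""Domain model for annotated circular mitochondrial genomes.

A vertebrate mitogenome is a circular DNA molecule of ~16.6 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one non-coding control
region (D-loop). Genes are densely packed, frequently abutting, overlapping
by a few bases, or separated by short intergenic spacers, and a minority are
encoded on the light (L) strand. This module provides the annotation types
(:class:`GeneFeature`, :class:`GeneTable`) plus the gene-map arithmetic:
feature lengths on a circle, junction gap/overlap accounting, gene-order
strings and an annotation validator.

Coordinates are 1-based and fully inclusive, the GenBank convention. A
feature that spans the circular origin is expressed with ``start > stop``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

__all__ = [
    "NucleotideSequence",
    "GeneFeature",
    "GeneTable",
    "Junction",
    "JunctionReport",
    "Finding",
    "CoordinateError",
    "reverse_complement",
    "feature_length",
    "feature_sequence",
    "junction_gaps",
    "validate_table",
    "gene_order_string",
    "canonical_locus",
    "PCG_LOCI",
]

Category = Literal["PCG", "tRNA", "rRNA", "control"]
Strand = Literal["H", "L"]

# '-' is tolerated so aligned sequences (alignment FASTA dialect) can be
# carried by the same type; composition and codon logic never count it.
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")
_ALPHABET = frozenset("ACGTN-")

#: Canonical names of the 13 vertebrate mitochondrial protein-coding genes,
#: in the conventional gene-map order.
PCG_LOCI = (
    "ND1", "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "Cytb",
)

# GenBank annotations are notoriously inconsistent about locus spelling;
# harmonize the common synonyms to one canonical name each.
_LOCUS_SYNONYMS = {
    "COX1": "COI", "CO1": "COI", "COXI": "COI",
    "COX2": "COII", "CO2": "COII", "COXII": "COII",
    "COX3": "COIII", "CO3": "COIII", "COXIII": "COIII",
    "CYTB": "Cytb", "COB": "Cytb", "CYT B": "Cytb", "MT-CYB": "Cytb",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "RRNS": "12S-rRNA", "12S": "12S-rRNA", "12S RRNA": "12S-rRNA",
    "12S-RRNA": "12S-rRNA", "S-RRNA": "12S-rRNA",
    "RRNL": "16S-rRNA", "16S": "16S-rRNA", "16S RRNA": "16S-rRNA",
    "16S-RRNA": "16S-rRNA", "L-RRNA": "16S-rRNA",
    "D-LOOP": "D-loop", "CONTROL REGION": "D-loop", "CR": "D-loop",
}


def canonical_locus(name: str) -> str:
    """Map a locus name to its canonical spelling (``COX1`` -> ``COI`` ...).

    Unknown names pass through verbatim with a warning so that exotic
    annotations remain usable.
    """
    key = name.strip().upper().replace("_", "")
    if key in _LOCUS_SYNONYMS:
        return _LOCUS_SYNONYMS[key]
    canon = {l.upper(): l for l in PCG_LOCI}
    if key in canon:
        return canon[key]
    if key.startswith("TRNA"):
        return "tRNA-" + name.strip()[5:].capitalize() if "-" in name else name.strip()
    if name.strip() not in ("D-loop",) and not name.strip().startswith("tRNA"):
        if key not in ("12S-RRNA", "16S-RRNA", "D-LOOP"):
            warnings.warn(f"unknown locus name {name!r} passed through verbatim")
    return name.strip()


class CoordinateError(ValueError):
    """A feature coordinate falls outside ``[1, genome_length]``."""


def _normalize_residues(residues: str) -> str:
    s = residues.upper().replace("U", "T")
    if not set(s) <= _ALPHABET:
        bad = sorted(set(s) - _ALPHABET)
        warnings.warn(f"ambiguity codes {bad} mapped to N")
        s = "".join(c if c in _ALPHABET else "N" for c in s)
    return s


def reverse_complement(residues: str) -> str:
    """Reverse complement over the ``ACGTN`` alphabet (an involution)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class NucleotideSequence:
    """A DNA sequence with linear or circular topology.

    Residues are normalized to uppercase ``ACGTN`` (``U`` -> ``T``, other
    ambiguity codes -> ``N`` with a warning).
    """

    residues: str
    topology: Literal["linear", "circular"] = "linear"
    id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        self.residues = _normalize_residues(self.residues)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            reverse_complement(self.residues), self.topology, self.id
        )


@dataclass
class GeneFeature:
    """One annotated gene on the genome.

    ``declared_*`` fields hold values transcribed from an annotation table
    verbatim; they are never recomputed or overwritten here — discrepancies
    between declared and coordinate-derived values are surfaced by
    :func:`validate_table`.
    """

    locus: str
    category: Category
    strand: Strand
    start: int
    stop: int
    anticodon: Optional[str] = None
    declared_start_codon: Optional[str] = None
    declared_stop_codon: Optional[str] = None
    declared_size: Optional[int] = None
    declared_intergenic: Optional[int] = None

    @property
    def wraps(self) -> bool:
        """True when the feature spans the circular origin (start > stop)."""
        return self.start > self.stop


@dataclass
class GeneTable:
    """Ordered gene annotation of one (usually circular) genome."""

    features: list[GeneFeature]
    genome_length: int
    circular: bool = True
    taxon: str = ""
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        for f in self.features:
            _check_coords(f, self.genome_length)

    def by_locus(self, locus: str) -> GeneFeature:
        canon = canonical_locus(locus)
        for f in self.features:
            if f.locus == locus or canonical_locus(f.locus) == canon:
                return f
        raise KeyError(locus)

    def of_category(self, category: Category) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]


def _check_coords(feature: GeneFeature, genome_length: int) -> None:
    for coord in (feature.start, feature.stop):
        if not 1 <= coord <= genome_length:
            raise CoordinateError(
                f"{feature.locus}: coordinate {coord} outside [1, {genome_length}]"
            )


def feature_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature, handling wrap across the circular origin.

    Non-wrapping: ``stop - start + 1``. Wrapping (``start > stop``):
    ``(L - start + 1) + stop``.
    """
    _check_coords(feature, genome_length)
    if feature.wraps:
        return (genome_length - feature.start + 1) + feature.stop
    return feature.stop - feature.start + 1


def feature_sequence(seq: NucleotideSequence, feature: GeneFeature) -> str:
    """Coding-sense residues of a feature.

    Resolves circular wrap and reverse-complements L-strand features so the
    returned string reads 5'->3' in the sense of the gene.
    """
    L = len(seq)
    _check_coords(feature, L)
    if feature.wraps:
        if seq.topology != "circular":
            raise CoordinateError(
                f"{feature.locus}: wrapping feature on a linear sequence"
            )
        sub = seq.residues[feature.start - 1:] + seq.residues[: feature.stop]
    else:
        sub = seq.residues[feature.start - 1: feature.stop]
    return reverse_complement(sub) if feature.strand == "L" else sub


@dataclass
class Junction:
    """Gap between two consecutive features: negative = overlap."""

    upstream: str
    downstream: str
    gap: int


@dataclass
class JunctionReport:
    """Totals of overlaps and spacers over the junctions of a gene table."""

    junctions: list[Junction]
    overlap_bp: int = 0
    overlap_junction_count: int = 0
    spacer_bp: int = 0
    spacer_region_count: int = 0
    largest_spacer: Optional[Junction] = None
    largest_overlap: Optional[Junction] = None

    def __post_init__(self) -> None:
        negs = [j for j in self.junctions if j.gap < 0]
        poss = [j for j in self.junctions if j.gap > 0]
        self.overlap_bp = sum(-j.gap for j in negs)
        self.overlap_junction_count = len(negs)
        self.spacer_bp = sum(j.gap for j in poss)
        self.spacer_region_count = len(poss)
        self.largest_spacer = max(poss, key=lambda j: j.gap, default=None)
        self.largest_overlap = min(negs, key=lambda j: j.gap, default=None)


def junction_gaps(table: GeneTable, include_origin_junction: bool = False) -> JunctionReport:
    """Gap/overlap accounting over consecutive feature pairs.

    For each consecutive pair in ascending-start order (H- and L-strand
    features interleaved, as laid out in a standard annotation table),
    ``gap = start(downstream) - stop(upstream) - 1``; a negative gap is an
    overlap of ``|gap|`` bp, a positive gap an intergenic spacer. The
    junction across the circular origin (last feature back to the first) is
    included only on request, since published tables typically omit it.
    """
    feats = table.features
    if len(feats) < 2:
        raise ValueError("need at least two features")
    starts = [f.start for f in feats]
    if starts != sorted(starts):
        raise ValueError("features are not in ascending-start order")

    junctions = [
        Junction(up.locus, down.locus, down.start - up.stop - 1)
        for up, down in zip(feats, feats[1:])
    ]
    if include_origin_junction and table.circular:
        last, first = feats[-1], feats[0]
        # going on around the circle: residues strictly between last.stop
        # and first.start
        gap = (table.genome_length - last.stop) + (first.start - 1)
        junctions.append(Junction(last.locus, first.locus, gap))
    return JunctionReport(junctions)


@dataclass
class Finding:
    """One validator warning (never fatal)."""

    kind: str
    locus: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.locus}: {self.message}"


_EXPECTED_CATEGORY_COUNTS = {"PCG": 13, "tRNA": 22, "rRNA": 2, "control": 1}


def validate_table(
    table: GeneTable, sequence: Optional[NucleotideSequence] = None
) -> list[Finding]:
    """Cross-check declared annotation values against coordinate arithmetic.

    Reports, without ever mutating the table:

    * declared size != stop - start + 1 (wrap-aware),
    * declared intergenic value != recomputed junction gap,
    * a declared PCG stop label inconsistent with CDS length mod 3
      (a complete stop needs length % 3 == 0, ``T-`` needs 1, ``TA-`` 2),
    * with a sequence: declared start/stop codon != sequence-derived codon,
    * missing canonical gene complements (13 PCG / 22 tRNA / 2 rRNA / 1
      control region).
    """
    findings: list[Finding] = []
    L = table.genome_length

    for f in table.features:
        derived = feature_length(f, L)
        if f.declared_size is not None and f.declared_size != derived:
            findings.append(Finding(
                "size", f.locus,
                f"declared size {f.declared_size} != derived {derived}",
            ))
        if f.category == "PCG" and f.declared_stop_codon is not None:
            tail = derived % 3
            label = f.declared_stop_codon
            expected_tail = {"T-": 1, "TA-": 2}.get(label, 0)
            if tail != expected_tail:
                findings.append(Finding(
                    "stop_frame", f.locus,
                    f"declared stop {label!r} implies tail {expected_tail} nt "
                    f"but length {derived} % 3 == {tail}",
                ))

    if len(table.features) >= 2:
        report = junction_gaps(table)
        # junction i sits upstream of feature i+1 (loci can repeat, e.g.
        # two tRNA-Leu genes, so match positionally)
        for f, j in zip(table.features[1:], report.junctions):
            if f.declared_intergenic is not None and f.declared_intergenic != j.gap:
                findings.append(Finding(
                    "intergenic", f.locus,
                    f"declared intergenic {f.declared_intergenic} != derived "
                    f"{j.gap}",
                ))

    if sequence is not None:
        # local import: codon extraction needs the genetic code machinery
        from .codons import extract_codons_from_cds, stop_label_of

        for f in table.of_category("PCG"):
            cds = feature_sequence(sequence, f)
            if len(cds) < 6:
                findings.append(Finding("cds", f.locus, "CDS shorter than 6 nt"))
                continue
            ext = extract_codons_from_cds(f.locus, cds)
            if (f.declared_start_codon is not None
                    and ext.start_label != f.declared_start_codon):
                findings.append(Finding(
                    "start_codon", f.locus,
                    f"declared start {f.declared_start_codon} != observed "
                    f"{ext.start_label}",
                ))
            if f.declared_stop_codon is not None:
                observed = stop_label_of(ext)
                if observed != f.declared_stop_codon:
                    findings.append(Finding(
                        "stop_codon", f.locus,
                        f"declared stop {f.declared_stop_codon} != observed "
                        f"{observed}",
                    ))

    counts = {cat: len(table.of_category(cat)) for cat in _EXPECTED_CATEGORY_COUNTS}
    for cat, expected in _EXPECTED_CATEGORY_COUNTS.items():
        if counts[cat] != expected:
            findings.append(Finding(
                "complement", cat,
                f"{counts[cat]} {cat} features annotated, expected {expected}",
            ))
    return findings


def gene_order_string(table: GeneTable) -> str:
    """Canonical comma-separated gene order with strand signs.

    L-strand loci are prefixed with ``-`` so that two genomes share a gene
    order iff their strings are equal.
    """
    tokens = [
        ("-" if f.strand == "L" else "") + f.locus for f in table.features
    ]
    return ",".join(tokens)
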