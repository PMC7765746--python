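"""Codon usage under the vertebrate mitochondrial genetic code.

Mitochondrial protein-coding genes (PCGs) are translated with NCBI
translation table 2: TGA codes Trp, ATA codes Met, and AGA/AGG are stops.
Many mitochondrial genes end on an incomplete stop codon — a terminal ``T``
or ``TA`` at the gene boundary that is completed to ``TAA`` by
post-transcriptional polyadenylation; these are labelled ``T-`` and ``TA-``.

This module extracts codons from annotated genes (strand- and wrap-aware),
classifies start/stop codons, and computes the two standard usage
statistics:

* RSCU — relative synonymous codon usage, a codon's count divided by the
  mean count over its synonymous family (1 = unbiased);
* CDpT — codons per thousand codons for each amino-acid family, with Ser
  split into Ser (TCN) and Ser2 (AGY) as is conventional for mitogenomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

from .core import GeneTable, NucleotideSequence, feature_length, feature_sequence

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "CodonExtraction",
    "CodonUsageTable",
    "MalformedCDSError",
    "extract_codons",
    "extract_codons_from_cds",
    "stop_label_of",
    "classify_start",
    "rscu",
    "cdpt",
    "pcg_codon_report",
]

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


class MalformedCDSError(ValueError):
    """CDS too short to carry a start and a stop."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with its start and stop codon sets."""

    table_id: int
    forward: Mapping[str, str]  # codon -> one-letter amino acid (stops absent)
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 2) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )

    def family_of(self, codon: str, split_ser: bool = False) -> Optional[str]:
        """Three-letter amino-acid family of a codon; None for stops.

        With ``split_ser`` the serine codons are partitioned into the
        TCN family (``Ser``) and the AGY family (``Ser2``).
        """
        aa = self.forward.get(codon)
        if aa is None:
            return None
        name = _AA3[aa]
        if split_ser and aa == "S":
            return "Ser2" if codon.startswith("AG") else "Ser"
        return name

    def families(self, split_ser: bool = False) -> dict[str, list[str]]:
        """Synonymous families: family name -> sorted member codons."""
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.forward):
            fams.setdefault(self.family_of(codon, split_ser), []).append(codon)
        return fams


#: Vertebrate mitochondrial code (NCBI transl_table 2).
VERTEBRATE_MITO = GeneticCode.from_ncbi(2)


@dataclass
class CodonExtraction:
    """Codons of one gene read in frame from its annotated start.

    ``3 * len(complete_codons) + len(incomplete_tail)`` always equals the
    CDS length. ``internal_stop_positions`` lists 0-based codon indices of
    in-frame stop codons before the terminator (annotation defects, not
    fatal).
    """

    gene: str
    complete_codons: list[str]
    incomplete_tail: str
    start_label: str
    internal_stop_positions: list[int] = field(default_factory=list)


def stop_label_of(extraction: CodonExtraction) -> str:
    """Observed termination label: a full stop triplet, ``T-`` or ``TA-``."""
    n = len(extraction.incomplete_tail)
    if n == 1:
        return "T-"
    if n == 2:
        return "TA-"
    return extraction.complete_codons[-1]


def extract_codons_from_cds(
    gene: str, cds: str, code: GeneticCode = VERTEBRATE_MITO
) -> CodonExtraction:
    """Split a coding-sense CDS string into complete codons and a 0-2 nt tail."""
    if len(cds) < 6:
        raise MalformedCDSError(f"{gene}: CDS of {len(cds)} nt is shorter than 6")
    ncod = len(cds) // 3
    codons = [cds[3 * i: 3 * i + 3] for i in range(ncod)]
    tail = cds[3 * ncod:]
    # the final complete codon is the terminator when there is no tail
    internal = codons[:-1] if not tail else codons
    stops = [i for i, c in enumerate(internal) if c in code.stop_codons]
    if stops:
        warnings.warn(f"{gene}: internal stop codon(s) at codon index {stops}")
    return CodonExtraction(
        gene=gene,
        complete_codons=codons,
        incomplete_tail=tail,
        start_label=codons[0],
        internal_stop_positions=stops,
    )


def extract_codons(
    record, gene: str, code: GeneticCode = VERTEBRATE_MITO
) -> CodonExtraction:
    """Extract the codons of one annotated PCG from a parsed record.

    The CDS is taken in coding sense: L-strand genes are
    reverse-complemented and origin-wrapping genes are unwrapped before
    reading triplets from the annotated first position.
    """
    feature = record.table.by_locus(gene)
    if feature.category != "PCG":
        raise ValueError(f"{gene} is annotated as {feature.category}, not PCG")
    cds = feature_sequence(record.sequence, feature)
    return extract_codons_from_cds(feature.locus, cds, code)


def classify_start(
    extraction: CodonExtraction, code: GeneticCode = VERTEBRATE_MITO
) -> str:
    """``canonical`` (ATG), ``alternative`` (other initiators of the code),
    or ``invalid``."""
    c = extraction.start_label
    if c == "ATG":
        return "canonical"
    if c in code.start_codons:
        return "alternative"
    return "invalid"


def rscu(
    counts: Mapping[str, int], code: GeneticCode = VERTEBRATE_MITO
) -> dict[str, float]:
    """Relative synonymous codon usage.

    RSCU(c) = count(c) / mean count over the synonymous family of c. Stop
    codons are excluded from families; a family with zero total usage gets
    RSCU 0 for all members. For every used family the family mean is 1 by
    construction.
    """
    out: dict[str, float] = {}
    for members in code.families().values():
        total = sum(counts.get(c, 0) for c in members)
        if total == 0:
            out.update({c: 0.0 for c in members})
        else:
            mean = total / len(members)
            out.update({c: counts.get(c, 0) / mean for c in members})
    return out


def cdpt(
    counts: Mapping[str, int], code: GeneticCode = VERTEBRATE_MITO
) -> dict[str, float]:
    """Codons per thousand codons per amino-acid family (Ser split TCN/AGY).

    CDpT(family) = 1000 * family count / total codon count; the values sum
    to 1000 up to rounding.
    """
    total = sum(v for c, v in counts.items() if c in code.forward)
    if total == 0:
        raise ValueError("no sense codons counted")
    out: dict[str, float] = {}
    for fam, members in code.families(split_ser=True).items():
        out[fam] = 1000.0 * sum(counts.get(c, 0) for c in members) / total
    return out


@dataclass
class CodonUsageTable:
    """Aggregate codon usage over all PCGs of one genome."""

    counts: dict[str, int]
    rscu: dict[str, float]
    cdpt: dict[str, float]
    #: floor(sum of PCG lengths / 3): the total including incomplete
    #: terminal codons, the number conventionally reported for mitogenomes.
    total_codons: int
    #: complete sense codons actually tallied (stops and tails excluded)
    counted_codons: int

    def rows(self, code: GeneticCode = VERTEBRATE_MITO) -> list[dict]:
        """Fig-style rows sorted by family then codon: codon,
        amino_acid_family, count, rscu, cdpt_family."""
        rows = []
        for fam, members in sorted(code.families(split_ser=True).items()):
            for c in members:
                rows.append({
                    "codon": c,
                    "amino_acid_family": fam,
                    "count": self.counts.get(c, 0),
                    "rscu": self.rscu.get(c, 0.0),
                    "cdpt_family": self.cdpt.get(fam, 0.0),
                })
        return rows


def pcg_codon_report(
    record,
    code: GeneticCode = VERTEBRATE_MITO,
    initiator_as_met: bool = False,
) -> tuple[CodonUsageTable, list[CodonExtraction]]:
    """Codon-usage table plus per-gene extractions over all annotated PCGs.

    Counting conventions: ``total_codons`` is floor(concatenated PCG
    length / 3), the figure conventionally quoted for mitogenomes (it
    counts incomplete terminal codons); the RSCU/CDpT tallies use complete
    sense codons only — stop codons and 1-2 nt tails are excluded.
    Initiator triplets are counted literally (GTG under Val) unless
    ``initiator_as_met`` re-assigns them to ATG.
    """
    pcgs = record.table.of_category("PCG")
    if not pcgs:
        raise ValueError("record contains no PCG features")
    extractions = [extract_codons(record, f.locus, code) for f in pcgs]
    total_len = sum(feature_length(f, record.table.genome_length) for f in pcgs)

    counts: dict[str, int] = {}
    for ext in extractions:
        codons = list(ext.complete_codons)
        if not ext.incomplete_tail and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        if initiator_as_met and codons and codons[0] in code.start_codons:
            codons[0] = "ATG"
        for c in codons:
            if c in code.forward:
                counts[c] = counts.get(c, 0) + 1

    table = CodonUsageTable(
        counts=counts,
        rscu=rscu(counts, code),
        cdpt=cdpt(counts, code),
        total_codons=total_len // 3,
        counted_codons=sum(counts.values()),
    )
    return table, extractions
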