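"""Cross-genome comparison matrices.

Two summaries that mitogenome announcements conventionally print for a
panel of congeners: the per-gene start/stop codon matrix (one row per
taxon, one column per protein-coding gene, cells like ``ATG/T-``) and the
genome-level length/composition/skew table. Locus names are harmonized
through the synonym map in :mod:`mitochar.core` so records annotated as
``COX1`` and ``COI`` land in the same column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .codons import extract_codons, stop_label_of
from .composition import base_composition
from .core import PCG_LOCI, canonical_locus

__all__ = ["StartStopMatrix", "GenomeSummaryRow", "startstop_matrix", "genome_summary"]


@dataclass
class StartStopMatrix:
    """Start/stop codon labels per taxon (rows) and PCG locus (columns).

    ``differences`` lists, per locus, the taxa whose label pair deviates
    from the column's majority label (ties broken toward the
    lexicographically smallest label).
    """

    taxa: list[str]
    loci: list[str]
    cells: dict[tuple[str, str], str]
    differences: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def row(self, taxon: str) -> list[str]:
        return [self.cells.get((taxon, locus), "") for locus in self.loci]

    def to_tsv(self) -> str:
        lines = ["Species\t" + "\t".join(self.loci)]
        for t in self.taxa:
            lines.append(t + "\t" + "\t".join(self.row(t)))
        return "\n".join(lines) + "\n"


def startstop_matrix(records) -> StartStopMatrix:
    """Build the start/stop matrix over several parsed records.

    Missing genes yield empty cells with a warning; duplicate taxon labels
    are an error. The difference report covers every locus with at least
    two distinct non-empty label pairs.
    """
    taxa = [r.table.taxon or r.sequence.id or f"record{i + 1}"
            for i, r in enumerate(records)]
    if len(set(taxa)) != len(taxa):
        raise ValueError(f"duplicate taxon labels: {taxa}")

    loci = list(PCG_LOCI)
    cells: dict[tuple[str, str], str] = {}
    for taxon, record in zip(taxa, records):
        present = {canonical_locus(f.locus): f
                   for f in record.table.of_category("PCG")}
        for locus in loci:
            if locus not in present:
                warnings.warn(f"{taxon}: no {locus} annotation; empty cell")
                continue
            ext = extract_codons(record, present[locus].locus)
            cells[(taxon, locus)] = f"{ext.start_label}/{stop_label_of(ext)}"

    differences: dict[str, list[tuple[str, str]]] = {}
    for locus in loci:
        col = [(t, cells[(t, locus)]) for t in taxa if (t, locus) in cells]
        labels = [v for _, v in col]
        if len(set(labels)) < 2:
            continue
        majority = max(sorted(set(labels)), key=labels.count)
        differences[locus] = [(t, v) for t, v in col if v != majority]
    return StartStopMatrix(taxa, loci, cells, differences)


@dataclass
class GenomeSummaryRow:
    taxon: str
    accession: Optional[str]
    length: int
    at_content: float
    at_skew: Optional[float]
    gc_skew: Optional[float]


def genome_summary(records) -> list[GenomeSummaryRow]:
    """Genome-level length / A+T% / skew rows, sorted by taxon."""
    rows = []
    for r in records:
        s = base_composition(r.sequence, "genome")
        rows.append(GenomeSummaryRow(
            taxon=r.table.taxon or r.sequence.id,
            accession=r.table.accession,
            length=len(r.sequence),
            at_content=s.at_content,
            at_skew=s.at_skew,
            gc_skew=s.gc_skew,
        ))
    return sorted(rows, key=lambda row: row.taxon)
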