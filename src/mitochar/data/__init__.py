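"""Packaged reference data.

Ships the published gene annotation of the Onychostoma lepturum
mitochondrial genome (GenBank MT258556, 16,598 bp): locus coordinates,
strands, declared sizes, start/stop codon labels, anticodons and the
intergenic column, transcribed verbatim from the announcement. The
transcription keeps the published values exactly as printed — including a
couple of internal inconsistencies (an intergenic value that differs from
the coordinate arithmetic, and a COIII stop label incompatible with the
gene's length mod 3) — so that :func:`mitochar.core.validate_table` can
surface them rather than silently "fixing" the record.

Also exposes the published whole-genome base percentages of the same
record, useful as composition targets for the synthetic-genome generator.
"""

from __future__ import annotations

from importlib import resources

from ..core import GeneTable
from ..io import read_gene_table

__all__ = [
    "olepturum_gene_table",
    "OLEPTURUM_GENOME_PERCENT",
    "OLEPTURUM_BASE_FRACTIONS",
]

#: Published whole-genome base composition of MT258556 (percent).
OLEPTURUM_GENOME_PERCENT = {"A": 31.3, "G": 16.2, "T": 24.0, "C": 28.6}

#: The same composition as fractions, for sequence generators.
OLEPTURUM_BASE_FRACTIONS = {b: p / 100.0 for b, p in OLEPTURUM_GENOME_PERCENT.items()}


def olepturum_gene_table() -> GeneTable:
    """The packaged 38-row annotation of the O. lepturum mitogenome.

    13 PCGs, 22 tRNAs, 2 rRNAs and the D-loop, ordered by ascending start,
    with all declared columns stored verbatim.
    """
    ref = resources.files(__package__) / "onychostoma_lepturum_mt258556.tsv"
    with resources.as_file(ref) as path:
        return read_gene_table(path)
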