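"""Base composition and strand-skew statistics.

Animal mitochondrial genomes show marked compositional strand asymmetry,
conventionally quantified by

* AT-skew = (A - T) / (A + T)
* GC-skew = (G - C) / (G + C)

computed on the heavy (reference) strand or on functional partitions of the
genome. This module computes per-partition base composition summaries: the
whole genome, the concatenated protein-coding genes and their three codon
positions, the rRNAs, the tRNAs and the control region.

Percentages are kept at full precision internally; reporting rounds to one
decimal for percentages and three decimals for skews.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .core import (
    GeneTable,
    NucleotideSequence,
    feature_length,
    feature_sequence,
)

__all__ = [
    "CompositionSummary",
    "UndefinedCompositionError",
    "base_composition",
    "skews",
    "partition_composition",
    "codon_position_subsequences",
]

_BASES = ("T", "C", "A", "G")


class UndefinedCompositionError(ValueError):
    """Sequence contains no unambiguous A/C/G/T bases."""


def skews(
    counts: Mapping[str, float],
) -> tuple[Optional[float], Optional[float]]:
    """AT- and GC-skew from base tallies (counts or percentages).

    Exact formula application; both are scale-invariant, so percentages and
    raw counts give identical results. A zero denominator yields ``None``
    for that skew rather than an exception.
    """
    a, t = counts.get("A", 0), counts.get("T", 0)
    g, c = counts.get("G", 0), counts.get("C", 0)
    if min(a, t, g, c) < 0:
        raise ValueError("negative base count")
    at = (a - t) / (a + t) if a + t > 0 else None
    gc = (g - c) / (g + c) if g + c > 0 else None
    return at, gc


@dataclass
class CompositionSummary:
    """Composition of one partition: counts, percentages, A+T%, skews.

    ``length`` is the number of residues in the partition; ambiguous bases
    (N) are excluded from both the numerator and denominator of every
    percentage. ``at_skew``/``gc_skew`` are ``None`` when undefined
    (zero denominator).
    """

    partition: str
    length: int
    counts: dict[str, int]
    pct: dict[str, float]
    at_content: float
    at_skew: Optional[float]
    gc_skew: Optional[float]

    def as_row(self) -> dict:
        """Reporting-precision row (percentages 1 dp, skews 3 dp)."""
        def r3(x):
            return None if x is None else round(x, 3)

        return {
            "partition": self.partition,
            "length": self.length,
            **{f"{b}%": round(self.pct[b], 1) for b in _BASES},
            "A+T%": round(self.at_content, 1),
            "AT-skew": r3(self.at_skew),
            "GC-skew": r3(self.gc_skew),
        }


def base_composition(
    seq: Union[NucleotideSequence, str], partition: str = "custom"
) -> CompositionSummary:
    """Tally A/C/G/T over a sequence and derive percentages and skews."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if not residues:
        raise UndefinedCompositionError("empty sequence")
    tally = Counter(residues)
    counts = {b: tally.get(b, 0) for b in _BASES}
    total = sum(counts.values())
    if total == 0:
        raise UndefinedCompositionError(
            f"partition {partition!r} has no unambiguous bases"
        )
    pct = {b: 100.0 * counts[b] / total for b in _BASES}
    at, gc = skews(counts)
    return CompositionSummary(
        partition=partition,
        length=len(residues),
        counts=counts,
        pct=pct,
        at_content=pct["A"] + pct["T"],
        at_skew=at,
        gc_skew=gc,
    )


def codon_position_subsequences(record) -> tuple[str, str, str]:
    """Concatenated 1st/2nd/3rd codon-position residues over all PCGs.

    Each protein-coding gene is taken in coding sense; positions are
    assigned 1,2,3 cyclically from its annotated first base, so a gene with
    an incomplete terminal codon contributes its 1-2 trailing nucleotides
    to positions 1 (and 2) only.
    """
    parts: list[list[str]] = [[], [], []]
    for f in record.table.of_category("PCG"):
        cds = feature_sequence(record.sequence, f)
        for i in range(3):
            parts[i].append(cds[i::3])
    return tuple("".join(p) for p in parts)


_PARTITION_LABELS = {
    "PCG": "PCGs",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "control": "D-loop",
}


def partition_composition(record) -> list[CompositionSummary]:
    """Table of composition summaries per functional partition.

    Partitions: whole genome (reference strand as deposited), concatenated
    PCGs, their three codon positions, rRNAs, tRNAs, and the control
    region. Gene partitions are strand-corrected to coding sense before
    counting; each partition's length equals the sum of its member feature
    lengths. Partitions with no annotated members are omitted with a
    warning.
    """
    seq, table = record.sequence, record.table
    out = [base_composition(seq, "genome")]

    concat: dict[str, str] = {}
    for cat, label in _PARTITION_LABELS.items():
        members = table.of_category(cat)
        if not members:
            warnings.warn(f"no {cat} features; partition {label!r} omitted")
            continue
        concat[label] = "".join(feature_sequence(seq, f) for f in members)

    if "PCGs" in concat:
        out.append(base_composition(concat.pop("PCGs"), "PCGs"))
        for i, sub in enumerate(codon_position_subsequences(record), start=1):
            out.append(base_composition(sub, f"codon_pos{i}"))
    for label in ("rRNA", "tRNA", "D-loop"):
        if label in concat:
            out.append(base_composition(concat[label], label))
    return out
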