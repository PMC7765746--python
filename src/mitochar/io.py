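"""Readers and writers: GenBank flat files, FASTA, gene-table TSV, Newick.

GenBank and FASTA parsing/writing go through Biopython; this module maps
between Biopython records and the domain types (:class:`~mitochar.core.GeneTable`,
:class:`~mitochar.core.NucleotideSequence`). Only the feature keys
gene/CDS/tRNA/rRNA/D-loop/misc_feature are consumed, which covers
mitogenome announcement records. Declared annotation-table values (size,
intergenic, codon labels, anticodon) survive a GenBank round-trip inside a
structured ``/note`` qualifier.

The gene-table TSV dialect has the columns::

    locus  category  strand  start  stop  size  start_codon  stop_codon  anticodon  intergenic

with empty cells for inapplicable fields, preceded by ``# key=value``
header comments (taxon, accession, genome_length, circular).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .core import GeneFeature, GeneTable, NucleotideSequence

__all__ = [
    "ParsedRecord",
    "FormatError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "write_newick",
    "load_record",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Input file does not conform to the expected dialect."""


@dataclass
class ParsedRecord:
    """A sequence plus its gene table, with provenance."""

    sequence: NucleotideSequence
    table: GeneTable
    provenance: str = ""


_CATEGORY_TO_KEY = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "D-loop"}
_KEY_TO_CATEGORY = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control",
    "D_loop": "control",
    "misc_feature": "control",
}

_META_RE = re.compile(r"mitochar_meta:\s*(.*)")


def _meta_note(f: GeneFeature) -> Optional[str]:
    fields = {
        "size": f.declared_size,
        "intergenic": f.declared_intergenic,
        "start_codon": f.declared_start_codon,
        "stop_codon": f.declared_stop_codon,
        "anticodon": f.anticodon,
    }
    parts = [f"{k}={v}" for k, v in fields.items() if v is not None]
    return "mitochar_meta: " + " ".join(parts) if parts else None


def _parse_meta(note: str) -> dict:
    m = _META_RE.search(note)
    if not m:
        return {}
    out = {}
    for part in m.group(1).split():
        k, _, v = part.partition("=")
        out[k] = int(v) if k in ("size", "intergenic") else v
    return out


def write_genbank(record: ParsedRecord, path: PathLike) -> None:
    """Emit a minimal standards-conformant GenBank flat file.

    LOCUS carries the length and circular flag; features use
    ``complement(...)`` for L-strand genes and a two-part ``join`` for
    features spanning the circular origin; the ORIGIN block holds the
    sequence in the standard 60-column layout.
    """
    t = record.table
    L = t.genome_length
    seq_word = record.sequence.id.split()[0] if record.sequence.id.strip() else ""
    rec_id = t.accession or seq_word or "genome"
    seqrec = SeqRecord(
        Seq(record.sequence.residues),
        id=rec_id,
        name=rec_id.replace(" ", "_")[:16],
        description=t.taxon or "",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if t.circular else "linear",
            "organism": t.taxon or "",
        },
    )
    for f in t.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, L, strand),
                SimpleLocation(0, f.stop, strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.stop, strand)
        quals = {"gene": [f.locus]}
        note = _meta_note(f)
        if note:
            quals["note"] = [note]
        seqrec.features.append(
            SeqFeature(loc, type=_CATEGORY_TO_KEY[f.category], qualifiers=quals)
        )
    SeqIO.write([seqrec], str(path), "genbank")


def _feature_from_seqfeature(sf, genome_length: int) -> GeneFeature:
    loc = sf.location
    parts = getattr(loc, "parts", [loc])
    if len(parts) == 2 and int(parts[0].end) == genome_length and int(parts[1].start) == 0:
        start, stop = int(parts[0].start) + 1, int(parts[1].end)
    elif len(parts) == 1:
        start, stop = int(loc.start) + 1, int(loc.end)
    else:
        raise FormatError(f"unsupported compound location {loc}")
    locus = (sf.qualifiers.get("gene") or sf.qualifiers.get("product") or ["?"])[0]
    meta = _parse_meta((sf.qualifiers.get("note") or [""])[0])
    return GeneFeature(
        locus=locus,
        category=_KEY_TO_CATEGORY[sf.type],
        strand="L" if loc.strand == -1 else "H",
        start=start,
        stop=stop,
        anticodon=meta.get("anticodon"),
        declared_start_codon=meta.get("start_codon"),
        declared_stop_codon=meta.get("stop_codon"),
        declared_size=meta.get("size"),
        declared_intergenic=meta.get("intergenic"),
    )


def read_genbank(path: PathLike) -> ParsedRecord:
    """Parse a GenBank flat file into a :class:`ParsedRecord`.

    ``complement(...)`` locations map to strand L; a two-part
    ``join(a..L,1..b)`` maps to an origin-wrapping feature; circular
    topology is read from the LOCUS line.
    """
    seqrec = SeqIO.read(str(path), "genbank")
    try:
        residues = str(seqrec.seq)
    except Exception as exc:  # undefined sequence: no ORIGIN block
        raise FormatError(f"{path}: no sequence (missing ORIGIN?)") from exc
    if not residues:
        raise FormatError(f"{path}: empty ORIGIN block")
    L = len(residues)
    circular = seqrec.annotations.get("topology", "linear") == "circular"
    seq = NucleotideSequence(
        residues, "circular" if circular else "linear", seqrec.id
    )
    features = []
    consumed_spans = set()
    deferred_genes = []
    for sf in seqrec.features:
        if sf.type in _KEY_TO_CATEGORY:
            f = _feature_from_seqfeature(sf, L)
            features.append(f)
            consumed_spans.add((f.start, f.stop))
        elif sf.type == "gene":
            deferred_genes.append(sf)
    # standalone gene features (no CDS/tRNA/rRNA sibling) still carry
    # annotation in some deposited records
    for sf in deferred_genes:
        f = _feature_from_seqfeature(
            type(sf)(sf.location, type="misc_feature", qualifiers=sf.qualifiers), L
        )
        if (f.start, f.stop) not in consumed_spans:
            f.category = _guess_category(f.locus)
            features.append(f)
    features.sort(key=lambda f: f.start)
    table = GeneTable(
        features=features,
        genome_length=L,
        circular=circular,
        taxon=seqrec.annotations.get("organism", "") or seqrec.description,
        accession=seqrec.id or None,
    )
    return ParsedRecord(seq, table, provenance=f"{path} [genbank]")


def _guess_category(locus: str) -> str:
    u = locus.upper()
    if u.startswith("TRNA") or u.startswith("TRN"):
        return "tRNA"
    if "RRNA" in u or u in ("RRNS", "RRNL"):
        return "rRNA"
    if "LOOP" in u or "CONTROL" in u:
        return "control"
    return "PCG"


def read_fasta(path: PathLike) -> list[NucleotideSequence]:
    """Read a multi-FASTA; lowercase and U are normalized, gaps preserved.

    Sequences containing ``-`` (alignment dialect) come back with their
    gaps intact so the file can feed the phylogenetics pipeline directly.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        warnings.warn(f"{path}: duplicate FASTA IDs")
    return [NucleotideSequence(str(r.seq), "linear", r.id) for r in records]


def write_fasta(seqs: Sequence[NucleotideSequence], path: PathLike) -> None:
    """Write multi-FASTA wrapped at 60 columns, IDs verbatim."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id or f"seq{i + 1}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


_TSV_COLUMNS = (
    "locus", "category", "strand", "start", "stop", "size",
    "start_codon", "stop_codon", "anticodon", "intergenic",
)


def write_gene_table(table: GeneTable, path: PathLike) -> None:
    """Write the gene-table TSV dialect (header comments + 10 columns)."""
    lines = [
        f"# taxon={table.taxon}",
        f"# accession={table.accession or ''}",
        f"# genome_length={table.genome_length}",
        f"# circular={'true' if table.circular else 'false'}",
        "\t".join(_TSV_COLUMNS),
    ]
    for f in table.features:
        cells = [
            f.locus, f.category, f.strand, str(f.start), str(f.stop),
            "" if f.declared_size is None else str(f.declared_size),
            f.declared_start_codon or "",
            f.declared_stop_codon or "",
            f.anticodon or "",
            "" if f.declared_intergenic is None else str(f.declared_intergenic),
        ]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gene_table(path: PathLike) -> GeneTable:
    """Read the gene-table TSV dialect written by :func:`write_gene_table`."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: Optional[list[str]] = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition("=")
            meta[k.strip()] = v.strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            if tuple(header) != _TSV_COLUMNS:
                raise FormatError(f"{path}: unexpected columns {header}")
            continue
        rows.append(cells + [""] * (len(_TSV_COLUMNS) - len(cells)))
    if header is None or not rows:
        raise FormatError(f"{path}: no gene rows")

    features = []
    for cells in rows:
        d = dict(zip(_TSV_COLUMNS, cells))
        features.append(GeneFeature(
            locus=d["locus"],
            category=d["category"],
            strand=d["strand"],
            start=int(d["start"]),
            stop=int(d["stop"]),
            declared_size=int(d["size"]) if d["size"] else None,
            declared_start_codon=d["start_codon"] or None,
            declared_stop_codon=d["stop_codon"] or None,
            anticodon=d["anticodon"] or None,
            declared_intergenic=int(d["intergenic"]) if d["intergenic"] else None,
        ))
    genome_length = int(meta.get("genome_length") or max(
        max(f.start, f.stop) for f in features
    ))
    return GeneTable(
        features=features,
        genome_length=genome_length,
        circular=meta.get("circular", "true") == "true",
        taxon=meta.get("taxon", ""),
        accession=meta.get("accession") or None,
    )


def write_newick(tree, path: PathLike) -> None:
    """Serialize a :class:`~mitochar.phylo.PhyloTree` (branch lengths to 6
    decimals, integer bootstrap supports as internal-node labels)."""
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")


def load_record(
    path: PathLike,
    table_path: Optional[PathLike] = None,
    fmt: Optional[str] = None,
) -> ParsedRecord:
    """Load a record from GenBank, or from FASTA + gene-table TSV.

    Format is inferred from the extension unless ``fmt`` is given
    (``genbank`` or ``fasta``).
    """
    p = Path(path)
    fmt = fmt or (
        "genbank" if p.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    )
    if fmt == "genbank":
        return read_genbank(p)
    seqs = read_fasta(p)
    if table_path is None:
        raise FormatError("FASTA input needs an accompanying gene-table TSV")
    table = read_gene_table(table_path)
    seq = seqs[0]
    seq = NucleotideSequence(
        seq.residues, "circular" if table.circular else "linear", seq.id
    )
    return ParsedRecord(seq, table, provenance=f"{p} + {table_path} [fasta+tsv]")
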