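"""Readers, writers, and the coordinate conventions shared by the pipeline.

Every module in this package speaks one coordinate convention: 0-based,
half-open intervals, listed in transcription order (for minus-strand genes
the first interval is the one with the highest genomic coordinates).  GFF3 on
disk is 1-based and closed; the conversion happens here and nowhere else, so
downstream intron-phase arithmetic is strand-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard residues plus X (unknown).  Gap characters are rejected:
#: the pipeline works on ungapped precursor sequences.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

Interval = tuple[int, int]


class ParseError(ValueError):
    """Malformed input file (syntax or illegal characters)."""


class ValidationError(ValueError):
    """Structurally invalid gene model (contract violation)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped amino-acid sequence (precursor, leader included)."""

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)}"
            )


@dataclass
class GeneModel:
    """Exon/CDS structure of one gene, in transcription order.

    ``tm_exon_index`` marks the exon encoding the transmembrane segment;
    it is optional because it can be derived later from a protein-level
    TM prediction.  ``partial_cds`` is a warning flag set when the total
    CDS length is not divisible by three (phases remain computable).
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    tm_exon_index: int | None = None
    partial_cds: bool = field(default=False)

    def __post_init__(self) -> None:
        self.exons = tuple(tuple(iv) for iv in self.exons)
        self.cds = tuple(tuple(iv) for iv in self.cds)
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            for s, e in ivs:
                if not (0 <= s < e):
                    raise ValidationError(
                        f"{self.gene_id}: bad {name} interval ({s}, {e})"
                    )
            self._check_transcription_order(name, ivs)
        for c in self.cds:
            if not any(ex[0] <= c[0] and c[1] <= ex[1] for ex in self.exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS {c} not contained in any exon"
                )
        if self.cds_length % 3 != 0:
            self.partial_cds = True

    def _check_transcription_order(self, name: str, ivs: Sequence[Interval]) -> None:
        for a, b in zip(ivs, ivs[1:]):
            ordered = a[1] <= b[0] if self.strand == "+" else b[1] <= a[0]
            if not ordered:
                raise ValidationError(
                    f"{self.gene_id}: {name} intervals not in transcription "
                    f"order or overlapping: {a} vs {b}"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> Interval:
        """Genomic footprint (min start, max end) over all exons."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header.
    Illegal residues (anything outside the 20-letter alphabet plus X) raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ParseError(f"{path}:1: not a FASTA file (no '>' header)")
    # Validate raw sequence lines up front: the parser below would silently
    # strip internal whitespace, hiding exactly the malformations we reject.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") or not line.strip():
            continue
        bad = set(line.rstrip("\r\n").upper()) - VALID_RESIDUES
        if bad:
            ch = sorted(bad)[0]
            raise ParseError(f"{path}:{lineno}: illegal residue {ch!r}")
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    Disk coordinates (1-based closed) are converted to the internal 0-based
    half-open convention, and minus-strand features are reordered into
    transcription order, so downstream phase math never sees a strand.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")
        )
        if gene.strand == "-":
            exons.reverse()
            cds.reverse()
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based closed coordinates on disk)."""
    lines = ["##gff-version 3"]
    for m in models:
        s, e = m.span
        lines.append(
            f"{m.seq_id}\tcd4lag3\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id}"
        )
        mrna_id = f"{m.gene_id}.t1"
        lines.append(
            f"{m.seq_id}\tcd4lag3\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
            f"ID={mrna_id};Parent={m.gene_id}"
        )
        for kind, ivs in (("exon", m.exons), ("CDS", m.cds)):
            for a, b in sorted(ivs):
                lines.append(
                    f"{m.seq_id}\tcd4lag3\t{kind}\t{a + 1}\t{b}\t.\t"
                    f"{m.strand}\t.\tParent={mrna_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(reports: Sequence, path: str | Path) -> None:
    """Serialize a collection of evidence reports as JSON (stable key order)."""
    payload = [r.to_dict() for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> list:
    """Inverse of :func:`write_report`; round-trips losslessly."""
    from .classifier import EvidenceReport  # local import: avoids cycle

    payload = json.loads(Path(path).read_text())
    return [EvidenceReport.from_dict(d) for d in payload]
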