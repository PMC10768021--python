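"""Intron phases, CDS-to-protein mapping, and cytoplasmic-tail exon counts.

The two gene-structure rules that separate the CD4 and LAG-3 lineages are
(1) the phase of the intron internal to the D1 Ig-domain coding sequence
(phase 1 in bony-vertebrate CD4, phase 2 — at a different position — in
LAG-3), and (2) how many coding exons lie behind the transmembrane-encoding
exon (one in LAG-3, two in bony-fish/tetrapod CD4, three in shark CD4).
Phases are defined on coding nucleotides only: an intron after ``n`` coding
nucleotides has phase ``n mod 3`` and interrupts protein residue ``n // 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .seq_io import GeneModel


class GeneStructureError(ValueError):
    pass


@dataclass(frozen=True)
class IntronRecord:
    """One intron between consecutive CDS intervals of a gene model."""

    index: int
    cds_offset: int  # coding nucleotides 5' of the intron
    phase: int  # cds_offset mod 3
    protein_pos: int  # 0-based residue containing / preceding the intron
    within_domain: str | None = None


@dataclass(frozen=True)
class TailStructure:
    tail_exon_count: int
    extra_exon: bool


def intron_phases(model: GeneModel) -> list[IntronRecord]:
    """Phase and protein position of every intron interrupting the CDS.

    One record per junction between consecutive CDS intervals, in
    transcription order; a single-interval CDS has no introns.
    """
    if not model.cds:
        raise GeneStructureError(f"{model.gene_id}: model has no CDS")
    records: list[IntronRecord] = []
    offset = 0
    for i, (s, e) in enumerate(model.cds[:-1]):
        offset += e - s
        records.append(
            IntronRecord(
                index=i,
                cds_offset=offset,
                phase=offset % 3,
                protein_pos=offset // 3,
            )
        )
    return records


def annotate_intron_domains(
    introns: Sequence[IntronRecord], domains: Sequence
) -> list[IntronRecord]:
    """Label introns whose protein position falls strictly inside a domain.

    *domains* are protein-coordinate annotations with ``label``, ``start``
    and ``end`` (half-open) attributes.  "Inside" is the strict interior:
    the first and last residue of a domain do not count, because the
    discriminating introns are the ones *internal* to D1, not the
    boundary-splitting ones.
    """
    out: list[IntronRecord] = []
    for rec in introns:
        label = None
        for d in domains:
            if d.start < rec.protein_pos < d.end - 1:
                label = d.label
                break
        out.append(replace(rec, within_domain=label))
    return out


def tail_structure(model: GeneModel) -> TailStructure:
    """Count coding exons strictly after the transmembrane-encoding exon.

    ``extra_exon`` flags counts of three or more — beyond the two-exon
    baseline of bony-vertebrate CD4 tails (the shark CD4 situation).
    """
    if model.tm_exon_index is None:
        raise GeneStructureError(
            f"{model.gene_id}: tm_exon_index not set; supply it or derive it "
            "from a transmembrane prediction (tail_analysis.find_tm) first"
        )
    count = 0
    for i, exon in enumerate(model.exons):
        if i <= model.tm_exon_index:
            continue
        if any(c[0] < exon[1] and exon[0] < c[1] for c in model.cds):
            count += 1
    return TailStructure(tail_exon_count=count, extra_exon=count >= 3)


def tm_exon_index_from_span(model: GeneModel, tm_span: tuple[int, int]) -> int:
    """Exon (transcription-order index) containing the last TM codon.

    *tm_span* is the protein-residue interval of the transmembrane segment.
    The mapping walks the CDS in transcription order to the genomic position
    of the final TM nucleotide, then locates the exon containing it.
    """
    target = 3 * tm_span[1] - 1  # last coding nucleotide of the TM segment
    if target < 0 or target >= model.cds_length:
        raise GeneStructureError(
            f"{model.gene_id}: TM span {tm_span} outside the CDS"
        )
    offset = 0
    genomic = None
    for s, e in model.cds:
        if target < offset + (e - s):
            k = target - offset
            genomic = s + k if model.strand == "+" else e - 1 - k
            break
        offset += e - s
    for i, (s, e) in enumerate(model.exons):
        if s <= genomic < e:
            return i
    raise GeneStructureError(
        f"{model.gene_id}: no exon contains CDS position {target}"
    )
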