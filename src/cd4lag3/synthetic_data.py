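"""Synthetic CD4/LAG-3-family genes with class-true planted features.

The generator emits protein sequences, gene models, synteny tables, and
expression tables whose discriminating features are planted by construction
and recorded in truth records, so every analysis stage — motif scanning,
intron phases, domain detection, tail profiling, synteny, expression, and
the classifier — can be exercised without any downloads.  Class templates
follow the comparative picture across jawed vertebrates:

========== =============================== ======= ========== =============
class      tail motifs                     tail ex D1 intron  ectodomain
========== =============================== ======= ========== =============
CD4        Y+CxC clasp, amphipathic start  2       phase 1    V-C2-V-C2
CD4-1      CD4 + P(K/Q)P(K/R)(A/G)FY(H/K/R) 2      phase 1    V-C2-V-C2
CD4-2      CD4 clasp, linker CxxC          2       phase 1    V-C2
SHARK_CD4  Y+CxH clasp, long tail          3       none       V-C2-V-C2
LAG-3      FPALE (ITIM-like), (EP)7 end    1       phase 2    V-C2-V-C2
FROG_LAG3  no inhibitory motif             1       phase 2    V-C2-V-C2
HYBRID     LAG-3 tail on a CD4 gene body   1       phase 1    V-C2-V-C2
========== =============================== ======= ========== =============

The D1-internal introns sit at different positions in the CD4 and LAG-3
templates, expression rows make CD4-type genes thymus-dominant (ratio 6,
lognormal noise sigma 0.2) and LAG-3-type genes not (ratio 1), and each
simulated locus carries a same-strand tandem neighbor so the head-to-tail
criterion is evaluable.  Everything is driven by numpy Generator seeds:
identical parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import GeneModel, ProteinRecord, write_fasta, write_gff3

CLASSES = ("CD4", "CD4-1", "CD4-2", "LAG-3", "HYBRID", "FROG_LAG3", "SHARK_CD4")
DEFAULT_CLASSES = ("CD4", "CD4-1", "CD4-2", "LAG-3")
CD4_TYPE = {"CD4", "CD4-1", "CD4-2", "SHARK_CD4"}

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Ectodomain background: no cysteine (would fake Ig cys pairs) and no
#: tryptophan (would fake WxC signatures).
ECTO_FILLER = "ADEGHIKLMNPQRSTV"
#: Tail background: additionally no F/Y/M/I/L/V, so no spurious inhibitory
#: motifs and no hydrophobic stretch competing with the planted TM.
TAIL_FILLER = "ADEGHKNPQRST"

TM_ALPHABET = "LIVF"
TM_LEN = 19
LEADER_LEN = 18
DOMAIN_SPACER = 4
#: Residues of tail kept on the transmembrane-encoding exon.
TM_EXON_TAIL_RESIDUES = 4

#: Expression model: thymus:spleen ratio per class and its lognormal sigma.
EXPRESSION_RATIO_CD4 = 6.0
EXPRESSION_RATIO_LAG3 = 1.0
EXPRESSION_SIGMA = 0.2
SPLEEN_BASE_SIGMA = 0.5

_AMPHIPATHIC = "LEKLLEKLLEK"


@dataclass(frozen=True)
class SimParams:
    n_per_class: int = 25
    mutation_rate: float = 0.0
    seed: int = 0
    classes: tuple[str, ...] = DEFAULT_CLASSES
    background: str = ECTO_FILLER

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class(es): {sorted(unknown)}")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    true_label: str
    strand: str
    tm_span: tuple[int, int]
    domains: tuple[tuple[int, int, str], ...]
    d1_intron_protein_pos: int | None
    d1_intron_phase: int | None
    clasp: str
    clasp_tail_pos: int | None
    inhibitory_tail_pos: int | None
    cd41_cterm_motif: bool
    tail_exon_count: int
    ep_repeat_n: int


@dataclass
class Cohort:
    records: list[ProteinRecord]
    models: list[GeneModel]
    synteny: pd.DataFrame
    expression: pd.DataFrame
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "true_label": t.true_label,
                    "strand": t.strand,
                    "tm_start": t.tm_span[0],
                    "tm_end": t.tm_span[1],
                    "d1_intron_phase": (
                        "NA" if t.d1_intron_phase is None else t.d1_intron_phase
                    ),
                    "tail_exon_count": t.tail_exon_count,
                    "clasp": t.clasp,
                }
            )
        return pd.DataFrame(rows)


def _rand_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _make_domain(rng: np.random.Generator, category: str) -> str:
    """One Ig-like domain: B/F cysteine pair spaced 55±10, category-true."""
    spacing = int(rng.integers(45, 66))
    arr = list(_rand_seq(rng, ECTO_FILLER, 20 + spacing))
    cb, cf = 15, 15 + spacing
    arr[cb] = "C"
    arr[cf] = "C"
    if category == "C2":
        arr[cf - 2] = "W"
        for off in (3, 4, 8, 11, 13, 14):  # scrub the V-start consensus slots
            arr[off] = "T"
    else:
        arr[3], arr[4], arr[8] = "V", "F", "G"
        arr[11], arr[13], arr[14] = "A", "L", "P"
    return "".join(arr)


def _make_tail(rng: np.random.Generator, cls: str) -> tuple[str, dict]:
    f = lambda n: _rand_seq(rng, TAIL_FILLER, n)
    planted: dict = {"clasp": "none", "clasp_pos": None, "inhib_pos": None,
                     "cd41": False, "ep_n": 0}
    if cls in ("CD4", "CD4-2"):
        tail = "RK" + f(3) + _AMPHIPATHIC + f(2) + "YCQC" + f(8)
        planted.update(clasp="CxC", clasp_pos=19)
    elif cls == "CD4-1":
        tail = "RK" + f(3) + _AMPHIPATHIC + f(2) + "YCQC" + f(4) + "PKPKAFYH"
        planted.update(clasp="CxC", clasp_pos=19, cd41=True)
    elif cls == "SHARK_CD4":
        tail = "RK" + f(3) + _AMPHIPATHIC + f(10) + "YCVH" + f(18)
        planted.update(clasp="CxH", clasp_pos=27)
    elif cls == "LAG-3":
        tail = "RRK" + f(4) + "FPALE" + f(4) + "EPEPEPEPEPEPEPEQL"
        planted.update(inhib_pos=7, ep_n=7)
    elif cls == "FROG_LAG3":
        tail = "RRK" + f(14)
    elif cls == "HYBRID":
        tail = "RRK" + f(4) + "FPALE" + f(8)
        planted.update(inhib_pos=7)
    else:
        raise ValueError(f"unknown class {cls!r}")
    return tail, planted


def generate_gene(
    cls: str, seed: int, gene_id: str | None = None, strand: str | None = None
) -> tuple[ProteinRecord, GeneModel, TruthRecord]:
    """One synthetic gene of the given class, fully determined by *seed*."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    rng = np.random.default_rng(seed)
    gene_id = gene_id or f"{cls}_{seed}"
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"

    leader = "M" + _rand_seq(rng, ECTO_FILLER, LEADER_LEN - 1)
    categories = ("V", "C2") if cls == "CD4-2" else ("V", "C2", "V", "C2")
    segments = [leader]
    pos = len(leader)
    domains: list[tuple[int, int, str]] = []
    for i, cat in enumerate(categories):
        if i:
            segments.append(_rand_seq(rng, ECTO_FILLER, DOMAIN_SPACER))
            pos += DOMAIN_SPACER
        dom = _make_domain(rng, cat)
        domains.append((pos, pos + len(dom), cat))
        segments.append(dom)
        pos += len(dom)
    if cls == "CD4-2":
        linker = (
            _rand_seq(rng, TAIL_FILLER, 2) + "CPPC"
            + _rand_seq(rng, TAIL_FILLER, 2) + "ENK"
        )
    else:
        linker = _rand_seq(rng, TAIL_FILLER, 6) + "ENK"
    segments.append(linker)
    pos += len(linker)
    tm_start = pos
    segments.append(_rand_seq(rng, TM_ALPHABET, TM_LEN))
    tm_end = tm_start + TM_LEN
    tail, planted = _make_tail(rng, cls)
    segments.append(tail)
    protein = "".join(segments)

    # D1-internal intron: phase 1 for CD4-lineage gene bodies, phase 2 (at a
    # different residue) for LAG-3-lineage; shark CD4 has none.
    d1_pos: int | None = None
    d1_phase: int | None = None
    if cls in ("CD4", "CD4-1", "CD4-2", "HYBRID"):
        d1_pos, d1_phase = domains[0][0] + 20, 1
    elif cls in ("LAG-3", "FROG_LAG3"):
        d1_pos, d1_phase = domains[0][0] + 30, 2

    junctions: list[int] = []
    if d1_pos is not None:
        junctions.append(3 * d1_pos + d1_phase)
    junctions.append(3 * tm_start)
    junctions.append(3 * (tm_end + TM_EXON_TAIL_RESIDUES))
    if cls in ("CD4", "CD4-1", "CD4-2"):
        junctions.append(3 * (tm_end + TM_EXON_TAIL_RESIDUES + 8))
        tail_exons = 2
    elif cls == "SHARK_CD4":
        junctions.append(3 * (tm_end + TM_EXON_TAIL_RESIDUES + 12))
        junctions.append(3 * (tm_end + TM_EXON_TAIL_RESIDUES + 24))
        tail_exons = 3
    else:
        tail_exons = 1

    offsets = [0, *junctions, 3 * len(protein)]
    g = 1200
    plus_exons: list[tuple[int, int]] = []
    for a, b in zip(offsets, offsets[1:]):
        plus_exons.append((g, g + (b - a)))
        g = plus_exons[-1][1] + int(rng.integers(80, 301))
    gene_end = plus_exons[-1][1]
    contig_len = gene_end + 1200
    if strand == "-":
        exons = tuple((contig_len - e, contig_len - s) for s, e in plus_exons)
    else:
        exons = tuple(plus_exons)
    model = GeneModel(
        gene_id=gene_id,
        seq_id=f"locus_{gene_id}",
        strand=strand,
        exons=exons,
        cds=exons,
    )
    truth = TruthRecord(
        gene_id=gene_id,
        true_label="LAG-3" if cls == "FROG_LAG3" else
        ("CD4" if cls == "SHARK_CD4" else cls),
        strand=strand,
        tm_span=(tm_start, tm_end),
        domains=tuple(domains),
        d1_intron_protein_pos=d1_pos,
        d1_intron_phase=d1_phase,
        clasp=planted["clasp"],
        clasp_tail_pos=planted["clasp_pos"],
        inhibitory_tail_pos=planted["inhib_pos"],
        cd41_cterm_motif=planted["cd41"],
        tail_exon_count=tail_exons,
        ep_repeat_n=planted["ep_n"],
    )
    return ProteinRecord(id=gene_id, sequence=protein), model, truth


def mutate(
    sequence: str,
    rate: float,
    seed: int,
    protected_spans: tuple[tuple[int, int], ...] = (),
) -> str:
    """I.i.d. residue substitutions outside the protected spans."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return sequence
    rng = np.random.default_rng(seed)
    protected = np.zeros(len(sequence), dtype=bool)
    for s, e in protected_spans:
        protected[s:e] = True
    out = list(sequence)
    draws = rng.random(len(sequence))
    for i, (a, p) in enumerate(zip(sequence, draws)):
        if protected[i] or p >= rate:
            continue
        choices = AA20.replace(a, "")
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _locus_synteny_rows(cls: str, model: GeneModel, ordinal: int) -> list[dict]:
    """Tandem-neighbor rows for one simulated locus (plus the gene itself)."""
    s, e = model.span
    if model.strand == "+":
        up_iv, down_iv = (200, 700), (e + 300, e + 800)
    else:
        # transcription runs right-to-left: upstream = higher coordinates
        up_iv, down_iv = (e + 300, e + 800), (200, 700)
    rows = [
        {
            "gene": model.gene_id,
            "seq_id": model.seq_id,
            "start": s,
            "end": e,
            "strand": model.strand,
        }
    ]
    if cls in CD4_TYPE or cls == "HYBRID":
        rows.append(
            {
                "gene": f"LAG3_nbr_{ordinal:04d}",
                "seq_id": model.seq_id,
                "start": up_iv[0],
                "end": up_iv[1],
                "strand": model.strand,
            }
        )
    if cls in ("LAG-3", "FROG_LAG3") or cls == "HYBRID":
        rows.append(
            {
                "gene": f"CD4_nbr_{ordinal:04d}",
                "seq_id": model.seq_id,
                "start": down_iv[0],
                "end": down_iv[1],
                "strand": model.strand,
            }
        )
    return rows


def generate_cohort(params: SimParams, outdir: str | Path | None = None) -> Cohort:
    """A full cohort: FASTA, GFF3, synteny TSV, expression TSV, truth TSV.

    Gene ids are anonymous (``gene_0000`` …); the class lives only in the
    truth records.  When *outdir* is given the five files are written there
    (cohort.fasta / cohort.gff3 / synteny.tsv / expression.tsv / truth.tsv).
    """
    master = np.random.default_rng(params.seed)
    records: list[ProteinRecord] = []
    models: list[GeneModel] = []
    truths: list[TruthRecord] = []
    syn_rows: list[dict] = []
    expr_rows: list[dict] = []
    ordinal = 0
    for cls in params.classes:
        for _ in range(params.n_per_class):
            gene_seed = int(master.integers(0, 2**31 - 1))
            mut_seed = int(master.integers(0, 2**31 - 1))
            gid = f"gene_{ordinal:04d}"
            rec, model, truth = generate_gene(cls, gene_seed, gene_id=gid)
            if params.mutation_rate > 0:
                rec = ProteinRecord(
                    id=gid,
                    sequence=mutate(rec.sequence, params.mutation_rate, mut_seed),
                )
            records.append(rec)
            models.append(model)
            truths.append(truth)
            syn_rows.extend(_locus_synteny_rows(cls, model, ordinal))
            ratio = (
                EXPRESSION_RATIO_CD4 if cls in CD4_TYPE else EXPRESSION_RATIO_LAG3
            )
            spleen = float(master.lognormal(0.0, SPLEEN_BASE_SIGMA))
            thymus = spleen * ratio * float(master.lognormal(0.0, EXPRESSION_SIGMA))
            expr_rows.append({"gene": gid, "spleen": spleen, "thymus": thymus})
            ordinal += 1
    synteny = (
        pd.DataFrame(syn_rows)
        .sort_values(["seq_id", "start"])
        .reset_index(drop=True)
    )
    expression = pd.DataFrame(expr_rows).set_index("gene")
    cohort = Cohort(records, models, synteny, expression, truths)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "cohort.fasta")
        write_gff3(models, outdir / "cohort.gff3")
        synteny.to_csv(outdir / "synteny.tsv", sep="\t", index=False)
        expression.to_csv(outdir / "expression.tsv", sep="\t")
        cohort.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return cohort


def generate_qpcr_table(
    genes: tuple[str, ...] = ("CD4", "LAG-3"),
    tissues: tuple[str, ...] = ("thymus", "spleen", "gill", "liver"),
    n_replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic relative-qPCR table with a housekeeping column per row."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        tissue_effect = {t: float(rng.lognormal(0.0, 1.0)) for t in tissues}
        for tissue in tissues:
            for rep in range(n_replicates):
                hk = float(rng.lognormal(0.0, 0.3))
                target = hk * tissue_effect[tissue] * float(rng.lognormal(0.0, 0.2))
                rows.append(
                    {
                        "gene": gene,
                        "tissue": tissue,
                        "replicate": rep,
                        "target_amount": target,
                        "housekeeping_amount": hk,
                    }
                )
    return pd.DataFrame(rows)
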