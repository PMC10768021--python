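"""Evidence-weighted CD4 / CD4-1 / CD4-2 / LAG-3 classification.

No single feature separates the lineages in every species (frogs lost the
LAG-3 inhibitory motif; sharks have no D1 intron at all), so identity is
called from the combination of cytoplasmic-tail motifs, gene structure,
ectodomain architecture, synteny, and expression.  Feature weights encode
the qualitative ranking of the evidence: the tail motifs and tail-exon
organization are sharp discriminators (3 and 2 points), the D1 intron phase
is sharp but bony-vertebrate-only (2), and expression and synteny are
supportive (1).  A call requires a winning score of at least 5 with a margin
of at least 3; anything weaker is AMBIGUOUS, and a CD4-type ectodomain over
a LAG-3-type tail — the lungfish situation — is HYBRID.  Unknown features
contribute nothing: absence of evidence is never evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import domain_architecture, gene_structure, synteny as synteny_mod
from . import expression as expression_mod
from . import seq_io, tail_analysis

MIN_WINNING_SCORE = 5
MIN_MARGIN = 3
#: Minimum per-side points before a CD4-ectodomain/LAG-3-tail conflict is
#: called HYBRID rather than resolved by the margin rule.
HYBRID_MIN_SIDE = 3

LABELS = ("CD4", "CD4-1", "CD4-2", "LAG-3", "HYBRID", "AMBIGUOUS")


@dataclass(frozen=True)
class FeatureVector:
    """Per-gene evidence; ``None`` always means unknown, never a default."""

    clasp: str | None = None  # "CxC" | "CxH" | "CxF" | "none"
    inhibitory: str | None = None  # "canonical_ITIM" | "ITIM_like" | "YxxM" | "none"
    cd41_cterm_motif: bool | None = None
    d1_intron_phase: int | str | None = None  # 0 | 1 | 2 | "absent"
    tail_exon_count: int | None = None
    architecture: str | None = None
    linker_cxxc: bool | None = None
    head_to_tail_role: str | None = None  # "upstream" | "downstream" | "none"
    thymus_dominant: bool | None = None
    ep_repeat_n: int | None = None
    acidic_fraction: float | None = None


@dataclass(frozen=True)
class Contribution:
    feature: str
    lineage: str  # "CD4" | "LAG-3"
    points: int
    rationale: str


@dataclass
class EvidenceReport:
    gene_id: str
    label: str
    cd4_score: int
    lag3_score: int
    features: dict
    contributions: list
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "label": self.label,
            "cd4_score": self.cd4_score,
            "lag3_score": self.lag3_score,
            "features": dict(self.features),
            "contributions": [asdict(c) for c in self.contributions],
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceReport":
        return cls(
            gene_id=d["gene_id"],
            label=d["label"],
            cd4_score=d["cd4_score"],
            lag3_score=d["lag3_score"],
            features=dict(d["features"]),
            contributions=[Contribution(**c) for c in d["contributions"]],
            notes=list(d.get("notes", [])),
        )


def _contrib(out, feature, lineage, points, rationale):
    out.append(Contribution(feature, lineage, points, rationale))
    return points


def score(features: FeatureVector) -> tuple[int, int, list[Contribution]]:
    """Additive lineage scores; unknown fields contribute zero."""
    contributions: list[Contribution] = []
    cd4 = 0
    lag3 = 0
    f = features

    if f.clasp in ("CxC", "CxH"):
        cd4 += _contrib(
            contributions, "clasp", "CD4", 3,
            f"tail {f.clasp} zinc-clasp motif for LCK binding",
        )
    elif f.clasp == "CxF":
        cd4 += _contrib(
            contributions, "clasp", "CD4", 2,
            "tail CxF: clasp with the second cysteine replaced by phenylalanine",
        )
    if f.tail_exon_count is not None and f.tail_exon_count >= 2:
        cd4 += _contrib(
            contributions, "tail_exon_count", "CD4", 2,
            "post-TM tail encoded by multiple exons (CD4-type organization)",
        )
    if f.d1_intron_phase == 1:
        cd4 += _contrib(
            contributions, "d1_intron_phase", "CD4", 2,
            "phase-1 intron internal to the D1 coding sequence",
        )
    if f.cd41_cterm_motif is True:
        cd4 += _contrib(
            contributions, "cd41_cterm_motif", "CD4", 1,
            "conserved CD4-1 C-terminal tail motif P(K/Q)P(K/R)(A/G)FY(H/K/R)",
        )
    if f.thymus_dominant is True:
        cd4 += _contrib(
            contributions, "thymus_dominant", "CD4", 1,
            "thymus-dominant expression (T-lineage marker pattern)",
        )
    if f.head_to_tail_role == "downstream":
        cd4 += _contrib(
            contributions, "head_to_tail_role", "CD4", 1,
            "tandem position downstream of LAG-3 (ancestral organization)",
        )

    if f.inhibitory in ("canonical_ITIM", "ITIM_like"):
        lag3 += _contrib(
            contributions, "inhibitory", "LAG-3", 3,
            f"tail inhibitory motif ({f.inhibitory})",
        )
    elif f.inhibitory == "YxxM":
        lag3 += _contrib(
            contributions, "inhibitory", "LAG-3", 2,
            "tail YxxM SH2-docking motif (teleost LAG-3 variant)",
        )
    if f.tail_exon_count == 1:
        lag3 += _contrib(
            contributions, "tail_exon_count", "LAG-3", 2,
            "post-TM tail encoded by a single exon (LAG-3-type organization)",
        )
    if f.d1_intron_phase == 2:
        lag3 += _contrib(
            contributions, "d1_intron_phase", "LAG-3", 2,
            "phase-2 intron internal to the D1 coding sequence",
        )
    if f.ep_repeat_n is not None and f.ep_repeat_n >= 3:
        lag3 += _contrib(
            contributions, "ep_repeat_n", "LAG-3", 1,
            "acidic EP-repeat near the tail end (tetrapod LAG-3 feature)",
        )
    if f.head_to_tail_role == "upstream":
        lag3 += _contrib(
            contributions, "head_to_tail_role", "LAG-3", 1,
            "tandem position upstream of CD4 (ancestral organization)",
        )
    # Absence of thymus dominance is deliberately worth 0 to LAG-3: LAG-3
    # expression is merely "not consistently" thymus-high — the absence of a
    # pattern, not an anti-pattern.
    return cd4, lag3, contributions


def _arch_n_domains(architecture: str | None) -> int | None:
    if not architecture:
        return None
    return len(architecture.split("-"))


def label(
    cd4_score: int,
    lag3_score: int,
    features: FeatureVector,
    min_winning_score: int = MIN_WINNING_SCORE,
    min_margin: int = MIN_MARGIN,
) -> str:
    """Resolve lineage scores into a final label.

    HYBRID takes precedence: a gene whose ectodomain-side evidence points
    CD4 (phase-1 D1 intron, four-domain V-C2-V-C2 architecture, CD4-1-type
    C-terminus) while its tail points LAG-3 (inhibitory motif on a
    single-exon tail), with at least ``HYBRID_MIN_SIDE`` points on each side.
    Otherwise the higher-scoring lineage wins if it reaches
    ``min_winning_score`` with a margin of ``min_margin``; a CD4 call is
    refined to CD4-1 (C-terminal motif) or CD4-2 (reduced ectodomain or
    linker CxxC) only when such a ray-finned-fish-specific cue is present.
    """
    f = features
    lag3_tail = 0
    if f.inhibitory in ("canonical_ITIM", "ITIM_like"):
        lag3_tail += 3
    elif f.inhibitory == "YxxM":
        lag3_tail += 2
    if f.tail_exon_count == 1:
        lag3_tail += 2
    cd4_ecto = 0
    if f.d1_intron_phase == 1:
        cd4_ecto += 2
    if f.architecture == "V-C2-V-C2":
        cd4_ecto += 1
    if f.cd41_cterm_motif is True:
        cd4_ecto += 1
    if (
        f.inhibitory in ("canonical_ITIM", "ITIM_like", "YxxM")
        and f.tail_exon_count == 1
        and lag3_tail >= HYBRID_MIN_SIDE
        and cd4_ecto >= HYBRID_MIN_SIDE
    ):
        return "HYBRID"

    winner = max(cd4_score, lag3_score)
    margin = abs(cd4_score - lag3_score)
    if winner < min_winning_score or margin < min_margin:
        return "AMBIGUOUS"
    if lag3_score > cd4_score:
        return "LAG-3"
    if f.cd41_cterm_motif is True:
        return "CD4-1"
    n_dom = _arch_n_domains(f.architecture)
    if (n_dom is not None and 1 <= n_dom < 4) or f.linker_cxxc is True:
        return "CD4-2"
    return "CD4"


def classify(features: FeatureVector, gene_id: str = "", notes=()) -> EvidenceReport:
    cd4, lag3, contributions = score(features)
    return EvidenceReport(
        gene_id=gene_id,
        label=label(cd4, lag3, features),
        cd4_score=cd4,
        lag3_score=lag3,
        features=asdict(features),
        contributions=contributions,
        notes=list(notes),
    )


def features_from_sequence(
    sequence: str,
) -> tuple[FeatureVector, dict, list[str]]:
    """Sequence-derived features plus intermediates for downstream stages.

    Returns (feature vector, intermediates, notes).  Intermediates carry the
    TM span, the domain annotations (needed to place the D1 intron when a
    gene model is supplied), and the tail profile.
    """
    notes: list[str] = []
    inter: dict = {}
    try:
        tm = tail_analysis.find_tm(sequence)
    except tail_analysis.TailAnalysisError as exc:
        notes.append(f"TM detection failed: {exc}")
        tm = None
    ecto_end = tm[0] if tm else len(sequence)
    domains = domain_architecture.detect_domains(sequence[:ecto_end])
    arch = domain_architecture.architecture_string(domains)
    inter["tm_span"] = tm
    inter["domains"] = domains
    linker = None
    if tm and domains:
        linker, _ = domain_architecture.linker_cxxc(
            sequence, domains[-1].end, tm[0]
        )
    profile = None
    if tm:
        try:
            profile = tail_analysis.profile_tail(sequence, tm_span=tm)
        except tail_analysis.TailAnalysisError as exc:
            notes.append(f"tail profiling failed: {exc}")
    inter["tail_profile"] = profile
    fv = FeatureVector(
        clasp=profile.clasp if profile else None,
        inhibitory=profile.inhibitory if profile else None,
        cd41_cterm_motif=profile.cd41_cterm_motif if profile else None,
        architecture=arch.string if domains else None,
        linker_cxxc=linker,
        ep_repeat_n=profile.ep_repeat_n if profile else None,
        acidic_fraction=profile.acidic_fraction if profile else None,
    )
    return fv, inter, notes


def _structure_features(model, inter, notes):
    """D1-intron phase and tail-exon count from a gene model."""
    d1_phase: int | str | None = None
    tail_exons: int | None = None
    try:
        introns = gene_structure.intron_phases(model)
        annotated = gene_structure.annotate_intron_domains(
            introns, inter.get("domains") or []
        )
        d1 = [r for r in annotated if r.within_domain == "D1"]
        d1_phase = d1[0].phase if d1 else "absent"
    except gene_structure.GeneStructureError as exc:
        notes.append(f"intron phases unavailable: {exc}")
    tm = inter.get("tm_span")
    try:
        idx = model.tm_exon_index
        if idx is None and tm is not None:
            idx = gene_structure.tm_exon_index_from_span(model, tm)
        if idx is not None:
            model = seq_io.GeneModel(
                model.gene_id, model.seq_id, model.strand,
                model.exons, model.cds, tm_exon_index=idx,
            )
            tail_exons = gene_structure.tail_structure(model).tail_exon_count
    except gene_structure.GeneStructureError as exc:
        notes.append(f"tail exon count unavailable: {exc}")
    return d1_phase, tail_exons


def classify_record(
    record: seq_io.ProteinRecord,
    model: seq_io.GeneModel | None = None,
    synteny_table=None,
    expression_matrix=None,
    test_tissue: str = "thymus",
    ref_tissue: str = "spleen",
) -> EvidenceReport:
    """Classify one gene from whatever evidence sources are available."""
    fv, inter, notes = features_from_sequence(record.sequence)
    d1_phase: int | str | None = None
    tail_exons: int | None = None
    if model is not None:
        d1_phase, tail_exons = _structure_features(model, inter, notes)
    role: str | None = None
    if synteny_table is not None:
        role = synteny_mod.tandem_role(synteny_table, record.id)
        if role == "unknown":
            role = None
            notes.append("gene absent from synteny table")
    dominant: bool | None = None
    if expression_matrix is not None:
        try:
            dom = expression_mod.tissue_dominance(
                expression_matrix, record.id, test_tissue, ref_tissue
            )
            dominant = dom.dominant
        except expression_mod.ExpressionError as exc:
            notes.append(f"expression evidence unavailable: {exc}")
    full = FeatureVector(
        clasp=fv.clasp,
        inhibitory=fv.inhibitory,
        cd41_cterm_motif=fv.cd41_cterm_motif,
        d1_intron_phase=d1_phase,
        tail_exon_count=tail_exons,
        architecture=fv.architecture,
        linker_cxxc=fv.linker_cxxc,
        head_to_tail_role=role,
        thymus_dominant=dominant,
        ep_repeat_n=fv.ep_repeat_n,
        acidic_fraction=fv.acidic_fraction,
    )
    return classify(full, gene_id=record.id, notes=notes)


def classify_pipeline(
    fasta: str | Path,
    gff3: str | Path | None = None,
    synteny_tsv: str | Path | None = None,
    expression_tsv: str | Path | None = None,
) -> list[EvidenceReport]:
    """End-to-end classification of every sequence in a FASTA file.

    Optional inputs (gene models, synteny table, expression matrix) enrich
    the feature vectors; genes absent from them simply get unknown features.
    Per-record failures are reported in the record's notes and the run
    continues.  Deterministic for fixed inputs.
    """
    records = seq_io.read_fasta(fasta)
    models = {m.gene_id: m for m in seq_io.read_gff3(gff3)} if gff3 else {}
    table = synteny_mod.read_synteny_tsv(synteny_tsv) if synteny_tsv else None
    matrix = (
        expression_mod.read_expression_tsv(expression_tsv)
        if expression_tsv
        else None
    )
    reports: list[EvidenceReport] = []
    for rec in records:
        try:
            reports.append(
                classify_record(
                    rec,
                    model=models.get(rec.id),
                    synteny_table=table,
                    expression_matrix=matrix,
                )
            )
        except Exception as exc:  # per-record failure, run continues
            reports.append(
                EvidenceReport(
                    gene_id=rec.id,
                    label="AMBIGUOUS",
                    cd4_score=0,
                    lag3_score=0,
                    features=asdict(FeatureVector()),
                    contributions=[],
                    notes=[f"classification failed: {exc}"],
                )
            )
    return reports
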