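"""Ig-like domain detection and V/C2 architecture strings for ectodomains.

CD4/LAG-3-family ectodomains are built from immunoglobulin-superfamily
domains in (ancestrally) V-C2-V-C2 order.  Detection here is sequence-rule
based, not profile based: an Ig-like domain is anchored by its B/F-strand
cysteine pair, the C2 category is called from the unusual WxC signature in
strand F (a hallmark of family domains D2 and D4), and the V category from
the conserved residues near the V-domain start — (I/V)4, (F/Y)5, G9, (A/V)12,
L14, P15 in the human-CD4 numbering used throughout the field.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import motif_engine

#: Allowed B-to-F cysteine spacing of an Ig-like domain (residues).
MIN_CYS_SPACING = 40
MAX_CYS_SPACING = 80

#: Residues upstream of the B-strand cysteine that belong to the domain
#: (the V-start consensus places the cysteine at position 16, 1-based).
_START_BEFORE_CYS_B = 15
_END_AFTER_CYS_F = 5

#: (offset from domain start, allowed residues) of the V-start consensus.
V_START_CONSENSUS: tuple[tuple[int, str], ...] = (
    (3, "IV"),
    (4, "FY"),
    (8, "G"),
    (11, "AV"),
    (13, "L"),
    (14, "P"),
)
#: Minimum consensus residues for a V call; fewer means "degenerate".
V_CONSENSUS_MIN = 3

_DOMAIN_LABELS = ("D1", "D2", "D3", "D4")

_CXXC = motif_engine.compile_pattern("CxxC", "cxxc")


@dataclass(frozen=True)
class DomainAnnotation:
    label: str
    category: str  # "V" | "C2" | "degenerate"
    start: int
    end: int
    cys_b: int | None = None
    cys_f: int | None = None
    wxc: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.label}: start must be < end")
        if self.cys_b is not None and self.cys_f is not None:
            spacing = self.cys_f - self.cys_b
            if not (MIN_CYS_SPACING <= spacing <= MAX_CYS_SPACING):
                raise ValueError(
                    f"{self.label}: cysteine spacing {spacing} outside "
                    f"[{MIN_CYS_SPACING}, {MAX_CYS_SPACING}]"
                )


@dataclass(frozen=True)
class Architecture:
    categories: tuple[str, ...]

    @property
    def string(self) -> str:
        return "-".join(
            "V*" if c == "degenerate" else c for c in self.categories
        )

    @property
    def n_domains(self) -> int:
        return len(self.categories)


def _v_consensus_count(sequence: str, start: int) -> int:
    n = 0
    for off, allowed in V_START_CONSENSUS:
        i = start + off
        if i < len(sequence) and sequence[i] in allowed:
            n += 1
    return n


def detect_domains(sequence: str) -> list[DomainAnnotation]:
    """Greedy left-to-right Ig-like domain detection on an ectodomain.

    A candidate domain is a cysteine pair spaced 40-80 residues apart; when a
    B-strand cysteine has several possible F-strand partners the closest one
    wins (deterministic, smallest-spacing tie-break), and accepted pairs never
    overlap.  Category: C2 when the F-strand cysteine carries the WxC
    signature (W two residues before it); otherwise V when at least
    ``V_CONSENSUS_MIN`` of the six start-consensus residues are present;
    otherwise degenerate.  Domains are labeled D1..D4, then "extra".
    """
    cys = [i for i, a in enumerate(sequence) if a == "C"]
    domains: list[DomainAnnotation] = []
    floor = 0
    for cb in cys:
        if cb < floor:
            continue
        partners = [
            cf for cf in cys if MIN_CYS_SPACING <= cf - cb <= MAX_CYS_SPACING
        ]
        if not partners:
            continue
        cf = min(partners)
        start = max(0, cb - _START_BEFORE_CYS_B)
        end = min(len(sequence), cf + _END_AFTER_CYS_F)
        wxc = cf >= 2 and sequence[cf - 2] == "W"
        if wxc:
            category = "C2"
        elif _v_consensus_count(sequence, start) >= V_CONSENSUS_MIN:
            category = "V"
        else:
            category = "degenerate"
        label = (
            _DOMAIN_LABELS[len(domains)]
            if len(domains) < len(_DOMAIN_LABELS)
            else "extra"
        )
        domains.append(
            DomainAnnotation(
                label=label,
                category=category,
                start=start,
                end=end,
                cys_b=cb,
                cys_f=cf,
                wxc=wxc,
            )
        )
        floor = cf + 1
    return domains


def architecture_string(domains: list[DomainAnnotation]) -> Architecture:
    """Hyphen-joined category list; degenerate V renders as ``V*``."""
    return Architecture(tuple(d.category for d in domains))


def linker_cxxc(
    sequence: str, region_start: int, region_end: int
) -> tuple[bool, int | None]:
    """CxxC in the membrane-proximal linker (between last domain and TM).

    The neoteleost-style CD4-2 hinge carries a CxxC that may mediate
    homodimerization; the search is restricted to the given region so a
    domain-internal CxxC never counts.  Returns (found, absolute position).
    """
    region = sequence[region_start:region_end]
    hits = motif_engine.scan(region, _CXXC)
    if not hits:
        return False, None
    return True, region_start + hits[0].start
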