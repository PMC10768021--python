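"""Degenerate amino-acid motif grammar, scanner, and Kozak-context rule.

The motifs that discriminate CD4 from LAG-3 are short and degenerate — the
CD4 zinc-clasp Cx(C/H), the LAG-3 inhibitory (F/Y)xxL(D/E), the canonical
ITIM (I/V/L)xYxx(L/V), the CD4-1 C-terminal P(K/Q)P(K/R)(A/G)FY(H/K/R), the
WxC signature of Ig-like C2 domains, and a few more.  A pattern here is an
ordered list of allowed-residue sets; the grammar is deliberately tiny:

* an upper-case residue letter is a singleton position,
* ``x`` is the wildcard (all 20 standard residues),
* ``[...]`` is a residue class.

The unknown residue ``X`` satisfies no position, including the wildcard —
feature extraction stays conservative on partially sequenced tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA20)


class PatternError(ValueError):
    """Malformed motif pattern string."""


@dataclass(frozen=True)
class MotifPattern:
    name: str
    positions: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError(f"{self.name}: pattern has length 0")
        if any(not p for p in self.positions):
            raise PatternError(f"{self.name}: empty position class")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int
    matched: str


@dataclass(frozen=True)
class KozakContext:
    """NNN-ATG-N heptamer around a start codon and its verdict."""

    heptamer: str
    verdict: str  # "favorable" | "unfavorable"


def compile_pattern(spec: str, name: str | None = None) -> MotifPattern:
    """Compile a pattern string such as ``"Cx[CH]"`` into a MotifPattern."""
    if not spec:
        raise PatternError("empty pattern")
    positions: list[frozenset] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "x":
            positions.append(_AA_SET)
            i += 1
        elif ch == "[":
            j = spec.find("]", i)
            if j == -1:
                raise PatternError(f"{spec!r}: unbalanced bracket at {i}")
            cls = spec[i + 1 : j]
            if not cls:
                raise PatternError(f"{spec!r}: empty class at {i}")
            bad = set(cls) - _AA_SET
            if bad:
                raise PatternError(f"{spec!r}: illegal residue(s) {sorted(bad)}")
            positions.append(frozenset(cls))
            i = j + 1
        elif ch in _AA_SET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise PatternError(f"{spec!r}: illegal character {ch!r} at {i}")
    return MotifPattern(name=name or spec, positions=tuple(positions))


def scan(sequence: str, pattern: MotifPattern | str) -> list[MotifHit]:
    """All (possibly overlapping) matches of *pattern* in *sequence*.

    Hits are returned in ascending start order.  ``X`` never matches.
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    k = len(pattern)
    hits: list[MotifHit] = []
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if all(c in p for c, p in zip(window, pattern.positions)):
            hits.append(MotifHit(pattern.name, i, window))
    return hits


def kozak_verdict(heptamer: str) -> KozakContext:
    """Evaluate the translation-initiation context of an ``NNN-ATG-N`` heptamer.

    Favorable iff the −3 position (character 1) is a purine (A/G) or the +4
    position (character 7) is G; a single strong position suffices.
    """
    if len(heptamer) != 7:
        raise ValueError(f"heptamer must have length 7, got {len(heptamer)}")
    if heptamer[3:6].upper() != "ATG":
        raise ValueError(f"{heptamer!r}: positions 4-6 are not ATG")
    up = heptamer.upper()
    favorable = up[0] in "AG" or up[6] == "G"
    return KozakContext(heptamer, "favorable" if favorable else "unfavorable")


# Inhibitory-motif classes, in decreasing order of strength.  A perfect ITIM
# is the strongest statement; the (F/Y)xxL(D/E) motif is "ITIM-like"; YxxM is
# a weaker SH2-docking variant seen in some teleost LAG-3 tails.
CANONICAL_ITIM = compile_pattern("[IVL]xYxx[LV]", "itim_canonical")
ITIM_LIKE = compile_pattern("[FY]xxL[DE]", "itim_like")
YXXM = compile_pattern("YxxM", "yxxm")


def classify_inhibitory_motif(fragment: str) -> str:
    """Classify a tail (sub)sequence into one inhibitory-motif class.

    Precedence: ``canonical_ITIM`` > ``ITIM_like`` > ``YxxM`` > ``none``.
    """
    if scan(fragment, CANONICAL_ITIM):
        return "canonical_ITIM"
    if scan(fragment, ITIM_LIKE):
        return "ITIM_like"
    if scan(fragment, YXXM):
        return "YxxM"
    return "none"


def load_catalogue(path: str | Path | None = None) -> dict[str, MotifPattern]:
    """Load the shipped motif catalogue (name → compiled pattern).

    The catalogue is a TSV of (name, pattern, note); a custom file with the
    same columns can be supplied.
    """
    if path is None:
        source = resources.files("cd4lag3.data").joinpath("motif_catalogue.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    catalogue: dict[str, MotifPattern] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        name, spec = fields[0], fields[1]
        catalogue[name] = compile_pattern(spec, name)
    return catalogue
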