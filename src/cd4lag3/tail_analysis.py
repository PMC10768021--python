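"""Transmembrane segment location and cytoplasmic-tail feature extraction.

The functional split between CD4 and LAG-3 lives in the cytoplasmic tail:
CD4-type tails carry a Cx(C/H) zinc-clasp (CxF in one sturgeon CD4-2
variant), often preceded by a tyrosine, an amphipathic membrane-proximal
helix, and — in ray-finned-fish CD4-1 — a conserved C-terminal motif;
LAG-3-type tails carry an ITIM-like (F/Y)xxL(D/E) motif (a canonical ITIM or
YxxM in some teleosts) and, in tetrapods, an acidic EP-repeat end.  This
module finds the transmembrane span, cuts the tail, and measures all of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from . import motif_engine

#: Window length of the transmembrane search and its mean-hydropathy cutoff.
TM_WINDOW = 19
TM_MIN_MEAN_HYDROPATHY = 1.5

#: Eisenberg consensus hydrophobicity scale (Eisenberg et al. 1984),
#: used for the helical hydrophobic moment.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Alpha-helical twist used for the hydrophobic moment (≈3.6 residues/turn).
HELIX_DEGREES_PER_RESIDUE = 100.0

AMPHIPATHIC_WINDOW = 11
ACIDIC_WINDOW = 17
CD41_CTERM_SEARCH = 12  # the CD4-1 motif sits in the last coding exon
BASIC_START_WINDOW = 5

_CLASP_PATTERNS = (
    ("CxC", motif_engine.compile_pattern("CxC", "CxC")),
    ("CxH", motif_engine.compile_pattern("CxH", "CxH")),
    ("CxF", motif_engine.compile_pattern("CxF", "CxF")),
)
_CD41_CTERM = motif_engine.compile_pattern("P[KQ]P[KR][AG]FY[HKR]", "cd41_cterm")
_EP = "EP"


class TailAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class TailProfile:
    tm_span: tuple[int, int]
    tail: str
    clasp: str  # "CxC" | "CxH" | "CxF" | "none"
    clasp_pos: int | None
    preceding_tyr: bool
    inhibitory: str  # classify_inhibitory_motif over the tail
    cd41_cterm_motif: bool
    ep_repeat_n: int
    acidic_fraction: float
    amphipathic_score: float
    basic_start: bool


def find_tm(sequence: str) -> tuple[int, int]:
    """Most hydrophobic 19-residue window (Kyte-Doolittle mean ≥ 1.5).

    Ties go to the most C-terminal window, because the tail is defined as
    everything downstream of the reported span.  Residues without a scale
    value (X) score 0.
    """
    n = len(sequence)
    if n < TM_WINDOW:
        raise TailAnalysisError(
            f"sequence of length {n} shorter than TM window {TM_WINDOW}"
        )
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in sequence])
    means = np.convolve(values, np.ones(TM_WINDOW) / TM_WINDOW, mode="valid")
    best = float(means.max())
    if best < TM_MIN_MEAN_HYDROPATHY:
        raise TailAnalysisError("no TM segment")
    start = int(np.flatnonzero(means >= best - 1e-12)[-1])
    return start, start + TM_WINDOW


def clasp_motif(tail: str) -> tuple[str, int | None, bool]:
    """Zinc-clasp call with precedence CxC > CxH > CxF.

    Returns (motif class, position of first hit, tyrosine-immediately-before
    flag).  The precedence is by motif class, not position: any CxC anywhere
    outranks a CxH earlier in the tail.
    """
    for name, pattern in _CLASP_PATTERNS:
        hits = motif_engine.scan(tail, pattern)
        if hits:
            pos = hits[0].start
            preceded = pos > 0 and tail[pos - 1] == "Y"
            return name, pos, preceded
    return "none", None, False


def ep_repeat(tail: str) -> int:
    """Maximal n such that (EP)^n occurs as a contiguous substring."""
    best = 0
    for i in range(len(tail)):
        n = 0
        j = i
        while tail[j : j + 2] == _EP:
            n += 1
            j += 2
        best = max(best, n)
    return best


def acidic_fraction(tail: str, window: int = ACIDIC_WINDOW) -> float:
    """Fraction of D/E over the final ``min(window, len)`` residues."""
    if not tail:
        raise TailAnalysisError("empty tail")
    w = min(window, len(tail))
    seg = tail[-w:]
    return sum(seg.count(a) for a in "DE") / w


def amphipathic_score(tail: str, window: int = AMPHIPATHIC_WINDOW) -> float:
    """Maximal per-residue helical hydrophobic moment over tail windows.

    For each window the Eisenberg hydrophobicities are centered on the
    window mean and summed as vectors rotated 100° per residue; the moment
    is the magnitude of that sum divided by the window length.  Centering
    makes the score a measure of *periodic variation*: a uniform stretch has
    no amphipathy and scores exactly 0, however hydrophobic it is.
    """
    if len(tail) < window:
        return 0.0
    values = np.array([EISENBERG.get(a, 0.0) for a in tail])
    angles = np.deg2rad(HELIX_DEGREES_PER_RESIDUE) * np.arange(window)
    phasor = np.exp(1j * angles)
    best = 0.0
    for i in range(len(tail) - window + 1):
        w = values[i : i + window]
        centered = w - w.mean()
        moment = abs(np.sum(centered * phasor)) / window
        if moment < 1e-12:  # numerical zero from the mean subtraction
            moment = 0.0
        best = max(best, float(moment))
    return best


def profile_tail(
    sequence: str, tm_span: tuple[int, int] | None = None
) -> TailProfile:
    """All cytoplasmic-tail features of a full-length precursor sequence.

    The TM span is located with :func:`find_tm` unless supplied; the tail is
    everything downstream of it.
    """
    if tm_span is None:
        tm_span = find_tm(sequence)
    tail = sequence[tm_span[1] :]
    if not tail:
        raise TailAnalysisError("no cytoplasmic tail downstream of the TM span")
    clasp, clasp_pos, preceded = clasp_motif(tail)
    cterm = tail[-CD41_CTERM_SEARCH:]
    return TailProfile(
        tm_span=tm_span,
        tail=tail,
        clasp=clasp,
        clasp_pos=clasp_pos,
        preceding_tyr=preceded,
        inhibitory=motif_engine.classify_inhibitory_motif(tail),
        cd41_cterm_motif=bool(motif_engine.scan(cterm, _CD41_CTERM)),
        ep_repeat_n=ep_repeat(tail),
        acidic_fraction=acidic_fraction(tail),
        amphipathic_score=amphipathic_score(tail),
        basic_start=any(a in "KR" for a in tail[:BASIC_START_WINDOW]),
    )
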