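"""Head-to-tail gene-orientation evidence from a gene-order table.

The ancestral organization of the locus is CD4 in tandem, same-strand,
directly downstream of LAG-3 — conserved in sharks, bichirs, and tetrapods,
broken in modern ray-finned fish.  The check is purely relative (a strand
flip of the whole region changes nothing) and tolerates a small number of
intervening genes, which covers the lungfish CD4/LAG-3 hybrid sitting
between the two and shark pseudogene fragments near the intact gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SYNTENY_COLUMNS = ["gene", "seq_id", "start", "end", "strand"]

#: Annotated genes allowed between the pair before tandemness is rejected.
MAX_INTERVENING = 2


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class TandemResult:
    """Outcome of a head-to-tail check.

    ``status`` is "tandem", "not_tandem", or "not_evaluable" (a gene absent
    from the table — missing synteny is absent evidence, not negative
    evidence).  ``verdict`` maps those to True / False / None.
    """

    status: str
    upstream: str
    downstream: str
    evidence: dict = field(default_factory=dict)

    @property
    def verdict(self) -> bool | None:
        return {"tandem": True, "not_tandem": False}.get(self.status)


def read_synteny_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SYNTENY_COLUMNS if c not in df.columns]
    if missing:
        raise SyntenyError(f"{path}: missing columns {missing}")
    return df.sort_values(["seq_id", "start"]).reset_index(drop=True)


def _single_row(table: pd.DataFrame, gene: str):
    rows = table[table["gene"] == gene]
    if rows.empty:
        return None
    return rows.iloc[0]


def head_to_tail(
    table: pd.DataFrame,
    upstream: str = "LAG-3",
    downstream: str = "CD4",
    max_intervening: int = MAX_INTERVENING,
) -> TandemResult:
    """Is *downstream* in same-strand tandem orientation behind *upstream*?

    True iff both genes share a sequence and a strand, the downstream gene
    begins at or after the upstream gene's end *in transcription
    orientation*, and at most *max_intervening* annotated genes lie between
    them.
    """
    up = _single_row(table, upstream)
    down = _single_row(table, downstream)
    if up is None or down is None:
        absent = [g for g, r in ((upstream, up), (downstream, down)) if r is None]
        return TandemResult(
            "not_evaluable", upstream, downstream, {"absent": absent}
        )
    evidence: dict = {
        "seq_id": (up["seq_id"], down["seq_id"]),
        "strands": (up["strand"], down["strand"]),
    }
    if up["seq_id"] != down["seq_id"] or up["strand"] != down["strand"]:
        return TandemResult("not_tandem", upstream, downstream, evidence)
    if up["strand"] == "+":
        ordered = down["start"] >= up["end"]
        lo, hi = up["end"], down["start"]
    else:
        ordered = down["end"] <= up["start"]
        lo, hi = down["end"], up["start"]
    if not ordered:
        evidence["reason"] = "order/orientation violated"
        return TandemResult("not_tandem", upstream, downstream, evidence)
    between = table[
        (table["seq_id"] == up["seq_id"])
        & (table["gene"] != upstream)
        & (table["gene"] != downstream)
        & (table["start"] >= lo)
        & (table["end"] <= hi)
    ]
    evidence["intervening"] = between["gene"].tolist()
    if len(between) > max_intervening:
        evidence["reason"] = f"more than {max_intervening} intervening genes"
        return TandemResult("not_tandem", upstream, downstream, evidence)
    return TandemResult("tandem", upstream, downstream, evidence)


def _norm(name: str) -> str:
    return name.upper().replace("-", "").replace("_", "")


def tandem_role(
    table: pd.DataFrame,
    gene: str,
    upstream_family: str = "LAG3",
    downstream_family: str = "CD4",
    max_intervening: int = MAX_INTERVENING,
) -> str:
    """Role of *gene* in a LAG-3 → CD4 tandem pair.

    Partners are other table entries whose (annotation-derived) names contain
    the family tokens.  Returns "downstream" when an upstream-family gene
    sits head-to-tail before *gene*, "upstream" when *gene* sits head-to-tail
    before a downstream-family gene, "none" when neither or both hold (a gene
    flanked on both sides is positionally uninformative), and "unknown" when
    *gene* is absent from the table.
    """
    row = _single_row(table, gene)
    if row is None:
        return "unknown"
    local = table[table["seq_id"] == row["seq_id"]]
    others = local[local["gene"] != gene]
    is_down = any(
        head_to_tail(local, partner, gene, max_intervening).verdict
        for partner in others.loc[
            others["gene"].map(lambda n: upstream_family in _norm(n)), "gene"
        ]
    )
    is_up = any(
        head_to_tail(local, gene, partner, max_intervening).verdict
        for partner in others.loc[
            others["gene"].map(lambda n: downstream_family in _norm(n)), "gene"
        ]
    )
    if is_down and not is_up:
        return "downstream"
    if is_up and not is_down:
        return "upstream"
    return "none"
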