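"""TPM normalization, the thymus-dominance criterion, and qPCR quantification.

CD4 is a T-lineage marker and its transcripts peak in the thymus in every
jawed vertebrate examined; LAG-3, an activation marker, shows no consistent
thymus bias.  The operational criterion used here is a thymus:spleen TPM
ratio of at least five (configurable) — the pattern observed in the nurse
shark thymus/spleen transcriptomes.  qPCR tables are reduced the standard
relative-quantification way: target amount over housekeeping amount per
replicate, tissue means scaled so the calibrator tissue is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Pseudocount (TPM) added to the reference tissue, so near-zero reference
#: values (they occur: PAX5 in thymus is 0.04 TPM) yield finite ratios.
RATIO_PSEUDOCOUNT = 0.01

#: Default fold-change for calling a gene dominant in the test tissue.
DOMINANCE_THRESHOLD = 5.0

QPCR_COLUMNS = ["gene", "tissue", "replicate", "target_amount", "housekeeping_amount"]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class DominanceResult:
    gene: str
    test_tissue: str
    ref_tissue: str
    ratio: float
    dominant: bool
    threshold: float


def tpm_from_counts(counts, effective_lengths) -> np.ndarray:
    """Transcripts-per-million from read counts and effective lengths.

    ``rate_i = count_i / length_i``; TPM is the rate vector rescaled to sum
    to 1e6.  All-zero counts are an error (no library to normalize).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ExpressionError("counts and lengths must have the same shape")
    if np.any(lengths <= 0):
        raise ExpressionError("effective lengths must be positive")
    if np.any(counts < 0):
        raise ExpressionError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise ExpressionError("all counts are zero")
    return rates / total * 1e6


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes × tissues TPM table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ExpressionError(f"{path}: negative expression values")
    return df


def load_nurse_shark_tpm() -> pd.DataFrame:
    """The shipped nurse-shark thymus/spleen TPM table (9 immune genes)."""
    source = resources.files("cd4lag3.data").joinpath(
        "nurse_shark_thymus_spleen_tpm.tsv"
    )
    with resources.as_file(source) as p:
        return read_expression_tsv(p)


def tissue_dominance(
    matrix: pd.DataFrame,
    gene: str,
    test_tissue: str,
    ref_tissue: str,
    threshold: float = DOMINANCE_THRESHOLD,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> DominanceResult:
    """Is *gene* expressed ≥ *threshold*-fold higher in *test* than *ref*?"""
    if gene not in matrix.index:
        raise ExpressionError(f"gene {gene!r} not in expression matrix")
    for t in (test_tissue, ref_tissue):
        if t not in matrix.columns:
            raise ExpressionError(f"tissue {t!r} not in expression matrix")
    test = float(matrix.loc[gene, test_tissue])
    ref = float(matrix.loc[gene, ref_tissue])
    ratio = test / (ref + pseudocount)
    return DominanceResult(
        gene=gene,
        test_tissue=test_tissue,
        ref_tissue=ref_tissue,
        ratio=ratio,
        dominant=ratio >= threshold,
        threshold=threshold,
    )


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionError(f"{path}: missing qPCR columns {missing}")
    return df


def qpcr_relative(table: pd.DataFrame, calibrator_tissue: str) -> pd.DataFrame:
    """Relative qPCR quantities, calibrator tissue set to exactly 1.

    Per replicate the target amount is divided by the housekeeping amount;
    per gene the per-tissue mean of those normalized values is divided by
    the calibrator tissue's mean.  Invariant under any global rescaling of
    target or housekeeping amounts.
    """
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ExpressionError(f"qPCR table missing columns {missing}")
    if (table["housekeeping_amount"] <= 0).any():
        raise ExpressionError("housekeeping amounts must be positive")
    if (table["target_amount"] <= 0).any():
        raise ExpressionError("target amounts must be positive")
    work = table.assign(norm=table["target_amount"] / table["housekeeping_amount"])
    means = work.groupby(["gene", "tissue"])["norm"].mean().unstack("tissue")
    if calibrator_tissue not in means.columns:
        raise ExpressionError(f"calibrator tissue {calibrator_tissue!r} absent")
    if means[calibrator_tissue].isna().any():
        genes = means.index[means[calibrator_tissue].isna()].tolist()
        raise ExpressionError(
            f"calibrator tissue missing for gene(s) {genes}"
        )
    return means.div(means[calibrator_tissue], axis=0)
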