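"""Per-cell quality metrics and the three exclusion rules.

A cell is excluded when it has 1000 or fewer total UMIs, 256 or fewer
detected genes, or a mitochondrial fraction strictly greater than 10%.
Boundary semantics are literal: a cell at exactly 1000 UMIs or exactly 256
genes is excluded; a mitochondrial fraction of exactly 0.10 is retained.
The rules are evaluated independently and every violated rule is recorded.

The mitochondrial fraction is computed from UMI counts by default
(``mito_basis="counts"``, the field-standard metric); ``mito_basis="genes"``
instead takes the fraction of *detected* genes that are mitochondrial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneExpressionMatrix

RULE_LOW_UMI = "low_umi"
RULE_LOW_GENES = "low_genes"
RULE_HIGH_MITO = "high_mito"
RULES = (RULE_LOW_UMI, RULE_LOW_GENES, RULE_HIGH_MITO)


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds.

    ``max_excluded_umi`` and ``max_excluded_genes`` are inclusive upper
    bounds of the *excluded* range; ``max_mito_fraction`` is the largest
    retained fraction.
    """

    max_excluded_umi: int = 1000
    max_excluded_genes: int = 256
    max_mito_fraction: float = 0.10
    mito_prefix: str = "mt-"
    mito_basis: str = "counts"

    def __post_init__(self) -> None:
        if self.max_excluded_umi < 0 or self.max_excluded_genes < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.mito_basis not in ("counts", "genes"):
            raise ValueError("mito_basis must be 'counts' or 'genes'")


def exclusion_percentage(n_excluded: int, n_input: int) -> float:
    """Percentage of excluded cells, one decimal; 0.0 for empty input."""
    if n_input == 0:
        return 0.0
    return round(100.0 * n_excluded / n_input, 1)


def compute_cell_qc(
    matrix: GeneExpressionMatrix, thresholds: QCThresholds = QCThresholds()
) -> pd.DataFrame:
    """One record per barcode with metrics, rule flags and exclusion status.

    Columns: ``total_umis``, ``detected_genes``, ``mito_fraction``,
    ``low_umi``, ``low_genes``, ``high_mito``, ``excluded``,
    ``violated_rules`` (semicolon-joined).
    """
    counts = matrix.counts.copy()
    counts.eliminate_zeros()
    total = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)
    detected = counts.getnnz(axis=1).astype(np.int64)

    mito_mask = np.array(
        [str(g).startswith(thresholds.mito_prefix) for g in matrix.genes], dtype=bool
    )
    if mito_mask.any():
        mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
        mito_detected = counts[:, mito_mask].getnnz(axis=1)
    else:
        mito_counts = np.zeros(matrix.n_cells)
        mito_detected = np.zeros(matrix.n_cells, dtype=np.int64)

    if thresholds.mito_basis == "counts":
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    else:
        mito_fraction = np.where(
            detected > 0, mito_detected / np.maximum(detected, 1), 0.0
        )

    low_umi = total <= thresholds.max_excluded_umi
    low_genes = detected <= thresholds.max_excluded_genes
    high_mito = mito_fraction > thresholds.max_mito_fraction
    excluded = low_umi | low_genes | high_mito

    flags = np.stack([low_umi, low_genes, high_mito], axis=1)
    violated = [
        ";".join(rule for rule, hit in zip(RULES, row) if hit) for row in flags
    ]
    return pd.DataFrame(
        {
            "total_umis": total,
            "detected_genes": detected,
            "mito_fraction": mito_fraction,
            "low_umi": low_umi,
            "low_genes": low_genes,
            "high_mito": high_mito,
            "excluded": excluded,
            "violated_rules": violated,
        },
        index=pd.Index(matrix.barcodes.astype(str), name="barcode"),
    )


def apply_qc(
    matrix: GeneExpressionMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GeneExpressionMatrix, pd.DataFrame, dict]:
    """Filter a matrix, returning (retained matrix, QC report, summary).

    The retained matrix holds exactly the non-excluded barcodes in their
    original order. The summary reports ``n_input``, ``n_excluded``,
    ``n_retained`` and ``pct_excluded`` (one decimal).
    """
    report = compute_cell_qc(matrix, thresholds)
    keep = ~report["excluded"].to_numpy()
    filtered = matrix.subset(keep)
    n_input = matrix.n_cells
    n_excluded = int(report["excluded"].sum())
    summary = {
        "n_input": n_input,
        "n_excluded": n_excluded,
        "n_retained": n_input - n_excluded,
        "pct_excluded": exclusion_percentage(n_excluded, n_input),
    }
    return filtered, report, summary
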