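"""Per-cell-type dark-vs-light differential expression.

For every annotated cell type (excluding "Others") each gene is tested with
a two-sided Wilcoxon rank-sum (tie-corrected normal approximation; exact
enumeration for groups of 8 or fewer cells per condition). Fold changes are
computed on depth-normalised means with a pseudocount of 1/target_sum, so
all-zero genes give log2FC = 0. Significance is the raw p < alpha filter
used for the headline per-type up/down counts; a BH-FDR column is emitted
alongside but not used for those counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from ._stats import ranksum_p
from .cell_typing import OTHERS, DEFAULT_TARGET_SUM, normalize_counts
from .io import GeneExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEConfig:
    alpha: float = 0.05
    min_cells_per_group: int = 3
    target_sum: float = DEFAULT_TARGET_SUM
    test: str = "wilcoxon"  # or "permutation"
    n_permutations: int = 9999
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in ("wilcoxon", "permutation"):
            raise ValueError("test must be 'wilcoxon' or 'permutation'")

    @property
    def pseudocount(self) -> float:
        return 1.0 / self.target_sum


def _labels_for(matrix: GeneExpressionMatrix, assignments: pd.Series) -> np.ndarray:
    barcodes = pd.Index(matrix.barcodes.astype(str))
    missing = barcodes.difference(assignments.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} barcodes have no assignment (e.g. {missing[0]!r})"
        )
    return assignments.reindex(barcodes).to_numpy()


def de_per_type(
    matrix_dark: GeneExpressionMatrix,
    matrix_light: GeneExpressionMatrix,
    assignments: pd.Series | pd.DataFrame,
    config: DEConfig = DEConfig(),
    types: list[str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Dark-vs-light DE per (cell type, gene).

    ``assignments`` is a Series mapping barcode to cell-type label covering
    both conditions (or an ``assign_types`` DataFrame). Types with fewer
    than ``min_cells_per_group`` cells in either condition are skipped with
    a logged notice. ``types`` and ``genes`` optionally restrict the
    computation (depth normalisation always uses the full gene universe).
    Returns one row per (eligible type, gene) with ``log2fc`` (light over
    dark), ``p_value``, ``q_value`` (BH within type), group sizes,
    normalised means, ``significant`` and ``direction``.
    """
    if isinstance(assignments, pd.DataFrame):
        assignments = assignments["assigned_type"]
    if list(matrix_dark.genes) != list(matrix_light.genes):
        raise ValueError("gene universes of the two conditions differ")

    labels_dark = _labels_for(matrix_dark, assignments)
    labels_light = _labels_for(matrix_light, assignments)

    norm_dark = normalize_counts(matrix_dark, target_sum=config.target_sum)
    norm_light = normalize_counts(matrix_light, target_sum=config.target_sum)
    eps = config.pseudocount
    all_genes = matrix_dark.genes.astype(str)
    if genes is None:
        gene_cols = slice(None)
        gene_names = all_genes
    else:
        index = {g: i for i, g in enumerate(all_genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValueError(f"genes absent from universe: {missing}")
        gene_cols = np.array([index[g] for g in genes])
        gene_names = np.array(genes, dtype=object)

    if types is None:
        types = [
            t
            for t in pd.unique(np.concatenate([labels_dark, labels_light]))
            if t != OTHERS
        ]
        types = sorted(types)

    frames = []
    for cell_type in types:
        mask_d = labels_dark == cell_type
        mask_l = labels_light == cell_type
        n_d, n_l = int(mask_d.sum()), int(mask_l.sum())
        if min(n_d, n_l) < config.min_cells_per_group:
            logger.info(
                "skipping %s: %d dark / %d light cells below minimum %d",
                cell_type,
                n_d,
                n_l,
                config.min_cells_per_group,
            )
            continue
        x = np.asarray(norm_dark.linear[mask_d][:, gene_cols].todense())
        y = np.asarray(norm_light.linear[mask_l][:, gene_cols].todense())
        p = ranksum_p(
            x,
            y,
            method=config.test,
            n_permutations=config.n_permutations,
            seed=config.permutation_seed,
        )
        mean_d = x.mean(axis=0)
        mean_l = y.mean(axis=0)
        log2fc = np.log2((mean_l + eps) / (mean_d + eps))
        direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
        significant = (p < config.alpha) & (direction != "none")
        frames.append(
            pd.DataFrame(
                {
                    "cell_type": cell_type,
                    "gene": gene_names,
                    "log2fc": log2fc,
                    "p_value": p,
                    "q_value": false_discovery_control(p, method="bh"),
                    "n_dark": n_d,
                    "n_light": n_l,
                    "mean_dark": mean_d,
                    "mean_light": mean_l,
                    "significant": significant,
                    "direction": direction,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "cell_type",
                "gene",
                "log2fc",
                "p_value",
                "q_value",
                "n_dark",
                "n_light",
                "mean_dark",
                "mean_light",
                "significant",
                "direction",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def count_significant(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-type counts of significantly up- and downregulated genes.

    n_up = #{genes with p < alpha and log2FC > 0}; n_down likewise with
    log2FC < 0.
    """
    if de.empty:
        return pd.DataFrame(columns=["n_up", "n_down"])
    sig = de["p_value"] < alpha
    up = sig & (de["log2fc"] > 0)
    down = sig & (de["log2fc"] < 0)
    out = (
        pd.DataFrame({"cell_type": de["cell_type"], "n_up": up, "n_down": down})
        .groupby("cell_type", sort=True)
        .sum()
    )
    return out.astype(int)


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (log2FC, -log10 p, significance) per cell type.

    p values are floored at the smallest positive float before the log.
    """
    tiny = np.finfo(np.float64).tiny
    p = np.maximum(de["p_value"].to_numpy(dtype=np.float64), tiny) if len(de) else []
    return pd.DataFrame(
        {
            "cell_type": de.get("cell_type", pd.Series(dtype=object)),
            "gene": de.get("gene", pd.Series(dtype=object)),
            "log2fc": de.get("log2fc", pd.Series(dtype=float)),
            "neg_log10_p": -np.log10(p) if len(de) else pd.Series(dtype=float),
            "significant": de.get("significant", pd.Series(dtype=bool)),
        }
    )
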