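"""Priority-ordered marker-based cell-type annotation.

Each QC-passing cell is scored against an ordered marker panel (mean
log-normalised expression of each type's markers) and receives the first
type in priority order whose score exceeds the threshold; cells passing no
rule fall through to "Others". The priority order places the rarer retinal
identities (RPE, endothelial, microglia, ...) before the dominant rod
signature so that co-expression resolves in their favour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import reference
from .io import GeneExpressionMatrix
from .qc import exclusion_percentage

logger = logging.getLogger(__name__)

OTHERS = reference.OTHERS
TOTAL = "Total"

DEFAULT_TARGET_SUM = 10_000.0
DEFAULT_SCORE_THRESHOLD = 0.5


class MissingMarkersError(ValueError):
    """All markers of a panel type are absent from the gene universe."""


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered (cell type, marker genes) entries; order is the priority."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        names = [t for t, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("cell-type names must be unique")
        for name, markers in self.entries:
            if not markers:
                raise ValueError(f"marker list for {name!r} is empty")

    @classmethod
    def default(cls) -> "MarkerPanel":
        return cls(
            tuple(
                (t, tuple(reference.DEFAULT_MARKERS[t]))
                for t in reference.PRIORITY_ORDER
            )
        )

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    def markers(self, cell_type: str) -> tuple[str, ...]:
        for t, m in self.entries:
            if t == cell_type:
                return m
        raise KeyError(cell_type)

    @property
    def all_markers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, markers in self.entries:
            for m in markers:
                seen.setdefault(m, None)
        return tuple(seen)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("priority_rank")
        entries = tuple(
            (row["cell_type"], tuple(str(row["markers"]).split(",")))
            for _, row in df.iterrows()
        )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"priority_rank": i + 1, "cell_type": t, "markers": ",".join(m)}
            for i, (t, m) in enumerate(self.entries)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedExpression:
    """Depth-normalised, log1p-transformed expression (cells x genes)."""

    barcodes: np.ndarray
    genes: np.ndarray
    values: sp.csr_matrix  # log1p of counts-per-target_sum
    linear: sp.csr_matrix  # counts-per-target_sum (no log)
    condition: np.ndarray | None
    target_sum: float


def normalize_counts(
    matrix: GeneExpressionMatrix, target_sum: float = DEFAULT_TARGET_SUM
) -> NormalizedExpression:
    """Scale each cell to ``target_sum`` total counts, then log(1+x).

    Deterministic; a cell with zero total counts (which cannot occur after
    QC) raises ``ValueError``.
    """
    counts = matrix.counts.astype(np.float64).tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cannot normalise cells with zero total counts")
    scale = sp.diags(target_sum / totals)
    linear = (scale @ counts).tocsr()
    values = linear.copy()
    values.data = np.log1p(values.data)
    return NormalizedExpression(
        barcodes=matrix.barcodes,
        genes=matrix.genes,
        values=values,
        linear=linear,
        condition=matrix.condition,
        target_sum=target_sum,
    )


def score_markers(
    normalized: NormalizedExpression,
    panel: MarkerPanel,
    allow_missing_markers: bool = False,
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Per-cell, per-type score: mean log-normalised expression of the
    type's markers that are present in the gene universe.

    Markers absent from the matrix are dropped with a warning; a type whose
    markers are all absent is a hard error unless ``allow_missing_markers``
    (then the type is skipped and can never be assigned).
    """
    genes = [str(g) for g in normalized.genes]
    if case_insensitive:
        index = {g.casefold(): i for i, g in enumerate(genes)}
        lookup = lambda g: index.get(g.casefold())  # noqa: E731
    else:
        index = {g: i for i, g in enumerate(genes)}
        lookup = index.get

    kept_types: list[str] = []
    weights = np.zeros((len(genes), len(panel.entries)))
    for cell_type, markers in panel.entries:
        cols = []
        for marker in markers:
            i = lookup(marker)
            if i is None:
                logger.warning(
                    "marker %s of %s absent from gene universe; dropped",
                    marker,
                    cell_type,
                )
            else:
                cols.append(i)
        if not cols:
            msg = f"all markers of {cell_type!r} are absent from the matrix"
            if not allow_missing_markers:
                raise MissingMarkersError(msg)
            logger.warning("%s; type skipped", msg)
            continue
        weights[cols, len(kept_types)] = 1.0 / len(cols)
        kept_types.append(cell_type)
    score_matrix = np.asarray(normalized.values @ weights[:, : len(kept_types)])
    return pd.DataFrame(
        score_matrix,
        columns=kept_types,
        index=pd.Index(normalized.barcodes.astype(str), name="barcode"),
    )


def assign_types(
    scores: pd.DataFrame,
    panel: MarkerPanel,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """First-match-wins assignment over the panel order.

    Returns a DataFrame indexed by barcode with ``assigned_type`` (panel
    type or "Others") and ``decision_basis`` ("priority_match" or
    "fallthrough").
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ordered = [t for t in panel.types if t in scores.columns]
    if ordered:
        passed = scores[ordered].to_numpy() > threshold
        any_pass = passed.any(axis=1)
        first = passed.argmax(axis=1)
        labels = np.where(any_pass, np.array(ordered, dtype=object)[first], OTHERS)
    else:
        any_pass = np.zeros(len(scores), dtype=bool)
        labels = np.full(len(scores), OTHERS, dtype=object)
    return pd.DataFrame(
        {
            "assigned_type": labels,
            "decision_basis": np.where(any_pass, "priority_match", "fallthrough"),
        },
        index=scores.index,
    )


def classify(
    matrix: GeneExpressionMatrix,
    panel: MarkerPanel | None = None,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    target_sum: float = DEFAULT_TARGET_SUM,
    **score_kwargs,
) -> pd.DataFrame:
    """Normalise, score and assign in one call."""
    panel = panel or MarkerPanel.default()
    normalized = normalize_counts(matrix, target_sum=target_sum)
    scores = score_markers(normalized, panel, **score_kwargs)
    return assign_types(scores, panel, threshold=threshold)


def _pct(n: int, total: int) -> float:
    return exclusion_percentage(n, total)  # same 100*n/total, one decimal


def composition_from_counts(
    n_dark: dict[str, int], n_light: dict[str, int]
) -> pd.DataFrame:
    """Composition table from per-type cell counts for the two conditions.

    Named types are sorted by (dark count, light count) descending; the
    "Others" row and a "Total" row come last. Percentages are of the
    condition total, one decimal.
    """
    types = sorted(
        (t for t in set(n_dark) | set(n_light) if t != OTHERS),
        key=lambda t: (-n_dark.get(t, 0), -n_light.get(t, 0), t),
    )
    if OTHERS in set(n_dark) | set(n_light):
        types.append(OTHERS)
    total_dark = sum(n_dark.values())
    total_light = sum(n_light.values())
    rows = []
    for t in types:
        nd, nl = n_dark.get(t, 0), n_light.get(t, 0)
        rows.append(
            {
                "cell_type": t,
                "n_dark": nd,
                "n_light": nl,
                "pct_dark": _pct(nd, total_dark),
                "pct_light": _pct(nl, total_light),
            }
        )
    rows.append(
        {
            "cell_type": TOTAL,
            "n_dark": total_dark,
            "n_light": total_light,
            "pct_dark": 100.0 if total_dark else 0.0,
            "pct_light": 100.0 if total_light else 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("cell_type")


def composition_table(
    assignments: dict[str, pd.Series | pd.DataFrame],
    panel: MarkerPanel | None = None,
) -> pd.DataFrame:
    """Composition table from per-condition assignments.

    ``assignments`` maps condition name ("dark"/"light") to either an
    assignment DataFrame from :func:`assign_types` or a Series of labels.
    All panel types are reported even when empty.
    """
    panel = panel or MarkerPanel.default()

    def _labels(obj) -> pd.Series:
        if isinstance(obj, pd.DataFrame):
            return obj["assigned_type"]
        return obj

    counts: dict[str, dict[str, int]] = {}
    for cond, obj in assignments.items():
        vc = _labels(obj).value_counts()
        counts[cond] = {t: int(vc.get(t, 0)) for t in (*panel.types, OTHERS)}
    dark = counts.get("dark", {t: 0 for t in (*panel.types, OTHERS)})
    light = counts.get("light", {t: 0 for t in (*panel.types, OTHERS)})
    table = composition_from_counts(dark, light)
    markers = {t: ", ".join(panel.markers(t)) for t in panel.types}
    table.insert(0, "markers", [markers.get(t, "–") for t in table.index])
    return table
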