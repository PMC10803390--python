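"""End-to-end orchestration: simulate/read -> QC -> classify -> DE -> reports.

A single seeded, configured run writes the QC reports, assignments, the
Table-style composition report (marker genes, per-type counts and
percentages, per-type up/down DE counts), the DE and volcano tables, and a
machine-readable summary. One pipeline seed fans out deterministically to
per-stage child seeds, so every artifact is reproducible from config+seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell_typing import (
    DEFAULT_SCORE_THRESHOLD,
    MarkerPanel,
    OTHERS,
    assign_types,
    composition_table,
    normalize_counts,
    score_markers,
)
from .diff_expr import DEConfig, count_significant, de_per_type, volcano_table
from .io import GeneExpressionMatrix, read_mtx_triplet
from .qc import QCThresholds, apply_qc
from .simulate import SyntheticConfig, generate_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one input source per condition: MTX directories xor a
    synthetic-data config."""

    out_dir: Path
    synthetic: SyntheticConfig | None = None
    dark_dir: Path | None = None
    light_dir: Path | None = None
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    panel: MarkerPanel = field(default_factory=MarkerPanel.default)
    classification_threshold: float = DEFAULT_SCORE_THRESHOLD
    de: DEConfig = field(default_factory=DEConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.dark_dir is not None and self.light_dir is not None
        from_synthetic = self.synthetic is not None
        if from_files == from_synthetic:
            raise ValueError(
                "provide either dark_dir+light_dir or a synthetic config, not both"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {"out_dir": Path(raw["out_dir"])}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "dark_dir" in raw:
            kwargs["dark_dir"] = Path(raw["dark_dir"])
            kwargs["light_dir"] = Path(raw["light_dir"])
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "qc" in raw:
            kwargs["qc_thresholds"] = QCThresholds(**raw["qc"])
        if "panel" in raw:
            kwargs["panel"] = MarkerPanel.from_tsv(raw["panel"])
        if "classification_threshold" in raw:
            kwargs["classification_threshold"] = float(raw["classification_threshold"])
        if "de" in raw:
            kwargs["de"] = DEConfig(**raw["de"])
        return cls(**kwargs)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns a manifest of artifact paths and the
    summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_seed, perm_seed = _child_seeds(config.seed, 2)

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=gen_seed)
        logger.info("stage simulate: seed %d", gen_seed)
        dark, light, truth = generate_counts(syn)
        truth.to_tsv(out / "ground_truth.tsv")
    else:
        logger.info("stage read: %s / %s", config.dark_dir, config.light_dir)
        dark = read_mtx_triplet(config.dark_dir, condition="dark")
        light = read_mtx_triplet(config.light_dir, condition="light")

    summary: dict = {"seed": config.seed, "conditions": {}}
    filtered: dict[str, GeneExpressionMatrix] = {}
    for name, matrix in (("dark", dark), ("light", light)):
        logger.info(
            "stage qc (%s): max_umi=%d max_genes=%d max_mito=%.3g basis=%s",
            name,
            config.qc_thresholds.max_excluded_umi,
            config.qc_thresholds.max_excluded_genes,
            config.qc_thresholds.max_mito_fraction,
            config.qc_thresholds.mito_basis,
        )
        kept, report, qc_summary = apply_qc(matrix, config.qc_thresholds)
        report.to_csv(out / f"qc_{name}.tsv", sep="\t")
        summary["conditions"][name] = qc_summary
        filtered[name] = kept

    assignments = {}
    for name, matrix in filtered.items():
        logger.info(
            "stage classify (%s): threshold %.3g", name, config.classification_threshold
        )
        normalized = normalize_counts(matrix, target_sum=config.de.target_sum)
        scores = score_markers(normalized, config.panel)
        assigned = assign_types(
            scores, config.panel, threshold=config.classification_threshold
        )
        assigned.to_csv(out / f"assignments_{name}.tsv", sep="\t")
        assignments[name] = assigned

    composition = composition_table(assignments, config.panel)

    logger.info("stage de: alpha %.3g test %s", config.de.alpha, config.de.test)
    all_assignments = pd.concat(
        [assignments["dark"]["assigned_type"], assignments["light"]["assigned_type"]]
    )
    de_cfg = dataclasses.replace(config.de, permutation_seed=perm_seed)
    de = de_per_type(filtered["dark"], filtered["light"], all_assignments, de_cfg)
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)
    volcano_table(de).to_csv(out / "volcano.tsv", sep="\t", index=False)
    de_counts = count_significant(de, alpha=config.de.alpha)
    de_counts.to_csv(out / "de_summary.csv")

    composition["n_up"] = [
        int(de_counts["n_up"].get(t, 0)) if t not in (OTHERS, "Total") else None
        for t in composition.index
    ]
    composition["n_down"] = [
        int(de_counts["n_down"].get(t, 0)) if t not in (OTHERS, "Total") else None
        for t in composition.index
    ]
    composition.to_csv(out / "composition.csv")

    summary["composition"] = {
        str(t): {
            "n_dark": int(row["n_dark"]),
            "n_light": int(row["n_light"]),
            "pct_dark": float(row["pct_dark"]),
            "pct_light": float(row["pct_light"]),
        }
        for t, row in composition.iterrows()
    }
    summary["de_counts"] = {
        str(t): {"n_up": int(r["n_up"]), "n_down": int(r["n_down"])}
        for t, r in de_counts.iterrows()
    }
    summary["thresholds"] = {
        "max_excluded_umi": config.qc_thresholds.max_excluded_umi,
        "max_excluded_genes": config.qc_thresholds.max_excluded_genes,
        "max_mito_fraction": config.qc_thresholds.max_mito_fraction,
        "mito_basis": config.qc_thresholds.mito_basis,
        "classification_threshold": config.classification_threshold,
        "alpha": config.de.alpha,
    }

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), sort_keys=True, indent=2))

    manifest = {
        "out_dir": str(out),
        "summary": str(summary_path),
        "artifacts": sorted(str(p) for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    manifest["summary_data"] = summary
    return manifest
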