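"""Seeded synthetic data with ground truth: two-condition retinal
scRNA-seq count matrices, flash-ERG traces and comparative-Ct tables.

The count generator draws each cell's library size from a log-normal, each
gene's counts from a negative binomial (gamma-Poisson) around a per-type
relative expression profile, and emulates the study design: published
dark-retina type proportions over 11 named types plus an unclassified
"Others" residue, type-specific marker elevation, a configurable fraction
of low-quality cells that each violate one of the three QC exclusion rules
by construction, and light-condition effects planted multiplicatively on
the negative-binomial means of the stated genes in the stated types only.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import reference
from .assay import ERGAmplitudes, ERGTrace
from .cell_typing import MarkerPanel
from .io import GeneExpressionMatrix, write_mtx_triplet
from .qc import RULE_HIGH_MITO, RULE_LOW_GENES, RULE_LOW_UMI, QCThresholds, compute_cell_qc

OTHERS = reference.OTHERS

#: Mouse mitochondrial genome protein-coding genes (13).
MITO_GENE_NAMES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

#: Baseline relative expression of the light-responsive genes:
#: (elsewhere level, {cell type: level}). Units are the same arbitrary
#: relative scale as the marker and background means.
EFFECT_GENE_BASELINES: dict[str, tuple[float, dict[str, float]]] = {
    "Edn2": (0.05, {reference.ROD: 1.0}),
    "Gfap": (0.05, {reference.MULLER: 2.0, reference.ASTROCYTE: 2.0}),
    "Serpina3n": (0.05, {reference.MULLER: 1.0, reference.ASTROCYTE: 1.0}),
    "S100a8": (0.05, {reference.BIPOLAR: 0.5, reference.ROD: 0.5}),
    "S100a9": (0.05, {reference.BIPOLAR: 0.5, reference.ROD: 0.5}),
    "Igf1": (0.05, {reference.ROD: 3.0, reference.ASTROCYTE: 3.0}),
    "Arr3": (0.05, {reference.CONE: 5.0, reference.ROD: 2.0}),
    "Gnat1": (0.05, {reference.ROD: 10.0, reference.CONE: 2.0}),
    "Cryaa": (1.0, {}),
    "Cryab": (1.0, {}),
}


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative 2**log2_fc change of a gene's NB mean in the stated
    cell types under the stated condition only."""

    gene: str
    cell_types: tuple[str, ...]
    condition: str = "light"
    log2_fc: float = 0.0


def default_planted_effects() -> tuple[PlantedEffect, ...]:
    """Light-condition stress signature: endothelin induction in rods,
    glial reaction, inflammatory S100 genes, broad crystallin induction,
    loss of Igf1 and of the phototransduction genes."""
    all_types = (*reference.PRIORITY_ORDER, OTHERS)
    return (
        PlantedEffect("Edn2", (reference.ROD,), "light", +2.0),
        PlantedEffect("Gfap", (reference.MULLER, reference.ASTROCYTE), "light", +1.5),
        PlantedEffect(
            "Serpina3n", (reference.MULLER, reference.ASTROCYTE), "light", +1.5
        ),
        PlantedEffect("S100a8", (reference.BIPOLAR, reference.ROD), "light", +1.5),
        PlantedEffect("S100a9", (reference.BIPOLAR, reference.ROD), "light", +1.5),
        PlantedEffect("Igf1", (reference.ROD, reference.ASTROCYTE), "light", -2.0),
        PlantedEffect("Arr3", (reference.ROD, reference.CONE), "light", -1.0),
        PlantedEffect("Gnat1", (reference.ROD, reference.CONE), "light", -1.0),
        PlantedEffect("Cryaa", all_types, "light", +1.0),
        PlantedEffect("Cryab", all_types, "light", +1.0),
    )


@dataclass(frozen=True)
class DepthModel:
    """Log-normal per-cell library-size distribution (natural-log scale)."""

    log_mean: float = math.log(6000.0)
    log_sd: float = 0.35


@dataclass(frozen=True)
class CountModel:
    """Gene-level negative-binomial parameters on a relative mean scale.

    ``dispersion`` is the NB overdispersion phi (variance = mu + phi*mu^2).
    A marker gene's relative mean is ``marker_mean`` in its own type and
    ``marker_mean_elsewhere`` (near zero: markers are specifically
    expressed) in every other type. Background genes draw a shared
    relative mean from a log-normal; mitochondrial genes are scaled to an
    expected ``mito_share`` of each cell's counts.
    """

    dispersion: float = 0.1
    marker_mean: float = 20.0
    marker_mean_elsewhere: float = 0.001
    background_log_mean: float = 0.0
    background_log_sd: float = 1.0
    mito_share: float = 0.04


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the two-condition generator."""

    n_cells_dark: int = 10311
    n_cells_light: int = 12091
    type_proportions: dict[str, float] = field(
        default_factory=reference.reference_type_proportions
    )
    low_quality_fraction: float = 0.058
    marker_panel: MarkerPanel = field(default_factory=MarkerPanel.default)
    n_background_genes: int = 2000
    n_mito_genes: int = 13
    depth_model: DepthModel = field(default_factory=DepthModel)
    count_model: CountModel = field(default_factory=CountModel)
    planted_effects: tuple[PlantedEffect, ...] = field(
        default_factory=default_planted_effects
    )
    seed: int = 0
    metadata: dict = field(default_factory=lambda: dict(reference.LIGHT_STIMULUS))

    def __post_init__(self) -> None:
        if self.n_cells_dark < 0 or self.n_cells_light < 0:
            raise ValueError("cell counts must be non-negative")
        if not 0.0 <= self.low_quality_fraction < 1.0:
            raise ValueError("low_quality_fraction must lie in [0, 1)")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions sum to {total!r}, not 1")
        known = set(self.marker_panel.types) | {OTHERS}
        unknown = set(self.type_proportions) - known
        if unknown:
            raise ValueError(f"unknown cell types in proportions: {sorted(unknown)}")
        for eff in self.planted_effects:
            if not math.isfinite(eff.log2_fc):
                raise ValueError(f"non-finite fold change for {eff.gene}")
            bad = set(eff.cell_types) - known
            if bad:
                raise ValueError(f"effect {eff.gene} targets unknown types {sorted(bad)}")
        if set(self.mito_genes) & set(self.marker_panel.all_markers):
            raise ValueError("marker genes must be disjoint from mito genes")

    @property
    def mito_genes(self) -> tuple[str, ...]:
        names = list(MITO_GENE_NAMES[: self.n_mito_genes])
        while len(names) < self.n_mito_genes:
            names.append(f"mt-G{len(names) + 1}")
        return tuple(names)

    @property
    def gene_universe(self) -> tuple[str, ...]:
        genes: dict[str, None] = {}
        for m in self.marker_panel.all_markers:
            genes.setdefault(m, None)
        for g in EFFECT_GENE_BASELINES:
            genes.setdefault(g, None)
        for g in self.mito_genes:
            genes.setdefault(g, None)
        for i in range(self.n_background_genes):
            genes.setdefault(f"Gene{i + 1:04d}", None)
        return tuple(genes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_panel"] = [
            {"cell_type": t, "markers": list(m)} for t, m in self.marker_panel.entries
        ]
        d["planted_effects"] = [dataclasses.asdict(e) for e in self.planted_effects]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)
        )


@dataclass
class GroundTruth:
    """Per-barcode truth and the planted-effect table actually applied."""

    cells: pd.DataFrame  # barcode, condition, true_type, low_quality, violated_rule
    effects: pd.DataFrame  # gene, cell_type, condition, log2_fc

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def _build_profiles(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-type relative-mean matrix (types+Others x gene universe)."""
    genes = list(config.gene_universe)
    types = [*config.marker_panel.types, OTHERS]
    cm = config.count_model
    profile = pd.DataFrame(0.0, index=types, columns=genes)

    bg = [g for g in genes if g.startswith("Gene")]
    bg_means = rng.lognormal(cm.background_log_mean, cm.background_log_sd, len(bg))
    profile.loc[:, bg] = np.tile(bg_means, (len(types), 1))

    for cell_type, markers in config.marker_panel.entries:
        for marker in markers:
            profile.loc[:, marker] = cm.marker_mean_elsewhere
            profile.loc[cell_type, marker] = cm.marker_mean
    for gene, (elsewhere, by_type) in EFFECT_GENE_BASELINES.items():
        profile.loc[:, gene] = elsewhere
        for cell_type, level in by_type.items():
            profile.loc[cell_type, gene] = level

    # Mitochondrial mass as a fixed expected share of each type's counts.
    mito = list(config.mito_genes)
    non_mito_mass = profile.drop(columns=mito, errors="ignore").sum(axis=1)
    per_gene = (
        cm.mito_share / (1.0 - cm.mito_share) * non_mito_mass / max(len(mito), 1)
    )
    for g in mito:
        profile.loc[:, g] = per_gene
    return profile


def _apply_effects(
    profile: pd.DataFrame, config: SyntheticConfig, condition: str
) -> pd.DataFrame:
    out = profile.copy()
    for eff in config.planted_effects:
        if eff.condition != condition:
            continue
        if eff.gene not in out.columns:
            raise ValueError(f"effect gene {eff.gene!r} absent from gene universe")
        for cell_type in eff.cell_types:
            out.loc[cell_type, eff.gene] *= 2.0 ** eff.log2_fc
    return out


def _degrade_low_umi(row: np.ndarray, rng: np.random.Generator) -> str:
    total = int(row.sum())
    target = int(rng.integers(300, 851))
    if total > target:
        row[:] = rng.binomial(row, target / total)
    return RULE_LOW_UMI


def _degrade_low_genes(row: np.ndarray, rng: np.random.Generator) -> str:
    k = int(rng.integers(60, 251))
    order = np.argsort(-row, kind="stable")
    row[order[k:]] = 0
    return RULE_LOW_GENES


def _degrade_high_mito(
    row: np.ndarray, mito_mask: np.ndarray, rng: np.random.Generator
) -> str:
    base = row[mito_mask].astype(np.float64)
    if base.sum() == 0:
        base[:] = 1.0
    non_mito = int(row[~mito_mask].sum())
    target = float(rng.uniform(0.18, 0.35))
    for _ in range(6):
        desired = target * non_mito / (1.0 - target)
        new = rng.poisson(base * desired / base.sum())
        if new.sum() / max(new.sum() + non_mito, 1) > 0.12:
            row[mito_mask] = new
            return RULE_HIGH_MITO
        target = min(0.6, target + 0.1)
    row[mito_mask] = np.ceil(base * desired / base.sum()).astype(row.dtype)
    return RULE_HIGH_MITO


def _qc_violations(
    counts: np.ndarray, mito_mask: np.ndarray, thresholds: QCThresholds
) -> np.ndarray:
    """Default-rule violation flags computed directly on a dense block."""
    total = counts.sum(axis=1)
    detected = (counts > 0).sum(axis=1)
    mito = counts[:, mito_mask].sum(axis=1)
    frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return (
        (total <= thresholds.max_excluded_umi)
        | (detected <= thresholds.max_excluded_genes)
        | (frac > thresholds.max_mito_fraction)
    )


def _simulate_condition(
    config: SyntheticConfig,
    condition: str,
    n_cells: int,
    profile: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[GeneExpressionMatrix, pd.DataFrame]:
    genes = list(profile.columns)
    type_names = list(profile.index)
    props = np.array([config.type_proportions.get(t, 0.0) for t in type_names])
    props = props / props.sum() if props.sum() else props
    mito_mask = np.array([g.startswith("mt-") for g in genes])

    type_idx = rng.choice(len(type_names), size=n_cells, p=props)
    libs = rng.lognormal(config.depth_model.log_mean, config.depth_model.log_sd, n_cells)
    P = profile.to_numpy()
    Pn = P / P.sum(axis=1, keepdims=True)
    phi = config.count_model.dispersion

    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    chunk = 2048
    for start in range(0, n_cells, chunk):
        sl = slice(start, min(start + chunk, n_cells))
        mu = libs[sl, None] * Pn[type_idx[sl]]
        lam = rng.gamma(1.0 / phi, mu * phi)
        counts[sl] = rng.poisson(lam)

    n_lq = int(round(config.low_quality_fraction * n_cells))
    lq_idx = np.sort(rng.choice(n_cells, size=n_lq, replace=False)) if n_lq else np.array([], dtype=int)
    rules = rng.choice(
        [RULE_LOW_UMI, RULE_LOW_GENES, RULE_HIGH_MITO], size=n_lq
    )
    thresholds = QCThresholds()
    violated = np.full(n_cells, "", dtype=object)
    for i, rule in zip(lq_idx, rules):
        for _ in range(5):
            row = counts[i]
            if rule == RULE_LOW_UMI:
                _degrade_low_umi(row, rng)
                ok = row.sum() <= thresholds.max_excluded_umi
            elif rule == RULE_LOW_GENES:
                _degrade_low_genes(row, rng)
                ok = (row > 0).sum() <= thresholds.max_excluded_genes
            else:
                _degrade_high_mito(row, mito_mask, rng)
                total = row.sum()
                ok = total > 0 and row[mito_mask].sum() / total > thresholds.max_mito_fraction
            if ok:
                break
        else:  # pragma: no cover - construction guarantees convergence
            raise RuntimeError(f"could not force QC violation {rule} on cell {i}")
        violated[i] = rule

    # Honest cells must sit clear of every threshold; a cell that lands in
    # the far lower tail of the depth distribution is redrawn.
    low_quality = violated != ""
    if n_cells:
        honest_bad = _qc_violations(counts, mito_mask, thresholds) & ~low_quality
        for i in np.flatnonzero(honest_bad):
            for _ in range(20):
                lib = rng.lognormal(
                    config.depth_model.log_mean, config.depth_model.log_sd
                )
                mu = lib * Pn[type_idx[i]]
                row = rng.poisson(rng.gamma(1.0 / phi, mu * phi))
                if not _qc_violations(row[None, :], mito_mask, thresholds)[0]:
                    counts[i] = row
                    break
            else:  # pragma: no cover - redraw converges in a try or two
                raise RuntimeError(f"could not draw a QC-passing honest cell {i}")

    barcodes = [f"{condition.upper()}-{i + 1:05d}" for i in range(n_cells)]
    true_type = np.array([type_names[j] for j in type_idx], dtype=object)
    matrix = GeneExpressionMatrix(
        barcodes=barcodes,
        genes=genes,
        counts=sp.csr_matrix(counts),
        condition=condition,
        true_type=true_type,
    )
    if n_cells:
        report = compute_cell_qc(matrix, thresholds)
        assert not (report["excluded"].to_numpy() & ~low_quality).any()
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "condition": condition,
            "true_type": true_type,
            "low_quality": low_quality,
            "violated_rule": violated,
        }
    )
    return matrix, truth


def generate_counts(
    config: SyntheticConfig | None = None,
) -> tuple[GeneExpressionMatrix, GeneExpressionMatrix, GroundTruth]:
    """Generate the dark and light count matrices plus ground truth.

    The seed fully determines the output: identical config and seed give
    byte-identical matrices.
    """
    config = config if config is not None else SyntheticConfig()
    universe = set(config.gene_universe)
    for eff in config.planted_effects:
        if eff.gene not in universe:
            raise ValueError(f"effect gene {eff.gene!r} absent from gene universe")
    rng = np.random.default_rng(config.seed)
    base_profile = _build_profiles(config, rng)
    dark_profile = _apply_effects(base_profile, config, "dark")
    light_profile = _apply_effects(base_profile, config, "light")

    dark, truth_dark = _simulate_condition(
        config, "dark", config.n_cells_dark, dark_profile, rng
    )
    light, truth_light = _simulate_condition(
        config, "light", config.n_cells_light, light_profile, rng
    )
    effects = pd.DataFrame(
        [
            {
                "gene": e.gene,
                "cell_type": t,
                "condition": e.condition,
                "log2_fc": e.log2_fc,
            }
            for e in config.planted_effects
            for t in e.cell_types
        ]
    )
    truth = GroundTruth(
        cells=pd.concat([truth_dark, truth_light], ignore_index=True),
        effects=effects,
    )
    return dark, light, truth


def write_synthetic_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write Cell-Ranger-style triplets per condition, the
    ground-truth TSV and the config YAML."""
    out_dir = Path(out_dir)
    dark, light, truth = generate_counts(config)
    paths: dict[str, Path] = {}
    for name, matrix in (("dark", dark), ("light", light)):
        cond_dir = out_dir / name
        write_mtx_triplet(matrix, cond_dir)
        paths[name] = cond_dir
    paths["ground_truth"] = out_dir / "ground_truth.tsv"
    truth.to_tsv(paths["ground_truth"])
    paths["config"] = out_dir / "config.yaml"
    config.to_yaml(paths["config"])
    return paths


def generate_erg_trace(
    a_amp: float,
    b_amp: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    t_start: float = -20.0,
    t_end: float = 250.0,
    dt: float = 0.5,
    flash_onset: float = 0.0,
    descent_start: float = 5.0,
    trough_time: float = 15.0,
    peak_time: float = 45.0,
    decay_tau: float = 60.0,
) -> tuple[ERGTrace, ERGAmplitudes]:
    """Synthesise a flash-ERG trace with known amplitudes.

    The noiseless trace sits at baseline 0 before the flash, descends
    linearly to exactly ``-a_amp`` at ``trough_time``, rises linearly to
    exactly ``-a_amp + b_amp`` at ``peak_time`` and then relaxes toward
    baseline (or stays level when the peak lies below baseline, so the
    trough-to-peak distance remains exactly ``b_amp``). Gaussian noise of
    sd ``noise_sd`` is added on top. Returns the trace and the true
    amplitudes.
    """
    if a_amp < 0 or b_amp < 0:
        raise ValueError("amplitudes must be non-negative")
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    if not flash_onset < descent_start < trough_time < peak_time < t_end:
        raise ValueError("require flash_onset < descent_start < trough < peak < t_end")

    time = np.arange(t_start, t_end + dt / 2, dt)
    trough_v = -a_amp
    peak_v = -a_amp + b_amp
    v = np.zeros_like(time)
    seg = (time > descent_start) & (time <= trough_time)
    v[seg] = trough_v * (time[seg] - descent_start) / (trough_time - descent_start)
    seg = (time > trough_time) & (time <= peak_time)
    v[seg] = trough_v + (peak_v - trough_v) * (time[seg] - trough_time) / (
        peak_time - trough_time
    )
    seg = time > peak_time
    if peak_v >= 0:
        v[seg] = peak_v * np.exp(-(time[seg] - peak_time) / decay_tau)
    else:
        v[seg] = peak_v

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, v.shape)

    trace = ERGTrace(time=time, voltage=v, flash_onset=flash_onset)
    truth = ERGAmplitudes(
        a_wave=a_amp,
        b_wave=b_amp,
        trough_time=trough_time,
        peak_time=peak_time,
        baseline=0.0,
    )
    return trace, truth


def generate_ct_table(
    true_fold_changes: dict[str, float],
    reference_gene: str = "RhoA",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    calibrator_sample: str = "control",
    treated_sample: str = "treated",
    base_ct_reference: float = 20.0,
    base_ct_target: float = 25.0,
) -> pd.DataFrame:
    """Long-format Ct table whose noiseless 2^-ddCt equals the requested
    fold changes in the treated sample (calibrator = 1)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for gene, fold in true_fold_changes.items():
        if not fold > 0:
            raise ValueError(f"fold change for {gene} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in (calibrator_sample, treated_sample):
        for gene in (reference_gene, *true_fold_changes):
            if gene == reference_gene:
                base = base_ct_reference
            elif sample == calibrator_sample:
                base = base_ct_target
            else:
                base = base_ct_target - math.log2(true_fold_changes[gene])
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep, "ct": base + noise}
                )
    return pd.DataFrame(rows)
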