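"""Formula-level assay metrics: ERG wave amplitudes and comparative Ct.

The electroretinogram a-wave is measured from the pre-flash baseline to the
trough of the initial negative deflection; the b-wave from that trough to
the following positive peak. Relative qPCR expression uses the comparative
Ct method (2^-ddCt) with replicates averaged on the Ct scale, an assumed
amplification efficiency of exactly 2, and expression normalised to a
reference gene (RhoA by default) and a calibrator sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENE = "RhoA"
#: Search window for the a-wave trough, ms after flash onset.
DEFAULT_A_WINDOW = (5.0, 50.0)
#: End of the b-wave peak search, ms after flash onset (start = trough).
DEFAULT_B_WINDOW_END = 200.0


@dataclass
class ERGTrace:
    """A single-flash ERG recording: time (ms) and voltage (µV)."""

    time: np.ndarray
    voltage: np.ndarray
    flash_onset: float = 0.0
    stimulus_meta: dict = field(
        default_factory=lambda: {"luminance_cd_m2": 3162, "flash_ms": 1}
    )

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValueError("time and voltage must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if (self.time < self.flash_onset).sum() < 2:
            raise ValueError("need at least 2 samples before flash onset")
        if (self.time >= self.flash_onset).sum() < 2:
            raise ValueError("need at least 2 samples after flash onset")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.time, "voltage_uv": self.voltage}).to_csv(
            path, index=False
        )
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"flash_onset": self.flash_onset, "stimulus_meta": self.stimulus_meta}
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path, flash_onset: float | None = None) -> "ERGTrace":
        df = pd.read_csv(path)
        meta: dict = {}
        if flash_onset is None:
            sidecar = Path(path).with_suffix(".json")
            if sidecar.exists():
                loaded = json.loads(sidecar.read_text())
                flash_onset = loaded.get("flash_onset", 0.0)
                meta = loaded.get("stimulus_meta", {})
            else:
                flash_onset = 0.0
        trace = cls(
            time=df["time_ms"].to_numpy(),
            voltage=df["voltage_uv"].to_numpy(),
            flash_onset=flash_onset,
        )
        if meta:
            trace.stimulus_meta = meta
        return trace


@dataclass(frozen=True)
class ERGAmplitudes:
    """Baseline-to-trough (a) and trough-to-peak (b) magnitudes, µV."""

    a_wave: float
    b_wave: float
    trough_time: float
    peak_time: float
    baseline: float


def measure_erg(
    trace: ERGTrace,
    a_window: tuple[float, float] = DEFAULT_A_WINDOW,
    b_window_end: float = DEFAULT_B_WINDOW_END,
) -> ERGAmplitudes:
    """Extract a-/b-wave amplitudes from a flash ERG trace.

    baseline = mean voltage over all pre-flash samples; trough = minimum
    voltage within the post-flash a-window; a_wave = baseline - trough;
    peak = maximum voltage after the trough up to ``b_window_end``;
    b_wave = peak - trough. First occurrence breaks plateau ties.
    """
    lo, hi = a_window
    if not 0 <= lo < hi:
        raise ValueError("a_window must satisfy 0 <= start < end")
    t, v = trace.time, trace.voltage
    baseline = float(v[t < trace.flash_onset].mean())

    a_sel = (t >= trace.flash_onset + lo) & (t <= trace.flash_onset + hi)
    if not a_sel.any():
        raise ValueError("a-wave search window contains no samples")
    a_idx = np.flatnonzero(a_sel)
    trough_i = a_idx[np.argmin(v[a_sel])]
    trough_time = float(t[trough_i])
    trough_v = float(v[trough_i])

    b_sel = (t > trough_time) & (t <= trace.flash_onset + b_window_end)
    if not b_sel.any():
        raise ValueError("b-wave search window contains no samples")
    b_idx = np.flatnonzero(b_sel)
    peak_i = b_idx[np.argmax(v[b_sel])]

    return ERGAmplitudes(
        a_wave=baseline - trough_v,
        b_wave=float(v[peak_i]) - trough_v,
        trough_time=trough_time,
        peak_time=float(t[peak_i]),
        baseline=baseline,
    )


def relative_expression(
    ct: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    calibrator_sample: str | None = None,
) -> pd.DataFrame:
    """Comparative-Ct relative expression, 2^-ddCt, per (sample, gene).

    ``ct`` is a long-format table with columns ``sample``, ``gene``,
    ``ct`` (and optionally ``replicate``). Replicates are averaged on the
    Ct scale; dCt = mean Ct(gene) - mean Ct(reference) per sample;
    ddCt = dCt(sample) - dCt(calibrator). The calibrator's own value is
    exactly 1.0. The reference gene itself, if requested, is reported as
    1.0 with a warning.
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if not np.all(np.isfinite(ct["ct"])) or np.any(ct["ct"] <= 0):
        raise ValueError("Ct values must be finite and positive")
    means = ct.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack()
    if reference_gene not in means.columns or means[reference_gene].isna().any():
        raise ValueError(
            f"reference gene {reference_gene!r} must be measured in every sample"
        )
    samples = list(means.index)
    if calibrator_sample is None:
        calibrator_sample = samples[0]
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")

    dct = means.sub(means[reference_gene], axis=0)
    ddct = dct - dct.loc[calibrator_sample]
    fold = 2.0 ** (-ddct)

    targets = [g for g in means.columns if g != reference_gene]
    if not targets:
        logger.warning(
            "target gene equals reference gene %r; relative expression is 1.0",
            reference_gene,
        )
        targets = [reference_gene]
    rows = []
    for gene in targets:
        for sample in samples:
            value = fold.loc[sample, gene]
            if pd.isna(value):
                continue
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "relative_expression": float(value),
                }
            )
    return pd.DataFrame(rows)
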