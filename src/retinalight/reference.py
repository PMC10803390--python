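"""Reference constants for the degenerating mouse retina study design.

Cell-type names, the marker panel used for priority annotation, and the
published per-condition cell-count composition of the two *Prom1*-null
retinas (dark-reared vs 15,000 lx / 3 h light-stimulated) that the synthetic
generator emulates and the composition report mirrors.
"""

from __future__ import annotations

import pandas as pd

# Canonical cell-type labels.
ROD = "Rod photoreceptor"
BIPOLAR = "Bipolar cell"
CONE = "Cone photoreceptor"
MULLER = "Müller cell"
AMACRINE = "Amacrine cell"
ASTROCYTE = "Astrocyte"
HORIZONTAL = "Horizontal cell"
ENDOTHELIAL = "Endothelial cell"
MICROGLIA = "Microglia"
RPE = "RPE cell"
GANGLION = "Ganglion cell"
OTHERS = "Others"

#: Classification priority: a cell is given the first label in this order
#: whose marker score passes the threshold. Rod photoreceptors come last so
#: that the rarer identities are not swallowed by the dominant rod signature.
PRIORITY_ORDER: tuple[str, ...] = (
    RPE,
    ENDOTHELIAL,
    MICROGLIA,
    HORIZONTAL,
    GANGLION,
    MULLER,
    CONE,
    BIPOLAR,
    ASTROCYTE,
    AMACRINE,
    ROD,
)

#: Marker genes that are specifically expressed in each retinal cell type.
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    RPE: ("RPE65",),
    ENDOTHELIAL: ("Cldn5",),
    MICROGLIA: ("C1qa",),
    HORIZONTAL: ("Lhx1", "Prox1"),
    GANGLION: ("Sncg", "Pou4f1"),
    MULLER: ("Crym",),
    CONE: ("Opn1sw",),
    BIPOLAR: ("Nrxn3", "Vsx2"),
    ASTROCYTE: ("Igfbp5",),
    AMACRINE: ("Gad1",),
    ROD: ("Sag", "RHO", "Pdc", "Gngt1", "Rp1"),
}

#: Published number of QC-passing cells per type and condition (dark /
#: light), in descending dark-count order with the unclassified residue last.
REFERENCE_CELL_COUNTS: dict[str, tuple[int, int]] = {
    ROD: (5376, 6812),
    BIPOLAR: (1733, 1780),
    CONE: (835, 894),
    MULLER: (478, 757),
    AMACRINE: (444, 193),
    ASTROCYTE: (118, 102),
    HORIZONTAL: (52, 48),
    ENDOTHELIAL: (28, 29),
    MICROGLIA: (20, 36),
    RPE: (19, 24),
    GANGLION: (19, 12),
    OTHERS: (593, 700),
}

#: Cells sequenced per condition before QC, and the number excluded by the
#: three quality rules (5.8% in both conditions).
SEQUENCED_CELLS = {"dark": 10311, "light": 12091}
EXCLUDED_CELLS = {"dark": 596, "light": 704}

#: Light stimulus applied to the light-condition animal (annotation only).
LIGHT_STIMULUS = {"luminance_lx": 15000, "duration_h": 3}


def reference_counts_frame() -> pd.DataFrame:
    """Reference composition as a DataFrame (index cell type)."""
    df = pd.DataFrame.from_dict(
        REFERENCE_CELL_COUNTS, orient="index", columns=["n_dark", "n_light"]
    )
    df.index.name = "cell_type"
    return df


def reference_type_proportions() -> dict[str, float]:
    """Dark-condition type fractions (12 classes, sum to 1) used as
    generator defaults."""
    total = sum(n for n, _ in REFERENCE_CELL_COUNTS.values())
    return {t: n / total for t, (n, _) in REFERENCE_CELL_COUNTS.items()}
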