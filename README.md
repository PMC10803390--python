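# retinalight

Single-cell analysis of the earliest light-induced transcriptional changes
in a degenerating mouse retina.

In *Prom1*-null mice — a model of retinitis pigmentosa — a brief bright
light stimulus (15,000 lx for 3 h) applied just after eye opening triggers
the first molecular signs of photoreceptor degeneration. `retinalight`
implements the downstream single-cell RNA-seq analysis that localises those
changes to individual retinal cell types, together with the two
formula-level assay computations used alongside it:

- **QC exclusion** — cells with ≤ 1000 UMIs, ≤ 256 detected genes, or a
  mitochondrial fraction > 10% are removed (boundaries are literal and each
  violated rule is recorded).
- **Priority marker annotation** — each cell is scored per type as the mean
  log-normalised expression of that type's marker genes (e.g. rods:
  *Sag, RHO, Pdc, Gngt1, Rp1*; cones: *Opn1sw*) and receives the *first*
  label in a fixed priority order (RPE → endothelial → microglia →
  horizontal → ganglion → Müller → cone → bipolar → astrocyte → amacrine →
  rod) whose score exceeds a threshold, else "Others".
- **Per-type differential expression** — for every annotated type, each gene
  is tested dark vs light with a two-sided Wilcoxon rank-sum test
  (tie-corrected normal approximation; exact enumeration when both groups
  have ≤ 8 cells), with log2 fold changes on depth-normalised means
  (light over dark, pseudocount 1/10 000) and per-type counts of genes with
  raw p < 0.05 up/down.
- **Assay metrics** — flash-ERG amplitudes (a-wave: baseline → trough;
  b-wave: trough → peak) and comparative-Ct relative expression
  (2^−ΔΔCt, normalised to *RhoA* and a calibrator sample).
- **Synthetic data** — a seeded negative-binomial generator emulating the
  two-condition design (≈ 10 000 cells/condition at the published type
  proportions, a 5.8% low-quality fraction violating the QC rules by
  construction, and the light-condition stress signature — *Edn2*↑ in rods,
  *Gfap*/*Serpina3n*↑ in Müller glia and astrocytes, *S100a8/9*↑ in bipolar
  and rod cells, crystallins↑ broadly, *Igf1*↓ in rods and astrocytes,
  *Arr3*/*Gnat1*↓ in photoreceptors) — with full ground truth for testing
  every stage.

## Worked example

```python
import pandas as pd
from retinalight import (SyntheticConfig, generate_counts, apply_qc,
                         classify, de_per_type, count_significant)

dark, light, truth = generate_counts(SyntheticConfig(
    n_cells_dark=2000, n_cells_light=2000, seed=1))

dark_qc, _, summary = apply_qc(dark)
print(summary)
# {'n_input': 2000, 'n_excluded': 116, 'n_retained': 1884, 'pct_excluded': 5.8}

light_qc, _, _ = apply_qc(light)
assignments = pd.concat([classify(dark_qc)["assigned_type"],
                         classify(light_qc)["assigned_type"]])
print(assignments.value_counts().head(3))
# Rod photoreceptor     2014
# Bipolar cell           700
# Cone photoreceptor     346

de = de_per_type(dark_qc, light_qc, assignments)
rod_edn2 = de.set_index(["cell_type", "gene"]).loc[
    ("Rod photoreceptor", "Edn2")]
print(round(rod_edn2["log2fc"], 2), rod_edn2["p_value"] < 0.05)
# 1.91 True
```

5.8% of cells fail QC (the generator's planted low-quality fraction), the
dominant class is rods, and the planted 4-fold *Edn2* induction in rods is
recovered as log2FC ≈ 2 with p < 0.05.

The same stages are available from the shell:

```bash
retinalight simulate --out data --seed 1
retinalight qc --mtx-dir data/dark --out qc.tsv
retinalight classify --mtx-dir data/dark --out assigned.tsv
retinalight run --config pipeline.yaml   # simulate → QC → classify → DE
```

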