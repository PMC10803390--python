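import numpy as np
import pandas as pd
import pytest

from retinalight import (
    MarkerPanel,
    apply_qc,
    assign_types,
    classify,
    composition_from_counts,
    composition_table,
    normalize_counts,
    reference,
    score_markers,
)
from retinalight.cell_typing import MissingMarkersError, NormalizedExpression

from conftest import make_gem

PANEL = MarkerPanel.default()


# ---------------------------------------------------------------- normalise
def test_single_expressed_gene_hits_closed_form():
    for c in (1, 7, 500):
        norm = normalize_counts(make_gem([[0, c, 0]]))
        row = norm.values.toarray()[0]
        assert row[1] == pytest.approx(np.log1p(10_000))
        assert row[0] == row[2] == 0.0


def test_proportional_cells_normalise_identically():
    norm = normalize_counts(make_gem([[2, 4, 6], [10, 20, 30]]))
    a, b = norm.values.toarray()
    np.testing.assert_allclose(a, b)


def test_normalised_linear_values_conserve_target_sum():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(30, 80))
    counts[:, 0] += 1  # no zero-total cells
    norm = normalize_counts(make_gem(counts))
    sums = np.expm1(norm.values.toarray()).sum(axis=1)
    # expm1 undoes the log; each cell must sum back to the target
    np.testing.assert_allclose(sums, 10_000.0, rtol=1e-6)


def test_zero_total_cell_rejected():
    with pytest.raises(ValueError, match="zero total"):
        normalize_counts(make_gem([[0, 0, 0]]))


# ------------------------------------------------------------------- score
def _norm_from_values(values, genes):
    values = np.asarray(values, dtype=float)
    import scipy.sparse as sp

    return NormalizedExpression(
        barcodes=np.array([f"c{i}" for i in range(values.shape[0])], dtype=object),
        genes=np.array(genes, dtype=object),
        values=sp.csr_matrix(values),
        linear=sp.csr_matrix(np.expm1(values)),
        condition=None,
        target_sum=10_000.0,
    )


def test_zero_cell_scores_zero_everywhere():
    norm = _norm_from_values(np.zeros((1, 3)), ["Opn1sw", "Crym", "Cldn5"])
    scores = score_markers(norm, PANEL, allow_missing_markers=True)
    assert (scores.to_numpy() == 0).all()


def test_single_marker_type_score_is_that_genes_value():
    norm = _norm_from_values([[1.7, 0.2, 0.0]], ["Opn1sw", "Crym", "Sag"])
    scores = score_markers(norm, PANEL, allow_missing_markers=True)
    assert scores.loc["c0", reference.CONE] == pytest.approx(1.7)
    assert scores.loc["c0", reference.MULLER] == pytest.approx(0.2)


def test_multi_marker_score_is_mean_of_present_markers():
    genes = ["Sag", "RHO", "Pdc", "Gngt1", "Rp1"]
    norm = _norm_from_values([[1.0, 2.0, 3.0, 4.0, 5.0]], genes)
    scores = score_markers(norm, PANEL, allow_missing_markers=True)
    assert scores.loc["c0", reference.ROD] == pytest.approx(3.0)
    # with two of five markers absent the mean is over the present three
    norm2 = _norm_from_values([[1.0, 2.0, 3.0]], genes[:3])
    scores2 = score_markers(norm2, PANEL, allow_missing_markers=True)
    assert scores2.loc["c0", reference.ROD] == pytest.approx(2.0)


def test_all_markers_absent_is_hard_error_unless_allowed():
    norm = _norm_from_values([[1.0]], ["Opn1sw"])
    with pytest.raises(MissingMarkersError):
        score_markers(norm, PANEL)
    scores = score_markers(norm, PANEL, allow_missing_markers=True)
    assert list(scores.columns) == [reference.CONE]


def test_case_insensitive_fallback_matches_mixed_casing():
    norm = _norm_from_values([[2.0]], ["rho"])
    scores = score_markers(
        norm, PANEL, allow_missing_markers=True, case_insensitive=True
    )
    assert scores.loc["c0", reference.ROD] == pytest.approx(2.0)


# ------------------------------------------------------------------ assign
def _scores(**kwargs):
    base = {t: 0.0 for t in PANEL.types}
    base.update(kwargs)
    return pd.DataFrame([base], index=["cell"])


def test_cone_marker_alone_gives_cone():
    out = assign_types(_scores(**{reference.CONE: 3.0}), PANEL)
    assert out.loc["cell", "assigned_type"] == reference.CONE


def test_priority_resolves_coexpression_to_earlier_type():
    scores = _scores(**{reference.ENDOTHELIAL: 2.0, reference.MULLER: 5.0})
    out = assign_types(scores, PANEL)
    # endothelial precedes Müller in the stated order even at lower score
    assert out.loc["cell", "assigned_type"] == reference.ENDOTHELIAL


def test_fallthrough_to_others():
    out = assign_types(_scores(), PANEL, threshold=0.5)
    assert out.loc["cell", "assigned_type"] == reference.OTHERS
    assert out.loc["cell", "decision_basis"] == "fallthrough"


def brute_force_first_match(score_row, order, threshold):
    for t in order:
        if score_row[t] > threshold:
            return t
    return reference.OTHERS


@pytest.mark.parametrize("perm_seed", [0, 1])
def test_assignment_matches_first_match_oracle_under_panel_permutation(perm_seed):
    rng = np.random.default_rng(perm_seed)
    order = list(PANEL.entries)
    rng.shuffle(order)
    panel = MarkerPanel(tuple(order))
    scores = pd.DataFrame(
        rng.uniform(0, 1.2, size=(500, len(panel.types))),
        columns=panel.types,
        index=[f"c{i}" for i in range(500)],
    )
    out = assign_types(scores, panel, threshold=0.5)
    for barcode, row in scores.iterrows():
        assert out.loc[barcode, "assigned_type"] == brute_force_first_match(
            row, panel.types, 0.5
        )


def test_assignment_invariant_to_cell_and_marker_order(small_dataset):
    _, (dark, _, _) = small_dataset
    filtered, _, _ = apply_qc(dark)
    baseline = classify(filtered)
    # permute cells
    rng = np.random.default_rng(0)
    perm = rng.permutation(filtered.n_cells)
    shuffled = classify(filtered.subset(perm))
    merged = baseline.join(shuffled, how="inner", rsuffix="_shuffled")
    assert (merged["assigned_type"] == merged["assigned_type_shuffled"]).all()
    # permute marker lists within each type
    reversed_panel = MarkerPanel(
        tuple((t, tuple(reversed(m))) for t, m in PANEL.entries)
    )
    again = classify(filtered, panel=reversed_panel)
    assert (baseline["assigned_type"] == again["assigned_type"]).all()


def test_recovery_on_synthetic_ground_truth(small_dataset):
    _, (dark, light, truth) = small_dataset
    truth_types = truth.cells.set_index("barcode")["true_type"]
    hits, n = 0, 0
    for gem in (dark, light):
        filtered, _, _ = apply_qc(gem)
        assigned = classify(filtered)["assigned_type"]
        expected = truth_types.loc[assigned.index]
        honest = expected != reference.OTHERS
        hits += (assigned[honest] == expected[honest]).sum()
        n += honest.sum()
    assert hits / n >= 0.95


# ------------------------------------------------------------- composition
def test_reference_counts_reproduce_published_percentages():
    counts = reference.reference_counts_frame()
    table = composition_from_counts(
        counts["n_dark"].to_dict(), counts["n_light"].to_dict()
    )
    assert table.loc[reference.ROD, "pct_dark"] == 55.3
    assert table.loc[reference.ROD, "pct_light"] == 59.8
    assert table.loc[reference.CONE, "pct_dark"] == 8.6
    assert table.loc[reference.CONE, "pct_light"] == 7.9
    assert table.loc["Total", "n_dark"] == 9715
    assert table.loc["Total", "n_light"] == 11387


def test_single_type_composition_is_hundred_percent():
    table = composition_from_counts({reference.ROD: 42}, {reference.ROD: 7})
    assert table.loc[reference.ROD, "pct_dark"] == 100.0
    assert table.loc[reference.ROD, "pct_light"] == 100.0


def test_composition_layout_and_conservation():
    labels_dark = pd.Series(
        [reference.ROD] * 6 + [reference.CONE] * 3 + [reference.OTHERS]
    )
    labels_light = pd.Series([reference.ROD] * 4 + [reference.MULLER] * 2)
    table = composition_table({"dark": labels_dark, "light": labels_light})
    assert list(table.index[-2:]) == [reference.OTHERS, "Total"]
    named = table.iloc[:-2]
    assert (named["n_dark"].sort_values(ascending=False) == named["n_dark"]).all()
    assert named["n_dark"].sum() + table.loc[reference.OTHERS, "n_dark"] == 10
    pct_sum = table.iloc[:-1]["pct_dark"].sum()
    assert 99.8 <= pct_sum <= 100.2
    assert table.loc[reference.ROD, "markers"] == "Sag, RHO, Pdc, Gngt1, Rp1"


def test_panel_tsv_round_trip(tmp_path):
    path = tmp_path / "panel.tsv"
    PANEL.to_tsv(path)
    assert MarkerPanel.from_tsv(path) == PANEL
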