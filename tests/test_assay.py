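import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retinalight import (
    ERGTrace,
    generate_ct_table,
    generate_erg_trace,
    measure_erg,
    relative_expression,
)


# ----------------------------------------------------------------- ddCt
def ct_rows(sample, gene, cts):
    return [
        {"sample": sample, "gene": gene, "replicate": i + 1, "ct": ct}
        for i, ct in enumerate(np.atleast_1d(cts))
    ]


def test_identical_cts_give_unit_expression_everywhere():
    ct = pd.DataFrame(
        ct_rows("control", "RhoA", [20, 20])
        + ct_rows("control", "Edn2", [25, 25])
        + ct_rows("treated", "RhoA", [20, 20])
        + ct_rows("treated", "Edn2", [25, 25])
    )
    out = relative_expression(ct, calibrator_sample="control")
    assert (out["relative_expression"] == 1.0).all()


def test_one_cycle_higher_target_halves_expression():
    ct = pd.DataFrame(
        ct_rows("control", "RhoA", 20)
        + ct_rows("control", "Edn2", 25)
        + ct_rows("treated", "RhoA", 20)
        + ct_rows("treated", "Edn2", 26)
    )
    out = relative_expression(ct, calibrator_sample="control").set_index("sample")
    assert out.loc["treated", "relative_expression"] == 0.5
    assert out.loc["control", "relative_expression"] == 1.0


def test_two_one_cycle_shifts_compose_to_quarter():
    ct = pd.DataFrame(
        ct_rows("control", "RhoA", 20)
        + ct_rows("control", "Edn2", 25)
        + ct_rows("mid", "RhoA", 20)
        + ct_rows("mid", "Edn2", 26)
        + ct_rows("high", "RhoA", 20)
        + ct_rows("high", "Edn2", 27)
    )
    out = relative_expression(ct, calibrator_sample="control").set_index("sample")
    assert out.loc["high", "relative_expression"] == 0.25


def test_matches_independent_step_by_step_recomputation():
    rng = np.random.default_rng(0)
    samples = ["control", "s1", "s2"]
    genes = ["RhoA", "Edn2", "Igf1", "Gfap"]
    rows = []
    for s in samples:
        for g in genes:
            rows += ct_rows(s, g, 18 + 10 * rng.random(3))
    ct = pd.DataFrame(rows)
    out = relative_expression(ct, calibrator_sample="control")

    # independent oracle: average replicates, then difference step by step
    mean_ct = {
        (s, g): np.mean([r["ct"] for r in rows if r["sample"] == s and r["gene"] == g])
        for s in samples
        for g in genes
    }
    for _, rec in out.iterrows():
        s, g = rec["sample"], rec["gene"]
        dct = mean_ct[(s, g)] - mean_ct[(s, "RhoA")]
        dct_cal = mean_ct[("control", g)] - mean_ct[("control", "RhoA")]
        assert rec["relative_expression"] == pytest.approx(
            2 ** -(dct - dct_cal), abs=1e-12
        )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-5, 5), seed=st.integers(0, 100))
def test_sample_wide_ct_shift_cancels_only_if_applied_to_reference_too(shift, seed):
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(
        ct_rows("control", "RhoA", 20 + rng.random())
        + ct_rows("control", "Edn2", 24 + rng.random())
        + ct_rows("treated", "RhoA", 20 + rng.random())
        + ct_rows("treated", "Edn2", 25 + rng.random())
    )
    out0 = relative_expression(base, calibrator_sample="control")

    both = base.copy()
    both.loc[both["sample"] == "treated", "ct"] += shift
    out_both = relative_expression(both, calibrator_sample="control")
    np.testing.assert_allclose(
        out0["relative_expression"], out_both["relative_expression"], rtol=1e-9
    )

    only_target = base.copy()
    sel = (only_target["sample"] == "treated") & (only_target["gene"] == "Edn2")
    only_target.loc[sel, "ct"] += shift
    out_target = relative_expression(only_target, calibrator_sample="control")
    treated = out_target.set_index("sample").loc["treated", "relative_expression"]
    expected = out0.set_index("sample").loc["treated", "relative_expression"]
    np.testing.assert_allclose(treated, expected * 2.0**-shift, rtol=1e-9)


def test_missing_reference_and_bad_ct_rejected():
    ct = pd.DataFrame(ct_rows("control", "Edn2", 25) + ct_rows("treated", "Edn2", 26))
    with pytest.raises(ValueError, match="reference"):
        relative_expression(ct)
    bad = pd.DataFrame(ct_rows("control", "RhoA", -1) + ct_rows("control", "E", 25))
    with pytest.raises(ValueError, match="positive"):
        relative_expression(bad)


def test_reference_gene_as_target_warns_and_returns_one(caplog):
    ct = pd.DataFrame(
        ct_rows("control", "RhoA", 20) + ct_rows("treated", "RhoA", 23)
    )
    with caplog.at_level("WARNING"):
        out = relative_expression(ct, calibrator_sample="control")
    assert (out["relative_expression"] == 1.0).all()
    assert "reference" in caplog.text


# ------------------------------------------------------------------- ERG
def test_flat_trace_measures_zero_amplitudes():
    trace, _ = generate_erg_trace(0.0, 0.0, noise_sd=0.0)
    amp = measure_erg(trace)
    assert amp.a_wave == 0.0
    assert amp.b_wave == 0.0


def test_constructed_trace_recovers_exact_amplitudes():
    trace, truth = generate_erg_trace(120.0, 370.0, noise_sd=0.0)
    amp = measure_erg(trace)
    assert amp.a_wave == pytest.approx(120.0, abs=1e-9)
    assert amp.b_wave == pytest.approx(370.0, abs=1e-9)
    assert amp.trough_time == pytest.approx(truth.trough_time)
    assert amp.peak_time == pytest.approx(truth.peak_time)
    assert amp.peak_time > amp.trough_time > trace.flash_onset


def test_trough_and_peak_values_forced_by_construction():
    trace, _ = generate_erg_trace(120.0, 370.0, noise_sd=0.0)
    assert trace.voltage.min() == pytest.approx(-120.0)
    assert trace.voltage.max() == pytest.approx(250.0)  # trough + 370


def test_peak_below_baseline_still_measures_requested_b_wave():
    trace, _ = generate_erg_trace(120.0, 50.0, noise_sd=0.0)
    amp = measure_erg(trace)
    assert amp.a_wave == pytest.approx(120.0)
    assert amp.b_wave == pytest.approx(50.0)


def test_offset_and_scale_invariances():
    trace, _ = generate_erg_trace(120.0, 370.0, noise_sd=2.0, seed=4)
    amp = measure_erg(trace)
    shifted = ERGTrace(trace.time, trace.voltage + 55.0, trace.flash_onset)
    amp_shift = measure_erg(shifted)
    assert amp_shift.a_wave == pytest.approx(amp.a_wave, abs=1e-9)
    assert amp_shift.b_wave == pytest.approx(amp.b_wave, abs=1e-9)
    scaled = ERGTrace(trace.time, trace.voltage * 3.0, trace.flash_onset)
    amp_scaled = measure_erg(scaled)
    assert amp_scaled.a_wave == pytest.approx(3.0 * amp.a_wave, abs=1e-9)
    assert amp_scaled.b_wave == pytest.approx(3.0 * amp.b_wave, abs=1e-9)


def test_noisy_recovery_mean_absolute_error_stays_small():
    errs_a, errs_b = [], []
    for seed in range(20):
        trace, truth = generate_erg_trace(120.0, 370.0, noise_sd=2.0, seed=seed)
        amp = measure_erg(trace)
        errs_a.append(abs(amp.a_wave - truth.a_wave))
        errs_b.append(abs(amp.b_wave - truth.b_wave))
    assert np.mean(errs_a) < 5.0
    assert np.mean(errs_b) < 5.0


def test_trace_validation_errors():
    with pytest.raises(ValueError, match="strictly increasing"):
        ERGTrace(time=[0, 0, 1, 2], voltage=[0, 0, 0, 0], flash_onset=0.5)
    with pytest.raises(ValueError, match="before flash"):
        ERGTrace(time=[-1, 0, 1, 2], voltage=[0, 0, 0, 0], flash_onset=0.0)
    trace, _ = generate_erg_trace(10.0, 20.0)
    with pytest.raises(ValueError, match="window"):
        measure_erg(trace, a_window=(500.0, 600.0))


def test_generator_input_validation():
    with pytest.raises(ValueError, match="sampling interval"):
        generate_erg_trace(1.0, 1.0, dt=-0.5)
    with pytest.raises(ValueError, match="non-negative"):
        generate_erg_trace(-1.0, 1.0)


def test_csv_round_trip(tmp_path):
    trace, _ = generate_erg_trace(120.0, 370.0, noise_sd=1.0, seed=0)
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = ERGTrace.from_csv(path)
    np.testing.assert_allclose(back.voltage, trace.voltage)
    assert back.flash_onset == trace.flash_onset


# -------------------------------------------------------- Ct generator
def test_unit_fold_noiseless_table_is_flat():
    ct = generate_ct_table({"Edn2": 1.0}, noise_sd=0.0)
    out = relative_expression(ct, calibrator_sample="control")
    assert (out["relative_expression"] == 1.0).all()


def test_half_fold_shifts_target_ct_up_one_cycle():
    ct = generate_ct_table({"Edn2": 0.5}, noise_sd=0.0)
    pivot = ct.groupby(["sample", "gene"])["ct"].mean()
    assert pivot["treated", "Edn2"] - pivot["control", "Edn2"] == pytest.approx(1.0)
    assert pivot["treated", "RhoA"] == pivot["control", "RhoA"]


def test_noisy_fold_recovery_geometric_mean():
    folds = []
    for seed in range(50):
        ct = generate_ct_table({"Edn2": 4.0}, noise_sd=0.1, seed=seed)
        out = relative_expression(ct, calibrator_sample="control")
        folds.append(
            out.set_index(["sample", "gene"]).loc[
                ("treated", "Edn2"), "relative_expression"
            ]
        )
    gmean = float(np.exp(np.mean(np.log(folds))))
    assert gmean == pytest.approx(4.0, rel=0.10)


def test_ct_generator_validation():
    with pytest.raises(ValueError, match="positive"):
        generate_ct_table({"Edn2": 0.0})
    with pytest.raises(ValueError, match="replicates"):
        generate_ct_table({"Edn2": 1.0}, n_replicates=0)
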