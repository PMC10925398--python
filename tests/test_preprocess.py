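"""Normalization, filtering, imputation, TAMPOR and bootstrap regression."""

import numpy as np
import pandas as pd
import pytest

from hepnet import (
    AbundanceMatrix,
    SampleSheet,
    TamporOptions,
    bootstrap_covariate_regress,
    channel_sum_normalize,
    detect_in_k_of_n,
    filter_missingness,
    impute_downshifted,
    simulate_tmt_plasma,
    tampor,
)

from conftest import random_matrix


def _matrix(values, scale="raw", proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}|G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=proteins, columns=samples), scale)


# ---------------------------------------------------------------- channel sum
def test_channel_sum_hand_example():
    m = _matrix([[2, 4], [2, 12]])  # column sums 4 and 16
    out = channel_sum_normalize(m)
    assert np.allclose(out.values, [[8, 4], [8, 12]])
    assert np.allclose(out.data.sum(axis=0), 16)


def test_channel_sum_single_sample_identity():
    m = _matrix([[3], [5]])
    out = channel_sum_normalize(m)
    assert np.allclose(out.values, m.values)


def test_channel_sum_equalizes_complete_columns(rng):
    m = random_matrix(rng, 30, 6, missing_frac=0.0)
    out = channel_sum_normalize(m)
    sums = out.data.sum(axis=0).to_numpy()
    assert np.allclose(sums, sums[0], rtol=1e-9)


def test_channel_sum_missing_stays_missing_and_all_missing_errors():
    m = _matrix([[2, np.nan], [2, 5]])
    out = channel_sum_normalize(m)
    assert np.isnan(out.data.iloc[0, 1])
    bad = _matrix([[2, np.nan], [2, np.nan]])
    with pytest.raises(ValueError, match="s1"):
        channel_sum_normalize(bad)


# ------------------------------------------------------------------ filtering
def test_filter_missingness_boundary():
    m = _matrix(
        [[1, 2, np.nan, np.nan], [1, np.nan, np.nan, np.nan], [1, 2, 3, 4]]
    )
    out = filter_missingness(m, 0.5)
    # exactly 50% missing is retained; 75% missing removed
    assert list(out.protein_ids) == ["P0|G0", "P2|G2"]
    strict = filter_missingness(m, 0.0)
    assert list(strict.protein_ids) == ["P2|G2"]


def test_detect_in_k_of_n_rules():
    m = _matrix([[1, np.nan, 3], [np.nan, np.nan, np.nan], [1, 2, np.nan]])
    groups = {"s0": "f", "s1": "f", "s2": "f"}
    sel = detect_in_k_of_n(m, groups, k=2)
    assert sel["f"] == {"P0|G0", "P2|G2"}
    union = detect_in_k_of_n(m, groups, k=1)
    assert union["f"] == {"P0|G0", "P2|G2"}
    with pytest.raises(ValueError, match="unknown sample"):
        detect_in_k_of_n(m, {"nope": "f"}, k=1)
    with pytest.raises(ValueError, match="exceeds"):
        detect_in_k_of_n(m, groups, k=4)


# ----------------------------------------------------------------- imputation
def test_impute_width_zero_is_deterministic_shift():
    m = _matrix([[1, 2, 3], [np.nan, 2, 4], [5, np.nan, 7]], scale="log2")
    out = impute_downshifted(m, width=0.0, downshift=1.8, seed=1)
    col0 = m.data["s0"].dropna()
    expect0 = col0.mean() - 1.8 * col0.std(ddof=1)
    assert out.data.loc["P1|G1", "s0"] == pytest.approx(expect0)
    # observed cells untouched
    assert out.data.loc["P0|G0", "s0"] == 1


def test_impute_identity_and_determinism(rng):
    complete = random_matrix(rng, 10, 4, missing_frac=0.0, scale="log2")
    complete = AbundanceMatrix(complete.data, "log2")
    out = impute_downshifted(complete, seed=3)
    pd.testing.assert_frame_equal(out.data, complete.data)
    holey = random_matrix(rng, 10, 4, missing_frac=0.2, scale="log2")
    a = impute_downshifted(holey, seed=5)
    b = impute_downshifted(holey, seed=5)
    pd.testing.assert_frame_equal(a.data, b.data)
    assert not a.data.isna().to_numpy().any()


def test_impute_requires_two_observed():
    m = _matrix([[1, 2], [np.nan, 3]], scale="log2")
    with pytest.raises(ValueError, match="s0"):
        impute_downshifted(m, seed=1)


# --------------------------------------------------------------------- TAMPOR
def _sheet_for(samples, batch_of, gis):
    rows = [
        {
            "sample_id": s,
            "set_label": "Set1",
            "batch_label": batch_of[s],
            "is_gis": s in gis,
            "diagnosis": None if s in gis else "Control",
        }
        for s in samples
    ]
    return SampleSheet(pd.DataFrame(rows))


def test_tampor_identical_columns_fixed_point():
    vals = np.exp2(np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]]))
    m = _matrix(vals)
    sheet = _sheet_for(["s0", "s1", "s2"], dict.fromkeys(["s0", "s1", "s2"], "b1"), {"s0"})
    out = tampor(m, sheet)
    expect = np.log2(np.nanmedian(vals, axis=1))
    assert np.allclose(out.values, expect[:, None], atol=1e-8)


def test_tampor_removes_planted_batch_effects():
    raw, sheet, _, truth = simulate_tmt_plasma(
        1, 4, 8, 150, 0, 0.0, 0.5, 0.0, 0.2, 0.0, seed=31, missing_rate=0.0
    )
    gis = list(sheet.gis_ids())
    pre = np.log2(raw.data[gis])
    pre_spread = float((pre.max(axis=1) - pre.min(axis=1)).median())
    out = tampor(raw, sheet)
    post = out.data[gis]
    post_spread = float((post.max(axis=1) - post.min(axis=1)).max())
    assert pre_spread > 0.3  # batch effects were really there
    assert post_spread < 1e-8


def test_tampor_idempotent(rng):
    for trial in range(5):
        raw, sheet, _, _ = simulate_tmt_plasma(
            1, 2, 6, 40, 5, 1.0, 0.4, 0.1, 0.2, 2.0, seed=100 + trial, missing_rate=0.05
        )
        once = tampor(raw, sheet)
        abundance = AbundanceMatrix(np.exp2(once.data), "normalized")
        twice = tampor(abundance, sheet)
        diff = (twice.data - once.data).abs().to_numpy()
        assert np.nanmax(diff) < 1e-6


def test_tampor_residual_medians_vanish():
    raw, sheet, _, _ = simulate_tmt_plasma(
        1, 2, 8, 80, 10, 1.0, 0.4, 0.1, 0.2, 2.0, seed=77, missing_rate=0.1
    )
    opts = TamporOptions()
    out = tampor(raw, sheet, opts)
    anchor = np.nanmedian(np.log2(raw.values), axis=1)
    residuals = out.data.to_numpy() - anchor[:, None]
    assert np.nanmax(np.abs(np.nanmedian(residuals, axis=0))) < opts.tol * 10
    assert np.nanmax(np.abs(np.nanmedian(residuals, axis=1))) < opts.tol * 10


def test_tampor_missing_gis_batch_errors():
    m = _matrix(np.exp2(np.ones((3, 4))))
    batch_of = {"s0": "b1", "s1": "b1", "s2": "b2", "s3": "b2"}
    sheet = _sheet_for(list(batch_of), batch_of, {"s0"})
    with pytest.raises(ValueError, match="b2"):
        tampor(m, sheet)
    # all_samples denominator needs no GIS
    out = tampor(m, sheet, TamporOptions(denominator="all_samples"))
    assert out.scale == "log2"


# --------------------------------------------------- bootstrap regression
def _regression_fixture(shift=1.0, n_per_batch=25, n_proteins=40, seed=8):
    rng = np.random.default_rng(seed)
    samples, rows, batch = [], [], []
    for b in range(2):
        for c in range(n_per_batch):
            sid = f"b{b}c{c}"
            samples.append(sid)
            batch.append(f"b{b}")
            rows.append(
                {
                    "sample_id": sid,
                    "set_label": "Set1",
                    "batch_label": f"b{b}",
                    "is_gis": False,
                    "diagnosis": "AD" if c % 2 else "Control",
                }
            )
    sheet = SampleSheet(pd.DataFrame(rows))
    base = rng.normal(10, 1, size=(n_proteins, 1))
    vals = base + rng.normal(0, 0.3, size=(n_proteins, len(samples)))
    vals[:, np.array(batch) == "b1"] += shift
    m = AbundanceMatrix(
        pd.DataFrame(vals, index=[f"P{i}|G{i}" for i in range(n_proteins)], columns=samples),
        "log2",
    )
    return m, sheet


def test_regress_removes_planted_batch_shift():
    m, sheet = _regression_fixture(shift=1.0, n_per_batch=50)
    out = bootstrap_covariate_regress(m, sheet, ["batch_label"], seed=4)
    b0 = out.data.loc[:, sheet.data.index[sheet.data["batch_label"] == "b0"]].mean(axis=1)
    b1 = out.data.loc[:, sheet.data.index[sheet.data["batch_label"] == "b1"]].mean(axis=1)
    assert float((b0 - b1).abs().max()) < 0.05 * 3  # per-protein batch means align
    assert float((b0 - b1).abs().mean()) < 0.05


def test_regress_null_covariate_changes_little():
    m, sheet = _regression_fixture(shift=0.0)
    out = bootstrap_covariate_regress(m, sheet, ["batch_label"], seed=4)
    change = (out.data - m.data).abs().to_numpy()
    # null covariate: corrections stay within a few fit standard errors
    assert np.mean(change) < 3 * 0.3 / np.sqrt(25)


def test_regress_plain_ols_degenerate_bootstrap():
    m, sheet = _regression_fixture(shift=0.7, n_per_batch=10, n_proteins=5)
    out = bootstrap_covariate_regress(m, sheet, ["batch_label"], n_boot=0, seed=1)
    # manual OLS correction for one protein
    y = m.data.iloc[0].to_numpy()
    diag = (sheet.data["diagnosis"] == "AD").to_numpy(dtype=float)
    b1 = (sheet.data["batch_label"] == "b1").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), diag, b1])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    expect = y - beta[2] * (b1 - b1.mean())
    assert np.allclose(out.data.iloc[0].to_numpy(), expect)


def test_regress_preserves_planted_group_difference():
    raw, sheet, _, truth = simulate_tmt_plasma(
        1, 2, 12, 60, 10, 1.0, 0.3, 0.1, 0.2, 0.0, seed=55, missing_rate=0.0
    )
    corrected = tampor(raw, sheet)
    out = bootstrap_covariate_regress(corrected, sheet, ["batch_label"], seed=2)
    diag = sheet.data["diagnosis"]
    ad = diag.index[diag == "AD"]
    ctl = diag.index[diag == "Control"]
    before = corrected.data[ad].mean(axis=1) - corrected.data[ctl].mean(axis=1)
    after = out.data[ad].mean(axis=1) - out.data[ctl].mean(axis=1)
    assert float((before - after).abs().max()) < 0.05


def test_regress_errors():
    m, sheet = _regression_fixture()
    with pytest.raises(ValueError, match="protected and covariate|both protected"):
        bootstrap_covariate_regress(m, sheet, ["diagnosis"], protect=["diagnosis"], seed=1)
    with pytest.raises(ValueError, match="not found"):
        bootstrap_covariate_regress(m, sheet, ["pmi"], seed=1)
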