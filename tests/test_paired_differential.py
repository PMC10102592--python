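"""The three-criterion paired tumor/NAT screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphopair import SimulationParams, simulate_protein_dataset
from phosphopair.normalization import global_normalize, to_log2
from phosphopair.paired_differential import (
    ScreenConfig,
    call_differential,
    concordance_fractions,
    differential_screen,
    pair_fold_changes,
    patient_coverage_filter,
    welch_test,
)
from phosphopair.tables_io import IntensityMatrix
from conftest import random_matrix


def _matrix(values, design, scale="linear"):
    arr = np.asarray(values, dtype=float)
    return IntensityMatrix(
        pd.DataFrame(arr, index=[f"F{i}" for i in range(arr.shape[0])],
                     columns=design.sample_ids),
        scale,
    )


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs", [{"p_threshold": 0.0}, {"fc_up": 0.9}, {"fc_down": 1.2},
               {"concordance_fraction": 1.5}, {"mean_method": "mode"}]
)
def test_screen_config_validation(kwargs):
    with pytest.raises(ValueError):
        ScreenConfig(**kwargs)


# ---------------------------------------------------------------------------
# patient coverage filter
# ---------------------------------------------------------------------------


def test_coverage_filter_strict_inequality(design10):
    # feature 0: 7/10 pairs complete (kept); feature 1: 6/10 (dropped, 0.60
    # is not > 0.60); feature 2: all pairs (kept)
    values = np.full((3, 20), 10.0)
    for i, n_missing in enumerate((3, 4, 0)):
        for p in range(n_missing):
            values[i, design10.sample_ids.index(f"P{p + 1}_T")] = np.nan
    X = _matrix(values, design10)
    kept = patient_coverage_filter(X, design10)
    assert kept.feature_ids == ["F0", "F2"]


def test_coverage_filter_matches_bruteforce(design10):
    X = random_matrix(np.random.default_rng(7), design10, n_features=100, missing_rate=0.35)
    kept = set(patient_coverage_filter(X, design10).feature_ids)
    expected = set()
    for fid in X.feature_ids:
        n = sum(
            not np.isnan(X.data.loc[fid, f"{p}_T"]) and not np.isnan(X.data.loc[fid, f"{p}_N"])
            for p in design10.patients()
        )
        if n > 6:
            expected.add(fid)
    assert kept == expected


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


def test_pair_fold_changes_basic_and_missing(design2):
    # design2 samples: P1_T P1_N (IDC), P2_T P2_N (ILC)
    X = _matrix([[20.0, 10.0, 5.0, np.nan]], design2)
    fcs_idc = pair_fold_changes(X, design2, "IDC")
    fcs_ilc = pair_fold_changes(X, design2, "ILC")
    assert fcs_idc.loc["F0", "P1"] == 2.0
    assert np.isnan(fcs_ilc.loc["F0", "P2"])


def test_pair_fold_changes_match_hand_division(design10):
    rng = np.random.default_rng(8)
    X = random_matrix(rng, design10, n_features=10, missing_rate=0.1)
    fcs = pair_fold_changes(X, design10, "ILC")
    for patient in design10.patients("ILC"):
        manual = X.data[f"{patient}_T"] / X.data[f"{patient}_N"]
        pd.testing.assert_series_equal(fcs[patient], manual, check_names=False)


# ---------------------------------------------------------------------------
# Welch test
# ---------------------------------------------------------------------------


def _welch_oracle(a, b):
    """Closed-form Welch statistic with Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def test_welch_known_example(design10):
    """tumor log2 [1,2,3] vs NAT [4,5,6]: t = -3.674, df = 4, p ~ 0.0213."""
    values = np.full((1, 20), np.nan)
    for sid, v in zip(["P1_T", "P2_T", "P3_T"], [1.0, 2.0, 3.0]):
        values[0, design10.sample_ids.index(sid)] = v
    for sid, v in zip(["P1_N", "P2_N", "P3_N"], [4.0, 5.0, 6.0]):
        values[0, design10.sample_ids.index(sid)] = v
    X = _matrix(values, design10, scale="log2")
    p = welch_test(X, design10, "IDC")
    t, df, p_oracle = _welch_oracle([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert df == pytest.approx(4.0)
    assert p["F0"] == pytest.approx(0.0213, abs=2e-4)
    assert p["F0"] == pytest.approx(p_oracle, abs=1e-12)


def test_welch_identical_groups_and_symmetry(design10):
    values = np.full((1, 20), np.nan)
    for p_idx in range(1, 6):
        values[0, design10.sample_ids.index(f"P{p_idx}_T")] = 5.0
        values[0, design10.sample_ids.index(f"P{p_idx}_N")] = 5.0
    X = _matrix(values, design10, scale="log2")
    assert welch_test(X, design10, "IDC")["F0"] == 1.0


def test_welch_insufficient_group_gives_nan(design10):
    values = np.full((1, 20), np.nan)
    values[0, design10.sample_ids.index("P1_T")] = 1.0
    for p_idx in range(1, 6):
        values[0, design10.sample_ids.index(f"P{p_idx}_N")] = 2.0
    X = _matrix(values, design10, scale="log2")
    assert np.isnan(welch_test(X, design10, "IDC")["F0"])


def test_welch_agrees_with_oracle_on_random_instances(design10):
    """100 random small instances agree with the closed form to 1e-10."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        a = rng.normal(0, 1, 5)
        b = rng.normal(rng.normal(), np.exp(rng.normal()), 5)
        # tumor columns get a, NAT columns get b, IDC subtype only
        values = np.full((1, 20), np.nan)
        for i in range(5):
            values[0, design10.sample_ids.index(f"P{i + 1}_T")] = a[i]
            values[0, design10.sample_ids.index(f"P{i + 1}_N")] = b[i]
        X = _matrix(values, design10, scale="log2")
        p = welch_test(X, design10, "IDC")["F0"]
        _, _, p_oracle = _welch_oracle(a, b)
        assert p == pytest.approx(p_oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# concordance + calls
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fcs, expected_up",
    [([1.6, 1.7, 1.52, 1.1, 0.9], 0.6), ([2.0, 1.8, 1.6, 1.55, 0.9], 0.8),
     ([1.0, 1.0, 1.0], 0.0)],
)
def test_concordance_fraction_counts(fcs, expected_up):
    frac_up, _ = concordance_fractions(fcs)
    assert frac_up == pytest.approx(expected_up)


def test_concordance_missing_pairs_excluded_from_denominator():
    frac_up, frac_down = concordance_fractions([2.0, np.nan, 0.5, np.nan])
    assert frac_up == 0.5 and frac_down == 0.5


@pytest.mark.parametrize(
    "mean_fc, p, frac_up, expected",
    [
        (2.0, 0.01, 0.8, "up"),
        (2.0, 0.01, 0.6, "ns"),  # 0.6 is not > 0.6: 4+ of 5 pairs required
        (1.4, 0.001, 0.8, "ns"),
        (2.0, 0.2, 0.8, "ns"),
    ],
)
def test_call_differential_three_criteria(mean_fc, p, frac_up, expected):
    assert call_differential(mean_fc, p, (frac_up, 0.0)) == expected


def test_call_differential_down_direction():
    assert call_differential(0.4, 0.01, (0.0, 0.8)) == "down"


# ---------------------------------------------------------------------------
# screen-level properties
# ---------------------------------------------------------------------------


def _screened_calls(X_log2, design, cfg):
    calls = set()
    for s in ("IDC", "ILC"):
        d = differential_screen(X_log2, design, s, cfg)
        calls |= {(f, s) for f in d.index[d["call"] != "ns"]}
    return calls


def test_tightening_any_threshold_shrinks_called_set():
    X, design, _ = simulate_protein_dataset(SimulationParams(seed=3, n_proteins=400))
    Xl, _ = global_normalize(to_log2(X))
    base = _screened_calls(Xl, design, ScreenConfig())
    tighter = [
        ScreenConfig(p_threshold=0.01),
        ScreenConfig(fc_up=2.0, fc_down=0.5),
        ScreenConfig(concordance_fraction=0.75),
    ]
    for cfg in tighter:
        assert _screened_calls(Xl, design, cfg) <= base


def test_null_data_rarely_called():
    """With no planted signal the screen calls well under 5% of features."""
    rates = []
    for seed in range(20):
        X, design, _ = simulate_protein_dataset(
            SimulationParams(seed=100 + seed, n_proteins=300, frac_differential=0.0))
        Xl, _ = global_normalize(to_log2(X))
        Xf = patient_coverage_filter(Xl, design)
        n_called = len(_screened_calls(Xf, design, ScreenConfig()))
        rates.append(n_called / (2 * len(Xf.feature_ids)))
    assert max(rates) < 0.05


def test_screen_output_is_self_consistent():
    X, design, _ = simulate_protein_dataset(SimulationParams(seed=9, n_proteins=200))
    Xl, _ = global_normalize(to_log2(X))
    d = differential_screen(Xl, design, "IDC", ScreenConfig())
    pair_cols = [c for c in d.columns if c.startswith("fc_")]
    for fid, row in d.iterrows():
        fcs = row[pair_cols].astype(float)
        frac_up, frac_down = concordance_fractions(fcs)
        if np.isfinite(row["frac_up"]):
            assert row["frac_up"] == pytest.approx(frac_up)
        assert row["call"] == call_differential(
            row["mean_fc"], row["welch_p"], (row["frac_up"], row["frac_down"]))
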