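"""Reader/writer behavior for every external table dialect."""

import numpy as np
import pandas as pd
import pytest

from phosphopair.tables_io import (
    IntensityMatrix,
    TableFormatError,
    load_kinome_groups,
    load_table2_fixture,
    read_design,
    read_kinase_substrates,
    read_matrix,
    read_phospho_table,
    read_protein_table,
    write_matrix,
    write_phospho_table,
    write_protein_table,
)
from conftest import random_matrix, write_design_file


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def test_read_design_ten_patient_layout(tmp_path, design10):
    path = write_design_file(design10, tmp_path / "design.tsv")
    d = read_design(path)
    assert len(d.entries) == 20
    assert d.n_pairs == 10
    assert d.patients("IDC") == [f"P{i}" for i in range(1, 6)]
    assert d.sample_of("P7", "tumor") == "P7_T"


def test_read_design_csv_dialect(tmp_path, design10):
    path = tmp_path / "design.csv"
    design10.entries.to_csv(path, index=False)
    assert read_design(path).n_pairs == 10


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda df: pd.concat([df, df.iloc[[0]]]), "P1"),  # second tumor for P1
        (lambda df: df.assign(tissue=df["tissue"].replace("NAT", "stroma")), "stroma"),
        (lambda df: df.iloc[:0], "no samples"),
    ],
)
def test_read_design_invariant_violations(tmp_path, design10, mutate, message):
    broken = mutate(design10.entries.copy())
    path = tmp_path / "design.tsv"
    broken.to_csv(path, sep="\t", index=False)
    with pytest.raises((TableFormatError, Exception), match=message):
        read_design(path)


# ---------------------------------------------------------------------------
# proteinGroups dialect
# ---------------------------------------------------------------------------


def _toy_protein_file(tmp_path, design, rows):
    cols = ["Majority protein IDs", "Reverse", "Potential contaminant"] + [
        f"Intensity {s}" for s in design.sample_ids
    ]
    pd.DataFrame(rows, columns=cols).to_csv(tmp_path / "pg.tsv", sep="\t", index=False)
    return tmp_path / "pg.tsv"


def test_protein_reader_drops_reverse_and_marks_zero_missing(tmp_path, design2):
    sids = design2.sample_ids  # 4 samples
    rows = [
        ["P1;P1b", "", ""] + [100.0, 0.0, 50.0, 25.0],
        ["REV__P2", "+", ""] + [9.0] * 4,
        ["P3", "", "+"] + [9.0] * 4,
    ]
    X = read_protein_table(_toy_protein_file(tmp_path, design2, rows), design2)
    assert X.feature_ids == ["P1"]  # first accession; flagged rows gone
    assert np.isnan(X.data.loc["P1", sids[1]])  # zero became missing
    assert X.data.loc["P1", sids[0]] == 100.0


def test_protein_reader_matches_hand_parsed_grid(tmp_path, design10):
    rng = np.random.default_rng(0)
    grid = rng.integers(1, 1000, (3, 20)).astype(float)
    rows = [[f"Q{i}", "", ""] + list(grid[i]) for i in range(3)]
    X = read_protein_table(_toy_protein_file(tmp_path, design10, rows), design10)
    assert X.sample_ids == design10.sample_ids
    np.testing.assert_array_equal(X.data.to_numpy(), grid)


def test_protein_reader_reports_missing_sample_columns(tmp_path, design10, design2):
    rows = [["P1", "", ""] + [1.0] * 4]
    path = _toy_protein_file(tmp_path, design2, rows)
    with pytest.raises(TableFormatError, match="P3_T"):
        read_protein_table(path, design10)


def test_protein_dialect_round_trip(tmp_path, design10):
    X = random_matrix(np.random.default_rng(1), design10)
    write_protein_table(X, tmp_path / "pg.tsv")
    back = read_protein_table(tmp_path / "pg.tsv", design10)
    pd.testing.assert_frame_equal(back.data, X.data)


def test_matrix_tsv_round_trip(tmp_path, design10):
    X = random_matrix(np.random.default_rng(2), design10)
    write_matrix(X, tmp_path / "m.tsv")
    back = read_matrix(tmp_path / "m.tsv")
    assert back.scale == X.scale
    pd.testing.assert_frame_equal(back.data, X.data)


# ---------------------------------------------------------------------------
# Phospho(STY)Sites dialect
# ---------------------------------------------------------------------------


def _phospho_frame(design, records):
    cols = {}
    cols["Protein"] = [r["protein"] for r in records]
    cols["Gene names"] = [r.get("gene", "") for r in records]
    cols["Amino acid"] = [r["residue"] for r in records]
    cols["Position"] = [r["position"] for r in records]
    cols["Localization prob"] = [r["prob"] for r in records]
    for mult in (1, 2, 3):
        for i, sid in enumerate(design.sample_ids):
            cols[f"Intensity {sid}___{mult}"] = [
                r.get(f"m{mult}", [0.0] * len(design.sample_ids))[i] for r in records
            ]
    return pd.DataFrame(cols)


def test_phospho_reader_splits_multiplicity_rows(tmp_path, design2):
    records = [
        {"protein": "PA", "gene": "GA", "residue": "S", "position": 15, "prob": 0.9,
         "m1": [10, 20, 0, 0], "m2": [0, 5, 5, 0]},
    ]
    _phospho_frame(design2, records).to_csv(tmp_path / "ph.tsv", sep="\t", index=False)
    T = read_phospho_table(tmp_path / "ph.tsv", design2)
    assert len(T) == 2
    assert sorted(T.sites["multiplicity"]) == [1, 2]
    assert np.isnan(T.intensities.iloc[0, 2])  # zero -> missing


def test_phospho_reader_keeps_low_probability_sites(tmp_path, design2):
    records = [{"protein": "PA", "residue": "T", "position": 3, "prob": 0.5,
                "m1": [1, 1, 1, 1]}]
    _phospho_frame(design2, records).to_csv(tmp_path / "ph.tsv", sep="\t", index=False)
    T = read_phospho_table(tmp_path / "ph.tsv", design2)
    assert len(T) == 1  # probability filtering is a separate stage


def test_phospho_reader_malformed_position_names_row(tmp_path, design2):
    records = [
        {"protein": "PA", "residue": "S", "position": 7, "prob": 0.9, "m1": [1, 1, 1, 1]},
        {"protein": "PB", "residue": "S", "position": "x9", "prob": 0.9, "m1": [1, 1, 1, 1]},
    ]
    _phospho_frame(design2, records).to_csv(tmp_path / "ph.tsv", sep="\t", index=False)
    with pytest.raises(TableFormatError, match="row 3"):
        read_phospho_table(tmp_path / "ph.tsv", design2)


def test_phospho_reader_matches_hand_tabulation(tmp_path, design2):
    rng = np.random.default_rng(3)
    records = []
    for i in range(5):
        vals = rng.integers(1, 100, 4).astype(float)
        records.append({"protein": f"P{i}", "gene": f"G{i}", "residue": "S",
                        "position": 10 + i, "prob": 0.95, "m1": list(vals)})
    _phospho_frame(design2, records).to_csv(tmp_path / "ph.tsv", sep="\t", index=False)
    T = read_phospho_table(tmp_path / "ph.tsv", design2)
    assert list(T.sites["protein_id"]) == [f"P{i}" for i in range(5)]
    assert list(T.sites["position"]) == [10 + i for i in range(5)]
    for i, rec in enumerate(records):
        np.testing.assert_array_equal(T.intensities.iloc[i].to_numpy(), rec["m1"])


def test_phospho_dialect_round_trip(tmp_path, design10):
    from phosphopair import SimulationParams, load_toy_kinase_substrates, simulate_phospho_dataset

    T, design, _ = simulate_phospho_dataset(
        SimulationParams(seed=5, n_sites=40, n_pairs_per_subtype=5),
        load_toy_kinase_substrates(),
    )
    write_phospho_table(T, tmp_path / "ph.tsv")
    back = read_phospho_table(tmp_path / "ph.tsv", design)
    key = ["protein_id", "position", "multiplicity"]
    orig = T.sites.sort_values(key).reset_index(drop=True)
    got = back.sites.sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(got[key], orig[key])
    got_int = back.intensities.iloc[back.sites.sort_values(key).index].reset_index(drop=True)
    orig_int = T.intensities.iloc[T.sites.sort_values(key).index].reset_index(drop=True)
    pd.testing.assert_frame_equal(got_int, orig_int)


# ---------------------------------------------------------------------------
# kinase-substrate annotations
# ---------------------------------------------------------------------------


def _ks_file(tmp_path, rows, columns=("GENE", "SUB_GENE", "SUB_MOD_RSD", "KIN_ORGANISM", "SUB_ORGANISM")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(tmp_path / "ks.tsv", sep="\t", index=False)
    return tmp_path / "ks.tsv"


def test_kinase_substrates_dedup_and_hand_built_set(tmp_path):
    rows = [
        ["AKT1", "GSK3B", "S9", "human", "human"],
        ["AKT1", "GSK3B", "S9", "human", "human"],  # duplicate triple
        ["AKT1", "BAD", "S99", "human", "human"],
        ["CDK2", "RB1", "S807", "human", "human"],
    ]
    table = read_kinase_substrates(_ks_file(tmp_path, rows))
    assert len(table) == 3
    assert table.substrates_of("AKT1") == {("GSK3B", "S9"), ("BAD", "S99")}


def test_kinase_substrates_organism_filter(tmp_path):
    rows = [
        ["AKT1", "GSK3B", "S9", "human", "human"],
        ["AKT1", "Gsk3b", "S9", "mouse", "mouse"],
    ]
    table = read_kinase_substrates(_ks_file(tmp_path, rows), organism_filter="human")
    assert len(table) == 1


def test_kinase_substrates_missing_column_error(tmp_path):
    rows = [["AKT1", "S9"]]
    path = _ks_file(tmp_path, rows, columns=("GENE", "SUB_MOD_RSD"))
    with pytest.raises(TableFormatError, match="SUB_GENE"):
        read_kinase_substrates(path)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------


def test_table2_fixture_values():
    fx = load_table2_fixture()
    rows = fx.rows.set_index("protein_label")
    assert len(fx.rows) == 13
    assert fx.rows["phos_fc_idc"].isna().sum() == 3
    assert rows.loc["H1X_HUMAN", "prot_fc_idc"] == 1.78
    assert rows.loc["H1X_HUMAN", "prot_fc_ilc"] == 0.56
    assert rows.loc["KTN1_HUMAN", "phos_fc_idc"] == 3.36
    assert rows.loc["KTN1_HUMAN", "phos_fc_ilc"] == 0.41
    assert rows.loc["SEPT2_HUMAN", "phos_fc_ilc"] == 0.67


def test_kinome_group_fixture_covers_ten_groups():
    groups = load_kinome_groups()
    assert groups["MAPK3"] == "CMGC"
    assert groups["AURKB"] == "AGC"
    assert set(groups.values()) == {
        "AGC", "CAMK", "CK1", "CMGC", "STE", "TK", "TKL", "RGC", "Atypical", "Other"
    }
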