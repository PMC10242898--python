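"""Wide-table I/O, manifests, and the command-line pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cotfam import SimulationConfig, simulate_table
from cotfam.cli import main
from cotfam.io import read_table, validate_table, write_data_dictionary, write_manifest, write_table


def test_write_read_round_trip_is_lossless(tmp_path, small_table):
    """Round trip preserves every value and every missingness marker."""
    path = tmp_path / "families.csv"
    write_table(small_table, path)
    back = read_table(path)
    pd.testing.assert_frame_equal(small_table, back, check_dtype=False)
    assert small_table.isna().sum().sum() == back.isna().sum().sum() > 0


def test_validate_table_names_offending_row_and_column(small_table):
    broken = small_table.copy()
    broken.loc[3, "sibling_link"] = "SIBLINGISH"
    with pytest.raises(ValueError, match="row 3.*SIBLINGISH"):
        validate_table(broken)
    missing_col = small_table.drop(columns=["c11_out"])
    with pytest.raises(ValueError, match="missing required columns"):
        validate_table(missing_col)


def test_manifest_and_dictionary(tmp_path):
    m = write_manifest(tmp_path / "m.json", seed=17, stage="simulate", n_units=10)
    data = json.loads(m.read_text())
    assert data["seed"] == 17 and data["stage"] == "simulate"
    assert "cotfam_version" in data
    d = write_data_dictionary(tmp_path / "dd.json")
    assert "sibling_link" in json.loads(d.read_text())


def test_cli_simulate_then_fit_share_seed(tmp_path):
    runner = CliRunner()
    sim_dir = tmp_path / "sim"
    res = runner.invoke(
        main, ["simulate", "--seed", "3", "--n-units", "150", "--out-dir", str(sim_dir)]
    )
    assert res.exit_code == 0, res.output
    assert (sim_dir / "families.csv").exists()
    assert (sim_dir / "data_dictionary.json").exists()
    man = json.loads((sim_dir / "manifest.json").read_text())
    assert man["seed"] == 3

    fit_dir = tmp_path / "fit"
    res = runner.invoke(
        main,
        [
            "fit", "--seed", "3", "--data", str(sim_dir / "families.csv"),
            "--out-dir", str(fit_dir), "--n-starts", "1",
            "--fix", "rho_A=0.372", "--fix", "rho_E=0.175", "--fix", "g=0.16",
        ],
    )
    assert res.exit_code == 0, res.output
    man2 = json.loads((fit_dir / "manifest.json").read_text())
    assert man2["seed"] == man["seed"]
    est = pd.read_csv(fit_dir / "estimates.csv")
    assert {"parameter", "estimate", "ci_low", "ci_high"} <= set(est.columns)


def test_cli_compare_emits_table_shape(tmp_path):
    runner = CliRunner()
    df = simulate_table(SimulationConfig(seed=8, n_units=150))
    data = tmp_path / "fam.csv"
    write_table(df, data)
    out = tmp_path / "cmp"
    res = runner.invoke(
        main,
        ["compare", "--seed", "1", "--data", str(data), "--out-dir", str(out),
         "--n-starts", "1"],
    )
    assert res.exit_code == 0, res.output
    table = pd.read_csv(out / "comparison.csv")
    assert len(table) == 6
    assert table["best_aic"].sum() == 1


def test_cli_assortment_reports_reference_numbers(tmp_path):
    runner = CliRunner()
    out = tmp_path / "am"
    res = runner.invoke(main, ["assortment", "--out-dir", str(out)])
    assert res.exit_code == 0, res.output
    row = pd.read_csv(out / "assortment.csv").iloc[0]
    assert row["d"] == pytest.approx(0.26)
    assert row["percent_genetic"] == pytest.approx(61.5, abs=0.05)
    assert row["inflation_equilibrium_pct"] == pytest.approx(19.05, abs=0.01)


def test_cli_recover_reports_bias_table(tmp_path):
    runner = CliRunner()
    out = tmp_path / "rec"
    res = runner.invoke(
        main,
        ["recover", "--seed", "2", "--n-units", "300", "--out-dir", str(out),
         "--n-starts", "1"],
    )
    assert res.exit_code == 0, res.output
    table = pd.read_csv(out / "recovery.csv")
    assert {"parameter", "truth", "estimate", "bias", "covered"} <= set(table.columns)
    assert len(table) == 18


def test_cli_fit_removes_partial_outputs_on_malformed_input(tmp_path):
    """A malformed table aborts with a row/column-naming error and leaves
    no partial artifacts behind."""
    bad = tmp_path / "bad.csv"
    df = simulate_table(SimulationConfig(seed=4, n_units=20))
    df.loc[5, "sibling_link"] = "WHAT"
    df.to_csv(bad, index=False, na_rep="NA")
    out = tmp_path / "out"
    runner = CliRunner()
    res = runner.invoke(main, ["fit", "--data", str(bad), "--out-dir", str(out)])
    assert res.exit_code != 0
    assert "row 5" in str(res.exception)
    assert not (out / "estimates.csv").exists()


def test_cli_decompose_emits_slices(tmp_path):
    runner = CliRunner()
    df = simulate_table(SimulationConfig(seed=19, n_units=200))
    data = tmp_path / "fam.csv"
    write_table(df, data)
    out = tmp_path / "dec"
    res = runner.invoke(
        main,
        ["decompose", "--data", str(data), "--out-dir", str(out), "--n-starts", "1",
         "--fix", "p_f=0"],
    )
    assert res.exit_code == 0, res.output
    table = pd.read_csv(out / "decomposition.csv")
    assert set(table["slice"]) == {"direct", "genetic", "assortment"}
    assert set(table["parent"]) == {"MOTHER", "FATHER"}
    shares = pd.read_csv(out / "variance_shares.csv")
    assert abs(shares.iloc[0].sum() - 1.0) < 1e-6
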