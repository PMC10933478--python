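"""I/O, configuration, and CLI tests."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from rupturekit import io
from rupturekit.cli import main as cli_main
from rupturekit.config import ConfigError, load_config


# --- image round-trips -------------------------------------------------------


def test_stack_roundtrip_2d(tmp_path):
    arr = np.random.default_rng(0).integers(0, 4000, (3, 32, 48)).astype(np.uint16)
    path = tmp_path / "field.ome.tif"
    io.write_stack(path, arr, ["Hoechst", "RFP", "GFP"], spacing=(0.65, 0.65))
    back, names = io.read_stack(path)
    np.testing.assert_array_equal(back, arr)
    assert names == ["Hoechst", "RFP", "GFP"]


def test_stack_roundtrip_3d_labels(tmp_path):
    labels = np.random.default_rng(1).integers(0, 5, (2, 10, 16, 16)).astype(np.int32)
    path = tmp_path / "labels.ome.tif"
    io.write_stack(path, labels, ["nucleus", "cell"], spacing=(0.2, 0.1, 0.1))
    back, _ = io.read_stack(path)
    np.testing.assert_array_equal(back, labels)


def test_get_channel_missing_names_file_and_channel(tmp_path):
    path = tmp_path / "x.ome.tif"
    io.write_stack(path, np.zeros((1, 4, 4)), ["DAPI"])
    with pytest.raises(KeyError, match="Lamin") as exc:
        io.get_channel(path, "Lamin")
    assert "x.ome.tif" in str(exc.value)
    with pytest.raises(FileNotFoundError):
        io.get_channel(tmp_path / "absent.tif", "DAPI")


def test_write_stack_validation(tmp_path):
    with pytest.raises(ValueError, match="channel names"):
        io.write_stack(tmp_path / "b.tif", np.zeros((2, 4, 4)), ["one"])
    with pytest.raises(ValueError, match="array"):
        io.write_stack(tmp_path / "c.tif", np.zeros((4, 4)), ["one"])


# --- tables ------------------------------------------------------------------


def test_table_roundtrip_and_schema(tmp_path):
    df = pd.DataFrame({"a": [1, 2], "b": ["x", "y"]})
    path = tmp_path / "t.csv"
    io.write_table(df, path, schema="cells")
    back = io.read_table(path, schema="cells")
    pd.testing.assert_frame_equal(back, df)
    with pytest.raises(ValueError, match="schema"):
        io.read_table(path, schema="summary")
    with pytest.raises(FileNotFoundError):
        io.read_table(tmp_path / "missing.csv")


def test_plate_map_validation(tmp_path):
    pm = tmp_path / "pm.csv"
    pm.write_text("well_id,condition,replicate,image\nW1,CTRL,1,w1.tif\n")
    with pytest.raises(FileNotFoundError, match="w1.tif"):
        io.read_plate_map(pm, image_root=tmp_path)
    (tmp_path / "w1.tif").write_bytes(b"")
    out = io.read_plate_map(pm, image_root=tmp_path)
    assert out["well_id"].tolist() == ["W1"]
    bad = tmp_path / "bad.csv"
    bad.write_text("well_id,condition\nW1,CTRL\n")
    with pytest.raises(ValueError, match="replicate"):
        io.read_plate_map(bad)


# --- GMT --------------------------------------------------------------------


def test_gmt_parse_and_duplicate_last_wins(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("TERM_A\tdesc a\tG1\tG2\n"
                   "TERM_B\tdesc b\tG3\n"
                   "TERM_A\tdesc a v2\tG4\n")
    with pytest.warns(UserWarning, match="TERM_A"):
        sets = io.read_gmt(gmt)
    assert sets["TERM_A"] == ("desc a v2", ["G4"])
    assert sets["TERM_B"] == ("desc b", ["G3"])


def test_gmt_malformed_raises(tmp_path):
    gmt = tmp_path / "bad.gmt"
    gmt.write_text("ONLY_TWO\tdesc\n")
    with pytest.raises(ValueError, match="GMT"):
        io.read_gmt(gmt)


# --- config -----------------------------------------------------------------


def test_config_defaults_and_toml(tmp_path):
    cfg = load_config(None)
    assert cfg.alpha == 0.05 and cfg.min_rfp_events == 175
    path = tmp_path / "run.toml"
    path.write_text("""
[run]
seed = 42
[calling]
k = 1.5
[stats]
alpha = 0.01
[lamina]
merge_cut_um3 = 3.0
voxel_spacing = [0.2, 0.1, 0.1]
""")
    cfg2 = load_config(path)
    assert cfg2.seed == 42
    assert cfg2.k == 1.5
    assert cfg2.alpha == 0.01
    assert cfg2.lamina.merge_cut_um3 == 3.0
    assert cfg2.voxel_spacing == (0.2, 0.1, 0.1)


def test_config_rejects_unknown_and_invalid(tmp_path):
    bad = tmp_path / "bad.toml"
    bad.write_text("[nonsense]\nx = 1\n")
    with pytest.raises(ConfigError, match="unknown config sections"):
        load_config(bad)
    bad2 = tmp_path / "bad2.toml"
    bad2.write_text("[stats]\nalpha = 2.0\n")
    with pytest.raises(ConfigError, match="alpha"):
        load_config(bad2)
    bad3 = tmp_path / "bad3.toml"
    bad3.write_text("[segmentation]\nbogus_knob = 1\n")
    with pytest.raises(ConfigError, match="bogus_knob"):
        load_config(bad3)
    with pytest.raises(ConfigError, match="not found"):
        load_config(tmp_path / "missing.toml")


# --- manifests ---------------------------------------------------------------


def test_manifest_hash_stability():
    cfg = {"alpha": 0.05, "nested": {"a": 1}}
    m1 = io.make_manifest("call", cfg, seed=3, counts={"cells": 10})
    m2 = io.make_manifest("call", dict(cfg), seed=3, counts={"cells": 10})
    assert m1 == m2
    m3 = io.make_manifest("call", {**cfg, "alpha": 0.01}, seed=3,
                          counts={"cells": 10})
    assert m3["config_hash"] != m1["config_hash"]


def test_manifest_write_read(tmp_path):
    m = io.make_manifest("stats", {"x": 1}, seed=0, counts={"rows": 5})
    io.write_manifest(tmp_path / "m.json", m)
    back = io.read_manifest(tmp_path / "m.json")
    assert "created" in back
    back.pop("created")
    assert back == m


# --- CLI --------------------------------------------------------------------


def _write_cfg(tmp_path, seed=5):
    cfg = tmp_path / "run.toml"
    cfg.write_text(f'[paths]\noutput_dir = "{tmp_path / "out"}"\n'
                   f'[run]\nseed = {seed}\n')
    return cfg


def test_cli_all_writes_consistent_artifacts(tmp_path):
    cfg = _write_cfg(tmp_path)
    runner = CliRunner()
    res = runner.invoke(cli_main, ["all", "-c", str(cfg),
                                   "--cells-per-well", "200"])
    assert res.exit_code == 0, res.output
    out = tmp_path / "out"
    for name in ("cells.csv", "calls.csv", "summary.csv", "volcano.csv",
                 "qc_ledger.csv", "manifest_call.json"):
        assert (out / name).exists()
    manifest = io.read_manifest(out / "manifest_call.json")
    c = manifest["counts"]
    assert c["cells_in"] == c["retained"] + c["removed"]
    assert manifest["seed"] == 5


def test_cli_rerun_same_seed_identical_manifests(tmp_path):
    runner = CliRunner()
    manifests = []
    for run in ("a", "b"):
        root = tmp_path / run
        root.mkdir()
        cfg = root / "run.toml"
        cfg.write_text(f'[paths]\noutput_dir = "{root / "out"}"\n[run]\nseed = 9\n')
        res = runner.invoke(cli_main, ["simulate-plate", "-c", str(cfg),
                                       "--cells-per-well", "100"])
        assert res.exit_code == 0, res.output
        m = io.read_manifest(root / "out" / "manifest_simulate-plate.json")
        m.pop("created")
        m.pop("config_hash")  # hash covers output_dir, which differs per run
        manifests.append(m)
        cells = (root / "out" / "cells.csv").read_text()
        manifests.append(cells)
    assert manifests[0] == manifests[2]
    assert manifests[1] == manifests[3]  # tables are bit-identical too


def test_cli_stats_without_call_table_errors(tmp_path):
    cfg = _write_cfg(tmp_path)
    runner = CliRunner()
    res = runner.invoke(cli_main, ["stats", "-c", str(cfg)])
    assert res.exit_code != 0
    assert "missing call table" in res.output


def test_cli_invalid_config_nonzero_exit(tmp_path):
    bad = tmp_path / "bad.toml"
    bad.write_text("[stats]\nalpha = 7\n")
    runner = CliRunner()
    res = runner.invoke(cli_main, ["simulate-plate", "-c", str(bad)])
    assert res.exit_code != 0
    assert "alpha" in res.output


def test_cli_phantom_then_gaps(tmp_path):
    cfg = tmp_path / "run.toml"
    cfg.write_text(f'[paths]\noutput_dir = "{tmp_path / "out"}"\n'
                   '[run]\nseed = 2\n'
                   '[lamina]\nvoxel_spacing = [0.25, 0.25, 0.25]\n')
    runner = CliRunner()
    res = runner.invoke(cli_main, ["simulate-phantom", "-c", str(cfg),
                                   "--theta", "30"])
    assert res.exit_code == 0, res.output
    res2 = runner.invoke(cli_main, ["gaps", "-c", str(cfg)])
    assert res2.exit_code == 0, res2.output
    gaps = io.read_table(tmp_path / "out" / "gaps.csv", schema="gaps")
    nucleus = io.read_table(tmp_path / "out" / "nucleus.csv", schema="nucleus")
    assert (gaps["status"] == "kept").sum() == nucleus["n_gaps"].iloc[0]
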