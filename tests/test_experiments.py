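import json

import numpy as np
import pandas as pd
import pytest

import bcmring as b


def small_config(**kw):
    base = dict(n_values=(8,), steps_per_tau=3.5, max_steps=2_000_000, seed=0)
    base.update(kw)
    return b.ExperimentConfig(**base)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="even"):
            b.ExperimentConfig(n_values=(7,))
        with pytest.raises(ValueError, match="k_ratio"):
            b.ExperimentConfig(k_ratio="triple")
        with pytest.raises(ValueError, match="epoch"):
            b.ExperimentConfig(n_values=(100,), max_steps=50)

    def test_yaml_roundtrip_with_override(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("profile_kind: triangular\nomega: 0.38\nn_values: [8, 10]\nseed: 5\n")
        cfg = b.ExperimentConfig.from_yaml(path, seed=9)
        assert cfg.profile_kind == "triangular"
        assert cfg.n_values == (8, 10)
        assert cfg.seed == 9  # flag overrides file


class TestSlowdown:
    def test_single_n_row_contents(self):
        res = b.run_slowdown_experiment(small_config())
        row = res.table.iloc[0]
        assert row["status"] == "ok"
        assert row["crit_mode"] == 4
        assert row["lambda_crit"] == pytest.approx(row["lambda_half_mode"])
        assert row["tau_theory_steps"] == pytest.approx(8 * row["tau_theory"])
        assert 0.5 < row["tau_sim"] / row["tau_theory_steps"] < 2.0
        assert row["r_squared"] > 0.99

    def test_tau_theory_column_matches_direct_call(self):
        cfg = small_config(n_values=(8, 10), max_steps=400_000)
        res = b.run_slowdown_experiment(cfg)
        for _, row in res.table.iterrows():
            direct = b.critical_timescale(b.von_mises_profile(int(row["N"]), 0.5), cfg.tau_w)
            assert row["tau_theory"] == pytest.approx(direct, rel=1e-12)
        assert res.table["tau_theory"].is_monotonic_increasing

    def test_delta_profile_theory(self):
        cfg = small_config(profile_kind="delta", omega=0.0, max_steps=50_000)
        res = b.run_slowdown_experiment(cfg)
        assert res.table.iloc[0]["tau_theory"] == pytest.approx(1000.0 / 8)

    def test_budget_truncation_flags_unconverged_run(self):
        # far too short a run for the fit window: flagged, not silently fit
        cfg = small_config(max_steps=2000)
        res = b.run_slowdown_experiment(cfg)
        assert res.table.iloc[0]["status"].startswith("failed")

    def test_requires_equal_ratio(self):
        with pytest.raises(ValueError, match="equal"):
            b.run_slowdown_experiment(small_config(k_ratio="half"))


class TestCompleteness:
    def test_equal_ratio_reproduces_slowdown_trajectory(self):
        cfg = small_config()
        slow = b.run_slowdown_experiment(cfg)
        comp = b.run_completeness_experiment(cfg)
        t1 = slow.trajectories["slowdown_von_mises_N8"]
        t2 = comp.trajectories["completeness_equal_N8"]
        np.testing.assert_array_equal(t1.weight_history, t2.weight_history)
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_undercomplete_run_converges_and_reports_winner(self):
        cfg = small_config(k_ratio="half", max_steps=1_000_000)
        res = b.run_completeness_experiment(cfg)
        row = res.table.iloc[0]
        assert row["K"] == 4 and row["init"] == "random"
        assert row["status"] == "ok"
        assert np.isfinite(row["conv_steps"])
        assert 0 <= row["winner"] < 4
        # selective steady state: theta = K
        assert row["final_theta"] == pytest.approx(4.0, rel=0.05)

    def test_overcomplete_run(self):
        cfg = small_config(k_ratio="double", max_steps=2_000_000)
        res = b.run_completeness_experiment(cfg)
        row = res.table.iloc[0]
        assert row["K"] == 16 and row["init"] == "random"
        assert np.isfinite(row["conv_steps"])


class TestExport:
    def test_full_roundtrip(self, tmp_path):
        cfg = small_config(max_steps=300_000)
        res = b.run_slowdown_experiment(cfg)
        files = b.export_results({"slowdown": res.table}, res.traces, cfg, output_dir=tmp_path)
        names = {f.name for f in files}
        assert "slowdown.csv" in names and "manifest.json" in names
        back = pd.read_csv(tmp_path / "slowdown.csv")
        assert back.shape[0] == res.table.shape[0]
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["seed"] == 0
        trace_files = [f for f in files if f.name.startswith("trace_")]
        assert trace_files
        header = trace_files[0].read_text().splitlines()[0]
        assert header == "step,angle,normalized_angle"

    def test_empty_results_manifest_only(self, tmp_path):
        cfg = small_config()
        files = b.export_results({"slowdown": pd.DataFrame()}, {}, cfg, output_dir=tmp_path)
        assert [f.name for f in files] == ["manifest.json"]


class TestDeterminism:
    def test_repeat_run_bit_identical(self, tmp_path):
        cfg = small_config(max_steps=300_000)
        res1 = b.run_slowdown_experiment(cfg)
        res2 = b.run_slowdown_experiment(cfg)
        pd.testing.assert_frame_equal(res1.table, res2.table, check_exact=True)
        b.export_results({"t": res1.table}, res1.traces, cfg, output_dir=tmp_path / "a")
        b.export_results({"t": res2.table}, res2.traces, cfg, output_dir=tmp_path / "b")
        for name in ("t.csv", "trace_slowdown_von_mises_N8.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestCLI:
    def test_spectrum_subcommand(self):
        from click.testing import CliRunner

        from bcmring.cli import main

        runner = CliRunner()
        result = runner.invoke(main, ["spectrum", "--n", "8", "--profile-kind", "von_mises"])
        assert result.exit_code == 0
        payload = json.loads(result.output[result.output.index("{"):])
        assert payload["crit_mode"] == 4

    def test_fixed_points_subcommand(self):
        from click.testing import CliRunner

        from bcmring.cli import main

        runner = CliRunner()
        result = runner.invoke(main, ["fixed-points", "--n", "4"])
        assert result.exit_code == 0
        reports = json.loads(result.output[result.output.index("["):])
        assert len(reports) == 4
        assert all(r["stability"] == "stable" for r in reports)
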