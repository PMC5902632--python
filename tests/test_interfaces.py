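"""I/O, report, plotting and CLI contracts."""

import json

import numpy as np
import pytest

from hoogfit.core import ExchangeModel, r1rho_profile
from hoogfit.fitting import fit_bm, monte_carlo_uncertainty
from hoogfit.io import (
    REPORT_CSV_COLUMNS,
    StudyConfig,
    plot_dispersion,
    read_decay_table,
    read_fit_report,
    read_profile_table,
    write_decay_table,
    write_fit_report,
    write_profile_table,
)
from hoogfit.synthetic import NoiseSpec, TruthTable, generate_study, scenario_truth

from conftest import make_profile


@pytest.fixture(scope="module")
def small_study(grid_small):
    truth = TruthTable((scenario_truth("echinomycin_bound_10C"),))
    return generate_study(truth, NoiseSpec(0.01, seed=4), grid_small)


class TestDecayTable:
    def test_roundtrip_is_identity(self, small_study, tmp_path):
        curves = small_study.curves["A3C8"]
        path = tmp_path / "decays.csv"
        write_decay_table(curves, path)
        back = read_decay_table(path)
        assert len(back) == len(curves)
        for a, b in zip(curves, back):
            np.testing.assert_allclose(b.intensities, a.intensities, atol=1e-12)
            assert b.condition.omega_sl == a.condition.omega_sl
            np.testing.assert_allclose(b.condition.delays, a.condition.delays, atol=1e-12)

    def test_well_formed_three_row_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "spin_label,nucleus,omega_sl_hz,offset_hz,delay_s,intensity,intensity_error\n"
            "A3C8,C13,1000,0,0.0,1.0,0.01\n"
            "A3C8,C13,1000,0,0.02,0.6,0.01\n"
            "A3C8,C13,1000,0,0.04,0.36,0.01\n"
        )
        curves = read_decay_table(p)
        assert len(curves) == 1 and len(curves[0].intensities) == 3

    def test_duplicate_delay_row_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "spin_label,nucleus,omega_sl_hz,offset_hz,delay_s,intensity,intensity_error\n"
            "A3C8,C13,1000,0,0.0,1.0,0.01\n"
            "A3C8,C13,1000,0,0.0,0.99,0.01\n"
        )
        with pytest.raises(ValueError, match="duplicate.*line.*2"):
            read_decay_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("spin_label,omega_sl_hz\nA,1\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_decay_table(p)

    def test_non_numeric_cell_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "spin_label,nucleus,omega_sl_hz,offset_hz,delay_s,intensity,intensity_error\n"
            "A3C8,C13,1000,0,zero,1.0,0.01\n"
        )
        with pytest.raises(ValueError, match="non-numeric.*delay_s.*2"):
            read_decay_table(p)


class TestProfileTable:
    def test_roundtrip(self, small_study, tmp_path):
        profs = list(small_study.profiles.values())
        path = tmp_path / "prof.csv"
        write_profile_table(profs, path)
        back = read_profile_table(path)
        np.testing.assert_allclose(back[0].r1rho, profs[0].r1rho, atol=1e-12)


class TestFitReport:
    @pytest.fixture(scope="class")
    def fit_and_profile(self, grid_small):
        truth = scenario_truth("echinomycin_bound_10C")
        prof = make_profile(truth.model, grid_small, noise_sd=0.2, seed=2,
                            label=truth.spin_label, temperature=10.0)
        fit = fit_bm(prof, method="eigen", seed=2)
        monte_carlo_uncertainty(fit, prof, n_children=40, seed=2)
        return fit, prof

    def test_report_reread_reproduces_values(self, fit_and_profile, tmp_path):
        fit, _ = fit_and_profile
        write_fit_report([fit], tmp_path / "report")
        payload = read_fit_report(tmp_path / "report")
        row = payload["fits"][0]
        assert row["p_b"] == fit.model.p_b
        assert row["k_ex"] == fit.model.k_ex
        assert row["p_b_sd"] == fit.uncertainties["p_b"]

    def test_csv_schema_is_stable(self, fit_and_profile, tmp_path):
        fit, _ = fit_and_profile
        _, csv_path = write_fit_report([fit], tmp_path / "report")
        header = csv_path.read_text().splitlines()[0].split(",")
        assert header == REPORT_CSV_COLUMNS == [
            "spin_label", "temperature", "model", "alignment",
            "p_b", "p_b_sd", "k_ex", "k_ex_sd", "delta_omega", "delta_omega_sd",
            "r1", "r1_sd", "r2", "r2_sd",
            "chi2", "reduced_chi2", "aic", "bic", "n_points", "seed",
        ]

    def test_empty_thermo_section_allowed(self, fit_and_profile, tmp_path):
        fit, _ = fit_and_profile
        jp, _ = write_fit_report([fit], tmp_path / "single_temp", thermo=None)
        assert json.loads(jp.read_text())["thermo"] == []

    def test_config_hash_embedded_and_stable(self, fit_and_profile, tmp_path):
        fit, _ = fit_and_profile
        cfg = StudyConfig(scenario="demo", seed=2)
        jp, _ = write_fit_report([fit], tmp_path / "cfg", config=cfg)
        payload = json.loads(jp.read_text())
        assert payload["config_hash"] == StudyConfig(scenario="demo", seed=2).config_hash()
        assert payload["config"]["seed"] == 2


class TestPlot:
    @pytest.mark.parametrize("with_fit", [False, True])
    def test_plot_writes_identical_bytes_twice(self, grid_small, tmp_path, with_fit):
        truth = scenario_truth("echinomycin_bound_10C")
        prof = make_profile(truth.model, grid_small, noise_sd=0.2, seed=3,
                            label="A3C8", temperature=10.0)
        fit = fit_bm(prof, method="eigen") if with_fit else None
        p1 = plot_dispersion(prof, fit, tmp_path / "a.png")
        p2 = plot_dispersion(prof, fit, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_model_curve_consistent_with_noisy_data(self, grid_small):
        # on self-generated data the fitted curve should pass within 3 s.d.
        # of at least 95% of the points
        truth = scenario_truth("echinomycin_bound_10C")
        prof = make_profile(truth.model, grid_small, noise_sd=0.2, seed=8)
        fit = fit_bm(prof, method="eigen")
        sim = r1rho_profile(fit.model, prof.conditions, "eigen")
        resid = np.abs(np.asarray(prof.r1rho) - sim) / np.asarray(prof.r1rho_error)
        assert np.mean(resid < 3.0) >= 0.95


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "scenario: demo\nfield_mhz: 700.0\nseed: 7\n"
            "bounds:\n  p_b: [1.0e-5, 0.5]\n  k_ex: [10, 100000]\n"
        )
        cfg = StudyConfig.from_yaml(p)
        assert cfg.seed == 7
        assert cfg.bounds.p_b == (1e-5, 0.5)

    def test_missing_input_path_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("input_paths: [/nonexistent/data.csv]\n")
        with pytest.raises(FileNotFoundError):
            StudyConfig.from_yaml(p)


class TestCli:
    def test_simulate_then_vanthoff_and_biasdemo(self, tmp_path):
        from click.testing import CliRunner

        from hoogfit.cli import main

        runner = CliRunner()
        r = runner.invoke(main, ["simulate", "--scenario", "echinomycin_bound_10C",
                                 "--seed", "1", "--out", str(tmp_path / "sim")])
        assert r.exit_code == 0, r.output
        truth = json.loads((tmp_path / "sim" / "truth.json").read_text())
        assert truth["p_b"] == 0.0207

        vh_csv = tmp_path / "vh.csv"
        vh_csv.write_text(
            "temperature_c,p_b,p_b_sd\n10.0,0.0207,0.003\n25.0,0.079,0.007\n"
        )
        r = runner.invoke(main, ["vanthoff", "--input", str(vh_csv),
                                 "--out", str(tmp_path / "vh.json")])
        assert r.exit_code == 0, r.output
        assert "dH" in r.output

        r = runner.invoke(main, ["biasdemo", "--alpha", "200", "--steps", "4000",
                                 "--seed", "2", "--out", str(tmp_path / "bias")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "bias" / "trajectory.csv").exists()

    def test_unknown_scenario_exits_with_validation_code(self, tmp_path):
        from click.testing import CliRunner

        from hoogfit.cli import main

        r = CliRunner().invoke(main, ["simulate", "--scenario", "nope",
                                      "--out", str(tmp_path)])
        assert r.exit_code == 2
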