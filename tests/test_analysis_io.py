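import numpy as np
import pytest
from click.testing import CliRunner

from refecho import (
    EchoMap2D,
    SNRParams,
    StretchedExpFit,
    normalize_slices,
    read_map,
    read_trace,
    ridge,
    snr_estimate,
    stretched_exp_fit,
    write_map,
    write_trace,
)
from refecho.cli import main

US = 1e-6


def stretched(t, V0, TM, x):
    return V0 * np.exp(-((t / TM) ** x))


class TestStretchedExpFit:
    def test_exact_recovery_of_noiseless_trace(self):
        t = np.linspace(0.1, 8.0, 60) * US
        fit = stretched_exp_fit(t, stretched(t, 1.0, 2.14 * US, 2.01))
        assert fit.TM == pytest.approx(2.14 * US, rel=1e-4)
        assert fit.x == pytest.approx(2.01, rel=1e-4)
        assert fit.V0 == pytest.approx(1.0, rel=1e-4)
        assert fit.residual_norm < 1e-8

    def test_pure_exponential_TM_is_1_over_e_time(self):
        t = np.linspace(0.05, 12.0, 80) * US
        fit = stretched_exp_fit(t, stretched(t, 2.0, 3.0 * US, 1.0))
        # V(TM) = V0 / e for a pure exponential
        assert stretched(fit.TM, fit.V0, fit.TM, fit.x) == pytest.approx(
            fit.V0 / np.e, rel=1e-6
        )
        assert fit.TM == pytest.approx(3.0 * US, rel=1e-6)

    def test_time_rescaling_equivariance(self):
        t = np.linspace(0.1, 9.0, 50) * US
        V = stretched(t, 1.0, 2.5 * US, 1.7)
        fit1 = stretched_exp_fit(t, V)
        fit2 = stretched_exp_fit(2.0 * t, V)
        assert fit2.TM == pytest.approx(2.0 * fit1.TM, rel=1e-6)
        assert fit2.x == pytest.approx(fit1.x, rel=1e-6)

    def test_noisy_recovery_within_3_percent(self):
        """Median recovered TM and x over 100 noisy traces (sigma = 0.01)."""
        t = np.linspace(0.1, 8.0, 60) * US
        truth = stretched(t, 1.0, 2.14 * US, 2.01)
        rng = np.random.default_rng(2024)
        tms, xs = [], []
        for _ in range(100):
            fit = stretched_exp_fit(t, truth + rng.normal(0, 0.01, t.size))
            tms.append(fit.TM)
            xs.append(fit.x)
        assert abs(np.median(tms) - 2.14 * US) / (2.14 * US) < 0.03
        assert abs(np.median(xs) - 2.01) / 2.01 < 0.03
        assert np.median([f for f in tms]) > 0

    def test_uncertainties_cover_noise_scale(self):
        t = np.linspace(0.1, 8.0, 60) * US
        rng = np.random.default_rng(7)
        V = stretched(t, 1.0, 2.0 * US, 2.0) + rng.normal(0, 0.01, t.size)
        fit = stretched_exp_fit(t, V)
        assert 0 < fit.TM_err < 0.3 * US
        assert 0 < fit.x_err < 0.3

    def test_degenerate_trace_raises(self):
        t = np.linspace(0.1, 5.0, 20) * US
        with pytest.raises(ValueError, match="decay"):
            stretched_exp_fit(t, np.ones(20))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            stretched_exp_fit(np.array([1, 2, 3]) * US, np.array([1.0, 0.5, 0.2]))


class TestNormalizeSlices:
    def _map(self):
        t1 = np.linspace(0, 4e-6, 17)
        t2 = np.linspace(0, 4e-6, 9)
        V = np.exp(-((t1[:, None] + 2 * t2[None, :]) / 3e-6) ** 2) * (
            1 + 0.2 * np.sin(t1[:, None] * 2e6)
        )
        return EchoMap2D(t1, t2, V, normalized=True)

    def test_every_slice_maximum_is_one_and_idempotent(self):
        emap = self._map()
        norm = normalize_slices(emap, axis="tau1")
        np.testing.assert_allclose(norm.V.max(axis=0), 1.0, atol=1e-12)
        again = normalize_slices(norm, axis="tau1")
        np.testing.assert_allclose(again.V, norm.V, atol=1e-12)
        norm2 = normalize_slices(emap, axis="tau2")
        np.testing.assert_allclose(norm2.V.max(axis=1), 1.0, atol=1e-12)

    def test_ridge_commutes_with_normalization(self):
        emap = self._map()
        raw_curve, _ = ridge(emap)
        norm_curve, _ = ridge(normalize_slices(emap, axis="tau1"))
        np.testing.assert_allclose(norm_curve.tau1_star, raw_curve.tau1_star, atol=1e-15)

    def test_zero_slice_flagged(self):
        t = np.linspace(0, 1e-6, 4)
        V = np.ones((4, 4))
        V[:, 2] = 0.0
        norm = normalize_slices(EchoMap2D(t, t, V), axis="tau1")
        assert norm.meta["zero_slices"] == [2]
        np.testing.assert_array_equal(norm.V[:, 2], 0.0)


class TestSNR:
    def _fit(self):
        return StretchedExpFit(V0=1.0, TM=2.14 * US, x=2.0, V0_err=0, TM_err=0,
                               x_err=0, residual_norm=0)

    def test_zero_modulation_depth(self):
        p = SNRParams(self._fit(), modulation_depth=0.0, T1=1e-3, tau=1e-6)
        assert snr_estimate(p) == 0.0

    def test_quadrupling_T1_halves_snr(self):
        p1 = SNRParams(self._fit(), 0.3, T1=1e-3, tau=1e-6)
        p4 = SNRParams(self._fit(), 0.3, T1=4e-3, tau=1e-6)
        assert snr_estimate(p4) == pytest.approx(snr_estimate(p1) / 2.0)

    def test_zero_evolution_time(self):
        p = SNRParams(self._fit(), 0.5, T1=1e-3, tau=0.0)
        assert snr_estimate(p) == pytest.approx(1.0 * 0.5 / np.sqrt(1e-3))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SNRParams(self._fit(), modulation_depth=1.5, T1=1e-3, tau=0.0)
        with pytest.raises(ValueError):
            SNRParams(self._fit(), 0.5, T1=-1.0, tau=0.0)


class TestFileIO:
    def test_trace_roundtrip(self, tmp_path):
        t = np.linspace(0, 5e-6, 100)
        V = np.exp(-t / 2e-6)
        p = tmp_path / "trace.dat"
        write_trace(p, t, V, header="synthetic decay")
        t2, V2 = read_trace(p)
        np.testing.assert_allclose(t2, t, atol=1e-16)
        np.testing.assert_array_equal(V2, V)
        assert sum(1 for ln in p.read_text().splitlines() if not ln.startswith("#")) == 100

    def test_map_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        t1 = np.linspace(0, 5e-6, 50)
        t2 = np.linspace(0, 7e-6, 50)
        emap = EchoMap2D(t1, t2, rng.random((50, 50)))
        p = tmp_path / "map.csv"
        write_map(p, emap)
        back = read_map(p)
        np.testing.assert_array_equal(back.V, emap.V)
        np.testing.assert_allclose(back.tau1, t1, atol=1e-18)
        np.testing.assert_allclose(back.tau2, t2, atol=1e-18)

    def test_shuffled_rows_rejected(self, tmp_path):
        t = np.linspace(0, 2e-6, 4)
        emap = EchoMap2D(t, t, np.random.default_rng(0).random((4, 4)))
        p = tmp_path / "map.csv"
        write_map(p, emap)
        lines = p.read_text().splitlines()
        lines[1], lines[3] = lines[3], lines[1]
        bad = tmp_path / "shuffled.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="non-monotonic"):
            read_map(bad)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b,c\n0,1,2\n")
        with pytest.raises(ValueError):
            read_map(p)

    def test_single_column_trace_rejected(self, tmp_path):
        p = tmp_path / "one.dat"
        p.write_text("1.0\n2.0\n")
        with pytest.raises(ValueError):
            read_trace(p)

    def test_map_axes_validation(self):
        with pytest.raises(ValueError, match="non-monotonic"):
            EchoMap2D(np.array([0.0, 2e-6, 1e-6]), np.array([0.0]), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="inconsistent"):
            EchoMap2D(np.array([0.0, 1e-6]), np.array([0.0]), np.zeros((3, 1)))


class TestCLI:
    def test_fit_command_recovers_fixture_parameters(self, tmp_path):
        t = np.linspace(0.05, 4.0, 80) * US  # tau axis; fit uses 2*tau
        V = stretched(2 * t, 1.0, 2.14 * US, 2.01)
        trace = tmp_path / "decay.dat"
        write_trace(trace, t, V)
        result = CliRunner().invoke(main, ["fit", str(trace)])
        assert result.exit_code == 0, result.output
        assert "TM = 2.14" in result.output
        assert "x  = 2.01" in result.output

    def test_simulate_refocused_and_analyze_pipeline(self, tmp_path):
        cfg = tmp_path / "config.yaml"
        cfg.write_text(
            "density: 0.004\ncutoff: 8.0\nseed: 3\nk: 2\n"
            "tau1_max_us: 3.0\ntau1_points: 7\ntau2_max_us: 3.0\ntau2_points: 5\n"
        )
        out = tmp_path / "map.csv"
        result = CliRunner().invoke(main, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert out.exists() and (tmp_path / "map.csv.log.yaml").exists()
        emap = read_map(out)
        assert emap.V[0, 0] == pytest.approx(1.0)
        result = CliRunner().invoke(main, ["analyze", str(out)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "map_ridge.csv").exists()
        assert (tmp_path / "map_normalized.csv").exists()
        assert "deviation onset" in result.output

    def test_simulate_hahn_trace(self, tmp_path):
        cfg = tmp_path / "config.yaml"
        cfg.write_text(
            "density: 0.004\ncutoff: 8.0\nseed: 3\nsequence: hahn\n"
            "tau1_max_us: 3.0\ntau1_points: 12\n"
        )
        out = tmp_path / "decay.dat"
        result = CliRunner().invoke(main, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        t, V = read_trace(out)
        assert t.size == 12 and V[0] == pytest.approx(1.0)

    def test_simulate_empty_bath_warns(self, tmp_path):
        cfg = tmp_path / "config.yaml"
        cfg.write_text("protonation: 0.0\nsequence: hahn\ntau1_points: 8\n")
        out = tmp_path / "flat.dat"
        result = CliRunner().invoke(
            main, ["simulate", "--config", str(cfg), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert "empty bath" in result.output
        _, V = read_trace(out)
        np.testing.assert_array_equal(V, 1.0)

    def test_analyze_diagonal_ridge_reports_none(self, tmp_path):
        t = np.linspace(0, 4e-6, 15)
        V = np.exp(-((t[:, None] - t[None, :]) / 2e-6) ** 2)
        p = tmp_path / "diag.csv"
        write_map(p, EchoMap2D(t, t, V))
        result = CliRunner().invoke(main, ["analyze", str(p)])
        assert result.exit_code == 0, result.output
        assert "deviation onset (tau2): none" in result.output

    def test_invalid_config_fails_with_diagnostic(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("no_such_key: 1\n")
        result = CliRunner().invoke(main, ["simulate", "--config", str(cfg)])
        assert result.exit_code != 0
        assert "unknown config keys" in result.output

    def test_ridge_command(self, tmp_path):
        t = np.linspace(0, 4e-6, 9)
        V = np.exp(-((t[:, None] + t[None, :]) / 2e-6) ** 2)
        p = tmp_path / "m.csv"
        write_map(p, EchoMap2D(t, t, V))
        result = CliRunner().invoke(main, ["ridge", str(p), "--out", str(tmp_path / "r.csv")])
        assert result.exit_code == 0, result.output
        text = (tmp_path / "r.csv").read_text()
        assert text.startswith("tau2_us,tau1_star_us,flag")
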