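"""Tests of the external-calibration quantification workflow."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanoburden.pyrolysis import (PyroSample, calibration_standard_mass,
                                  censored_mean, detection_limits,
                                  fit_calibration, quantify_organ,
                                  spike_recovery)
from nanoburden.synthetic import generate_pyro_run


class TestFitCalibration:
    def test_exact_line(self):
        masses = [37, 150, 600, 1500, 3700]
        curve = fit_calibration(masses, [2.0 * m for m in masses])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_distinct_masses_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration([10, 10, 20], [20, 20, 40])

    def test_lung_standard_preparation(self):
        # 62 mg stock / 25 mL, 50 µL -> 10 mL, 3 µL pipetted
        assert calibration_standard_mass(62.0, pipetted_ul=3.0) == pytest.approx(37.2)

    def test_node_standard_preparation(self):
        assert calibration_standard_mass(49.0, pipetted_ul=2.0) == pytest.approx(19.6)


class TestQuantifyOrgan:
    CURVE = fit_calibration([37, 150, 600, 1500, 3700],
                            [2.0 * m + 10 for m in [37, 150, 600, 1500, 3700]])

    def test_dilution_factor_1000(self):
        # 190 ng in the crucible, 20 µL of a 20 mL extract -> 190 µg/organ
        sample = PyroSample(peak_area=2.0 * 190 + 10, aliquot_ul=20,
                            extract_ml=20)
        out = quantify_organ(sample, self.CURVE)
        assert out["mass_per_organ_ug"] == pytest.approx(190.0)

    @pytest.mark.parametrize("organ_ug, wet_g, per_g", [
        (3800.0, 1.05, 3.619), (260.0, 0.91, 0.2857)])
    def test_per_gram_normalisation(self, organ_ug, wet_g, per_g):
        crucible_ng = organ_ug  # dilution factor 1000
        sample = PyroSample(peak_area=2.0 * crucible_ng + 10, aliquot_ul=20,
                            extract_ml=20, organ_wet_mass_g=wet_g)
        out = quantify_organ(sample, self.CURVE)
        assert out["mass_per_g_mg"] == pytest.approx(per_g, abs=2e-3)

    def test_area_below_intercept_reports_zero_flagged(self):
        sample = PyroSample(peak_area=5.0, aliquot_ul=20, extract_ml=20)
        out = quantify_organ(sample, self.CURVE)
        assert out["mass_per_organ_ug"] == 0.0 and out["below_range"]

    def test_dilution_linearity(self):
        a = quantify_organ(PyroSample(410.0, 20, 20), self.CURVE)
        b = quantify_organ(PyroSample(410.0, 20, 40), self.CURVE)
        assert b["mass_per_organ_ug"] == pytest.approx(
            2 * a["mass_per_organ_ug"])


class TestDetectionLimits:
    def _node_curve(self, sd_ng=2.0, lowest=20.0):
        rng = np.random.default_rng(1)
        masses = np.concatenate([np.full(6, lowest), [115, 575, 1140]])
        areas = 3.0 * masses
        areas[:6] += rng.normal(0, 3.0 * sd_ng, 6)  # scatter on the mass scale
        return fit_calibration(masses, areas)

    def test_node_loq_from_dilution_factor_75(self):
        curve = self._node_curve()
        limits = detection_limits(curve, dilution_factor=75.0)
        assert limits.loq_ug == pytest.approx(1.5)

    def test_node_lod_with_default_margin(self):
        # default margin = 20% of lowest mass -> LOD = 0.8 * LOQ = 1.2 µg
        limits = detection_limits(self._node_curve(), 75.0)
        assert limits.lod_ug == pytest.approx(1.2)

    def test_zero_replicate_scatter_gives_lod_equal_loq(self):
        masses = np.array([20.0, 20, 20, 115, 575, 1140])
        curve = fit_calibration(masses, 3.0 * masses)
        limits = detection_limits(curve, 75.0, k=3.0)
        assert limits.lod_ug == pytest.approx(limits.loq_ug)

    def test_missing_sd_warns_and_falls_back(self):
        masses = [20, 115, 575, 1140]
        curve = fit_calibration(masses, [3.0 * m for m in masses])
        with pytest.warns(UserWarning, match="no replicate SD"):
            limits = detection_limits(curve, 75.0, k=3.0)
        assert limits.lod_ug == limits.loq_ug

    @given(lowest=st.floats(1.0, 500.0), dilution=st.floats(1.0, 2000.0),
           k=st.floats(0.0, 5.0), sd=st.floats(0.0, 100.0))
    def test_lod_never_exceeds_loq(self, lowest, dilution, k, sd):
        masses = np.array([lowest, lowest, 10 * lowest, 50 * lowest])
        areas = 2.0 * masses
        areas[1] += 2.0 * sd
        curve = fit_calibration(masses, areas)
        limits = detection_limits(curve, dilution, k=k)
        assert 0 < limits.lod_ug <= limits.loq_ug


class TestSpikeRecovery:
    @pytest.mark.parametrize("measured, endo, spiked, expected", [
        (100.0, 0.0, 100.0, 100.0),
        (163.0, 100.0, 100.0, 63.0),
    ])
    def test_recovery_arithmetic(self, measured, endo, spiked, expected):
        assert spike_recovery(measured, spiked, endo) == pytest.approx(expected)

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError):
            spike_recovery(10.0, 0.0)


class TestRoundTrip:
    def test_noise_free_recovery_is_exact(self):
        masses = np.array([37.0, 150, 600, 1500, 3700])
        run = generate_pyro_run(masses, slope=3.5, intercept=40.0)
        curve = fit_calibration(run["mass_ng"], run["peak_area"])
        for m, a in zip(masses, run["peak_area"]):
            sample = PyroSample(peak_area=a, aliquot_ul=20, extract_ml=20)
            out = quantify_organ(sample, curve)
            assert out["crucible_mass_ng"] == pytest.approx(m, rel=1e-9)

    def test_bias_shrinks_with_noise(self):
        masses = np.repeat([37.0, 150, 600, 1500, 3700], 3)
        bias = {}
        for sd in (40.0, 4.0):
            errs = []
            for seed in range(30):
                run = generate_pyro_run(masses, 3.5, 40.0, noise_sd=sd,
                                        seed=seed)
                curve = fit_calibration(run["mass_ng"], run["peak_area"])
                probe = generate_pyro_run([600.0], 3.5, 40.0, noise_sd=sd,
                                          seed=1000 + seed)
                out = quantify_organ(
                    PyroSample(probe["peak_area"].iloc[0], 20, 20), curve)
                errs.append(out["crucible_mass_ng"] / 600.0 - 1.0)
            bias[sd] = abs(np.mean(errs))
        assert bias[4.0] < bias[40.0]


def test_censored_mean_substitution():
    assert censored_mean([0.5, 3.0, 5.0], lod_ug=1.2) == pytest.approx(
        (0.6 + 3.0 + 5.0) / 3)
    assert censored_mean([0.5, 3.0, 5.0], 1.2, "exclude") == pytest.approx(4.0)
    with pytest.raises(ValueError):
        censored_mean([0.1], 1.2, "exclude")
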