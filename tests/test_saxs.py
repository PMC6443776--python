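import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from silkstruct import saxs, synthgen
from silkstruct.profiles import Profile1D

from conftest import square_wave_autocorrelation


class TestKratky:
    def test_inverse_square_gives_flat_curve(self):
        q = np.linspace(0.1, 2.0, 200)
        prof = Profile1D(q, 1.0 / q**2, kind="q", wavelength=0.0709)
        k = saxs.kratky_transform(prof)
        np.testing.assert_allclose(k.intensity, 1.0, rtol=1e-12)

    def test_enhances_lamellar_peaks(self, default_lamellar_profile):
        k = saxs.kratky_transform(default_lamellar_profile)
        idx, _ = find_peaks(k.intensity,
                            prominence=2e-4 * np.max(k.intensity))
        assert len(idx) == 5

    def test_requires_q_profile(self, default_waxd_profile):
        with pytest.raises(ValueError):
            saxs.kratky_transform(default_waxd_profile)


class TestHarmonicPeaks:
    def test_long_period_recovery(self, default_lamellar_profile):
        res = saxs.find_harmonic_peaks(
            saxs.kratky_transform(default_lamellar_profile))
        assert res.lp_1st == pytest.approx(38.5, abs=0.1)

    def test_ratio_is_three_halves(self, default_lamellar_profile):
        res = saxs.find_harmonic_peaks(
            saxs.kratky_transform(default_lamellar_profile))
        assert res.ratio_2nd_3rd == pytest.approx(1.50, abs=0.01)

    def test_order_assignment_consistency(self, default_lamellar_profile):
        res = saxs.find_harmonic_peaks(
            saxs.kratky_transform(default_lamellar_profile))
        orders = [n for n, _ in res.peak_positions_q]
        assert orders == [1, 2, 3, 4, 5]
        q1 = res.peak_positions_q[0][1]
        for n, qn in res.peak_positions_q:
            assert abs(qn / (n * q1) - 1.0) < 1e-3

    def test_single_peak_profile(self):
        q = np.linspace(0.02, 2.0, 2000)
        qc = 2 * np.pi / 10.0
        i = np.exp(-0.5 * ((q - qc) / 0.02) ** 2)
        prof = Profile1D(q, q**2 * i, kind="q", wavelength=0.0709,
                         meta={"representation": "kratky"})
        res = saxs.find_harmonic_peaks(prof)
        assert res.lp_1st == pytest.approx(10.0, abs=0.05)
        assert res.lp_2nd is None and res.lp_3rd is None

    def test_no_peaks_rejected(self):
        q = np.linspace(0.02, 2.0, 500)
        prof = Profile1D(q, np.full_like(q, 2.0), kind="q", wavelength=0.0709)
        with pytest.raises(ValueError, match="no harmonic peaks"):
            saxs.find_harmonic_peaks(prof)


class TestCorrelationFunction:
    def test_invariant_is_maximum(self, default_lamellar_profile):
        corr = saxs.correlation_function(default_lamellar_profile)
        assert corr.Q == pytest.approx(float(np.max(corr.K)))

    def test_long_period_against_real_space_oracle(self,
                                                   default_lamellar_profile):
        corr = saxs.correlation_function(default_lamellar_profile)
        lag, ac = square_wave_autocorrelation(38.5, 15.7 / 38.5)
        pk, _ = find_peaks(ac, prominence=0.002 * ac[0])
        lp_oracle = lag[pk[0]]
        assert abs(corr.Lp - lp_oracle) / lp_oracle < 0.02

    @pytest.mark.parametrize("phi", [0.3, 0.41, 0.5])
    def test_oracle_equivalence_across_fractions(self, phi):
        prof = synthgen.generate_saxs_meridional(synthgen.LamellarModelParams(
            long_period=38.5, phase1_fraction=phi, n_orders=8,
            peak_width_sigma=0.008))
        corr = saxs.correlation_function(prof)
        lag, ac = square_wave_autocorrelation(38.5, phi)
        pk, _ = find_peaks(ac, prominence=0.002 * ac[0])
        assert abs(corr.Lp - lag[pk[0]]) / lag[pk[0]] < 0.02
        assert abs(corr.phase1_fraction - phi) < 0.03

    def test_symmetric_lamella_first_zero_at_quarter_period(self):
        prof = synthgen.generate_saxs_meridional(synthgen.LamellarModelParams(
            long_period=38.5, phase1_fraction=0.5, n_orders=8,
            peak_width_sigma=0.008))
        corr = saxs.correlation_function(prof)
        iz = np.nonzero(corr.K < 0)[0][0]
        z0 = float(np.interp(0.0, [corr.K[iz], corr.K[iz - 1]],
                             [corr.z[iz], corr.z[iz - 1]]))
        assert z0 == pytest.approx(corr.Lp / 4.0, rel=0.02)

    def test_study_geometry_decomposition(self, default_lamellar_profile):
        # printed decomposition: Lp 38.2, d_pI 12.5, <d_pI> 15.7
        corr = saxs.correlation_function(default_lamellar_profile)
        assert corr.Lp == pytest.approx(38.2, abs=0.5)
        assert corr.d_pI_mean == pytest.approx(15.7, abs=1.0)
        assert corr.d_pI == pytest.approx(12.5, abs=3.0)
        assert 0 < corr.d_pI <= corr.d_pI_mean < corr.Lp
        assert corr.phase2_thickness == pytest.approx(22.8, abs=1.0)

    def test_non_decaying_tail_rejected(self):
        q = np.linspace(0.02, 2.0, 500)
        prof = Profile1D(q, np.full_like(q, 5.0), kind="q", wavelength=0.0709)
        with pytest.raises(ValueError, match="decayed"):
            saxs.correlation_function(prof)


class TestLongPeriodStrain:
    def test_full_run_printed_values(self):
        strain = saxs.long_period_strain([37.5, 44.7])
        assert round(float(strain[1]), 1) == 19.2

    def test_stage_one_printed_values(self):
        strain = saxs.long_period_strain([37.5, 38.1])
        assert round(float(strain[1]), 1) == 1.6

    def test_constant_series_zero(self):
        np.testing.assert_array_equal(saxs.long_period_strain([38.0] * 5),
                                      np.zeros(5))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            saxs.long_period_strain([0.0, 38.0])


class TestScherrer:
    def test_recovery_of_generating_bundle(self):
        prof = synthgen.generate_saxs_equatorial(
            bundle_thickness=150.0, fibril_spacing=4.7,
            instrumental_fwhm=0.005)
        center, fwhm = saxs.fit_equatorial_peak(prof)
        res = saxs.scherrer_thickness(center, fwhm, 0.005, prof.wavelength)
        assert res.d == pytest.approx(150.0, abs=7.0)

    def test_zero_instrumental_width_limit(self):
        res = saxs.scherrer_thickness(1.34, 0.04, 0.0, 0.15418)
        assert res.beta == pytest.approx(res.beta_obs)

    def test_doubling_size_halves_corrected_width(self):
        widths = []
        for d in (100.0, 200.0):
            prof = synthgen.generate_saxs_equatorial(bundle_thickness=d,
                                                     instrumental_fwhm=0.002)
            center, fwhm = saxs.fit_equatorial_peak(prof)
            widths.append(
                saxs.scherrer_thickness(center, fwhm, 0.002,
                                        prof.wavelength).beta)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.01)

    @pytest.mark.parametrize("true_size", [50.0, 100.0, 200.0, 300.0])
    def test_size_sweep_recovery(self, true_size):
        size_fwhm = 2 * np.pi * 0.9 / true_size
        instr = 0.5 * size_fwhm
        prof = synthgen.generate_saxs_equatorial(bundle_thickness=true_size,
                                                 instrumental_fwhm=instr)
        center, fwhm = saxs.fit_equatorial_peak(prof)
        res = saxs.scherrer_thickness(center, fwhm, instr, prof.wavelength)
        assert abs(res.d - true_size) / true_size < 0.05

    def test_unresolvable_size_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            saxs.scherrer_thickness(1.34, 0.01, 0.02, 0.15418)


class TestDeformationSeries:
    @staticmethod
    def _experiment():
        from silkstruct.pipeline import (
            DEFAULT_DEFORMATION_CONFIG,
            _synthesize_deformation_experiment,
        )

        return _synthesize_deformation_experiment(DEFAULT_DEFORMATION_CONFIG)

    def test_stage_boundaries_match_generator(self):
        frames, log, params = self._experiment()
        series = saxs.assemble_deformation_series(frames, log)
        frame_step_pct = 100.0 * 9.0 * (10.0 / 1000.0) / 15.0  # 0.6 %/frame
        assert series.yield_strain_percent == pytest.approx(
            100 * params.yield_strain, abs=frame_step_pct)
        assert series.fracture_strain_percent == pytest.approx(
            100 * params.fracture_strain, abs=frame_step_pct)

    def test_strains_computed_against_frame_zero(self):
        frames, log, _ = self._experiment()
        series = saxs.assemble_deformation_series(frames, log)
        f = series.frames
        assert f["crystal_strain"].iloc[0] == 0.0
        assert f["lp_strain"].iloc[0] == 0.0
        assert f["lp_strain"].iloc[-1] == pytest.approx(19.2, abs=0.2)
        assert f["crystal_strain"].iloc[-1] == pytest.approx(1.42, abs=0.05)

    def test_harmonic_ratio_constant(self):
        frames, log, _ = self._experiment()
        series = saxs.assemble_deformation_series(frames, log)
        np.testing.assert_allclose(series.frames["lp_ratio_2nd_3rd"], 1.5,
                                   atol=0.02)

    def test_single_frame_input(self):
        frames = pd.DataFrame({"time": [0.0], "d002": [3.52],
                               "orientation_index": [0.9], "lp_2nd": [18.75],
                               "lp_3rd": [12.5]})
        log = pd.DataFrame({"time": [0.0, 1.0], "strain_percent": [0.0, 0.1],
                            "stress_gpa": [0.0, 0.01]})
        series = saxs.assemble_deformation_series(frames, log)
        assert len(series.frames) == 1
        assert series.frames["crystal_strain"].iloc[0] == 0.0
        assert series.frames["lp_strain"].iloc[0] == 0.0

    def test_misaligned_clock_rejected(self):
        frames = pd.DataFrame({"time": [0.0, 500.0], "d002": [3.52, 3.53],
                               "orientation_index": [0.9, 0.9],
                               "lp_2nd": [18.75, 18.8],
                               "lp_3rd": [12.5, 12.53]})
        log = pd.DataFrame({"time": [0.0, 9.0], "strain_percent": [0.0, 0.6],
                            "stress_gpa": [0.0, 0.1]})
        with pytest.raises(ValueError, match="misaligned"):
            saxs.assemble_deformation_series(frames, log)


class TestPhaseClosure:
    def test_complementary_thickness(self):
        assert saxs.complementary_phase_thickness(38.5, 15.7) == pytest.approx(
            22.8)

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError):
            saxs.complementary_phase_thickness(38.5, 40.0)
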