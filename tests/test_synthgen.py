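import numpy as np
import pytest

from silkstruct import synthgen
from silkstruct.mechanics import tensile_properties


class TestSaxsMeridional:
    def test_peak_positions_harmonic(self, default_lamellar_profile):
        # q_n = 2πn/L_p computed by hand: 0.16320·n for L_p = 38.5 nm
        truth = default_lamellar_profile.meta["truth"]
        qn = np.array(truth["peak_positions_q"])
        np.testing.assert_allclose(qn, 2 * np.pi / 38.5 * np.arange(1, 6),
                                   rtol=1e-12)
        assert qn[0] == pytest.approx(0.1632, abs=1e-4)
        # harmonicity of the recorded positions
        np.testing.assert_allclose(qn / qn[0], np.arange(1, 6), rtol=1e-9)

    def test_argmax_scan_recovers_positions(self, default_lamellar_profile):
        # independent oracle: local argmax scan near each truth position
        q = default_lamellar_profile.abscissa
        i = default_lamellar_profile.intensity
        for qc in default_lamellar_profile.meta["truth"]["peak_positions_q"]:
            window = (q > qc - 0.05) & (q < qc + 0.05)
            q_found = q[window][np.argmax(i[window])]
            assert abs(q_found - qc) / qc < 0.005

    def test_even_orders_suppressed_for_symmetric_lamella(self):
        params = synthgen.LamellarModelParams(
            long_period=20.0, phase1_fraction=0.5, n_orders=2)
        prof = synthgen.generate_saxs_meridional(params)
        assert prof.meta["truth"]["suppressed_orders"] == [2]
        q2 = prof.meta["truth"]["peak_positions_q"][1]
        near_q2 = np.abs(prof.abscissa - q2) < 0.02
        assert np.max(prof.intensity[near_q2]) < 1e-12

    def test_paper_like_phase_geometry(self, default_lamellar_profile):
        truth = default_lamellar_profile.meta["truth"]
        assert truth["phase1_thickness_nm"] == pytest.approx(15.7)
        assert truth["phase2_thickness_nm"] == pytest.approx(22.8)

    def test_seed_reproducible_and_truth_seed_free(self):
        kw = dict(long_period=30.0, phase1_fraction=0.4, n_orders=3,
                  noise="poisson", mean_counts=500.0)
        a = synthgen.generate_saxs_meridional(
            synthgen.LamellarModelParams(seed=7, **kw))
        b = synthgen.generate_saxs_meridional(
            synthgen.LamellarModelParams(seed=7, **kw))
        c = synthgen.generate_saxs_meridional(
            synthgen.LamellarModelParams(seed=8, **kw))
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)
        assert a.meta["truth"] == c.meta["truth"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            synthgen.LamellarModelParams(phase1_fraction=1.2)
        with pytest.raises(ValueError):
            synthgen.LamellarModelParams(long_period=-1.0)
        with pytest.raises(ValueError):
            synthgen.LamellarModelParams(n_orders=9)


class TestSaxsEquatorial:
    def test_peak_position(self):
        prof = synthgen.generate_saxs_equatorial(fibril_spacing=4.7)
        assert prof.meta["truth"]["peak_position_q"] == pytest.approx(
            2 * np.pi / 4.7)  # 1.3368 nm^-1
        assert prof.meta["truth"]["peak_position_q"] == pytest.approx(
            1.3368, abs=1e-3)

    def test_infinite_bundle_delta_limit(self):
        prof = synthgen.generate_saxs_equatorial(
            bundle_thickness=np.inf, instrumental_fwhm=0.0)
        assert prof.meta["truth"]["observed_fwhm_q"] == 0.0
        # numerically the peak must be much narrower than a finite bundle's
        finite = synthgen.generate_saxs_equatorial(bundle_thickness=150.0)
        half = lambda p: np.sum(
            p.intensity > 0.5 * np.max(p.intensity)) * np.diff(p.abscissa)[0]
        assert half(prof) < half(finite)

    def test_zero_wavelength_rejected(self):
        with pytest.raises(ValueError, match="wavelength"):
            synthgen.generate_saxs_equatorial(wavelength=0.0)

    def test_bundle_thinner_than_spacing_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_saxs_equatorial(bundle_thickness=2.0,
                                              fibril_spacing=4.7)


class TestWaxdProfile:
    def test_equal_areas_give_half_crystallinity(self):
        params = synthgen.WaxdModelParams(
            crystalline_peaks=[synthgen.WaxdPeak(18.9, 0.5, 5.0, "200")],
            amorphous_peak=synthgen.WaxdPeak(20.6, 3.0, 5.0, "amorphous",
                                             chi=None),
        )
        assert params.crystallinity_true == pytest.approx(0.5)

    def test_zero_crystalline_area(self):
        params = synthgen.WaxdModelParams(
            crystalline_peaks=[],
            amorphous_peak=synthgen.WaxdPeak(20.6, 3.0, 5.0, "amorphous",
                                             chi=None),
        )
        assert params.crystallinity_true == 0.0

    def test_requested_crystallinity_exact_by_construction(self):
        params = synthgen.default_waxd_params(crystallinity_true=0.37)
        prof = synthgen.generate_waxd_profile(params)
        truth = prof.meta["truth"]
        ac, aa = truth["crystalline_area"], truth["amorphous_area"]
        assert ac / (ac + aa) == pytest.approx(0.37, rel=1e-12)

    def test_direct_integration_oracle(self, default_waxd_profile):
        # independent oracle: numeric integration of the profile above
        # background equals the summed generating areas within 0.5%
        truth = default_waxd_profile.meta["truth"]
        total_area = np.trapezoid(
            default_waxd_profile.intensity - truth["background_level"],
            default_waxd_profile.abscissa)
        expected = truth["crystalline_area"] + truth["amorphous_area"]
        assert total_area == pytest.approx(expected, rel=0.005)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            synthgen.WaxdModelParams(
                crystalline_peaks=[synthgen.WaxdPeak(18.9, 0.5, -1.0)],
                amorphous_peak=synthgen.WaxdPeak(20.6, 3.0, 5.0, chi=None),
            )

    def test_peak_outside_window_rejected(self):
        params = synthgen.WaxdModelParams(
            crystalline_peaks=[synthgen.WaxdPeak(5.0, 0.5, 1.0, "bad")],
            amorphous_peak=synthgen.WaxdPeak(20.6, 3.0, 5.0, chi=None),
        )
        with pytest.raises(ValueError, match="window"):
            synthgen.generate_waxd_profile(params)


class TestFiberDiagram:
    def test_beam_center_outside_image_rejected(self, small_diagram_kwargs):
        params = synthgen.default_waxd_params()
        with pytest.raises(ValueError, match="beam center"):
            synthgen.generate_fiber_diagram(params, image_shape=(64, 64),
                                            beam_center=(100, 100))

    def test_truth_records_orientation(self, small_diagram_kwargs):
        params = synthgen.default_waxd_params(orientation_fwhm=18.0)
        diagram = synthgen.generate_fiber_diagram(params,
                                                  **small_diagram_kwargs)
        assert diagram.meta["truth"]["orientation_index"] == pytest.approx(0.9)


class TestStressStrain:
    def test_table_like_ground_truth(self):
        # modulus 28.1 GPa, fracture strain 0.32; hardening chosen so the
        # recorded strength is the generating stress at fracture
        params = synthgen.TensileModelParams(
            modulus=28.1, yield_strain=0.033, hardening_slope=3.75,
            fracture_strain=0.32)
        curve = synthgen.generate_stress_strain(params)
        truth = curve.meta["truth"]
        assert truth["modulus_gpa"] == pytest.approx(28.1)
        assert truth["extensibility"] == pytest.approx(0.32)
        assert truth["strength_gpa"] == pytest.approx(
            28.1 * 0.033 + 3.75 * (0.32 - 0.033))

    def test_pure_elastic_toughness_closed_form(self):
        params = synthgen.TensileModelParams(
            modulus=10.0, yield_strain=0.1, hardening_slope=0.0,
            fracture_strain=0.1)
        curve = synthgen.generate_stress_strain(params)
        # toughness = E·ε²/2 = 10·0.01/2 GPa = 50 MJ/m³
        assert curve.meta["truth"]["toughness_mj_m3"] == pytest.approx(50.0)

    def test_toughness_matches_trapezoid_oracle(self):
        params = synthgen.TensileModelParams(
            modulus=17.0, yield_strain=0.04, hardening_slope=6.0,
            fracture_strain=0.25)
        curve = synthgen.generate_stress_strain(params)
        oracle = np.trapezoid(curve.stress, curve.strain) * 1000.0
        assert curve.meta["truth"]["toughness_mj_m3"] == pytest.approx(
            oracle, rel=1e-9)

    def test_noise_seeded(self):
        kw = dict(noise_sd=0.05)
        a = synthgen.generate_stress_strain(
            synthgen.TensileModelParams(seed=3, **kw))
        b = synthgen.generate_stress_strain(
            synthgen.TensileModelParams(seed=3, **kw))
        np.testing.assert_array_equal(a.stress, b.stress)

    def test_invalid_yield_rejected(self):
        with pytest.raises(ValueError):
            synthgen.TensileModelParams(yield_strain=0.5, fracture_strain=0.3)


class TestSequences:
    def test_default_architecture(self):
        params = synthgen.SequenceModelParams()
        assert params.motif_length == 160
        records, ann = synthgen.generate_sequences(params)
        seq = str(records[0].seq)
        assert len(seq) == 800
        assert ann["n_motifs"] == 5
        for m in ann["motifs"]:
            s, e = m["pab_span"]
            assert seq[s - 1:e] == "A" * 22

    def test_single_motif_single_run(self):
        params = synthgen.SequenceModelParams(n_motifs=1)
        records, ann = synthgen.generate_sequences(params)
        seq = str(records[0].seq)
        import re

        runs = [m.group() for m in re.finditer("A{10,}", seq)]
        assert len(runs) == 1 and len(runs[0]) == 22

    def test_gly_ala_fraction_near_80_percent(self):
        records, _ = synthgen.generate_sequences(
            synthgen.SequenceModelParams(n_motifs=20, seed=11))
        seq = str(records[0].seq)
        frac = sum(1 for ch in seq if ch in "GA") / len(seq)
        assert frac == pytest.approx(0.80, abs=0.03)

    def test_reproducible(self):
        a, _ = synthgen.generate_sequences(synthgen.SequenceModelParams(seed=5))
        b, _ = synthgen.generate_sequences(synthgen.SequenceModelParams(seed=5))
        assert str(a[0].seq) == str(b[0].seq)

    def test_rejects_zero_motifs(self):
        with pytest.raises(ValueError, match="n_motifs"):
            synthgen.SequenceModelParams(n_motifs=0)
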