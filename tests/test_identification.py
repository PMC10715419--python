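import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uremia_omics import (
    MS2Spectrum,
    adduct_mz,
    match_feature_to_standard,
    monoisotopic_mass,
    ppm_error,
    spectral_similarity,
)
from uremia_omics.spectra_io import (
    read_spectra_mgf,
    read_standards_msp,
    write_spectra_mgf,
    write_standards_msp,
)
from uremia_omics.synthetic_data import synthetic_spectrum


class TestMass:
    def test_water(self):
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=1e-6)

    def test_creatinine(self):
        assert monoisotopic_mass("C4H7N3O") == pytest.approx(113.058912, abs=1e-5)

    def test_empty_formula_is_zero(self):
        assert monoisotopic_mass("") == 0.0

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("Xx2H4")

    def test_protonated_creatinine(self):
        assert adduct_mz(monoisotopic_mass("C4H7N3O"), "[M+H]+") == pytest.approx(
            114.066188, abs=1e-5)

    def test_deprotonated_taurine(self):
        assert adduct_mz(monoisotopic_mass("C2H7NO3S"), "[M-H]-") == pytest.approx(
            124.007388, abs=1e-5)

    def test_zero_mass_gives_bare_proton(self):
        assert adduct_mz(0.0, "[M+H]+") == pytest.approx(1.007276, abs=1e-6)
        assert adduct_mz(0.0, "[M-H]-") == pytest.approx(-1.007276, abs=1e-6)

    def test_unsupported_adduct_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(100.0, "[M+Na]+")


class TestPpm:
    def test_equal_masses_zero_ppm(self):
        assert ppm_error(100.0, 100.0) == 0.0

    def test_one_ppm_example(self):
        assert ppm_error(100.0001, 100.0) == pytest.approx(1.0)

    def test_taurine_printed_mz_within_negative_tolerance(self):
        theo = adduct_mz(monoisotopic_mass("C2H7NO3S"), "[M-H]-")
        assert ppm_error(124.00748, theo) == pytest.approx(0.745, abs=0.01)
        assert ppm_error(124.00748, theo) <= 2.0

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=50, max_value=1000),
           st.floats(min_value=50, max_value=1000),
           st.floats(min_value=0.1, max_value=100))
    def test_scale_free(self, a, b, k):
        assert ppm_error(k * a, k * b) == pytest.approx(ppm_error(a, b), rel=1e-9)


def _spec(mz, intensities, precursor=500.0, mode="positive"):
    return MS2Spectrum(precursor_mz=precursor, mode=mode,
                       mz=np.asarray(mz, float),
                       intensities=np.asarray(intensities, float))


class TestSpectralSimilarity:
    def test_self_match_is_one(self):
        s = synthetic_spectrum("anything", 400.0, "positive")
        assert spectral_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_fragments_score_zero(self):
        a = _spec([100, 200, 300], [1, 1, 1])
        b = _spec([150, 250, 350], [1, 1, 1])
        assert spectral_similarity(a, b) == 0.0

    def test_half_the_unit_peaks_gives_inverse_sqrt_two(self):
        # 2k unit peaks vs the first k of them: cosine = k / (sqrt(2k) sqrt(k))
        mz = np.arange(100, 100 + 10 * 10, 10, dtype=float)
        full = _spec(mz, np.ones(10))
        half = _spec(mz[:5], np.ones(5))
        assert spectral_similarity(full, half) == pytest.approx(1 / np.sqrt(2))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=100.0))
    def test_symmetric_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = _spec(np.sort(rng.uniform(100, 900, 8)), rng.uniform(0.1, 1, 8))
        b = _spec(np.sort(rng.uniform(100, 900, 8)), rng.uniform(0.1, 1, 8))
        ab = spectral_similarity(a, b)
        assert spectral_similarity(b, a) == pytest.approx(ab)
        scaled = _spec(a.mz, a.intensities * scale)
        assert spectral_similarity(scaled, b) == pytest.approx(ab)

    def test_matches_independent_cosine_on_well_separated_peaks(self):
        # cross-check against matchms' greedy cosine with sqrt intensities
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(42)
        for _ in range(5):
            mza = np.sort(rng.choice(np.arange(100, 900, 5.0), 10, replace=False))
            mzb = np.sort(rng.choice(np.arange(100, 900, 5.0), 10, replace=False))
            ia = rng.uniform(0.1, 1, 10)
            ib = rng.uniform(0.1, 1, 10)
            mine = spectral_similarity(_spec(mza, ia), _spec(mzb, ib), frag_tol=0.05)
            ref = CosineGreedy(tolerance=0.05).pair(
                Spectrum(mz=mza, intensities=np.sqrt(ia),
                         metadata={"precursor_mz": 500.0}),
                Spectrum(mz=mzb, intensities=np.sqrt(ib),
                         metadata={"precursor_mz": 500.0}),
            )
            assert mine == pytest.approx(float(ref["score"]), abs=1e-9)


class TestMatching:
    def test_unperturbed_self_match_confirms(self, library):
        std = next(s for s in library if s.name == "Creatinine")
        m = match_feature_to_standard(
            "f1", std.theoretical_mz, std.rt, std.mode, std.spectrum, std)
        assert m.confirmed and m.mass_ok and m.rt_ok and m.ms2_ok
        assert m.ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_rt_shift_beyond_window_blocks_confirmation(self, library):
        std = next(s for s in library if s.name == "Creatinine")
        m = match_feature_to_standard(
            "f1", std.theoretical_mz, std.rt + 5.0, std.mode, std.spectrum, std,
            rt_window=2.0)
        assert not m.rt_ok and not m.confirmed
        assert m.mass_ok and m.ms2_ok

    def test_polarity_mismatch_rejected(self, library):
        std = next(s for s in library if s.name == "Taurine")  # negative mode
        with pytest.raises(ValueError, match="polarity"):
            match_feature_to_standard(
                "f1", std.theoretical_mz, std.rt, "positive", std.spectrum, std)

    def test_loosening_tolerances_never_unconfirms(self, library):
        std = next(s for s in library if s.name == "L-Leucine")
        feature_mz = std.theoretical_mz * (1 + 0.8e-6)  # 0.8 ppm off
        base = dict(rt_window=1.0, ppm_tol_pos=1.0, score_min=0.7)
        m0 = match_feature_to_standard(
            "f1", feature_mz, std.rt + 0.5, std.mode, std.spectrum, std, **base)
        assert m0.confirmed
        for loosened in (dict(base, rt_window=5.0), dict(base, ppm_tol_pos=5.0),
                         dict(base, score_min=0.1)):
            m = match_feature_to_standard(
                "f1", feature_mz, std.rt + 0.5, std.mode, std.spectrum, std,
                **loosened)
            assert m.confirmed

    def test_missing_ms2_needs_escape_hatch(self, library):
        std = next(s for s in library if s.name == "Caffeine")
        m = match_feature_to_standard(
            "f1", std.theoretical_mz, std.rt, std.mode, None, std)
        assert not m.confirmed
        m = match_feature_to_standard(
            "f1", std.theoretical_mz, std.rt, std.mode, None, std,
            allow_no_ms2=True)
        assert m.confirmed and m.ms2_score is None


class TestSpectraIO:
    def test_msp_library_round_trip(self, library, tmp_path):
        path = tmp_path / "standards.msp"
        write_standards_msp(library, path)
        back = read_standards_msp(path)
        assert [s.name for s in back] == [s.name for s in library]
        for a, b in zip(library, back):
            assert a.formula == b.formula and a.adduct == b.adduct
            assert b.observed_mz == pytest.approx(a.observed_mz)
            assert b.rt == pytest.approx(a.rt)
            np.testing.assert_allclose(b.spectrum.mz, a.spectrum.mz, atol=1e-6)

    def test_mgf_round_trip(self, tmp_path):
        spectra = {f"F{i}": synthetic_spectrum(f"F{i}", 300.0 + i, "positive")
                   for i in range(3)}
        path = tmp_path / "features.mgf"
        write_spectra_mgf(spectra, path)
        back = read_spectra_mgf(path)
        assert set(back) == set(spectra)
        for k in spectra:
            np.testing.assert_allclose(back[k].mz, spectra[k].mz, atol=1e-6)
            assert back[k].precursor_mz == pytest.approx(spectra[k].precursor_mz)
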