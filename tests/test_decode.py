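"""Decoding-pipeline tests: transform, axes, calibration, peak picking,
harmonics, and slices.  Cubes are built with the forward simulator at
desk scale (64-256 indices) so every expected quantity has a bookkeeping
oracle."""

import numpy as np
import pytest

from swim2d.config import InstrumentConfig
from swim2d.decode import (
    MZ_BAND,
    Spectrum2D,
    autocorrelation_spectrum,
    detect_autocorrelation_peaks,
    first_pass_axis,
    flag_harmonics,
    pick_peaks,
    recalibrate,
    slice_horizontal,
    slice_vertical,
    transform_cube,
)
from swim2d.forward_sim import (
    DataCube,
    FragChannel,
    IonSpecies,
    SimulationConfig,
    generate_cube,
)
from swim2d.secular import calibration_k0, calibration_k1, encoding_from_mz

from conftest import quiet_sim


def _synthetic_cube(cfg, traces, product_axis):
    """Cube assembled directly from per-column index traces (decode-only
    oracle input, bypassing the forward simulator)."""
    n = cfg.n_indices
    mat = np.zeros((n, len(product_axis)))
    for col, trace in traces.items():
        mat[:, col] = trace
    return DataCube(intensities=mat, product_axis=np.asarray(product_axis),
                    instrument=cfg, sim=None)


@pytest.fixture(scope="module")
def cfg64():
    return InstrumentConfig(dac_rate=2.5e6, pulse_duration=2e-3, T=0.8e-4,
                            n_indices=64)


@pytest.fixture(scope="module")
def cfg256():
    return InstrumentConfig(dac_rate=2.5e6, pulse_duration=2e-3, T=0.8e-4,
                            n_indices=256)


class TestTransform:
    def test_zero_fill_row_bookkeeping(self, cfg64):
        """N-index cube: zero-fill once -> 2N-point transform; the N real
        non-negative-frequency rows are retained, spaced 1/(2N)."""
        cube = _synthetic_cube(cfg64, {0: np.ones(64)}, [100.0, 101.0])
        spec = transform_cube(cube)
        assert spec.n_rows == 64
        assert spec.fe_axis[1] - spec.fe_axis[0] == pytest.approx(1.0 / 128)
        assert spec.fe_axis[0] == 0.0

    def test_constant_cube_is_silent_after_mean_subtraction(self, cfg64):
        cube = _synthetic_cube(cfg64, {0: np.full(64, 7.0)}, [100.0, 101.0])
        spec = transform_cube(cube)
        assert np.all(spec.magnitude < 1e-10)

    def test_pure_cosine_lands_on_its_row(self, cfg64):
        n = np.arange(64)
        cube = _synthetic_cube(
            cfg64, {1: 1.0 + 0.5 * np.cos(2 * np.pi * 0.25 * n)},
            [100.0, 101.0, 102.0])
        spec = transform_cube(cube)
        row = np.argmax(spec.magnitude[:, 1])
        assert spec.fe_axis[row] == pytest.approx(0.25)
        assert spec.magnitude[:, 0].max() < 1e-10

    def test_non_finite_rejected(self, cfg64):
        cube = _synthetic_cube(cfg64, {0: np.ones(64)}, [100.0])
        cube.intensities[3, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            transform_cube(cube)

    def test_hann_window_option(self, cfg64):
        n = np.arange(64)
        cube = _synthetic_cube(
            cfg64, {0: 1 + np.cos(2 * np.pi * 0.2 * n)}, [100.0])
        rect = transform_cube(cube)
        hann = transform_cube(cube, window="hann")
        # apodization widens the main lobe and lowers the peak
        assert hann.magnitude.max() < rect.magnitude.max()

    def test_magnitude_invariant_under_index_shift(self, cfg64):
        """Phase information is discarded: circularly shifting the cube in
        the index direction leaves the magnitude unchanged (< 1%) on the
        true DFT rows.  (Odd, zero-fill-interpolated rows mix the shifted
        edge and are not shift-invariant.)"""
        n = np.arange(64)
        fe = 10 / 64  # commensurate with the window
        trace = 1 + 0.4 * np.cos(2 * np.pi * fe * n + 0.3)
        a = transform_cube(_synthetic_cube(cfg64, {0: trace}, [100.0]))
        b = transform_cube(_synthetic_cube(cfg64, {0: np.roll(trace, 17)}, [100.0]))
        top = a.magnitude.max()
        even = np.arange(0, 64, 2)
        assert np.abs(a.magnitude[even] - b.magnitude[even]).max() < 0.01 * top


class TestFirstPassAxis:
    def test_reciprocal_inversion_roundtrip(self, cfg64):
        cube = _synthetic_cube(cfg64, {0: np.ones(64)}, [100.0])
        spec = first_pass_axis(transform_cube(cube), method="eq5")
        k0, k1 = calibration_k0(cfg64), calibration_k1(cfg64)
        ok = np.isfinite(spec.precursor_axis)
        np.testing.assert_allclose(
            spec.precursor_axis[ok], k1 / (spec.fe_axis[ok] + k0), rtol=1e-12)

    def test_row_zero_gets_sentinel(self, cfg64):
        cube = _synthetic_cube(cfg64, {0: np.ones(64)}, [100.0])
        for method in ("eq5", "eq6"):
            spec = first_pass_axis(transform_cube(cube), method=method)
            assert np.isnan(spec.precursor_axis[0])  # maps above m/z 4500
            assert len(spec.precursor_axis) == spec.n_rows  # never dropped

    def test_axis_monotone_decreasing_both_methods(self, cfg64):
        cube = _synthetic_cube(cfg64, {0: np.ones(64)}, [100.0])
        for method in ("eq5", "eq6"):
            spec = first_pass_axis(transform_cube(cube), method=method)
            ax = spec.first_pass
            assert np.all(np.diff(ax) < 0)

    def test_methods_diverge_at_low_mass(self, cfg256):
        """The adiabatic (eq5) and high-q (eq6) axes agree at high m/z and
        diverge increasingly below m/z 400."""
        cube = _synthetic_cube(cfg256, {0: np.ones(256)}, [100.0])
        base = transform_cube(cube)
        a5 = first_pass_axis(base, method="eq5").first_pass
        a6 = first_pass_axis(base, method="eq6").first_pass
        rel = np.abs(a5 - a6) / a6
        def rel_at(mz):
            return rel[np.nanargmin(np.abs(a6 - mz))]
        assert rel_at(200) > rel_at(400) > rel_at(1000)
        assert rel_at(2000) < 1e-3


class TestAutocorrelationAndCalibration:
    def test_one_diagonal_peak_per_isotopologue(self, cfg256):
        """Noiseless, fragmentation-free species: the only 2D peaks are the
        isotopologue precursors, each sitting on the autocorrelation line."""
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                        product_axis=(440.0, 460.0, 2000))
        sp = IonSpecies.with_isotopes(450.0, 3, 1.0, (0.6, 0.3, 0.1))
        cube = generate_cube([sp], cfg256, sim)
        spec = first_pass_axis(transform_cube(cube))
        pairs = detect_autocorrelation_peaks(spec)
        assert len(pairs) == 3
        for fe, pmz in pairs:
            assert min(abs(pmz - (450.0 + k * 1.003355 / 3)) for k in range(3)) < 0.02

    def test_fragmentation_free_mixture_all_on_diagonal(self, cfg256):
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                        product_axis=(150.0, 1300.0, 4000))
        species = [IonSpecies(mz=m, z=1) for m in (300.0, 622.0, 922.0, 1222.0)]
        cube = generate_cube(species, cfg256, sim)
        spec = first_pass_axis(transform_cube(cube))
        peaks = [p for p in pick_peaks(spec)
                 if np.isfinite(p.precursor_mz)]
        flag_harmonics(peaks, spec.fe_axis[1] - spec.fe_axis[0])
        fundamentals = [p for p in peaks if p.harmonic_order == 1]
        assert len(fundamentals) == 4
        assert all(p.on_autocorrelation for p in fundamentals)

    def test_zero_tolerance_fails_calibration(self, cfg256):
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                        product_axis=(440.0, 460.0, 1000))
        cube = generate_cube([IonSpecies(mz=450.0, z=3)], cfg256, sim)
        spec = first_pass_axis(transform_cube(cube))
        with pytest.raises(ValueError, match="calibration impossible"):
            detect_autocorrelation_peaks(spec, tol_ppm=0.0)

    def test_recalibration_centres_species_within_one_bin(self, cfg256):
        """End-to-end: simulate known species, decode, recalibrate from the
        diagonal; every centroided precursor lands within one precursor bin
        of truth."""
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                        product_axis=(150.0, 1300.0, 4000))
        mzs = (300.0, 622.0, 922.0, 1222.0)
        cube = generate_cube([IonSpecies(mz=m, z=1) for m in mzs], cfg256, sim)
        spec = first_pass_axis(transform_cube(cube))
        pairs = detect_autocorrelation_peaks(spec)
        spec = recalibrate(spec, pairs, order=1)
        # centroid scatter (sidelobe skew) leaves ~0.1%-scale residuals
        assert spec.calibration.residual_rms < 3.0
        peaks = [p for p in pick_peaks(spec) if p.on_autocorrelation]
        for m in mzs:
            best = min(peaks, key=lambda p: abs(p.product_mz - m))
            row = spec.row_nearest(m)
            bin_w = abs(spec.precursor_axis[row + 1] - spec.precursor_axis[row])
            assert abs(best.precursor_mz - m) < bin_w

    def test_identity_pairs_leave_axis_unchanged(self, cfg256):
        cube = _synthetic_cube(cfg256, {0: np.ones(256)}, [100.0])
        spec = first_pass_axis(transform_cube(cube))
        fes = [encoding_from_mz(m, cfg256) for m in (300, 600, 900, 1500)]
        pairs = [(fe, calibration_k1(cfg256) / (fe + calibration_k0(cfg256)))
                 for fe in fes]
        recal = recalibrate(spec, pairs, order=1)
        ok = np.isfinite(spec.precursor_axis)
        np.testing.assert_allclose(recal.precursor_axis[ok],
                                   spec.precursor_axis[ok], rtol=1e-9)

    def test_quadratic_beats_linear_on_model_misfit(self, cfg256):
        """Cube generated with the high-q-accurate secular map but first
        passed through the adiabatic axis: a quadratic recalibration
        absorbs the curvature better than a line."""
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                        fs_method="koizumi",
                        product_axis=(150.0, 1300.0, 4000))
        mzs = (180.0, 250.0, 400.0, 700.0, 1222.0)
        cube = generate_cube([IonSpecies(mz=m, z=1) for m in mzs], cfg256, sim)
        spec = first_pass_axis(transform_cube(cube), method="eq5")
        # the adiabatic first pass is off by >10% at the lowest masses, so
        # the diagonal match tolerance must be wide open here
        pairs = detect_autocorrelation_peaks(spec, tol_ppm=2e5)
        lin = recalibrate(spec, pairs, order=1)
        quad = recalibrate(spec, pairs, order=2)
        assert quad.calibration.residual_rms < lin.calibration.residual_rms


class TestPeakPicking:
    def test_expected_peak_count(self, cfg256):
        """Noiseless 3-species, 4-fragments-each cube: exactly 3 precursor
        + 12 fragment fundamental peaks."""
        rng = np.random.default_rng(5)
        species = []
        for m in (350.0, 500.0, 800.0):
            chans = tuple(FragChannel(float(p), 1, "uvpd", 0.1)
                          for p in rng.uniform(160, 330, 4))
            species.append(IonSpecies(mz=m, z=1, channels=chans))
        sim = quiet_sim(v_crit=np.inf, excitation_scale=1.0,
                        product_axis=(150.0, 900.0, 3000))
        cube = generate_cube(species, cfg256, sim)
        spec = first_pass_axis(transform_cube(cube))
        peaks = pick_peaks(spec)
        flag_harmonics(peaks, spec.fe_axis[1] - spec.fe_axis[0])
        fundamentals = [p for p in peaks if p.harmonic_order == 1]
        assert len(fundamentals) == 15

    def test_infinite_threshold_empty(self, cfg64):
        cube = _synthetic_cube(
            cfg64, {0: 1 + np.cos(2 * np.pi * 0.25 * np.arange(64))}, [100.0])
        spec = first_pass_axis(transform_cube(cube))
        assert pick_peaks(spec, snr_threshold=np.inf) == []

    def test_centroid_exact_on_symmetric_peak(self, cfg64):
        """A peak symmetric across rows centroids to its apex exactly in
        the (uniform) frequency coordinate."""
        n = np.arange(64)
        trace = 1 + np.cos(2 * np.pi * (16 / 64) * n)  # exact bin, row 32
        cube = _synthetic_cube(cfg64, {0: trace}, [100.0])
        spec = transform_cube(cube)
        peaks = pick_peaks(first_pass_axis(spec))
        assert peaks[0].fe == pytest.approx(16 / 64, abs=1e-12)

    def test_streak_column_noise_estimate_suppresses_artifacts(self, cfg256):
        """A column with an elevated noise floor (vertical streak under an
        intense precursor) must not sprout spurious peaks: the per-column
        MAD threshold scales with the streak."""
        rng = np.random.default_rng(8)
        n = 256
        quiet_col = 0.01 * rng.standard_normal(n) + 1
        streak_col = 30.0 * np.abs(rng.standard_normal(n)) + 1
        cube = _synthetic_cube(
            InstrumentConfig(dac_rate=2.5e6, pulse_duration=2e-3, T=8e-5,
                             n_indices=256),
            {0: quiet_col, 1: streak_col}, [100.0, 101.0])
        spec = first_pass_axis(transform_cube(cube))
        streak_peaks = [p for p in pick_peaks(spec, snr_threshold=6.0)
                        if p.col == 1]
        assert len(streak_peaks) <= 2


class TestHarmonics:
    def test_mixed_mode_second_harmonic_flagged(self, cfg256):
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0, uvpd_pmax=0.5,
                        product_axis=(440.0, 460.0, 800))
        sp = IonSpecies(mz=450.0, z=3,
                        channels=(FragChannel(445.0, 1, "uvpd", 0.3),))
        cube = generate_cube([sp], cfg256, sim)
        spec = first_pass_axis(transform_cube(cube))
        peaks = pick_peaks(spec)
        flag_harmonics(peaks, spec.fe_axis[1] - spec.fe_axis[0])
        fe = encoding_from_mz(450.0, cfg256)
        col0 = spec.column_nearest(450.0)
        second = [p for p in peaks
                  if abs(p.fe - 2 * fe) < 2 / 256 and abs(p.col - col0) <= 1]
        assert second and all(p.harmonic_order == 2 for p in second)

    def test_pure_tone_all_fundamental(self, cfg64):
        trace = 1 + 0.5 * np.cos(2 * np.pi * 0.125 * np.arange(64))
        cube = _synthetic_cube(cfg64, {0: trace}, [100.0])
        spec = first_pass_axis(transform_cube(cube))
        peaks = pick_peaks(spec)
        flag_harmonics(peaks, spec.fe_axis[1] - spec.fe_axis[0])
        assert all(p.harmonic_order == 1 for p in peaks)

    def test_third_harmonic_of_fundamental_flagged_order_three(self, cfg64):
        n = np.arange(64)
        trace = (1 + 0.6 * np.cos(2 * np.pi * 0.125 * n)
                 + 0.25 * np.cos(2 * np.pi * 0.25 * n)
                 + 0.1 * np.cos(2 * np.pi * 0.375 * n))
        cube = _synthetic_cube(cfg64, {0: trace}, [100.0])
        spec = first_pass_axis(transform_cube(cube))
        # low threshold: the MAD estimate treats leakage tails as noise
        peaks = pick_peaks(spec, snr_threshold=2.0)
        flag_harmonics(peaks, spec.fe_axis[1] - spec.fe_axis[0])

        def order_near(fe):
            return min(peaks, key=lambda p: abs(p.fe - fe)).harmonic_order

        assert order_near(0.125) == 1
        assert order_near(0.25) == 2
        assert order_near(0.375) == 3


@pytest.fixture(scope="module")
def decoded(cfg256):
    sim = quiet_sim(v_crit=0.5, excitation_scale=1.0, uvpd_pmax=0.4,
                    product_axis=(150.0, 1300.0, 4000))
    shared = 195.0
    species = [
        IonSpecies(mz=m, z=z, channels=(
            FragChannel(shared, 1, "uvpd", 0.2),
            FragChannel(um, 1, "uvpd", 0.2)))
        for m, z, um in ((402.0, 3, 380.0), (602.5, 2, 530.0),
                         (1204.0, 1, 880.0))
    ]
    cube = generate_cube(species, cfg256, sim)
    spec = first_pass_axis(transform_cube(cube))
    pairs = detect_autocorrelation_peaks(spec)
    return recalibrate(spec, pairs, order=1), species


class TestSlices:
    def test_horizontal_slice_contains_fragments_and_self(self, decoded):
        spec, species = decoded
        sp = species[0]
        mzs, inten = slice_horizontal(spec, sp.mz, half_width=1)
        def peak_at(m):
            return inten[np.argmin(np.abs(mzs - m))]
        floor = np.median(inten)
        assert peak_at(sp.mz) > 50 * (floor + 1e-12)
        for ch in sp.channels:
            assert peak_at(ch.product_mz) > 50 * (floor + 1e-12)

    def test_slice_between_peaks_is_near_empty(self, cfg256):
        """A slice through a noiseless apodized cube away from the only
        species is empty to leakage precision (the rectangular window's
        1/d tails are the only thing a slice can pick up; Hann kills
        them)."""
        sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                        product_axis=(440.0, 460.0, 500))
        cube = generate_cube([IonSpecies(mz=450.0, z=3)], cfg256, sim)
        spec = first_pass_axis(transform_cube(cube, window="hann"))
        _, inten = slice_horizontal(spec, 900.0)
        assert inten.max() < 0.005 * spec.magnitude.max()

    def test_vertical_slice_precursor_scan_shared_fragment(self, decoded):
        """A fragment shared by three precursors shows three peaks in its
        vertical slice (a precursor scan)."""
        spec, species = decoded
        pre, inten = slice_vertical(spec, 195.0, tol=0.5)
        hits = 0
        for sp in species:
            row = spec.row_nearest(sp.mz)
            window = inten[max(row - 3, 0):row + 4]
            hits += window.max() > 0.05 * inten[np.isfinite(pre)].max()
        assert hits == 3

    def test_vertical_slice_unique_fragment_single_peak(self, decoded):
        spec, species = decoded
        pre, inten = slice_vertical(spec, 380.0, tol=0.5)
        strong_rows = np.nonzero(inten > 0.3 * inten.max())[0]
        rows_of_species = {spec.row_nearest(sp.mz) for sp in species}
        near = {r for r in strong_rows
                if min(abs(r - rs) for rs in rows_of_species) <= 3}
        target = spec.row_nearest(species[0].mz)
        assert near and all(abs(r - target) <= 3 for r in near)

    def test_empty_column_zero(self, decoded):
        spec, _ = decoded
        _, inten = slice_vertical(spec, 1100.0)
        assert np.all(inten < 1e-9 * spec.magnitude.max())

    def test_out_of_axis_errors(self, decoded):
        spec, _ = decoded
        with pytest.raises(ValueError):
            slice_horizontal(spec, 9000.0)
        with pytest.raises(ValueError):
            slice_vertical(spec, 5.0)

    def test_autocorrelation_spectrum_contains_all_species(self, decoded):
        spec, species = decoded
        mzs, diag = autocorrelation_spectrum(spec)
        floor = np.median(diag)
        for sp in species:
            assert diag[np.argmin(np.abs(mzs - sp.mz))] > 20 * (floor + 1e-12)

    def test_heavier_fragmentation_reduces_diagonal_intensity(self, cfg256):
        """Diagonal intensities reflect surviving precursor, not abundance:
        in the flux-periodic regime, raising the fragment yield depletes
        the precursor and lowers its diagonal peak."""
        def diag_height(pmax):
            sim = quiet_sim(v_crit=0.5, excitation_scale=1.0,
                            uvpd_pmax=pmax, product_axis=(150.0, 500.0, 1500))
            sp = IonSpecies(mz=450.0, z=3,
                            channels=(FragChannel(200.0, 1, "uvpd", 1.0),))
            cube = generate_cube([sp], cfg256, sim)
            spec = first_pass_axis(transform_cube(cube))
            _, diag = autocorrelation_spectrum(spec)
            return diag.max()

        assert diag_height(0.8) < diag_height(0.2)

    def test_empty_cube_zero_diagonal(self, cfg64):
        cube = _synthetic_cube(cfg64, {}, [100.0, 200.0, 300.0])
        spec = first_pass_axis(transform_cube(cube))
        _, diag = autocorrelation_spectrum(spec)
        assert np.all(diag == 0.0)

    def test_product_axis_passes_through_unchanged(self, cfg256, decoded):
        spec, _ = decoded
        sim = quiet_sim(product_axis=(440.0, 460.0, 500))
        cube = generate_cube([IonSpecies(mz=450.0, z=3)], cfg256, sim)
        spec2 = first_pass_axis(transform_cube(cube))
        assert np.array_equal(spec2.product_axis, cube.product_axis)
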