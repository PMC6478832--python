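"""Reconstruction core: deconvolution, unmixing, cone recovery, baselines."""

import numpy as np
import pytest

from ssos.optics import (
    GridSpec,
    Spectrum,
    Volume,
    conjugate_symmetry_error,
    fft_volume,
    ifft_spectrum,
    make_otf,
    otf_support,
)
from ssos.recon import (
    PatternNotFoundError,
    ReconOptions,
    combine_spectra,
    deconvolve,
    deconvolved_widefield,
    emulate_from_sim,
    estimate_pattern,
    homodyne_os_sim,
    overlap_mask,
    recover_cone,
    ssos_reconstruct,
    subtract_components,
    widefield_from_pair,
)
from ssos.simulate import (
    NoiseConfig,
    PatternParams,
    add_poisson,
    form_raw_pair,
    three_phase_stack,
)


@pytest.fixture(scope="module")
def band_sample(small_grid, small_otf):
    """Random real sample whose spectrum lies well inside the OTF support."""
    rng = np.random.default_rng(5)
    raw = Volume(rng.random(small_grid.shape), small_grid)
    S = fft_volume(raw).values
    S[np.abs(small_otf.values) < 0.3] = 0.0
    v = ifft_spectrum(Spectrum(S, small_grid)).real
    v = v - v.min() + 0.05 * np.ptp(v)
    return Volume(v, small_grid)


@pytest.fixture(scope="module")
def test_pattern():
    # effective contrast 0.5 from full raw contrast at the anisotropy limit
    return PatternParams(
        freq_px=12, phase_offset=0.7, mod_contrast=0.5, raw_mod=1.0, pol_ratio=3.0
    )


@pytest.fixture(scope="module")
def raw_pair(band_sample, test_pattern, small_psf):
    return form_raw_pair(band_sample, test_pattern, small_psf)


class TestWidefield:
    def test_average_of_equals(self, band_sample):
        i0 = widefield_from_pair(band_sample, band_sample)
        assert np.array_equal(i0.values, band_sample.values)

    def test_linearity(self, raw_pair, small_grid):
        i_p, i_s = raw_pair
        scaled = widefield_from_pair(
            Volume(3.0 * i_p.values, small_grid), Volume(3.0 * i_s.values, small_grid)
        )
        base = widefield_from_pair(i_p, i_s)
        assert np.allclose(scaled.values, 3.0 * base.values, rtol=1e-12)

    def test_pattern_cancels_in_average(self, raw_pair, test_pattern, small_grid):
        """π-shifted exposures sum to a constant, so the widefield average
        carries no component at the pattern frequency."""
        i_p, i_s = raw_pair
        i0 = widefield_from_pair(i_p, i_s)
        spec = np.fft.fft(i0.values, axis=2)
        at_p = np.abs(spec[..., test_pattern.freq_px]).max()
        assert at_p < 1e-9 * np.abs(spec).max()

    def test_grid_mismatch_rejected(self, raw_pair):
        other = GridSpec(shape=(16, 8, 32), voxel_xy=40.0, voxel_z=40.0)
        with pytest.raises(ValueError, match="grid"):
            widefield_from_pair(raw_pair[0], Volume(np.zeros(other.shape), other))


class TestEstimatePattern:
    def test_noise_free_recovery(self, raw_pair, small_otf):
        est = estimate_pattern(*raw_pair, small_otf, ReconOptions(wiener_w=1e-6))
        assert est.freq_px == 12
        assert abs(est.phase_offset - 0.7) < 0.05
        assert abs(est.mod_contrast - 0.5) / 0.5 < 0.10

    def test_recovery_under_shot_noise(self, raw_pair, small_otf, small_grid):
        i_p, i_s = raw_pair
        hits = 0
        for seed in range(20):
            noisy_p = add_poisson(i_p, NoiseConfig(1e4, seed=2 * seed))
            noisy_s = add_poisson(i_s, NoiseConfig(1e4, seed=2 * seed + 1))
            est = estimate_pattern(noisy_p, noisy_s, small_otf)
            hits += est.freq_px == 12
        assert hits >= 18

    def test_unmodulated_input_rejected(self, band_sample, small_psf, small_otf):
        flat = PatternParams(freq_px=12, raw_mod=0.0, pol_ratio=3.0)
        i_p, i_s = form_raw_pair(band_sample, flat, small_psf)
        with pytest.raises(PatternNotFoundError):
            estimate_pattern(i_p, i_s, small_otf)


class TestDeconvolve:
    def test_delta_psf_is_identity(self, small_grid):
        nz, ny, nx = small_grid.shape
        delta = np.zeros(small_grid.shape)
        delta[nz // 2, ny // 2, nx // 2] = 1.0
        H = make_otf(Volume(delta, small_grid))
        img = Volume(np.random.default_rng(2).random(small_grid.shape), small_grid)
        S = deconvolve(img, H, ReconOptions(wiener_w=1e-12))
        assert np.allclose(S.values, fft_volume(img).values, rtol=1e-6, atol=1e-9)

    def test_wiener_round_trip(self, band_sample, small_psf, small_otf):
        from ssos.simulate import convolve_psf

        blurred = convolve_psf(band_sample, small_psf)
        S = deconvolve(blurred, small_otf, ReconOptions(wiener_w=1e-6))
        S_true = fft_volume(band_sample).values
        good = np.abs(small_otf.values) > 10 * 1e-3
        err = np.linalg.norm((S.values - S_true)[good]) / np.linalg.norm(S_true[good])
        assert err < 0.01

    def test_richardson_lucy_flux_and_positivity(self, band_sample, small_psf, small_otf):
        from ssos.simulate import convolve_psf

        blurred = convolve_psf(band_sample, small_psf)
        opts = ReconOptions(deconv_method="richardson_lucy", rl_iterations=10)
        S = deconvolve(blurred, small_otf, opts)
        est = ifft_spectrum(S).real
        assert est.sum() == pytest.approx(blurred.values.sum(), rel=1e-3)
        assert est.min() > -1e-3 * est.max()  # support truncation only


class TestUnmixing:
    def test_zero_sample_gives_zero(self, small_grid, small_psi, test_pattern):
        zero = Spectrum(np.zeros(small_grid.shape, complex), small_grid)
        out = subtract_components(zero, zero, test_pattern, small_psi)
        assert np.all(out.values == 0)

    def test_in_band_sample_leaves_nothing(
        self, small_grid, small_otf, small_psi, small_psf, test_pattern
    ):
        """A sample whose spectrum stays inside Ψ and both its ±p translates
        has no missing-cone content: the subtraction must cancel S1 exactly."""
        p = test_pattern.freq_px
        psi = small_psi.values
        inner = psi & np.roll(psi, p, axis=2) & np.roll(psi, -p, axis=2)
        inner &= np.abs(small_otf.values) > 0.1
        rng = np.random.default_rng(9)
        raw = np.fft.fftshift(np.fft.fftn(rng.random(small_grid.shape)))
        S = np.where(inner, raw, 0)
        v = ifft_spectrum(Spectrum(S, small_grid)).real
        sample = Volume(v - v.min() + 0.1 * np.ptp(v), small_grid)
        i_p, i_s = form_raw_pair(sample, test_pattern, small_psf)
        opts = ReconOptions(wiener_w=1e-9)
        S0 = deconvolve(widefield_from_pair(i_p, i_s), small_otf, opts)
        S1 = deconvolve(i_p, small_otf, opts)
        S1p = subtract_components(S1, S0, test_pattern, small_psi)
        rel_energy = np.sum(np.abs(S1p.values) ** 2) / np.sum(np.abs(S1.values) ** 2)
        assert rel_energy < 1e-4

    def test_residual_is_translated_cone_content(self, full_recon):
        """On the chirp phantom the subtraction residue sits exactly where the
        ±p-shifted sample spectrum entered the support from outside it."""
        sc = full_recon["scenario"]
        res = full_recon["result"]
        pat = sc.pattern
        psi = res.psi.values
        S_true = fft_volume(full_recon["sample"]).values
        scale = (pat.pol_ratio + 1) / (1 + pat.raw_mod)
        w = res.pattern.complex_weight  # weights the subtraction actually used
        p = res.pattern.freq_px
        oracle = np.where(
            psi,
            w * np.roll(S_true, p, axis=2) * (~np.roll(psi, p, axis=2))
            + np.conj(w) * np.roll(S_true, -p, axis=2) * (~np.roll(psi, -p, axis=2)),
            0,
        ) * scale
        S1p = res.spectra["S1p"].values
        Hm = np.abs(make_otf(full_recon["psf"]).values)
        # the residue itself is filtered only by the OTF at its own bin
        good = (np.abs(oracle) > 0) & (Hm > 1e-2)
        err = np.linalg.norm((S1p - oracle)[good]) / np.linalg.norm(oracle[good])
        assert err < 0.05
        # and (almost) nothing survives where the copies were subtracted:
        # there the cancellation involves the OTF at the bin and at its
        # two ±p translates, so all three must be healthy to judge
        elsewhere = (
            psi
            & (np.abs(oracle) == 0)
            & (Hm > 1e-2)
            & (np.roll(Hm, p, axis=2) > 1e-2)
            & (np.roll(Hm, -p, axis=2) > 1e-2)
        )
        leak = np.linalg.norm(S1p[elsewhere]) / np.linalg.norm(oracle[good])
        assert leak < 0.05

    def test_modulation_guard(self, small_grid, small_psi):
        zero = Spectrum(np.zeros(small_grid.shape, complex), small_grid)
        weak = PatternParams(freq_px=12, mod_contrast=0.0)
        with pytest.raises(ValueError, match="contrast"):
            subtract_components(zero, zero, weak, small_psi)


class TestOverlapMask:
    def test_zero_shift_returns_psi(self, small_psi):
        omega = overlap_mask(small_psi, PatternParams(freq_px=0))
        assert np.array_equal(omega.values, small_psi.values)

    def test_subset_of_both_shifts(self, small_psi, test_pattern):
        omega = overlap_mask(small_psi, test_pattern).values
        p = test_pattern.freq_px
        assert not np.any(omega & ~np.roll(small_psi.values, p, axis=2))
        assert not np.any(omega & ~np.roll(small_psi.values, -p, axis=2))

    def test_symmetric(self, small_psi, test_pattern):
        from ssos.optics import mirror_spectrum

        omega = overlap_mask(small_psi, test_pattern).values
        mirrored = mirror_spectrum(omega.astype(complex)).real.astype(bool)
        assert np.array_equal(omega, mirrored)


class TestConeRecovery:
    def test_zero_input_zero_output(self, small_grid, small_psi, test_pattern):
        zero = Spectrum(np.zeros(small_grid.shape, complex), small_grid)
        omega = overlap_mask(small_psi, test_pattern)
        out = recover_cone(zero, omega, small_psi, test_pattern)
        assert np.all(out.values == 0)

    def test_recovered_cone_matches_truth(self, full_recon):
        """Noise-free chirp phantom: the filled cone equals the ground-truth
        spectrum wherever the recovery drew on a healthy part of the OTF."""
        res = full_recon["result"]
        sc = full_recon["scenario"]
        pat = sc.pattern
        scale = (pat.pol_ratio + 1) / (1 + pat.raw_mod)
        S_true = fft_volume(full_recon["sample"]).values
        S1bar = res.spectra["S1bar"].values
        cone = S1bar != 0
        H = np.abs(make_otf(full_recon["psf"]).values)
        p = res.pattern.freq_px
        psi = res.psi.values
        vA = np.roll(psi, -p, axis=2) & np.roll(psi, -2 * p, axis=2)
        vB = np.roll(psi, p, axis=2) & np.roll(psi, 2 * p, axis=2)
        h_src = np.where(
            vA & vB,
            np.minimum(np.roll(H, -p, axis=2), np.roll(H, p, axis=2)),
            np.where(vA, np.roll(H, -p, axis=2), np.roll(H, p, axis=2)),
        )
        good = cone & (h_src > 10 * 1e-3)
        err = np.linalg.norm((S1bar / scale - S_true)[good]) / np.linalg.norm(
            S_true[good]
        )
        assert err < 0.02

    def test_conjugate_symmetry_of_all_stages(self, full_recon):
        res = full_recon["result"]
        for name in ("S0", "S1", "S1p", "S1bar", "S_OS"):
            assert conjugate_symmetry_error(res.spectra[name]) < 1e-9, name


class TestCombine:
    def test_empty_cone_degenerates_to_widefield(self, raw_pair, small_otf, small_grid):
        opts = ReconOptions(wiener_w=1e-6)
        i0 = widefield_from_pair(*raw_pair)
        S0 = deconvolve(i0, small_otf, opts)
        psi = otf_support(small_otf, opts.support_eps)
        zero = Spectrum(np.zeros(small_grid.shape, complex), small_grid)
        _, s_os = combine_spectra(S0, zero, psi)
        wf = deconvolved_widefield(i0, small_otf, opts)
        assert np.allclose(s_os.values, wf.values, atol=1e-9 * wf.values.max())

    def test_parseval_on_disjoint_supports(self, full_recon):
        res = full_recon["result"]
        psi = res.psi.values
        e_total = np.sum(np.abs(res.spectra["S_OS"].values) ** 2)
        e_s0 = np.sum(np.abs(res.spectra["S0"].values[psi]) ** 2)
        e_cone = np.sum(np.abs(res.spectra["S1bar"].values[~psi]) ** 2)
        assert e_total == pytest.approx(e_s0 + e_cone, rel=1e-12)

    def test_overlapping_contribution_rejected(self, full_recon, small_grid):
        res = full_recon["result"]
        bad = res.spectra["S0"].values.copy()  # fully inside Ψ: must trip
        with pytest.raises(AssertionError, match="overlap"):
            combine_spectra(
                res.spectra["S0"],
                Spectrum(bad, res.spectra["S0"].grid),
                res.psi,
            )


class TestPipeline:
    def test_linearity(self, raw_pair, small_psf, test_pattern, small_grid):
        opts = ReconOptions(wiener_w=1e-6)
        i_p, i_s = raw_pair
        base = ssos_reconstruct(i_p, i_s, small_psf, opts, pattern=test_pattern)
        scaled = ssos_reconstruct(
            Volume(2.5 * i_p.values, small_grid),
            Volume(2.5 * i_s.values, small_grid),
            small_psf,
            opts,
            pattern=test_pattern,
        )
        diff = np.abs(scaled.s_os.values - 2.5 * base.s_os.values).max()
        assert diff < 1e-6 * np.abs(base.s_os.values).max() * 2.5

    def test_lateral_shift_covariance(self, band_sample, small_psf, small_grid):
        """Shifting the sample by one pattern period shifts the reconstruction
        by the same amount: the processing chain is shift-invariant."""
        pattern = PatternParams(
            freq_px=16, phase_offset=0.3, mod_contrast=0.5, raw_mod=1.0,
            pol_ratio=3.0,
        )
        period = small_grid.shape[2] // 16  # integer voxels
        opts = ReconOptions(wiener_w=1e-6)
        pair = form_raw_pair(band_sample, pattern, small_psf)
        base = ssos_reconstruct(*pair, small_psf, opts, pattern=pattern)
        shifted_sample = Volume(
            np.roll(band_sample.values, period, axis=2), small_grid
        )
        pair2 = form_raw_pair(shifted_sample, pattern, small_psf)
        shifted = ssos_reconstruct(*pair2, small_psf, opts, pattern=pattern)
        expected = np.roll(base.s_os.values, period, axis=2)
        assert np.abs(shifted.s_os.values - expected).max() < 1e-6 * np.abs(
            expected
        ).max()

    def test_cone_fill_positive_then_zero_when_unshifted(self, full_recon):
        res = full_recon["result"]
        assert res.diagnostics["cone_fill"] > 0
        sc = full_recon["scenario"]
        no_shift = PatternParams(
            freq_px=0, phase_offset=0.0, mod_contrast=sc.pattern.mod_contrast
        )
        i_p, i_s = full_recon["pair"]
        res0 = ssos_reconstruct(
            i_p, i_s, full_recon["psf"], full_recon["opts"], pattern=no_shift
        )
        assert res0.diagnostics["cone_fill"] == 0

    def test_imaginary_residual_negligible(self, full_recon):
        assert full_recon["result"].diagnostics["imag_residual"] < 1e-6

    def test_zero_modulation_errors_not_widefield(self, full_recon):
        weak = PatternParams(freq_px=19, phase_offset=0.0, mod_contrast=0.005)
        with pytest.raises(ValueError, match="n_min"):
            ssos_reconstruct(
                *full_recon["pair"], full_recon["psf"], full_recon["opts"],
                pattern=weak,
            )


class TestHomodyneBaseline:
    def test_equal_frames_vanish(self, band_sample):
        out = homodyne_os_sim(band_sample, band_sample, band_sample)
        assert np.all(out.values == 0)

    def test_three_phase_constant_sample(self, small_grid, small_psf):
        """Unit-amplitude sinusoid triplet: the geometric sum removes the
        carrier and returns the constant amplitude × 3/√2."""
        params = PatternParams(freq_px=8, phase_offset=0.2, raw_mod=0.8)
        uniform = Volume(np.ones(small_grid.shape), small_grid)
        frames = three_phase_stack(uniform, params, small_psf)
        i_os = homodyne_os_sim(*frames)
        # carrier amplitude read spectrally (lattice samples miss the crest)
        line = frames[0].values[0, 0]
        amp = 2.0 * abs(np.fft.fft(line)[8]) / line.size
        expected = amp * 3.0 / np.sqrt(2.0)
        assert np.ptp(i_os.values) < 1e-9 * expected
        assert i_os.values.mean() == pytest.approx(expected, rel=1e-9)

    def test_non_negative(self, raw_pair, band_sample):
        out = homodyne_os_sim(raw_pair[0], raw_pair[1], band_sample)
        assert out.values.min() >= 0


class TestEmulation:
    def test_phase_stepped_average_halves_modulation(
        self, band_sample, small_psf, small_grid
    ):
        """cos(θ+2π/3) + cos(θ+4π/3) = −cos θ: averaging the two stepped
        frames yields the π-shifted pattern at half the raw contrast."""
        params = PatternParams(freq_px=12, phase_offset=0.7, raw_mod=0.5)
        frames = three_phase_stack(band_sample, params, small_psf)
        i1, i2, ratio = emulate_from_sim(frames)
        assert ratio == 0.5
        assert np.array_equal(i1.values, frames[0].values)
        from ssos.simulate import convolve_psf

        nx = small_grid.shape[2]
        ix = np.arange(nx)
        expected_pattern = (
            1.0 - 0.25 * np.cos(2 * np.pi * 12 * ix / nx + 0.7)
        ) / 1.5
        expected = convolve_psf(
            Volume(band_sample.values * expected_pattern, small_grid), small_psf
        )
        assert np.abs(i2.values - expected.values).max() < 1e-9 * expected.values.max()

    def test_constant_frames_identical(self, small_grid):
        const = Volume(np.ones(small_grid.shape), small_grid)
        i1, i2, _ = emulate_from_sim([const, const, const])
        assert np.allclose(i1.values, i2.values)

    def test_emulated_pair_keeps_wave_vector(self, band_sample, small_psf, small_otf):
        params = PatternParams(freq_px=12, phase_offset=0.7, raw_mod=0.5)
        frames = three_phase_stack(band_sample, params, small_psf)
        i1, i2, _ = emulate_from_sim(frames)
        est = estimate_pattern(i1, i2, small_otf, ReconOptions(wiener_w=1e-6))
        assert est.freq_px == 12

    def test_requires_three_frames(self, band_sample):
        with pytest.raises(ValueError, match="three"):
            emulate_from_sim([band_sample, band_sample])
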