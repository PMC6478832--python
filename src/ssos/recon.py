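"""Single-shot optical-sectioning (ssOS) reconstruction.

The method recovers missing-cone axial frequency content from just two raw
images taken under π-phase-shifted sinusoidal illumination:

1. the average of the pair is a widefield image (the patterns cancel) and
   either raw frame is a structured-illumination image;
2. both are deconvolved and truncated to the OTF support Ψ;
3. the widefield spectrum and its two pattern-shifted, weighted copies are
   subtracted from the SI spectrum, leaving only sample content that the
   pattern translated *into* the support from outside it;
4. shifting those fragments back by ∓p and dividing by the pattern weights
   restores the missing-cone spectrum (averaging where both shifted copies
   contribute, taking the single one elsewhere);
5. the widefield spectrum inside Ψ and the recovered cone outside Ψ are
   recombined and inverse-transformed.

All spectral shifts are integer-bin circular shifts; the pattern frequency,
phase and contrast are estimated from the raw data at bin precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .optics import (
    GridSpec,
    Spectrum,
    SupportMask,
    Volume,
    fft_volume,
    ifft_spectrum,
    make_otf,
    otf_support,
)
from .simulate import PatternParams

__all__ = [
    "ReconOptions",
    "ReconResult",
    "PatternNotFoundError",
    "widefield_from_pair",
    "estimate_pattern",
    "deconvolve",
    "deconvolved_widefield",
    "subtract_components",
    "overlap_mask",
    "recover_cone",
    "combine_spectra",
    "ssos_reconstruct",
    "homodyne_os_sim",
    "emulate_from_sim",
]


class PatternNotFoundError(RuntimeError):
    """No off-DC illumination peak could be located above the noise floor."""


@dataclass
class ReconOptions:
    """Tunable knobs of the reconstruction.

    wiener_w is the Wiener regularizer on the scale of |H|² with H(0) = 1
    (1e-3 suits shot-noise-limited data; 1e-6 is appropriate noise-free);
    support_eps thresholds the OTF support Ψ relative to max|H|; n_min
    guards the division by the estimated modulation contrast.
    """

    deconv_method: str = "wiener"
    wiener_w: float = 1e-3
    rl_iterations: int = 20
    support_eps: float = 1e-3
    n_min: float = 0.01
    enforce_real: bool = True

    def __post_init__(self) -> None:
        if self.deconv_method not in ("wiener", "richardson_lucy"):
            raise ValueError("deconv_method must be 'wiener' or 'richardson_lucy'")
        if self.wiener_w <= 0:
            raise ValueError("wiener_w must be positive")
        if self.rl_iterations < 1:
            raise ValueError("rl_iterations must be >= 1")
        if self.n_min <= 0:
            raise ValueError("n_min must be positive")


@dataclass
class ReconResult:
    """Output bundle of :func:`ssos_reconstruct`."""

    s_os: Volume
    spectra: Dict[str, Spectrum]
    psi: SupportMask
    omega: SupportMask
    pattern: PatternParams
    diagnostics: Dict[str, float]


def _require_same_grid(*items) -> GridSpec:
    grids = {it.grid for it in items}
    if len(grids) != 1:
        raise ValueError(f"inputs live on different grids: {grids}")
    return items[0].grid


def _roll_x(arr: np.ndarray, bins: int) -> np.ndarray:
    """Circular shift along x: out(k) = arr(k - bins)."""
    return np.roll(arr, bins, axis=2)


# ---------------------------------------------------------------------------
# Stage 1: widefield / SI split
# ---------------------------------------------------------------------------

def widefield_from_pair(i_prime: Volume, i_dprime: Volume) -> Volume:
    """Widefield image i_0 = (i' + i'')/2; the π-shifted patterns cancel."""
    grid = _require_same_grid(i_prime, i_dprime)
    return Volume(0.5 * (i_prime.values + i_dprime.values), grid)


# ---------------------------------------------------------------------------
# Stage 2: deconvolution
# ---------------------------------------------------------------------------

def _richardson_lucy_circular(
    img: np.ndarray, H: np.ndarray, iterations: int, eps: float = 1e-12
) -> np.ndarray:
    """Multiplicative Richardson-Lucy with circular FFT convolutions.

    Uses the same circular convolution as the forward model, so the iterate
    stays non-negative and conserves total intensity exactly (H(0) = 1).
    """
    Hu = np.fft.ifftshift(H)

    def conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        return np.fft.ifftn(np.fft.fftn(x) * kernel).real

    img = np.clip(img, 0.0, None)
    est = np.full_like(img, img.mean() if img.mean() > 0 else 1.0)
    for _ in range(iterations):
        blurred = conv(est, Hu)
        ratio = img / np.clip(blurred, eps, None)
        est = est * np.clip(conv(ratio, np.conj(Hu)), 0.0, None)
    return est


def deconvolve(i: Volume, H: Spectrum, opts: Optional[ReconOptions] = None) -> Spectrum:
    """Deconvolve an image with the OTF and truncate to the support Ψ.

    Wiener: S = I·conj(H)/(|H|² + w).  Richardson-Lucy: iterate in real
    space (multiplicative, flux-conserving), then transform.  Both are
    zeroed outside Ψ — outside the support the data carry no information.
    """
    opts = opts or ReconOptions()
    _require_same_grid(i, H)
    psi = otf_support(H, opts.support_eps)
    if opts.deconv_method == "wiener":
        I = fft_volume(i).values
        S = I * np.conj(H.values) / (np.abs(H.values) ** 2 + opts.wiener_w)
    else:
        est = _richardson_lucy_circular(i.values, H.values, opts.rl_iterations)
        S = np.fft.fftshift(np.fft.fftn(est))
    S = np.where(psi.values, S, 0.0 + 0.0j)
    return Spectrum(S, i.grid)


def deconvolved_widefield(
    i0: Volume, H: Spectrum, opts: Optional[ReconOptions] = None
) -> Volume:
    """Real-space deconvolved widefield image (the baseline of the method)."""
    S0 = deconvolve(i0, H, opts)
    return Volume(ifft_spectrum(S0).real, i0.grid)


# ---------------------------------------------------------------------------
# Stage 3: pattern estimation
# ---------------------------------------------------------------------------

def _xcorr_along_x(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """C(q) = Σ_k conj(a(k))·b(k + q·x̂) for every circular x-shift q."""
    A = np.fft.fft(a, axis=2)
    B = np.fft.fft(b, axis=2)
    c = np.fft.ifft(np.conj(A) * B, axis=2)
    return c.sum(axis=(0, 1))


def _estimate_from_spectra(
    S0: Spectrum, S1: Spectrum, psi: SupportMask
) -> PatternParams:
    nx = S0.grid.shape[2]
    corr = _xcorr_along_x(S0.values, S1.values)
    mag = np.abs(corr)
    # The correlation carries a smooth object-autocorrelation background that
    # peaks towards DC; the illumination shows up as an isolated single-bin
    # peak (patterns are snapped to the frequency lattice).  Candidates must
    # therefore stand clearly above their immediate neighbours — including
    # the DC bin itself, which disqualifies the autocorrelation shoulder.
    neighbors = np.maximum(np.roll(mag, 1), np.roll(mag, -1))
    isolated = mag >= 1.5 * neighbors
    isolated[0] = False
    floor = np.median(mag[1:])
    candidates = np.flatnonzero(isolated & (mag > 3.0 * floor))
    if candidates.size == 0:
        raise PatternNotFoundError(
            "pattern not found: no isolated off-DC correlation peak"
        )
    q_star = int(candidates[np.argmax(mag[candidates])])
    p = q_star if q_star <= nx // 2 else q_star - nx
    # normalized complex weight at the peak: w = (n/2)·exp(i·φ0)
    denom = float(
        np.sum(np.abs(S0.values) ** 2 * _roll_x(psi.values, -p))
    )
    if denom == 0:
        raise PatternNotFoundError("pattern not found: empty overlap region")
    w = corr[p % nx] / denom
    if p < 0:  # report the positive-frequency convention
        p, w = -p, np.conj(w)
    if 2.0 * abs(w) < 0.01:
        raise PatternNotFoundError(
            "pattern not found: correlation peak implies negligible modulation"
        )
    n = min(2.0 * abs(w), 1.0)
    phi0 = float(np.angle(w))
    return PatternParams(freq_px=p, phase_offset=phi0, mod_contrast=n)


def estimate_pattern(
    i_prime: Volume,
    i_dprime: Volume,
    H: Spectrum,
    opts: Optional[ReconOptions] = None,
) -> PatternParams:
    """Retrieve the pattern frequency, phase and contrast from the raw data.

    The lateral frequency p is located (at integer-bin precision) as the
    strongest off-DC peak of the cross-correlation between the deconvolved
    widefield spectrum and the deconvolved SI spectrum; the normalized
    complex weight at that peak carries the phase φ0 and the modulation
    contrast n (clamped to [0, 1]).
    """
    opts = opts or ReconOptions()
    _require_same_grid(i_prime, i_dprime, H)
    psi = otf_support(H, opts.support_eps)
    i0 = widefield_from_pair(i_prime, i_dprime)
    S0 = deconvolve(i0, H, opts)
    S1 = deconvolve(i_prime, H, opts)
    return _estimate_from_spectra(S0, S1, psi)


# ---------------------------------------------------------------------------
# Stage 4: spectral unmixing
# ---------------------------------------------------------------------------

def subtract_components(
    S1: Spectrum,
    S0: Spectrum,
    params: PatternParams,
    psi: Optional[SupportMask] = None,
) -> Spectrum:
    """Remove the widefield spectrum and its shifted copies from the SI one.

    S1' = S1 − S0 − w·S0(k − p) − conj(w)·S0(k + p) with w = (n/2)·e^{iφ0}.
    What survives is the sample content that the pattern translated into the
    support from outside it (the missing-cone fragments at ±p).  When Ψ is
    given, the residue the shifted copies leave outside the support is
    zeroed — only in-support bins carry signal.
    """
    grid = _require_same_grid(S1, S0)
    if params.mod_contrast < 1e-12:
        raise ValueError("modulation contrast too small for unmixing")
    w = params.complex_weight
    p = params.freq_px
    out = (
        S1.values
        - S0.values
        - w * _roll_x(S0.values, p)
        - np.conj(w) * _roll_x(S0.values, -p)
    )
    if psi is not None:
        out = np.where(psi.values, out, 0.0 + 0.0j)
    return Spectrum(out, grid)


def overlap_mask(psi: SupportMask, params: PatternParams) -> SupportMask:
    """Ω: overlap of the two pattern-shifted OTF supports Ψ(k ∓ p).

    Inside Ω both back-shifted cone components exist and are averaged; where
    only one shifted support covers a bin, that component is taken alone.
    """
    p = params.freq_px
    shifted_plus = _roll_x(psi.values, p)
    shifted_minus = _roll_x(psi.values, -p)
    return SupportMask(shifted_plus & shifted_minus, psi.grid)


def recover_cone(
    S1p: Spectrum,
    omega: SupportMask,
    psi: SupportMask,
    params: PatternParams,
) -> Spectrum:
    """Shift the cone fragments back by ∓p, unweight and average them.

    A(k) = S1'(k + p)/w lives on Ψ(k + p); B(k) = S1'(k − p)/conj(w) on
    Ψ(k − p).  A branch is only trusted where its source bin is free of the
    *other* sideband's leakage: the conjugate copy at the source bin was
    subtracted exactly only if its own origin lay inside Ψ, which for branch
    A means Ψ(k + 2p) (and Ψ(k − 2p) for B) — the per-branch half of the Ω
    overlap restriction.  On Ω both branches are averaged, on a single
    trusted branch that component is used alone, and the result is
    restricted to bins outside Ψ — its only role is to fill the missing
    cone.
    """
    grid = _require_same_grid(S1p, omega, psi)
    n = params.mod_contrast
    if n < 1e-12:
        raise ValueError("modulation contrast below the unmixing guard")
    w = params.complex_weight
    p = params.freq_px
    s1p = np.where(psi.values, S1p.values, 0.0 + 0.0j)
    A = _roll_x(s1p, -p) / w
    B = _roll_x(s1p, p) / np.conj(w)
    valid_A = _roll_x(psi.values, -p) & _roll_x(psi.values, -2 * p)
    valid_B = _roll_x(psi.values, p) & _roll_x(psi.values, 2 * p)
    both = omega.values & valid_A & valid_B
    only_A = valid_A & ~valid_B
    only_B = valid_B & ~valid_A
    out = np.zeros_like(A)
    out[both] = 0.5 * (A[both] + B[both])
    out[only_A] = A[only_A]
    out[only_B] = B[only_B]
    out[psi.values] = 0.0
    return Spectrum(out, grid)


def combine_spectra(
    S0: Spectrum, S1bar: Spectrum, psi: SupportMask
) -> Tuple[Spectrum, Volume]:
    """S_OS = S0 inside Ψ + recovered cone outside Ψ; inverse transform."""
    grid = _require_same_grid(S0, S1bar, psi)
    inside = np.where(psi.values, S0.values, 0.0 + 0.0j)
    outside = np.where(psi.values, 0.0 + 0.0j, S1bar.values)
    leak = np.abs(S1bar.values[psi.values])
    if leak.size and leak.max() > 1e-9 * max(np.abs(S0.values).max(), 1e-300):
        raise AssertionError(
            "recovered-cone spectrum overlaps the OTF support; stages disagree"
        )
    S_os = Spectrum(inside + outside, grid)
    complex_img = ifft_spectrum(S_os)
    s_os = Volume(complex_img.real, grid)
    return S_os, s_os


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def ssos_reconstruct(
    i_prime: Volume,
    i_dprime: Volume,
    h: Volume,
    opts: Optional[ReconOptions] = None,
    pattern: Optional[PatternParams] = None,
) -> ReconResult:
    """Full ssOS pipeline on a π-shifted raw image pair.

    Stages: widefield average → deconvolution of i_0 and i_1 = i' →
    pattern estimation (unless ``pattern`` is supplied) → subtraction of
    shifted widefield copies → overlap masking → cone shift/average →
    recombination.  Deterministic given inputs and options.
    """
    opts = opts or ReconOptions()
    grid = _require_same_grid(i_prime, i_dprime, h)
    H = make_otf(h)
    psi = otf_support(H, opts.support_eps)
    i0 = widefield_from_pair(i_prime, i_dprime)
    S0 = deconvolve(i0, H, opts)
    S1 = deconvolve(i_prime, H, opts)
    if pattern is None:
        pattern = _estimate_from_spectra(S0, S1, psi)
    if pattern.mod_contrast < opts.n_min:
        raise ValueError(
            f"estimated modulation contrast {pattern.mod_contrast:.4f} is below "
            f"n_min = {opts.n_min}; unmixing would be numerically meaningless"
        )
    S1p = subtract_components(S1, S0, pattern, psi)
    omega = overlap_mask(psi, pattern)
    S1bar = recover_cone(S1p, omega, psi, pattern)
    S_os, s_os = combine_spectra(S0, S1bar, psi)
    complex_img = ifft_spectrum(S_os)
    total = float(np.sum(np.abs(complex_img) ** 2))
    imag_residual = float(np.sum(complex_img.imag**2) / total) if total > 0 else 0.0
    cone_fill = int(np.count_nonzero(S1bar.values))
    return ReconResult(
        s_os=s_os,
        spectra={"S0": S0, "S1": S1, "S1p": S1p, "S1bar": S1bar, "S_OS": S_os},
        psi=psi,
        omega=omega,
        pattern=pattern,
        diagnostics={"imag_residual": imag_residual, "cone_fill": float(cone_fill)},
    )


# ---------------------------------------------------------------------------
# Baselines and emulation
# ---------------------------------------------------------------------------

def homodyne_os_sim(i1: Volume, i2: Volume, i3: Volume) -> Volume:
    """Three-phase homodyne OS-SIM baseline.

    i_OS = sqrt((i1−i2)² + (i1−i3)² + (i2−i3)²).  Non-linear: the geometric
    sum of difference images is not shift-invariant, so no PSF exists for
    the sectioned image — this is the classical method ssOS replaces.
    """
    grid = _require_same_grid(i1, i2, i3)
    a = i1.values - i2.values
    b = i1.values - i3.values
    c = i2.values - i3.values
    return Volume(np.sqrt(a * a + b * b + c * c), grid)


def emulate_from_sim(
    phases: Sequence[Volume],
) -> Tuple[Volume, Volume, float]:
    """Build a ssOS raw pair from three 2π/3 phase-stepped SIM frames.

    The phase-0 frame is used as i' directly; averaging the other two frames
    yields i'' carrying the same wave-vector with the pattern phase shifted
    by π and the modulation halved (cos(θ+2π/3) + cos(θ+4π/3) = −cos θ).
    Returns (i', i'', modulation ratio of i'' relative to i').
    """
    if len(phases) != 3:
        raise ValueError("exactly three phase-stepped frames are required")
    grid = _require_same_grid(*phases)
    i_prime = Volume(phases[0].values.copy(), grid)
    i_dprime = Volume(0.5 * (phases[1].values + phases[2].values), grid)
    return i_prime, i_dprime, 0.5
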