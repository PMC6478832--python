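"""Forward imaging simulator: phantoms, polarization-coded pattern pairs,
anisotropy mixing and Poisson noise.

The simulator produces everything needed to exercise the single-shot
optical-sectioning (ssOS) reconstruction without external data: a tilted
frequency-chirp phantom whose stripe frequency rises linearly with depth, a
pair of π-phase-shifted sinusoidal excitation patterns coded in orthogonal
polarizations, the anisotropy-mixed raw image pair recorded behind a
polarizing beam splitter, and shot noise at a configurable photon budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .optics import GridSpec, Spectrum, Volume, fft_volume, make_otf

__all__ = [
    "PatternParams",
    "ChirpSampleSpec",
    "NoiseConfig",
    "make_chirp_sample",
    "chirp_local_frequency",
    "excitation_patterns",
    "effective_patterns",
    "anisotropy_ratio",
    "effective_modulation",
    "form_raw_pair",
    "three_phase_stack",
    "add_poisson",
    "convolve_psf",
]


@dataclass
class PatternParams:
    """Sinusoidal illumination pattern descriptor.

    ``freq_px`` is the lateral frequency in integer bins along x (k_y = k_z =
    0): patterns are snapped to the frequency lattice so spectral shifts are
    exact circular bin shifts.  ``mod_contrast`` is the *effective* contrast
    n seen after polarization cross-talk; ``raw_mod`` the raw optical
    contrast m of each pattern; ``pol_ratio`` the parallel-to-perpendicular
    emission ratio t.
    """

    freq_px: int
    phase_offset: float = 0.0
    mod_contrast: float = 1.0
    raw_mod: Optional[float] = None
    pol_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        self.freq_px = int(self.freq_px)
        if not (0.0 <= self.mod_contrast <= 1.0):
            raise ValueError("mod_contrast must lie in [0, 1]")
        if self.raw_mod is not None and not (0.0 <= self.raw_mod <= 1.0):
            raise ValueError("raw_mod must lie in [0, 1]")
        if self.pol_ratio is not None and self.pol_ratio < 1.0:
            raise ValueError("pol_ratio t must be >= 1")

    @property
    def complex_weight(self) -> complex:
        """Weight (n/2)·exp(iφ0) carried by the S(k − p) sideband."""
        return 0.5 * self.mod_contrast * np.exp(1j * self.phase_offset)


@dataclass
class ChirpSampleSpec:
    """Tilted frequency-chirp phantom description.

    Stripes are perpendicular to an axis tilted ``tilt_deg`` away from the
    optical (z) axis within the x–z plane.  The local stripe frequency rises
    linearly from zero at the top z-plane to ``f_max`` (cycles/µm) at the
    bottom plane.
    """

    grid: GridSpec
    tilt_deg: float = 15.0
    f_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_deg < 90.0):
            raise ValueError("tilt_deg must lie in [0, 90)")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        vz, _, vx = self.grid.voxels_um
        th = np.deg2rad(self.tilt_deg)
        if self.f_max * np.cos(th) > 0.5 / vz + 1e-12:
            raise ValueError("f_max exceeds the axial Nyquist frequency")
        if self.f_max * np.sin(th) > 0.5 / vx + 1e-12:
            raise ValueError("f_max exceeds the lateral Nyquist frequency")


@dataclass
class NoiseConfig:
    """Photon budget and seed for the Poisson noise model."""

    peak_photons: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_photons <= 0:
            raise ValueError("peak_photons must be positive")


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

def chirp_local_frequency(spec: ChirpSampleSpec) -> np.ndarray:
    """Local stripe frequency (cycles/µm) at the centre of each depth plane."""
    nz = spec.grid.shape[0]
    vz = spec.grid.voxels_um[0]
    z = np.arange(nz) * vz
    lz = (nz - 1) * vz
    return spec.f_max * z / lz


def make_chirp_sample(spec: ChirpSampleSpec) -> Volume:
    """Tilted linear-chirp stripe phantom, s = ½(1 + cos φ), values in [0, 1].

    The phase is φ(z, x) = 2π[sinθ·f(z)·x + cosθ·∫f dz] with f(z) linear in
    depth, which makes the local frequency along the tilted axis equal f(z)
    exactly on the central sampling line (x = 0) of every plane.
    """
    nz, ny, nx = spec.grid.shape
    vz, _, vx = spec.grid.voxels_um
    th = np.deg2rad(spec.tilt_deg)
    z = np.arange(nz) * vz
    lz = (nz - 1) * vz
    x = (np.arange(nx) - nx // 2) * vx
    f_z = spec.f_max * z / lz
    f_int = spec.f_max * z**2 / (2.0 * lz)
    phi = 2.0 * np.pi * (
        np.sin(th) * f_z[:, None] * x[None, :] + np.cos(th) * f_int[:, None]
    )
    s = 0.5 * (1.0 + np.cos(phi))
    values = np.repeat(s[:, None, :], ny, axis=1)
    return Volume(values, spec.grid)


# ---------------------------------------------------------------------------
# Patterns and anisotropy mixing
# ---------------------------------------------------------------------------

def _pattern_phase(params: PatternParams, grid: GridSpec) -> np.ndarray:
    nx = grid.shape[2]
    ix = np.arange(nx)
    return 2.0 * np.pi * params.freq_px * ix / nx + params.phase_offset


def excitation_patterns(
    params: PatternParams, grid: GridSpec
) -> Tuple[Volume, Volume]:
    """Normalized π-shifted excitation pattern pair (e_p, e_s).

    e_p = (1 + m·cos(x·p + φ0)) / (1 + m) and e_s is the same pattern
    phase-shifted by π.  Both are invariant along y and z (the illumination
    lattice is invariant along the optical axis) and their sum is the
    spatial constant 2/(1 + m).
    """
    if params.raw_mod is None:
        raise ValueError("raw_mod m is required to form excitation patterns")
    m = params.raw_mod
    phase = _pattern_phase(params, grid)
    e_p_line = (1.0 + m * np.cos(phase)) / (1.0 + m)
    e_s_line = (1.0 + m * np.cos(phase + np.pi)) / (1.0 + m)
    shape = grid.shape
    e_p = np.broadcast_to(e_p_line, shape).copy()
    e_s = np.broadcast_to(e_s_line, shape).copy()
    return Volume(e_p, grid), Volume(e_s, grid)


def effective_patterns(
    params: PatternParams, grid: GridSpec
) -> Tuple[Volume, Volume]:
    """Effective excitation pair (e'_p, e'_s) seen by the two detection arms.

    e'_p = (1+t)/(t(m+1)) − m(1−t)/(t(m+1))·cos(x·p + φ0), and e'_s with the
    opposite cosine sign.  For t = 3, m = 1 this is 2/3 ± 1/3·cos, i.e. a
    single harmonic with 50% modulation contrast.
    """
    if params.raw_mod is None or params.pol_ratio is None:
        raise ValueError("raw_mod and pol_ratio are required")
    m, t = params.raw_mod, params.pol_ratio
    phase = _pattern_phase(params, grid)
    offset = (1.0 + t) / (t * (m + 1.0))
    amp = m * (1.0 - t) / (t * (m + 1.0))
    e_p_line = offset - amp * np.cos(phase)
    e_s_line = offset + amp * np.cos(phase)
    shape = grid.shape
    return (
        Volume(np.broadcast_to(e_p_line, shape).copy(), grid),
        Volume(np.broadcast_to(e_s_line, shape).copy(), grid),
    )


def anisotropy_ratio(r: float) -> float:
    """Parallel-to-perpendicular emission ratio t = (1 + 2r)/(1 − r).

    ``r`` is the fluorescence anisotropy; r = 0.4 (the one-photon theoretical
    maximum for immobile dipoles) gives the 3:1 ratio, r = 0 isotropic
    emission (t = 1, no multiplexing).
    """
    if not (0.0 <= r < 1.0):
        raise ValueError("anisotropy r must lie in [0, 1)")
    if r > 0.4:
        warnings.warn(
            "anisotropy above the one-photon theoretical maximum of 0.4",
            stacklevel=2,
        )
    return (1.0 + 2.0 * r) / (1.0 - r)


def effective_modulation(t: float, m: float) -> float:
    """Effective modulation contrast n = m·(t − 1)/(t + 1).

    The polarization cross-talk between the two π-shifted patterns reduces
    the raw contrast m to the contrast n actually present in each recorded
    arm; t = 1 (isotropic emission) cancels the patterns entirely.
    """
    if t < 1.0:
        raise ValueError("intensity ratio t must be >= 1")
    if not (0.0 <= m <= 1.0):
        raise ValueError("raw contrast m must lie in [0, 1]")
    return m * (t - 1.0) / (t + 1.0)


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------

def convolve_psf(v: Volume, h: Volume) -> Volume:
    """Circular (FFT-based) convolution of a volume with the centred PSF."""
    if v.grid != h.grid:
        raise ValueError("volume and PSF grids differ")
    H = make_otf(h)
    V = fft_volume(v)
    out = np.fft.ifftn(np.fft.ifftshift(V.values * H.values)).real
    return Volume(out, v.grid)


def form_raw_pair(
    s: Volume, params: PatternParams, h: Volume
) -> Tuple[Volume, Volume]:
    """Anisotropy-mixed raw image pair (i_p, i_s).

    i_p = h ⊗ [t·(s·e_p) + s·e_s] and i_s with the two patterns swapped:
    each detection arm records its own pattern weighted by t plus the
    cross-talk of the orthogonal, π-shifted pattern.
    """
    if s.grid != h.grid:
        raise ValueError("sample and PSF grids differ")
    if params.pol_ratio is None:
        raise ValueError("pol_ratio t is required to mix the arms")
    if params.freq_px == 0:
        raise ValueError("structured illumination requires freq_px != 0")
    t = params.pol_ratio
    e_p, e_s = excitation_patterns(params, s.grid)
    i_p = convolve_psf(
        Volume(t * s.values * e_p.values + s.values * e_s.values, s.grid), h
    )
    i_s = convolve_psf(
        Volume(t * s.values * e_s.values + s.values * e_p.values, s.grid), h
    )
    return i_p, i_s


def three_phase_stack(
    s: Volume,
    params: PatternParams,
    h: Volume,
    steps: Sequence[float] = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0),
) -> Tuple[Volume, ...]:
    """Conventional phase-stepped SIM frames i_k = h ⊗ [s·(1 + m·cos(... + Δk))/(1+m)].

    Used to emulate a ssOS raw pair from 3-phase SIM data and as input to the
    homodyne OS-SIM baseline.
    """
    if params.raw_mod is None:
        raise ValueError("raw_mod m is required")
    m = params.raw_mod
    base = _pattern_phase(params, s.grid)
    frames = []
    for step in steps:
        e = (1.0 + m * np.cos(base + step)) / (1.0 + m)
        frames.append(
            convolve_psf(Volume(s.values * np.broadcast_to(e, s.grid.shape), s.grid), h)
        )
    return tuple(frames)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_poisson(
    v: Volume, noise: NoiseConfig, scale: Optional[float] = None
) -> Volume:
    """Poisson photon counts with the brightest voxel at ``peak_photons``.

    The volume is scaled so its maximum equals the photon budget (or by an
    explicit ``scale``, e.g. to share one scale across a raw pair) and
    independent Poisson counts are drawn per voxel.  Identical seed and
    input give identical output.
    """
    vals = v.values
    tol = -1e-9 * max(vals.max(), 1.0)
    if vals.min() < tol:
        raise ValueError("Poisson noise requires non-negative intensities")
    vals = np.clip(vals, 0.0, None)
    if scale is None:
        peak = vals.max()
        if peak == 0:
            raise ValueError("cannot scale an all-zero volume to a photon peak")
        scale = noise.peak_photons / peak
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(vals * scale).astype(np.float64)
    return Volume(counts, v.grid)
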