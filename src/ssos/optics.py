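"""Scalar diffraction model of the widefield fluorescence microscope.

Provides the core lattice types (:class:`GridSpec`, :class:`Volume`,
:class:`Spectrum`, :class:`SupportMask`), the optical configuration, the
band-limit formulas, and the scalar pupil-integral PSF/OTF model whose
missing cone of axial frequencies is the whole reason structured
illumination is needed for optical sectioning.

Conventions
-----------
* Axis order is ``(z, y, x)`` with ``z`` the optical axis.
* Lengths are nanometres in configurations; spatial frequencies are
  cycles/µm everywhere they are reported.
* Frequency lattices are DC-centred (``np.fft.fftshift`` layout); the DC
  bin sits at index ``shape // 2`` along every axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "OpticalConfig",
    "GridSpec",
    "Volume",
    "Spectrum",
    "SupportMask",
    "lateral_cutoff",
    "axial_confocal_cutoff",
    "make_psf",
    "make_otf",
    "otf_support",
    "fft_volume",
    "ifft_spectrum",
    "mirror_spectrum",
    "conjugate_symmetry_error",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Microscope parameters governing the PSF/OTF and the cutoff formulas.

    Attributes
    ----------
    numerical_aperture : float
        NA of the objective; must be strictly below the immersion index.
    refr_index : float
        Refractive index of the immersion medium (the optical *n*, distinct
        from the modulation contrast *n* of a pattern).
    wavelength_em, wavelength_exc : float
        Emission / excitation wavelengths in nm.
    voxel_xy, voxel_z : float
        Sampling voxel sizes in nm.
    """

    numerical_aperture: float
    refr_index: float
    wavelength_em: float
    wavelength_exc: float
    voxel_xy: float
    voxel_z: float

    def __post_init__(self) -> None:
        if not (0.0 < self.numerical_aperture < self.refr_index):
            raise ValueError(
                f"numerical_aperture must satisfy 0 < NA < refractive index; "
                f"got NA={self.numerical_aperture}, n={self.refr_index}"
            )
        for name in ("wavelength_em", "wavelength_exc", "voxel_xy", "voxel_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def default_config() -> OpticalConfig:
    """High-NA oil-immersion configuration used throughout the simulations."""
    return OpticalConfig(
        numerical_aperture=1.49,
        refr_index=1.518,
        wavelength_em=520.0,
        wavelength_exc=488.0,
        voxel_xy=40.0,
        voxel_z=40.0,
    )


@dataclass(frozen=True)
class GridSpec:
    """Sampling lattice shared by real-space volumes and their spectra."""

    shape: Tuple[int, int, int]
    voxel_xy: float  # nm
    voxel_z: float  # nm

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("shape must be (nz, ny, nx)")
        nz, ny, nx = self.shape
        # nz == 1 is tolerated for single-plane stacks; otherwise every axis
        # must be even and >= 4 so the DC bin is well defined after centring
        for n in (ny, nx) if nz == 1 else self.shape:
            if n < 4 or n % 2 != 0:
                raise ValueError(
                    f"grid dimensions must be even and >= 4, got {self.shape}"
                )
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def voxels_um(self) -> Tuple[float, float, float]:
        """Voxel size per axis (z, y, x) in µm."""
        return (self.voxel_z * 1e-3, self.voxel_xy * 1e-3, self.voxel_xy * 1e-3)

    def freq_axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """DC-centred frequency axes (fz, fy, fx) in cycles/µm."""
        return tuple(
            np.fft.fftshift(np.fft.fftfreq(n, d=v))
            for n, v in zip(self.shape, self.voxels_um)
        )

    def freq_steps(self) -> Tuple[float, float, float]:
        """Frequency bin width per axis in cycles/µm."""
        return tuple(1.0 / (n * v) for n, v in zip(self.shape, self.voxels_um))


def _check_grid(values: np.ndarray, grid: GridSpec) -> None:
    if tuple(values.shape) != tuple(grid.shape):
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")


@dataclass
class Volume:
    """Real-space 3-D lattice of (typically non-negative) intensities."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_grid(self.values, self.grid)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume contains non-finite values")


@dataclass
class Spectrum:
    """DC-centred complex Fourier twin of a :class:`Volume`."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        _check_grid(self.values, self.grid)


@dataclass
class SupportMask:
    """Boolean DC-centred frequency-space set (Ψ, Ω, ...)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        _check_grid(self.values, self.grid)


# ---------------------------------------------------------------------------
# FFT plumbing (DC-centred convention)
# ---------------------------------------------------------------------------

def fft_volume(v: Volume) -> Spectrum:
    """Forward transform of a real volume, DC-centred."""
    return Spectrum(np.fft.fftshift(np.fft.fftn(v.values)), v.grid)


def ifft_spectrum(s: Spectrum) -> np.ndarray:
    """Inverse transform of a DC-centred spectrum (complex output)."""
    return np.fft.ifftn(np.fft.ifftshift(s.values))


def mirror_spectrum(values: np.ndarray) -> np.ndarray:
    """Map a DC-centred lattice under k -> -k (modular index negation)."""
    un = np.fft.ifftshift(values)
    rev = un[::-1, ::-1, ::-1]
    rev = np.roll(rev, 1, axis=(0, 1, 2))
    return np.fft.fftshift(rev)


def conjugate_symmetry_error(s: Spectrum) -> float:
    """Relative deviation from V(-k) = conj(V(k))."""
    v = s.values
    mirrored = mirror_spectrum(v)
    denom = np.linalg.norm(v.ravel())
    if denom == 0:
        return 0.0
    return float(np.linalg.norm((v - np.conj(mirrored)).ravel()) / denom)


# ---------------------------------------------------------------------------
# Band limits
# ---------------------------------------------------------------------------

def lateral_cutoff(
    cfg: OpticalConfig, which: Literal["emission", "excitation"] = "emission"
) -> float:
    """Incoherent lateral cutoff 2·NA/λ in cycles/µm.

    ``which`` selects the emission (detection) or excitation wavelength.
    """
    if which == "emission":
        lam = cfg.wavelength_em
    elif which == "excitation":
        lam = cfg.wavelength_exc
    else:
        raise ValueError(f"unknown wavelength selector: {which!r}")
    return 2.0 * cfg.numerical_aperture / (lam * 1e-3)


def axial_confocal_cutoff(cfg: OpticalConfig) -> Tuple[float, float]:
    """Confocal axial resolution Δz (nm) and its cutoff frequency (cycles/µm).

    Uses Δz = 0.64·λ_em / (n − sqrt(n² − NA²)); the cutoff is 1/Δz.
    """
    na, n = cfg.numerical_aperture, cfg.refr_index
    if na >= n:
        raise ValueError("NA must be smaller than the immersion index")
    dz_nm = 0.64 * cfg.wavelength_em / (n - np.sqrt(n * n - na * na))
    return float(dz_nm), float(1e3 / dz_nm)


# ---------------------------------------------------------------------------
# PSF / OTF
# ---------------------------------------------------------------------------

def make_psf(cfg: OpticalConfig, grid: GridSpec) -> Volume:
    """Scalar pupil-integral widefield intensity PSF.

    For every defocus plane the amplitude PSF is the inverse transform of the
    circular pupil carrying the defocus phase exp(2πi·z·k_z(k_r)) with
    k_z = sqrt((n/λ_em)² − k_r²); the intensity is its squared magnitude.
    The result is centred at ``shape // 2``, non-negative and normalized to
    unit total intensity.
    """
    k_c = lateral_cutoff(cfg, "emission")
    vz_um, vy_um, vx_um = grid.voxels_um
    nyquist = 1.0 / (2.0 * k_c)
    if vx_um > nyquist + 1e-12:
        raise ValueError(
            f"voxel_xy = {grid.voxel_xy} nm undersamples the lateral emission "
            f"cutoff {k_c:.4f} cycles/um (need <= {nyquist * 1e3:.1f} nm)"
        )
    nz, ny, nx = grid.shape
    lam_um = cfg.wavelength_em * 1e-3
    kx = np.fft.fftfreq(nx, d=vx_um)
    ky = np.fft.fftfreq(ny, d=vy_um)
    kr2 = ky[:, None] ** 2 + kx[None, :] ** 2
    pupil = kr2 <= (cfg.numerical_aperture / lam_um) ** 2
    k_sphere = (cfg.refr_index / lam_um) ** 2 - kr2
    kz = np.sqrt(np.clip(k_sphere, 0.0, None))
    z = (np.arange(nz) - nz // 2) * vz_um
    defocus = np.exp(2j * np.pi * z[:, None, None] * kz[None, :, :])
    field = np.fft.ifft2(pupil[None, :, :] * defocus, axes=(1, 2))
    h = np.abs(field) ** 2
    h = np.fft.fftshift(h, axes=(1, 2))  # centre laterally; z already centred
    h /= h.sum()
    return Volume(h, grid)


def make_otf(h: Volume) -> Spectrum:
    """OTF: forward transform of the (centred) PSF, DC-centred, H(0) = 1."""
    H = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(h.values)))
    return Spectrum(H, h.grid)


def otf_support(H: Spectrum, eps: float = 1e-3) -> SupportMask:
    """Support Ψ of the OTF: bins where |H| exceeds ``eps``·max|H|.

    The magnitude lattice is symmetrized under k -> -k before thresholding
    so the mask is exactly symmetric; the DC bin is always included.
    """
    if not (0.0 < eps < 1.0):
        raise ValueError("eps must lie in (0, 1)")
    mag = np.abs(H.values)
    peak = mag.max()
    if peak == 0:
        raise ValueError("degenerate OTF: all bins are zero")
    mag = np.maximum(mag, mirror_spectrum(mag))
    mask = mag > eps * peak
    nz, ny, nx = H.grid.shape
    mask[nz // 2, ny // 2, nx // 2] = True
    return SupportMask(mask, H.grid)
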