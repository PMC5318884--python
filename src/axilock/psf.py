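"""Scalar-diffraction two-photon excitation PSF with pupil aberrations.

The focal field is computed plane-by-plane as the inverse Fourier transform
of the (apodized, phase-aberrated) pupil function multiplied by an
angular-spectrum defocus kernel ``exp(i 2 pi z sqrt((n/lambda)^2 - f^2))``.
The effective two-photon PSF is the square of the excitation intensity —
point-scanning two-photon detection collects all emitted photons, so no
detection PSF enters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .zernike import PupilGrid, WavefrontCoeffs, phase_map

__all__ = ["OpticalConfig", "PSF3D", "pupil_grid", "field_psf", "two_photon_psf", "compute_psf"]


@dataclass(frozen=True)
class OpticalConfig:
    """Microscope/simulation geometry.

    Defaults mirror a water-dipping 16x/0.8 physiology objective with 920 nm
    excitation.  ``dx`` must keep the excitation field band-limited on the
    grid (dx <= wavelength / (2 NA)); coarser sampling raises rather than
    silently aliasing.
    """

    wavelength: float = 0.920  # μm, excitation
    numerical_aperture: float = 0.8
    immersion_index: float = 1.33
    dx: float = 0.4  # μm
    dy: float = 0.4  # μm
    dz: float = 0.8  # μm
    nx: int = 128
    ny: int = 128
    nz: int = 64
    apodization: str = "uniform"  # or "gaussian" (overfilled back aperture)
    gaussian_fill: float = 1.5  # beam 1/e^2 radius / pupil radius when gaussian

    def __post_init__(self):
        if self.numerical_aperture >= self.immersion_index:
            raise ValueError("numerical aperture must be below the immersion index")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("all grid steps must be positive")
        if min(self.nx, self.ny, self.nz) < 8:
            raise ValueError("grid too small to hold a PSF")
        nyq = self.wavelength / (2.0 * self.numerical_aperture)
        if self.dx > nyq or self.dy > nyq:
            raise ValueError(
                f"lateral step {max(self.dx, self.dy):.3f} μm undersamples the field "
                f"(Nyquist limit {nyq:.3f} μm at NA {self.numerical_aperture})"
            )
        if self.apodization not in ("uniform", "gaussian"):
            raise ValueError(f"unknown apodization {self.apodization!r}")

    @property
    def cutoff(self) -> float:
        """Pupil-edge spatial frequency NA/λ in 1/μm."""
        return self.numerical_aperture / self.wavelength

    def z_axis(self) -> np.ndarray:
        """Axial coordinates (μm) of the PSF planes; focus at index nz//2."""
        return (np.arange(self.nz) - self.nz // 2) * self.dz


def pupil_grid(cfg: OpticalConfig) -> PupilGrid:
    """Pupil coordinates on the FFT frequency grid implied by ``cfg``."""
    fx = np.fft.fftfreq(cfg.nx, cfg.dx)
    fy = np.fft.fftfreq(cfg.ny, cfg.dy)
    return PupilGrid.from_frequencies(fx, fy, cfg.cutoff)


def _pupil_amplitude(cfg: OpticalConfig, grid: PupilGrid) -> np.ndarray:
    amp = grid.mask.astype(float)
    if cfg.apodization == "gaussian":
        amp = amp * np.exp(-((grid.rho / cfg.gaussian_fill) ** 2))
    return amp


def field_psf(phase: np.ndarray, cfg: OpticalConfig) -> np.ndarray:
    """Complex excitation field on the 3D grid for a given pupil phase (rad).

    ``phase`` must be sampled on ``pupil_grid(cfg)`` (FFT frequency layout).
    Returns an (nz, ny, nx) complex array with the nominal focus at the grid
    center for zero aberration.  Angular-spectrum propagation is unitary, so
    the per-plane energy is conserved.
    """
    grid = pupil_grid(cfg)
    if phase.shape != grid.rho.shape:
        raise ValueError(
            f"phase shape {phase.shape} does not match the pupil grid {grid.rho.shape}"
        )
    pupil = _pupil_amplitude(cfg, grid) * np.exp(1j * phase)
    pupil[~grid.mask] = 0.0

    fx = np.fft.fftfreq(cfg.nx, cfg.dx)
    fy = np.fft.fftfreq(cfg.ny, cfg.dy)
    fxx, fyy = np.meshgrid(fx, fy, indexing="xy")
    f2 = fxx**2 + fyy**2
    n_over_lam = cfg.immersion_index / cfg.wavelength
    kz = 2.0 * np.pi * np.sqrt(np.maximum(n_over_lam**2 - f2, 0.0))
    kz0 = 2.0 * np.pi * n_over_lam  # remove the carrier so phases stay gentle

    field = np.empty((cfg.nz, cfg.ny, cfg.nx), dtype=complex)
    for i, z in enumerate(cfg.z_axis()):
        plane = np.fft.ifft2(pupil * np.exp(1j * (kz - kz0) * z))
        field[i] = np.fft.fftshift(plane)
    return field


@dataclass
class PSF3D:
    """Normalized two-photon excitation PSF on a voxel grid.

    ``intensity`` sums to 1 over the full grid: aberrations redistribute but
    never create or destroy excitation, which is exactly the mechanism that
    lets a bright out-of-focus fluorophore bias an intensity metric.
    """

    intensity: np.ndarray  # (nz, ny, nx), non-negative, unit sum
    dx: float
    dy: float
    dz: float
    z_origin: int  # index of the nominal focal plane
    normalization: str = "unit-sum"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.intensity.ndim != 3:
            raise ValueError("PSF intensity must be 3D (nz, ny, nx)")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("PSF intensity must be finite and non-negative")

    def z_axis(self) -> np.ndarray:
        return (np.arange(self.intensity.shape[0]) - self.z_origin) * self.dz

    def save_tiff(self, path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.intensity.astype(np.float32), photometric="minisblack")
        sidecar = {
            "dx": self.dx,
            "dy": self.dy,
            "dz": self.dz,
            "z_origin": self.z_origin,
            "normalization": self.normalization,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def two_photon_psf(fld: np.ndarray, cfg: OpticalConfig) -> PSF3D:
    """Two-photon PSF: squared excitation intensity, normalized to unit sum."""
    if not np.all(np.isfinite(fld)):
        raise ValueError("field contains non-finite values")
    intensity = np.abs(fld) ** 4
    total = intensity.sum()
    if total <= 0:
        raise ValueError("field is identically zero")
    return PSF3D(
        intensity=intensity / total,
        dx=cfg.dx,
        dy=cfg.dy,
        dz=cfg.dz,
        z_origin=cfg.nz // 2,
    )


def compute_psf(coeffs: WavefrontCoeffs, cfg: OpticalConfig) -> PSF3D:
    """Aberrated two-photon PSF for a Zernike coefficient vector."""
    phi = phase_map(coeffs, pupil_grid(cfg))
    psf = two_photon_psf(field_psf(phi, cfg), cfg)
    psf.meta["coeffs"] = dict(coeffs.coeffs)
    psf.meta["wavelength"] = cfg.wavelength
    psf.meta["numerical_aperture"] = cfg.numerical_aperture
    return psf
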