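"""Virtual two-photon scanning microscope.

Images are formed plane-by-plane: the frame at stage depth z0 is
``sum_z psf_plane(z - z0) (x) sample_plane(z)`` with 2D circular (FFT)
convolution.  Circularity makes the mean image intensity depend only on the
sample's mean axial profile — the exact property that defeats the mean
intensity metric on structured samples.  Detection noise is Poisson shot
noise plus Gaussian read noise; photobleaching is an optional exponential
decay across the acquisition sequence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantoms import Sample3D
from .psf import PSF3D, OpticalConfig, compute_psf
from .zernike import WavefrontCoeffs

__all__ = [
    "ImageStack",
    "NoiseModel",
    "scan_plane",
    "scan_stack",
    "add_detection_noise",
    "apply_bleaching",
    "correct_bleaching",
    "VirtualMicroscope",
    "virtual_microscope",
]


@dataclass
class ImageStack:
    """Acquired/simulated frames at known z positions.

    ``order`` records acquisition order (for bleaching correction), which may
    differ from z order.  ``meta`` carries wavefront coefficients, seeds, etc.
    """

    frames: np.ndarray  # (n, ny, nx)
    z_positions: np.ndarray  # μm, one per frame
    order: np.ndarray | None = None  # acquisition index per frame
    dx: float = 0.4
    dy: float = 0.4
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, ny, nx)")
        if len(self.z_positions) != len(self.frames):
            raise ValueError("one z position per frame required")
        if self.order is None:
            self.order = np.arange(len(self.frames))
        self.order = np.asarray(self.order, dtype=int)
        if len(set(self.order.tolist())) != len(self.order):
            raise ValueError("acquisition order indices must be unique")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")

    def __len__(self):
        return len(self.frames)

    def mean_intensities(self) -> np.ndarray:
        return self.frames.mean(axis=(1, 2))

    def save_tiff(self, path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")
        sidecar = {
            "z_positions": self.z_positions.tolist(),
            "order": self.order.tolist(),
            "dx": self.dx,
            "dy": self.dy,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load_tiff(cls, path) -> "ImageStack":
        import tifffile

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, np.asarray(sidecar["z_positions"]),
                   order=np.asarray(sidecar["order"]),
                   dx=float(sidecar["dx"]), dy=float(sidecar["dy"]),
                   meta=sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, WavefrontCoeffs):
        return {str(j): a for j, a in obj.coeffs.items()}
    return obj


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: Poisson shot noise + Gaussian read noise (counts).

    ``photon_scale`` converts ideal image units to expected photon counts.
    """

    photon_scale: float = 1.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")


def add_detection_noise(image: np.ndarray, model: NoiseModel,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Noisy detector counts for an ideal image (deterministic per seed)."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    counts = rng.poisson(np.clip(image, 0, None) * model.photon_scale).astype(float)
    if model.read_noise_sd > 0:
        counts += rng.normal(0.0, model.read_noise_sd, size=counts.shape)
    return np.clip(counts, 0.0, None)


def _psf_plane_ffts(psf: PSF3D, shape) -> dict[int, np.ndarray]:
    """rfft2 of each PSF plane, zero-padded/centered to the frame shape.

    Keys are axial plane offsets in grid steps relative to the focal plane.
    """
    ny, nx = shape
    pnz, pny, pnx = psf.intensity.shape
    if pny > ny or pnx > nx:
        raise ValueError("PSF laterally larger than the sample frame")
    out = {}
    for k in range(pnz):
        plane = psf.intensity[k]
        if plane.max() == 0.0 and plane.min() == 0.0:
            continue
        if (pny, pnx) != (ny, nx):
            pad = np.zeros((ny, nx))
            oy, ox = (ny - pny) // 2, (nx - pnx) // 2
            pad[oy:oy + pny, ox:ox + pnx] = plane
            plane = pad
        # kernel is centered on the grid; ifftshift so convolution adds no shift
        out[k - psf.z_origin] = np.fft.rfft2(np.fft.ifftshift(plane))
    return out


def _check_steps(sample: Sample3D, psf: PSF3D):
    if not (np.isclose(sample.dx, psf.dx) and np.isclose(sample.dy, psf.dy)):
        raise ValueError("sample and PSF lateral steps differ")
    if not np.isclose(sample.dz, psf.dz):
        raise ValueError("sample and PSF axial steps differ")


def scan_plane(sample: Sample3D, psf: PSF3D, z0: float) -> np.ndarray:
    """Ideal transverse scan at stage depth ``z0`` (μm).

    z0 is snapped to the nearest axial grid step; PSF planes outside their
    computed support contribute nothing (the PSF decays there).
    """
    _check_steps(sample, psf)
    sample_f = np.fft.rfft2(sample.concentration, axes=(-2, -1))
    return _scan_plane_cached(sample_f, sample, _psf_plane_ffts(psf, sample.shape[1:]),
                              sample.shape[1:], z0)


def _scan_plane_cached(sample_f: np.ndarray, sample: Sample3D,
                       psf_f: dict[int, np.ndarray], shape, z0: float) -> np.ndarray:
    dz = sample.dz
    acc = None
    for iz, zs in enumerate(sample.z_axis()):
        # nearest psf plane; floor(+0.5) keeps half-step ties consistent
        k = int(np.floor((zs - z0) / dz + 0.5))
        pf = psf_f.get(k)
        if pf is None:
            continue
        term = pf * sample_f[iz]
        acc = term if acc is None else acc + term
    if acc is None:
        return np.zeros(shape)
    return np.clip(np.fft.irfft2(acc, s=shape), 0.0, None)


def scan_stack(sample: Sample3D, psf: PSF3D, z_list, order=None,
               meta: dict | None = None) -> ImageStack:
    """One ideal scan per depth in ``z_list``; metadata records the wavefront."""
    z_list = np.atleast_1d(np.asarray(z_list, dtype=float))
    if z_list.size == 0:
        raise ValueError("z_list must not be empty")
    _check_steps(sample, psf)
    sample_f = np.fft.rfft2(sample.concentration, axes=(-2, -1))
    psf_f = _psf_plane_ffts(psf, sample.shape[1:])
    frames = np.stack([
        _scan_plane_cached(sample_f, sample, psf_f, sample.shape[1:], z0)
        for z0 in z_list
    ])
    meta = dict(meta or {})
    meta.setdefault("coeffs", psf.meta.get("coeffs", {}))
    return ImageStack(frames, z_list, order=order, dx=sample.dx, dy=sample.dy, meta=meta)


def apply_bleaching(stack: ImageStack, rate: float) -> ImageStack:
    """Exponential photobleaching: frame with order k scaled by exp(-rate k)."""
    if rate < 0:
        raise ValueError("bleaching rate must be non-negative")
    factors = np.exp(-rate * stack.order.astype(float))
    return ImageStack(stack.frames * factors[:, None, None], stack.z_positions,
                      order=stack.order.copy(), dx=stack.dx, dy=stack.dy,
                      meta={**stack.meta, "bleach_rate": rate})


def correct_bleaching(stack: ImageStack) -> ImageStack:
    """Undo exponential intensity decay across the acquisition sequence.

    Fits frame-mean intensity vs acquisition order to A exp(-b k) (log-linear
    least squares) and divides each frame by exp(-b k).  Needs >= 3 frames;
    a failed fit falls back to no correction with a warning.
    """
    if len(stack) < 3:
        raise ValueError("bleaching correction needs at least 3 frames")
    means = stack.mean_intensities()
    if np.any(means <= 0):
        raise ValueError("bleaching fit requires positive frame means")
    k = stack.order.astype(float)
    try:
        slope, _ = np.polyfit(k, np.log(means), 1)
    except Exception:  # pragma: no cover - degenerate numerics
        warnings.warn("bleaching fit failed; returning stack uncorrected", stacklevel=2)
        return stack
    b = -slope
    corr = np.exp(b * k)
    return ImageStack(stack.frames * corr[:, None, None], stack.z_positions,
                      order=stack.order.copy(), dx=stack.dx, dy=stack.dy,
                      meta={**stack.meta, "bleach_corrected_b": float(b)})


class VirtualMicroscope:
    """Simulated microscope exposing the acquisition contract.

    ``set_wavefront`` sets the correction applied on the excitation path (a
    deformable-mirror stand-in, clamped to ``max_stroke`` per mode);
    ``acquire(z)`` returns one frame.  A hidden ``injected`` aberration
    models the sample/system aberration the optimizer must find: the PSF is
    built from injected + correction.  With ``frozen_noise=True`` the same
    noise realization is replayed on every acquisition, making closed-loop
    runs exactly reproducible; otherwise the generator advances per frame.
    """

    def __init__(self, sample: Sample3D, optics: OpticalConfig,
                 noise: NoiseModel | None = None,
                 injected: WavefrontCoeffs | None = None,
                 bleach_rate: float = 0.0,
                 max_stroke: float = 3.0,
                 frozen_noise: bool = False):
        if not (np.isclose(sample.dx, optics.dx) and np.isclose(sample.dy, optics.dy)
                and np.isclose(sample.dz, optics.dz)):
            raise ValueError("sample voxel steps must match the optical config")
        self.sample = sample
        self.optics = optics
        self.noise = noise
        self.injected = injected or WavefrontCoeffs.zero()
        self.bleach_rate = float(bleach_rate)
        self.max_stroke = float(max_stroke)
        self.frozen_noise = frozen_noise
        self.correction = WavefrontCoeffs.zero()
        self.last_clamped: list[int] = []
        self.n_acquired = 0
        self._rng = np.random.default_rng(noise.seed if noise else 0)
        self._sample_f = np.fft.rfft2(sample.concentration, axes=(-2, -1))
        self._psf_cache: dict[tuple, dict[int, np.ndarray]] = {}

    # -- acquisition contract -------------------------------------------------
    def set_wavefront(self, coeffs: WavefrontCoeffs) -> WavefrontCoeffs:
        """Apply a correction wavefront; returns the (possibly clamped) one."""
        clamped = {}
        self.last_clamped = []
        for j, a in coeffs.coeffs.items():
            if abs(a) > self.max_stroke:
                self.last_clamped.append(j)
                a = float(np.sign(a) * self.max_stroke)
            clamped[j] = a
        self.correction = WavefrontCoeffs(clamped)
        return self.correction

    def acquire(self, z: float) -> np.ndarray:
        """One transverse scan at depth z (μm), with noise and bleaching."""
        ideal = _scan_plane_cached(self._sample_f, self.sample, self._psf_ffts(),
                                   self.sample.shape[1:], z)
        if self.bleach_rate > 0:
            ideal = ideal * np.exp(-self.bleach_rate * self.n_acquired)
        self.n_acquired += 1
        if self.noise is None:
            return ideal
        rng = (np.random.default_rng(self.noise.seed) if self.frozen_noise
               else self._rng)
        return add_detection_noise(ideal, self.noise, rng)

    def acquire_stack(self, z_list, meta: dict | None = None) -> ImageStack:
        z_list = np.atleast_1d(np.asarray(z_list, dtype=float))
        if z_list.size == 0:
            raise ValueError("z_list must not be empty")
        frames = np.stack([self.acquire(z) for z in z_list])
        meta = dict(meta or {})
        meta.setdefault("correction", dict(self.correction.coeffs))
        return ImageStack(frames, z_list, dx=self.sample.dx, dy=self.sample.dy,
                          meta=meta)

    # -- internals ------------------------------------------------------------
    def _total_phase_coeffs(self) -> WavefrontCoeffs:
        return self.injected + self.correction

    def _psf_ffts(self) -> dict[int, np.ndarray]:
        total = self._total_phase_coeffs()
        key = tuple(sorted((j, round(a, 9)) for j, a in total.coeffs.items()))
        hit = self._psf_cache.get(key)
        if hit is None:
            psf = compute_psf(total, self.optics)
            hit = _psf_plane_ffts(psf, self.sample.shape[1:])
            if len(self._psf_cache) > 16:
                self._psf_cache.clear()
            self._psf_cache[key] = hit
        return hit


def virtual_microscope(sample: Sample3D, optics: OpticalConfig,
                       noise: NoiseModel | None = None, **kw) -> VirtualMicroscope:
    """Build a :class:`VirtualMicroscope` (the acquisition contract)."""
    return VirtualMicroscope(sample, optics, noise, **kw)
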