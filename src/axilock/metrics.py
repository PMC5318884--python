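"""Image-quality metrics for sensorless wavefront optimization.

Three intensity-related metrics:

* ``M1`` — mean image intensity.  Blind to transverse structure (it only
  sees the sample's mean axial profile), so it cannot lock on objects and is
  easily biased by bright out-of-focus fluorophores.
* ``M2`` — intensity variance ("sharpness").  Sensitive to structure, but
  confounded by small bright processes (dendrites) between the objects of
  interest.
* ``M3`` — variance of the band-pass-filtered image ("filtered image
  sharpness").  The band is chosen so ~10 μm somata are highlighted while
  both the smooth background (low frequencies) and fine processes/noise
  (high frequencies) are suppressed; this is the metric used for both axial
  locking and modal optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ImageStack, correct_bleaching

__all__ = [
    "BandpassSpec",
    "MetricCurve",
    "bandpass_filter",
    "metric_m1",
    "metric_m2",
    "metric_m3",
    "evaluate_metric",
    "metric_z_profile",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Difference-of-Gaussians band-pass in object space.

    Structures with characteristic scales outside [high_cut, low_cut] (μm)
    are suppressed.  The defaults highlight 10 μm neuron somata against the
    smooth background (low_cut just above the soma scale) while keeping the
    aberration-sensitive mid/high spatial frequencies (high_cut near the
    diffraction scale) — narrowing the band from above costs metric
    sensitivity faster than it gains soma selectivity.  The filter is
    applied via FFT (periodic boundaries, matching the circular imaging
    model); Gaussian sigmas are cut / (2 sqrt(2 ln 2)) so each cutoff is the
    FWHM of the corresponding smoothing kernel.
    """

    low_cut: float = 15.0  # μm: larger structures suppressed
    high_cut: float = 1.5  # μm: smaller structures suppressed
    family: str = "difference-of-gaussians"

    def __post_init__(self):
        if not (0 <= self.high_cut < self.low_cut):
            raise ValueError("need 0 <= high_cut < low_cut")

    @classmethod
    def all_pass(cls) -> "BandpassSpec":
        """Degenerate band keeping everything but the DC offset (M3 == M2)."""
        return cls(low_cut=np.inf, high_cut=0.0)


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _gauss_transfer(f2: np.ndarray, cut: float) -> np.ndarray:
    if cut == 0.0:
        return np.ones_like(f2)
    if not np.isfinite(cut):
        # infinite smoothing keeps only the DC component
        out = np.zeros_like(f2)
        out[f2 == 0.0] = 1.0
        return out
    sigma = cut / _FWHM
    return np.exp(-2.0 * np.pi**2 * sigma**2 * f2)


def bandpass_filter(image: np.ndarray, band: BandpassSpec,
                    pixel_size: float | tuple[float, float]) -> np.ndarray:
    """Band-pass an image via FFT with exact Gaussian transfer functions."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    dy, dx = (pixel_size, pixel_size) if np.isscalar(pixel_size) else pixel_size
    fy = np.fft.fftfreq(image.shape[0], dy)[:, None]
    fx = np.fft.rfftfreq(image.shape[1], dx)[None, :]
    f2 = fx**2 + fy**2
    transfer = _gauss_transfer(f2, band.high_cut) - _gauss_transfer(f2, band.low_cut)
    return np.fft.irfft2(np.fft.rfft2(image) * transfer, s=image.shape)


def metric_m1(image: np.ndarray) -> float:
    """Mean image intensity."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    return float(image.mean())


def metric_m2(image: np.ndarray) -> float:
    """Image intensity variance (population variance; sharpness metric)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    return float(image.var())


def metric_m3(image: np.ndarray, band: BandpassSpec | None = None,
              pixel_size: float | tuple[float, float] = 1.0) -> float:
    """Filtered image sharpness: variance of the band-passed image.

    Invariant to constant intensity offsets; with an all-pass band it equals
    ``metric_m2`` exactly.
    """
    band = band or BandpassSpec()
    return float(bandpass_filter(image, band, pixel_size).var())


def evaluate_metric(image: np.ndarray, metric: str,
                    band: BandpassSpec | None = None,
                    pixel_size: float | tuple[float, float] = 1.0) -> float:
    metric = metric.lower()
    if metric == "m1":
        return metric_m1(image)
    if metric == "m2":
        return metric_m2(image)
    if metric == "m3":
        return metric_m3(image, band, pixel_size)
    raise ValueError(f"unknown metric {metric!r} (expected m1, m2 or m3)")


@dataclass
class MetricCurve:
    """Metric values along z (μm) or along a mode amplitude (rad)."""

    abscissa: np.ndarray
    values: np.ndarray
    metric: str
    normalization: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.abscissa.shape != self.values.shape:
            raise ValueError("abscissa and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")

    def argmax(self) -> float:
        return float(self.abscissa[int(np.argmax(self.values))])

    def local_maxima(self, min_rel_prominence: float = 0.0):
        """Abscissas of interior local maxima, most prominent first."""
        from scipy.signal import find_peaks

        span = self.values.max() - self.values.min()
        peaks, props = find_peaks(self.values,
                                  prominence=min_rel_prominence * span if span else None)
        order = np.argsort(props["prominences"])[::-1] if len(peaks) else []
        return [float(self.abscissa[peaks[i]]) for i in order]

    def to_csv(self, path, abscissa_name: str = "z_um") -> None:
        header = f"{abscissa_name},{self.metric}[{self.normalization}]"
        np.savetxt(path, np.column_stack([self.abscissa, self.values]),
                   delimiter=",", header=header, comments="")


def metric_z_profile(stack: ImageStack, metric: str,
                     band: BandpassSpec | None = None,
                     bleach_correct: bool = False) -> MetricCurve:
    """Per-frame metric vs z, optionally bleach-corrected first."""
    if len(stack) < 2:
        raise ValueError("need at least 2 planes for a z profile")
    if bleach_correct:
        stack = correct_bleaching(stack)
    vals = [evaluate_metric(f, metric, band, (stack.dy, stack.dx))
            for f in stack.frames]
    idx = np.argsort(stack.z_positions)
    return MetricCurve(stack.z_positions[idx], np.asarray(vals)[idx], metric.lower(),
                       meta=dict(stack.meta))


def sensitivity_sweep(microscope, j: int, amplitudes, metric: str, z: float,
                      band: BandpassSpec | None = None,
                      repeats: int = 1) -> MetricCurve:
    """Metric vs amplitude of a single mode, normalized to the value at 0.

    The amplitude is applied on top of the microscope's current correction;
    the correction is restored afterwards.  With ``repeats`` > 1 the metric
    is averaged over that many acquisitions per amplitude, which tames the
    frame-to-frame scatter of noisy photon-counting images without touching
    the noise-induced bias the comparison is about.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.any(np.isclose(amplitudes, 0.0)):
        raise ValueError("amplitude sweep must include 0 for normalization")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    base = microscope.correction
    vals = []
    try:
        for a in amplitudes:
            microscope.set_wavefront(base.with_mode(j, base[j] + a))
            v = [evaluate_metric(microscope.acquire(z), metric, band,
                                 (microscope.sample.dy, microscope.sample.dx))
                 for _ in range(repeats)]
            vals.append(float(np.mean(v)))
    finally:
        microscope.set_wavefront(base)
    vals = np.asarray(vals)
    ref = vals[int(np.argmin(np.abs(amplitudes)))]
    if ref == 0:
        raise ValueError("metric vanishes at zero amplitude; cannot normalize")
    return MetricCurve(amplitudes, vals / ref, metric.lower(),
                       normalization="value-at-zero", meta={"mode": j})
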