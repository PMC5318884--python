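"""Axially-locked modal wavefront optimization (the 4N+1 scheme).

The procedure, run against any acquisition contract (simulated or real):

1. Acquire a z-stack (default 40 μm) around the region of interest with the
   current (default) wavefront and compute the filtered sharpness metric
   M3(z).
2. Lock the imaging plane at the depth z0 maximizing M3 — on an object of
   interest, typically a soma.  This is what removes the sample-dependence
   bias: subsequent modal optimization, defocus included, is centered on a
   bright structure instead of being free to stretch the focus toward one.
3. For each of the N Zernike modes (defocus included, tip/tilt never),
   probe 4 amplitudes spanning -1.5..+1.5 rad around the current
   coefficient and evaluate the metric at z0; one reference image at the
   current wavefront completes the 4N+1 image budget per iteration.
4. Update all modes at once at the end of the cycle, and iterate (default
   3 cycles) to absorb the metric couplings between Zernike modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import BandpassSpec, evaluate_metric, metric_z_profile
from .simulate import ImageStack
from .zernike import DEFAULT_MODE_SET, WavefrontCoeffs

__all__ = [
    "OptimizerConfig",
    "ModeProbe",
    "OptimizationTrace",
    "axial_lock",
    "optimize_mode",
    "run_optimization",
    "compare_correction",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the axially-locked modal optimization.

    ``probe_offsets`` are added to the current per-mode coefficient; the
    defaults place the 4 probes uniformly over the -1.5..+1.5 rad range.
    ``rule`` is "interpolated" (parabola through the best probe and its
    neighbors, vertex clamped to the probed interval) or "argmax" (best
    sampled point).
    """

    modes: tuple = DEFAULT_MODE_SET
    probe_offsets: tuple = (-1.5, -0.5, 0.5, 1.5)
    iterations: int = 3
    lock_span: float = 40.0  # μm
    lock_step: float = 0.8  # μm; matches the default axial voxel step
    metric: str = "m3"
    band: BandpassSpec = field(default_factory=BandpassSpec)
    rule: str = "interpolated"
    bleach_correct: bool = False
    flat_tol: float = 0.05  # lock fails if max/min metric ratio < 1 + this
    lock: bool = True  # False: plain fixed-depth modal optimization (the
    # biased baseline the axial locking is designed to replace)

    def __post_init__(self):
        if len(self.probe_offsets) < 2:
            raise ValueError("need at least 2 probe amplitudes per mode")
        if self.iterations < 1:
            raise ValueError("need at least 1 iteration")
        if self.lock_span <= 0 or self.lock_step <= 0:
            raise ValueError("lock span and step must be positive")
        if self.rule not in ("interpolated", "argmax"):
            raise ValueError(f"unknown maximization rule {self.rule!r}")
        if any(j in (1, 2) for j in self.modes):
            raise ValueError("tip and tilt (j=1,2) must not be optimized")


@dataclass
class ModeProbe:
    """One mode's probe record within an iteration."""

    mode: int
    amplitudes: list  # absolute coefficients probed (current + offsets)
    values: list  # metric value per probe
    reference_amplitude: float
    reference_value: float
    chosen: float


@dataclass
class OptimizationTrace:
    """Complete, replayable record of an optimization run."""

    locked_z: float
    lock_frames: int
    iterations: list = field(default_factory=list)  # list of lists of ModeProbe
    reference_values: list = field(default_factory=list)  # metric per iteration
    final_coeffs: WavefrontCoeffs = field(default_factory=WavefrontCoeffs.zero)

    @property
    def total_modal_images(self) -> int:
        """Modal-scan image count: probes x modes per iteration + references."""
        return sum(len(p.values) for it in self.iterations for p in it) + len(
            self.reference_values
        )

    @property
    def total_images(self) -> int:
        return self.total_modal_images + self.lock_frames


def _lock_z_grid(z_center: float, cfg: OptimizerConfig) -> np.ndarray:
    half = cfg.lock_span / 2.0
    n = int(round(cfg.lock_span / cfg.lock_step)) + 1
    return z_center + np.linspace(-half, half, n)


def axial_lock(microscope, z_center: float, cfg: OptimizerConfig | None = None):
    """Step 1: lock the imaging depth on the metric's axial maximum.

    Acquires the locking z-stack around ``z_center`` with the current
    wavefront, evaluates the metric per plane (bleach-corrected when
    enabled) and returns ``(z0, MetricCurve)``.  Ties break toward
    ``z_center``.  A flat profile (no structure to lock on) raises.
    """
    cfg = cfg or OptimizerConfig()
    z_grid = _lock_z_grid(z_center, cfg)
    stack = microscope.acquire_stack(z_grid, meta={"purpose": "axial-lock"})
    curve = metric_z_profile(stack, cfg.metric, cfg.band,
                             bleach_correct=cfg.bleach_correct)
    vmax, vmin = curve.values.max(), curve.values.min()
    if vmax <= 0 or (vmin > 0 and vmax / vmin < 1.0 + cfg.flat_tol):
        raise RuntimeError("no lockable structure: axial metric profile is flat")
    best = curve.values.max()
    candidates = np.flatnonzero(curve.values >= best)
    z_cand = curve.abscissa[candidates]
    z0 = float(z_cand[np.argmin(np.abs(z_cand - z_center))])
    return z0, curve


def _parabola_vertex(x: np.ndarray, y: np.ndarray):
    """Vertex of the LS parabola through (x, y); None if convex/degenerate."""
    try:
        a, b, _ = np.polyfit(x, y, 2)
    except Exception:
        return None
    if not np.isfinite(a) or a >= 0:
        return None
    return float(-b / (2.0 * a))


def _choose_coefficient(amps: np.ndarray, vals: np.ndarray, current: float,
                        rule: str) -> float:
    """Maximizing coefficient from probed (amplitude, metric) samples.

    ``amps``/``vals`` include the reference point at ``current``.  A flat
    response returns ``current`` unchanged; the result never leaves the
    probed interval.
    """
    if np.allclose(vals, vals[0], rtol=1e-12, atol=0.0):
        return float(current)
    order = np.argsort(amps)
    amps, vals = amps[order], vals[order]
    i_best = int(np.argmax(vals))
    best = float(amps[i_best])
    if rule == "argmax":
        return best
    # interpolated: parabola through the best sample and its nearest
    # neighbors (local fit is far less biased than one through all probes
    # when the peak sits off-center in the probed range)
    lo, hi = max(i_best - 1, 0), min(i_best + 1, len(amps) - 1)
    if hi - lo < 2:  # peak at the edge: widen inward
        lo, hi = (0, 2) if i_best <= 1 else (len(amps) - 3, len(amps) - 1)
    vertex = _parabola_vertex(amps[lo:hi + 1], vals[lo:hi + 1])
    if vertex is None:
        return best
    return float(np.clip(vertex, amps[0], amps[-1]))


def optimize_mode(microscope, j: int, current: WavefrontCoeffs, z0: float,
                  cfg: OptimizerConfig, reference_value: float | None = None) -> ModeProbe:
    """Step 4 for one mode: probe amplitudes around the current coefficient.

    Returns the probe record including the chosen (metric-maximizing)
    coefficient for mode ``j``.  The wavefront is restored to ``current``
    before returning.
    """
    pixel = (microscope.sample.dy, microscope.sample.dx)
    if reference_value is None:
        microscope.set_wavefront(current)
        reference_value = evaluate_metric(microscope.acquire(z0), cfg.metric,
                                          cfg.band, pixel)
    c0 = current[j]
    amps, vals = [], []
    try:
        for off in cfg.probe_offsets:
            microscope.set_wavefront(current.with_mode(j, c0 + off))
            v = evaluate_metric(microscope.acquire(z0), cfg.metric, cfg.band, pixel)
            amps.append(c0 + off)
            vals.append(v)
    finally:
        microscope.set_wavefront(current)
    all_amps = np.array(amps + [c0])
    all_vals = np.array(vals + [reference_value])
    if np.all(all_vals <= 0):
        warnings.warn(f"mode {j}: all probe images empty; coefficient unchanged",
                      stacklevel=2)
        chosen = c0
    else:
        chosen = _choose_coefficient(all_amps, all_vals, c0, cfg.rule)
    return ModeProbe(mode=j, amplitudes=amps, values=vals,
                     reference_amplitude=c0, reference_value=float(reference_value),
                     chosen=float(chosen))


def run_optimization(microscope, z_center: float,
                     cfg: OptimizerConfig | None = None,
                     initial: WavefrontCoeffs | None = None):
    """The full axially-locked modal optimization.

    Locks once, then runs ``cfg.iterations`` cycles; within a cycle every
    mode is probed against the same current wavefront (one reference image
    per cycle) and the wavefront is updated with all chosen coefficients at
    the cycle's end.  Returns ``(final_coeffs, OptimizationTrace)``.
    """
    cfg = cfg or OptimizerConfig()
    current = initial or microscope.correction
    microscope.set_wavefront(current)
    if cfg.lock:
        z0, lock_curve = axial_lock(microscope, z_center, cfg)
        trace = OptimizationTrace(locked_z=z0, lock_frames=len(lock_curve.values))
    else:
        z0 = z_center
        trace = OptimizationTrace(locked_z=z0, lock_frames=0)
    pixel = (microscope.sample.dy, microscope.sample.dx)

    for _ in range(cfg.iterations):
        microscope.set_wavefront(current)
        ref = evaluate_metric(microscope.acquire(z0), cfg.metric, cfg.band, pixel)
        trace.reference_values.append(float(ref))
        probes = [optimize_mode(microscope, j, current, z0, cfg, reference_value=ref)
                  for j in cfg.modes]
        trace.iterations.append(probes)
        # batch wavefront update (procedure step 5); track the clamped
        # wavefront the hardware actually applies
        for p in probes:
            current = current.with_mode(p.mode, p.chosen)
        current = microscope.set_wavefront(current)
    microscope.set_wavefront(current)
    trace.final_coeffs = current
    return current, trace


def compare_correction(microscope, coeffs_before: WavefrontCoeffs,
                       coeffs_after: WavefrontCoeffs, z_list) -> tuple[ImageStack, ImageStack]:
    """Step 7: image the FOV with and without the final correction.

    Both stacks cover the same depths; each stack's metadata carries both
    coefficient sets.
    """
    stacks = []
    saved = microscope.correction
    try:
        for tag, coeffs in (("before", coeffs_before), ("after", coeffs_after)):
            microscope.set_wavefront(coeffs)
            stacks.append(microscope.acquire_stack(
                z_list,
                meta={"role": tag,
                      "coeffs_before": dict(coeffs_before.coeffs),
                      "coeffs_after": dict(coeffs_after.coeffs)}))
    finally:
        microscope.set_wavefront(saved)
    return stacks[0], stacks[1]
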