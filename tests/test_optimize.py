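"""Axially-locked modal optimizer: locking, probing, closed-loop recovery."""

import numpy as np
import pytest

from axilock.optimize import (
    OptimizerConfig,
    axial_lock,
    compare_correction,
    optimize_mode,
    run_optimization,
)
from axilock.phantoms import Sample3D, make_bead
from axilock.simulate import VirtualMicroscope
from axilock.zernike import DEFAULT_MODE_SET, WavefrontCoeffs


@pytest.fixture(scope="module")
def bead_mic(grid, optics, bead_in_focus):
    return VirtualMicroscope(bead_in_focus, optics)


def test_config_validation():
    with pytest.raises(ValueError):
        OptimizerConfig(iterations=0)
    with pytest.raises(ValueError):
        OptimizerConfig(modes=(1, 4, 5))  # tip must never be optimized
    with pytest.raises(ValueError):
        OptimizerConfig(probe_offsets=(0.5,))


def test_axial_lock_finds_displaced_bead(grid, optics):
    bead = make_bead(10.0, center=(0.0, 0.0, 5.0), grid=grid)
    mic = VirtualMicroscope(bead, optics)
    z0, curve = axial_lock(mic, 0.0, OptimizerConfig())
    assert z0 == pytest.approx(5.0, abs=0.8)
    assert len(curve.values) == 51  # 40 μm span at the 0.8 μm axial step


def test_axial_lock_on_slab_avoids_mid_depth(grid, optics, slab):
    mic = VirtualMicroscope(slab, optics)
    z0, _ = axial_lock(mic, 0.0, OptimizerConfig())
    assert min(abs(z0 - 8.0), abs(z0 + 8.0)) <= 2.0
    assert abs(z0) > 2.0


def test_axial_lock_rejects_empty_sample(grid, optics):
    empty = Sample3D(np.zeros((grid.nz, grid.ny, grid.nx)),
                     grid.dx, grid.dy, grid.dz)
    mic = VirtualMicroscope(empty, optics)
    with pytest.raises(RuntimeError, match="no lockable structure"):
        axial_lock(mic, 0.0, OptimizerConfig())


@pytest.mark.parametrize("mode, injected", [
    (8, -0.8), (12, 0.6), (4, -1.0), (5, 1.2), (3, 0.0),
])
def test_single_mode_recovery(grid, optics, bead_in_focus, mode, injected):
    """One probe cycle recovers a single-mode injection within 0.15 rad."""
    mic = VirtualMicroscope(bead_in_focus, optics,
                            injected=WavefrontCoeffs({mode: injected}))
    probe = optimize_mode(mic, mode, WavefrontCoeffs.zero(), 0.0,
                          OptimizerConfig())
    assert probe.chosen == pytest.approx(-injected, abs=0.15)


def test_flat_metric_keeps_current_coefficient(grid, optics):
    uniform = Sample3D(np.ones((grid.nz, grid.ny, grid.nx)),
                       grid.dx, grid.dy, grid.dz)
    mic = VirtualMicroscope(uniform, optics)
    probe = optimize_mode(mic, 5, WavefrontCoeffs({5: 0.3}), 0.0,
                          OptimizerConfig(metric="m1"))
    assert probe.chosen == pytest.approx(0.3)


def test_image_budget_is_4n_plus_1(bead_mic):
    """3 iterations x (4 probes x 8 modes + 1 reference) = 99 images."""
    final, trace = run_optimization(bead_mic, 0.0, OptimizerConfig())
    assert trace.total_modal_images == 99
    per_iter = [len(it) for it in trace.iterations]
    assert per_iter == [8, 8, 8]
    assert all(len(p.values) == 4 for it in trace.iterations for p in it)
    assert len(trace.reference_values) == 3
    # null case: no spurious correction on an unaberrated bead
    assert final.rms() < 0.1


def test_metric_non_decreasing_across_iterations(grid, optics, slab):
    inj = WavefrontCoeffs({5: 0.7, 8: -0.5, 12: 0.4})
    mic = VirtualMicroscope(slab, optics, injected=inj)
    _, trace = run_optimization(mic, 0.0, OptimizerConfig())
    refs = trace.reference_values
    assert all(b >= a * (1 - 1e-6) for a, b in zip(refs, refs[1:]))


def test_closed_loop_recovers_multimode_aberration(grid, optics, slab):
    """RMS-1.0 injection over the 8 default modes: non-displacement modes
    recover below 0.15 rad; the defocus component is bounded refocusing."""
    rng = np.random.default_rng(3)
    v = rng.normal(size=8)
    v *= 1.0 / np.linalg.norm(v)
    inj = WavefrontCoeffs(dict(zip(DEFAULT_MODE_SET, v)))
    mic = VirtualMicroscope(slab, optics, injected=inj)
    final, trace = run_optimization(mic, 0.0, OptimizerConfig())
    residual = inj + final
    assert residual.rms(exclude=(0, 4)) < 0.15
    assert abs(residual[4]) * 1.6 <= 2.0  # equivalent focal shift, μm


def test_axial_locking_avoids_out_of_focus_bias(grid, optics):
    """The headline mechanism: a bright bead 12 μm out of focus drags a
    fixed-depth mean-intensity optimization to a strongly aberrated
    wavefront, while locking first makes the optimization return ~zero."""
    bead = make_bead(10.0, center=(0.0, 0.0, 12.0), grid=grid)

    mic = VirtualMicroscope(bead, optics)
    biased, _ = run_optimization(mic, 0.0, OptimizerConfig(metric="m1", lock=False))
    assert biased.rms() > 0.5

    mic = VirtualMicroscope(bead, optics)
    corrected, trace = run_optimization(mic, 0.0, OptimizerConfig())
    assert trace.locked_z == pytest.approx(12.0, abs=0.8)
    assert corrected.rms() < 0.15


def test_compare_correction_stacks(grid, optics):
    bead = make_bead(10.0, grid=grid)
    inj = WavefrontCoeffs({8: 1.0})
    mic = VirtualMicroscope(bead, optics, injected=inj)
    recovered = WavefrontCoeffs({8: -1.0})
    z = np.arange(-8.0, 8.1, 0.8)
    before, after = compare_correction(mic, WavefrontCoeffs.zero(), recovered, z)
    assert after.frames.max() > before.frames.max()
    assert before.meta["coeffs_after"] == {8: -1.0}
    same_a, same_b = compare_correction(mic, recovered, recovered, z)
    assert np.array_equal(same_a.frames, same_b.frames)
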