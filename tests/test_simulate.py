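"""Imaging model: convolution identities, noise, bleaching, the contract."""

import numpy as np
import pytest

from axilock.phantoms import Sample3D, make_bead
from axilock.simulate import (
    ImageStack,
    NoiseModel,
    VirtualMicroscope,
    add_detection_noise,
    apply_bleaching,
    correct_bleaching,
    scan_plane,
    scan_stack,
)
from axilock.zernike import WavefrontCoeffs


def _point_sample(grid, value=1.0):
    vol = np.zeros((grid.nz, grid.ny, grid.nx))
    vol[grid.nz // 2, grid.ny // 2, grid.nx // 2] = value
    return Sample3D(vol, grid.dx, grid.dy, grid.dz)


def test_point_sample_images_the_psf_plane(grid, psf0):
    image = scan_plane(_point_sample(grid), psf0, 0.0)
    focal = psf0.intensity[psf0.z_origin]
    assert np.allclose(image, focal, atol=1e-12 * focal.max())


def test_uniform_volume_gives_constant_image(grid, optics):
    from axilock.psf import compute_psf

    uniform = Sample3D(np.ones((grid.nz, grid.ny, grid.nx)),
                       grid.dx, grid.dy, grid.dz)
    psf_ab = compute_psf(WavefrontCoeffs({8: 1.2}), optics)
    image = scan_plane(uniform, psf_ab, 0.0)
    assert np.ptp(image) < 1e-12 * image.mean()


def test_lateral_shift_equivariance(grid, psf0, bead_in_focus):
    base = scan_plane(bead_in_focus, psf0, 0.0)
    rolled_sample = Sample3D(np.roll(bead_in_focus.concentration, 7, axis=2),
                             grid.dx, grid.dy, grid.dz)
    shifted = scan_plane(rolled_sample, psf0, 0.0)
    assert np.allclose(shifted, np.roll(base, 7, axis=1), atol=1e-12 * base.max())


def test_scan_is_linear_in_the_sample(grid, psf0, bead_in_focus, slab):
    mix = Sample3D(2.0 * bead_in_focus.concentration + 0.5 * slab.concentration,
                   grid.dx, grid.dy, grid.dz)
    lhs = scan_plane(mix, psf0, -4.0)
    rhs = (2.0 * scan_plane(bead_in_focus, psf0, -4.0)
           + 0.5 * scan_plane(slab, psf0, -4.0))
    assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-14)


def test_mean_intensity_ignores_transverse_structure(grid, psf0, slab):
    """Scrambling each sample plane transversely leaves the image mean
    invariant (circular convolution) while sharpness metrics change."""
    rng = np.random.default_rng(0)
    scrambled = np.stack([
        plane.ravel()[rng.permutation(plane.size)].reshape(plane.shape)
        for plane in slab.concentration
    ])
    scrambled = Sample3D(scrambled, grid.dx, grid.dy, grid.dz)
    img_orig = scan_plane(slab, psf0, -8.0)
    img_scr = scan_plane(scrambled, psf0, -8.0)
    assert img_scr.mean() == pytest.approx(img_orig.mean(), rel=1e-12)
    assert img_scr.var() != pytest.approx(img_orig.var(), rel=0.01)


def test_scan_stack_shapes_and_order(grid, psf0, bead_in_focus):
    z = np.arange(-20.0, 20.0 + 1e-9, 1.0 + 0.0)  # 40 μm span
    z = np.arange(41) * 1.0 - 20.0
    stack = scan_stack(bead_in_focus, psf0, z[::-1], order=np.arange(41))
    assert len(stack) == 41
    assert np.array_equal(stack.order, np.arange(41))
    single = scan_stack(bead_in_focus, psf0, [0.0])
    assert np.allclose(single.frames[0], scan_plane(bead_in_focus, psf0, 0.0))
    with pytest.raises(ValueError):
        scan_stack(bead_in_focus, psf0, [])


def test_noise_deterministic_and_unbiased():
    ideal = np.full((64, 64), 5.0)
    model = NoiseModel(photon_scale=1e5, read_noise_sd=0.0, seed=42)
    a = add_detection_noise(ideal, model)
    b = add_detection_noise(ideal, model)
    assert np.array_equal(a, b)
    # relative deviation shrinks as photon_scale grows (3 sigma bound)
    rel = abs(a.mean() / 1e5 - 5.0) / 5.0
    assert rel < 3.0 / np.sqrt(5.0 * 1e5 * 64 * 64)
    assert not add_detection_noise(np.zeros((8, 8)), model).any()


def test_bleaching_roundtrip(grid, psf0, bead_in_focus):
    z = np.arange(-9.6, 9.7, 0.8)  # symmetric, on the axial voxel grid
    stack = scan_stack(bead_in_focus, psf0, z)
    bleached = apply_bleaching(stack, 0.01)
    assert np.allclose(apply_bleaching(stack, 0.0).frames, stack.frames)
    corrected = correct_bleaching(bleached)
    assert np.allclose(corrected.mean_intensities(), stack.mean_intensities(),
                       rtol=0.01)
    with pytest.raises(ValueError, match="at least 3"):
        correct_bleaching(ImageStack(stack.frames[:2], z[:2]))


def test_stack_requires_consistent_metadata():
    frames = np.zeros((3, 4, 4))
    with pytest.raises(ValueError):
        ImageStack(frames, [0.0, 1.0])  # z count mismatch
    with pytest.raises(ValueError):
        ImageStack(frames, [0.0, 1.0, 2.0], order=[0, 0, 1])


def test_microscope_contract(grid, optics, bead_in_focus):
    mic = VirtualMicroscope(bead_in_focus, optics,
                            noise=NoiseModel(photon_scale=100.0, seed=1),
                            frozen_noise=True)
    applied = mic.set_wavefront(WavefrontCoeffs({5: 10.0}))
    assert applied[5] == pytest.approx(mic.max_stroke)
    assert mic.last_clamped == [5]
    mic.set_wavefront(WavefrontCoeffs.zero())
    a = mic.acquire(0.0)
    b = mic.acquire(0.0)
    assert np.array_equal(a, b)  # frozen noise replays exactly


def test_microscope_brightest_at_bead_depth(grid, optics):
    bead = make_bead(10.0, center=(0.0, 0.0, 4.8), grid=grid)
    mic = VirtualMicroscope(bead, optics)
    z = np.arange(-9.6, 9.7, 0.8)
    sweep = [mic.acquire(zq).max() for zq in z]
    assert z[int(np.argmax(sweep))] == pytest.approx(4.8, abs=0.8)


def test_stack_tiff_roundtrip(tmp_path, grid, psf0, bead_in_focus):
    stack = scan_stack(bead_in_focus, psf0, [-2.0, 0.0, 2.0])
    path = tmp_path / "stack.tif"
    stack.save_tiff(path)
    loaded = ImageStack.load_tiff(path)
    assert np.allclose(loaded.frames, stack.frames, atol=1e-6 * stack.frames.max())
    assert np.array_equal(loaded.z_positions, stack.z_positions)
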