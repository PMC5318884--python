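"""The three metrics: identities, filtering, axial profiles, sensitivity."""

import numpy as np
import pytest

from axilock.metrics import (
    BandpassSpec,
    MetricCurve,
    bandpass_filter,
    metric_m1,
    metric_m2,
    metric_m3,
    metric_z_profile,
    sensitivity_sweep,
)
from axilock.simulate import scan_stack


def test_m1_m2_basic_identities():
    rng = np.random.default_rng(0)
    img = rng.random((32, 32))
    assert metric_m1(np.full((8, 8), 3.7)) == pytest.approx(3.7)
    assert metric_m1(2.0 * img) == pytest.approx(2.0 * metric_m1(img))
    assert metric_m2(np.full((8, 8), 3.7)) == pytest.approx(0.0, abs=1e-24)
    assert metric_m2(3.0 * img) == pytest.approx(9.0 * metric_m2(img))
    # population-variance identity: M2 = mean(img^2) - mean(img)^2
    assert metric_m2(img) == pytest.approx(metric_m1(img**2) - metric_m1(img) ** 2,
                                           rel=1e-12)


def test_m3_offset_invariance_and_allpass():
    rng = np.random.default_rng(1)
    img = rng.random((64, 64))
    band = BandpassSpec()
    assert metric_m3(np.full((16, 16), 2.0), band, 0.4) == pytest.approx(0.0, abs=1e-20)
    assert metric_m3(img + 5.0, band, 0.4) == pytest.approx(
        metric_m3(img, band, 0.4), rel=1e-9)
    # an all-pass band reduces M3 to M2 exactly
    assert metric_m3(img, BandpassSpec.all_pass(), 0.4) == pytest.approx(
        metric_m2(img), rel=1e-12)


def test_band_validation():
    with pytest.raises(ValueError):
        BandpassSpec(low_cut=2.0, high_cut=4.0)
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros((0, 0)), BandpassSpec(), 0.4)


def test_bandpass_suppresses_out_of_band_scales():
    """A 2 px structure passes a 1.5-15 μm band; a 100 px ramp mostly not."""
    x = np.arange(128) * 0.4
    fine = np.sin(2 * np.pi * x / 5.0)[None, :] * np.ones((128, 1))  # 5 μm period
    coarse = np.sin(2 * np.pi * x / 51.2)[None, :] * np.ones((128, 1))
    sub = np.sin(2 * np.pi * x / 0.9)[None, :] * np.ones((128, 1))  # sub-μm
    band = BandpassSpec()
    keep = bandpass_filter(fine, band, 0.4).std() / fine.std()
    kill_lo = bandpass_filter(coarse, band, 0.4).std() / coarse.std()
    kill_hi = bandpass_filter(sub, band, 0.4).std() / sub.std()
    assert keep > 0.6
    assert kill_lo < 0.35
    assert kill_hi < 0.35


def test_bead_z_profile_single_peak(grid, psf0, bead_in_focus):
    z = np.arange(-12.0, 12.1, 0.8)
    stack = scan_stack(bead_in_focus, psf0, z)
    curve = metric_z_profile(stack, "m1")
    assert curve.argmax() == pytest.approx(0.0, abs=0.8)
    assert len(curve.local_maxima(0.05)) == 1


def test_slab_profiles_reproduce_metric_behaviors(slab_stack):
    """M3 localizes both somata; M1 does not; M2 sees the dendrite layer."""
    m3 = metric_z_profile(slab_stack, "m3", BandpassSpec())
    top2 = sorted(m3.local_maxima(0.05)[:2])
    assert len(top2) == 2
    assert top2[0] == pytest.approx(-8.0, abs=2.0)
    assert top2[1] == pytest.approx(8.0, abs=2.0)

    m1 = metric_z_profile(slab_stack, "m1")
    m1_top2 = sorted(m1.local_maxima(0.05)[:2])
    m1_separates = (len(m1_top2) == 2
                    and abs(m1_top2[0] + 8.0) <= 2.0
                    and abs(m1_top2[1] - 8.0) <= 2.0)
    assert not m1_separates

    m2 = metric_z_profile(slab_stack, "m2")
    # dendrite confound: an extra local maximum between the somata
    between = [t for t in m2.local_maxima(0.03) if -5.0 < t < 5.0]
    assert between


def test_metric_curve_validation():
    with pytest.raises(ValueError):
        MetricCurve([0.0, 1.0], [1.0], "m1")
    with pytest.raises(ValueError):
        MetricCurve([0.0], [np.nan], "m1")


def test_sensitivity_normalized_at_zero(grid, optics, bead_in_focus):
    from axilock.simulate import VirtualMicroscope

    mic = VirtualMicroscope(bead_in_focus, optics)
    curve = sensitivity_sweep(mic, 12, [-1.0, 0.0, 1.0], "m3", z=0.0)
    assert curve.values[1] == pytest.approx(1.0)
    assert curve.values[0] < 1.0 and curve.values[2] < 1.0
    with pytest.raises(ValueError, match="include 0"):
        sensitivity_sweep(mic, 12, [0.5, 1.0], "m3", z=0.0)


def test_in_focus_bead_metrics_peak_at_zero(grid, optics, bead_in_focus):
    """All three metrics are maximal at zero aberration on a centered bead."""
    from axilock.psf import compute_psf
    from axilock.zernike import WavefrontCoeffs
    from axilock.metrics import evaluate_metric

    amps = np.arange(-1.5, 1.51, 0.75)
    for mode in (8, 12):
        vals = {m: [] for m in ("m1", "m2", "m3")}
        for a in amps:
            psf = compute_psf(WavefrontCoeffs({mode: a}), optics)
            frame = scan_stack(bead_in_focus, psf, [0.0]).frames[0]
            for m in vals:
                vals[m].append(evaluate_metric(frame, m, BandpassSpec(), 0.4))
        for m, v in vals.items():
            assert amps[int(np.argmax(v))] == 0.0, (mode, m)
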