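import dataclasses

import numpy as np
import pytest

from octmac.io import OCTVolume
from octmac.phantom import PhantomSpec, generate_phantom
from octmac.segmentation import BRIGHT_TO_DARK, DARK_TO_BRIGHT, \
    SegmentationConfig, SegmentationError, compute_surface_cost, qc_surfaces, \
    segment_retina
from octmac.surfaces import SurfaceOrderError, SurfaceSet


def _column(values):
    return np.asarray(values, dtype=float)[None, None, :]


def test_cost_minimum_at_step_for_matching_polarity():
    col = _column([0, 0, 0, 0, 0, 100, 100])
    c = compute_surface_cost(col, DARK_TO_BRIGHT).values[0, 0]
    assert c.argmin() == 5  # first voxel of the bright band
    c2 = compute_surface_cost(col, BRIGHT_TO_DARK).values[0, 0]
    assert c2[5] >= 0.5  # opposite polarity: the step is high-cost there
    assert c2.argmin() != 5


def test_constant_column_has_flat_cost():
    c = compute_surface_cost(_column([7.0] * 10), DARK_TO_BRIGHT).values
    assert np.allclose(c, c.flat[0])


def test_degenerate_depth_rejected():
    with pytest.raises(ValueError):
        compute_surface_cost(np.zeros((4, 2, 2)), DARK_TO_BRIGHT)


def test_noiseless_phantom_recovered_exactly():
    # 128-depth grid: the coarsest where every band is >= 2 voxels thick
    spec = PhantomSpec(shape=(64, 16, 128), speckle_shape=0.0, floor_sd=0.0,
                       axial_blur_sigma=0.0, modulate=False)
    vol, truth = generate_phantom(spec, seed=0)
    ss = segment_retina(vol)
    assert np.array_equal(ss.z, truth.z)


def test_speckle_phantom_recovered_within_a_voxel(small_spec):
    vol, truth = generate_phantom(small_spec, seed=1)
    ss = segment_retina(vol)
    mae = np.abs(ss.z.astype(int) - truth.z.astype(int)).mean(axis=(1, 2))
    assert (mae <= 1.2).all()  # small-grid unit check; the acceptance test
    # runs the full-scale criterion


def test_recovery_degrades_gracefully_with_speckle(small_spec):
    """Mean surface error is monotone (within tolerance) in the noise level."""
    maes = []
    for k in (0.0, 160.0, 40.0, 10.0)[::-1]:  # k down = noise up
        spec = dataclasses.replace(small_spec, speckle_shape=k)
        vol, truth = generate_phantom(spec, seed=2)
        ss = segment_retina(vol)
        maes.append(np.abs(ss.z.astype(int) - truth.z.astype(int)).mean())
    assert maes[-1] <= maes[-2] <= maes[0] + 0.05  # k=inf..10 ordering, small slack


def test_pure_noise_volume_fails_or_is_flagged():
    rng = np.random.default_rng(3)
    vol = OCTVolume(rng.integers(0, 65536, (32, 8, 64), dtype=np.uint16),
                    dx_mm=6 / 32, dy_mm=6 / 8)
    try:
        ss = segment_retina(vol)
    except SegmentationError:
        return  # explicit failure is acceptable
    ss.validate(64, min_separation=1)  # never a silently crossing set
    report = qc_surfaces(ss, vol)
    assert not report.ok


def test_returned_surfaces_satisfy_smoothness(small_spec):
    vol, _ = generate_phantom(small_spec, seed=4)
    cfg = SegmentationConfig()
    ss = segment_retina(vol, cfg)
    assert np.abs(np.diff(ss.z, axis=1)).max() <= cfg.dx
    assert np.abs(np.diff(ss.z, axis=2)).max() <= cfg.dy


def test_surface_set_ordering_enforced():
    z = np.arange(11)[:, None, None] * 4 + np.zeros((11, 4, 2), dtype=int) + 5
    z[5] = z[4]  # zero separation between S5 and S6
    with pytest.raises(SurfaceOrderError, match="S5"):
        SurfaceSet(z).validate(64, min_separation=1)


# -- QC proxy ---------------------------------------------------------------


def test_qc_passes_ground_truth(clean_small_spec):
    vol, truth = generate_phantom(clean_small_spec, seed=6)
    assert qc_surfaces(truth, vol).ok


def test_qc_flags_zero_thickness_bscan(clean_small_spec):
    vol, truth = generate_phantom(clean_small_spec, seed=7)
    z = truth.z.copy()
    z[1, :, 3] = z[2, :, 3]  # GCL collapses on B-scan 3
    report = qc_surfaces(SurfaceSet(z), vol)
    assert not report.ok
    assert any(y == 3 and "GCL" in reason for y, reason in report.flags)


def test_qc_flags_gross_boundary_errors_at_cohort_rate(clean_small_spec):
    """With ~5% of volumes carrying gross boundary errors, at least 90% of the
    corrupted ones are flagged (and clean ones pass)."""
    rng = np.random.default_rng(8)
    vol, truth = generate_phantom(clean_small_spec, seed=8)
    n, corrupted, caught, false_alarm = 36, 0, 0, 0
    for i in range(n):
        z = truth.z.copy()
        bad = rng.random() < 0.055
        if bad:
            corrupted += 1
            y = int(rng.integers(0, z.shape[2]))
            s = int(rng.integers(1, 10))
            z[s:, :, y] += 15  # a gross mis-identification on one B-scan
            z = np.minimum(z, clean_small_spec.shape[2] - 1)
        report = qc_surfaces(SurfaceSet(z), vol)
        if bad and not report.ok:
            caught += 1
        if not bad and not report.ok:
            false_alarm += 1
    assert corrupted > 0
    assert caught >= 0.9 * corrupted
    assert false_alarm == 0
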