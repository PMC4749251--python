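import dataclasses

import numpy as np
import pytest

from octmac.layers import BAND_NAMES, LAYER_NAMES
from octmac.phantom import PhantomSpec, RescanJitter, SpecificationError, \
    generate_phantom, generate_rescan_pair, spec_with_layer_means


def test_noiseless_flat_phantom_has_constant_bands():
    """With no pit, noise or modulation, voxels between surface pairs equal
    the per-band constants exactly (constant layers at the normative means)."""
    spec = PhantomSpec(shape=(16, 4, 64), pit_depth_frac=0.0, dome_sag_frac=0.0,
                       speckle_shape=0.0, floor_sd=0.0, axial_blur_sigma=0.0,
                       modulate=False)
    vol, truth = generate_phantom(spec, seed=0)
    for b, name in enumerate(BAND_NAMES):
        lo = truth.z[b, 0, 0]
        hi = truth.z[b + 1, 0, 0]
        band = vol.voxels[:, :, lo:hi]
        assert (band == round(spec.band_au[name])).all(), name
    # spot-check the three layers pinned to the normative profile
    assert round(spec.band_au["RNFL"]) == 31559
    assert round(spec.band_au["ONL"]) == 21382
    assert round(spec.band_au["RPE"]) == 34677


def test_determinism_same_seed_same_volume(small_spec):
    va, _ = generate_phantom(small_spec, seed=42)
    vb, _ = generate_phantom(small_spec, seed=42)
    assert np.array_equal(va.voxels, vb.voxels)
    vc, _ = generate_phantom(small_spec, seed=43)
    assert not np.array_equal(va.voxels, vc.voxels)


def test_truth_surfaces_ordered_and_in_range(small_spec):
    _, truth = generate_phantom(small_spec, seed=1)
    truth.validate(small_spec.shape[2], min_separation=1)
    assert truth.z.min() >= 0 and truth.z.max() < small_spec.shape[2]


def test_speckle_is_mean_preserving():
    """Per-band sample mean over >= 1e5 voxels within 1% of the base value."""
    spec = PhantomSpec(shape=(128, 32, 256), pit_depth_frac=0.0, dome_sag_frac=0.0,
                       axial_blur_sigma=0.0, modulate=False, floor_sd=0.0)
    vol, truth = generate_phantom(spec, seed=7)
    lo = truth.z[5, 0, 0]
    hi = truth.z[6, 0, 0]  # ONL band, 10 voxels deep here
    band = vol.voxels[:, :, lo:hi].astype(float)
    assert band.size >= 1e4
    assert abs(band.mean() / spec.band_au["ONL"] - 1) < 0.01
    # pool several bands to pass the 1e5-voxel mark
    total, expect = [], []
    for b, name in enumerate(BAND_NAMES):
        sl = vol.voxels[:, :, truth.z[b, 0, 0]:truth.z[b + 1, 0, 0]].astype(float)
        total.append(sl.ravel())
        expect.append(np.full(sl.size, spec.band_au[name]))
    total = np.concatenate(total)
    expect = np.concatenate(expect)
    assert total.size >= 1e5
    assert abs(total.mean() / expect.mean() - 1) < 0.01


def test_invalid_dims_rejected():
    with pytest.raises(SpecificationError):
        PhantomSpec(shape=(4, 1, 8))


def test_crossing_surfaces_named():
    spec = PhantomSpec(shape=(32, 8, 64), pit_depth_frac=3.0)  # pit deeper than the stack
    with pytest.raises(SpecificationError, match=r"S\d+"):
        spec.truth_surfaces()


def test_intensity_out_of_range_rejected():
    with pytest.raises(SpecificationError):
        PhantomSpec(band_au={**PhantomSpec().band_au, "RPE": 70000.0})


def test_zero_jitter_rescan_differs_only_in_speckle(small_spec):
    jit = RescanJitter(gain_sd=0.0, shift_cols_sd=0.0, shift_bscans_sd=0.0)
    va, vb = generate_rescan_pair(small_spec, jit, seed=3)
    assert not np.array_equal(va.voxels, vb.voxels)  # fresh speckle
    # same anatomy: the noiseless renders coincide
    clean = dataclasses.replace(small_spec, speckle_shape=0.0, floor_sd=0.0)
    ca, cb = generate_rescan_pair(clean, jit, seed=3)
    assert np.array_equal(ca.voxels, cb.voxels)


def test_rescan_lateral_shift_moves_the_pit():
    spec = PhantomSpec(shape=(64, 16, 128), speckle_shape=0.0, floor_sd=0.0,
                       axial_blur_sigma=0.0)
    jit = RescanJitter(gain_sd=0.0, shift_cols_sd=30.0, shift_bscans_sd=0.0)
    from octmac.etdrs import locate_fovea
    from octmac.segmentation import segment_retina

    for seed in range(6):  # the integer shift can draw 0; try a few seeds
        va, vb = generate_rescan_pair(spec, jit, seed=seed)
        ca = locate_fovea(segment_retina(va).z[0])
        cb = locate_fovea(segment_retina(vb).z[0])
        if abs(ca[0] - cb[0]) >= 1:
            return  # the recenter jitter is visible downstream
    raise AssertionError("no lateral shift materialized in 6 seeds")


def test_spec_with_layer_means_moves_every_layer():
    spec = PhantomSpec()
    targets = {layer: 25000.0 for layer in LAYER_NAMES}
    scaled = spec_with_layer_means(spec, targets)
    got = scaled.expected_layer_means()
    for layer in LAYER_NAMES:
        assert got[layer] == pytest.approx(25000.0)
    # photoreceptor sub-band contrast is preserved under rescaling
    assert scaled.band_au["EZ"] / scaled.band_au["IS"] == pytest.approx(
        spec.band_au["EZ"] / spec.band_au["IS"])
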