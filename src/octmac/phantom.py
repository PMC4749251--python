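"""Synthetic macular OCT phantoms with known ground truth.

The phantom emulates the structure the measurement pipeline must recover from
a real 6x6 mm macular raster: eight stacked retinal layers (ten tissue bands
between eleven surfaces) with a foveal pit, per-layer mean intensities on the
16-bit AU scale, a regional intensity pattern (central depression or elevation
and a nasal-temporal gradient per layer), multiplicative speckle, an axial
point-spread blur, and an operator-rescan variability model.

Default per-layer intensities follow the normative macular profile of healthy
adult eyes on the 16-bit Topcon export scale (RPE brightest at ~34677 AU, ONL
darkest at ~21382 AU); the regional modulation encodes the observed
nasal > temporal pattern for RNFL/GCL, the reverse for ONL/photoreceptor/RPE,
and the central depression of all layers except RPE. The generator is the
ground-truth oracle for every downstream stage: it returns the exact
discretized surfaces alongside the rendered volume.

All randomness flows through a single :func:`numpy.random.default_rng` seed;
identical spec + seed produce bit-identical volumes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import AU_MAX, OCTVolume
from .layers import BAND_NAMES, BAND_THICKNESS_FRAC, BAND_TO_LAYER, LAYER_NAMES
from .surfaces import SurfaceOrderError, SurfaceSet


class SpecificationError(ValueError):
    """Raised for an invalid phantom specification."""


# thickness of each band as a fraction of the volume depth
DEFAULT_BAND_THICKNESS_FRAC = BAND_THICKNESS_FRAC

# per-band mean intensity (AU). The three photoreceptor sub-bands (inner
# segment, ellipsoid band, outer segment) are chosen so their 6:5:5
# thickness-weighted mean equals the photoreceptor-layer norm of 31759.63 AU.
DEFAULT_BAND_AU: Dict[str, float] = {
    "RNFL": 31558.68,
    "GCL": 26653.71,
    "IPL": 26677.85,
    "INL": 23538.66,
    "OPL": 24824.14,
    "ONL": 21381.69,
    "IS": 27000.0,
    "EZ": 40000.0,
    "OS": 29230.816,
    "RPE": 34677.2,
}

# regional modulation per reported layer: ratio of the central subfield to the
# whole-chart mean, and the nasal-minus-temporal outer-quadrant difference as a
# fraction of the whole-chart mean
DEFAULT_CENTRAL_RATIO: Dict[str, float] = {
    "RNFL": 0.7637, "GCL": 0.9400, "IPL": 0.9710, "INL": 1.0218,
    "OPL": 0.9678, "ONL": 1.0049, "PR": 0.9942, "RPE": 1.0390,
}
DEFAULT_NT_RATIO: Dict[str, float] = {
    "RNFL": 0.0878, "GCL": 0.0157, "IPL": 0.0004, "INL": -0.0055,
    "OPL": -0.0029, "ONL": -0.0093, "PR": -0.0224, "RPE": -0.0144,
}


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic macular volume.

    Geometry is parameterized in fractions of the depth axis so the same spec
    scales from desk-size grids to the full 512x128 raster. The foveal pit is
    a radial Gaussian depression applied to surfaces S1..S6 with linearly
    decaying amplitude, zero from the ELM (S7) outward; a gentle parabolic
    dome models global retinal curvature.
    """

    shape: Tuple[int, int, int] = (128, 32, 256)
    extent_mm: Tuple[float, float] = (6.0, 6.0)
    laterality: str = "OD"
    image_quality: float = 60.0

    retina_top_frac: float = 0.30
    band_thickness_frac: Tuple[float, ...] = DEFAULT_BAND_THICKNESS_FRAC
    band_au: Dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_BAND_AU))
    vitreous_au: float = 2000.0
    choroid_au: float = 15000.0

    pit_depth_frac: float = 0.35     # fraction of the S1..S7 stack depth; the
                                     # depression decays linearly with depth offset
    pit_sigma_mm: float = 0.6
    pit_center_mm: Tuple[float, float] = (0.0, 0.0)  # offset from field center
    dome_sag_frac: float = 0.02      # axial sag at 3 mm radius, fraction of depth

    modulate: bool = True
    central_ratio: Dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CENTRAL_RATIO))
    nt_ratio: Dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_NT_RATIO))
    central_sigma_mm: float = 0.35

    speckle_shape: float = 40.0      # gamma shape k; sigma/mu = 1/sqrt(k); 0 disables
    floor_sd: float = 100.0          # additive zero-mean noise floor, AU
    axial_blur_sigma: float = 1.0    # voxels

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if nx < 8 or ny < 2 or nz < 16:
            raise SpecificationError(f"phantom dims {self.shape} below minimum (8, 2, 16)")
        if len(self.band_thickness_frac) != len(BAND_NAMES):
            raise SpecificationError("need one thickness per tissue band")
        for name in BAND_NAMES:
            au = self.band_au[name]
            if not 0 <= au <= AU_MAX:
                raise SpecificationError(f"band {name} intensity {au} outside [0, {AU_MAX}]")
        for au in (self.vitreous_au, self.choroid_au):
            if not 0 <= au <= AU_MAX:
                raise SpecificationError("background intensity outside the AU range")
        if self.laterality not in ("OD", "OS"):
            raise SpecificationError("laterality must be OD or OS")

    # -- geometry -----------------------------------------------------------

    def lateral_grids_mm(self):
        """Signed (x, y) coordinates of A-scan centers, mm from field center."""
        nx, ny, _ = self.shape
        wx, wy = self.extent_mm
        gx = (np.arange(nx) + 0.5) * (wx / nx) - wx / 2
        gy = (np.arange(ny) + 0.5) * (wy / ny) - wy / 2
        return gx, gy

    def surface_maps(self) -> np.ndarray:
        """Continuous truth surfaces, shape (11, ncols, nbscans), float voxels."""
        nx, ny, nz = self.shape
        gx, gy = self.lateral_grids_mm()
        xx = gx[:, None]
        yy = gy[None, :]
        r2 = xx**2 + yy**2
        top = self.retina_top_frac * nz + self.dome_sag_frac * nz * (r2 / 9.0)

        thick = np.asarray(self.band_thickness_frac) * nz
        offsets = np.concatenate([[0.0], np.cumsum(thick)])  # 11 values

        px, py = self.pit_center_mm
        rho2 = (xx - px) ** 2 + (yy - py) ** 2
        pit_shape = np.exp(-rho2 / (2 * self.pit_sigma_mm**2))
        pit_depth = self.pit_depth_frac * offsets[6]  # S1..S7 stack depth

        surf = np.empty((11, nx, ny))
        for i in range(11):
            # depression amplitude decays linearly with anatomical depth,
            # vanishing at the ONL/photoreceptor boundary (S7) and beyond
            amp = pit_depth * max(0.0, 1.0 - offsets[i] / offsets[6])
            surf[i] = top + offsets[i] + amp * pit_shape
        return surf

    def truth_surfaces(self) -> SurfaceSet:
        """Discretized ground-truth surfaces; errors if any pair crosses."""
        s = np.rint(self.surface_maps()).astype(np.int32)
        ss = SurfaceSet(s)
        try:
            ss.validate(self.shape[2], min_separation=1)
        except SurfaceOrderError as err:
            raise SpecificationError(f"invalid phantom geometry: {err}") from err
        return ss

    # -- intensity ----------------------------------------------------------

    def modulation_field(self, layer: str) -> np.ndarray:
        """Multiplicative regional intensity pattern for one layer, (nx, ny)."""
        nx, ny, _ = self.shape
        if not self.modulate:
            return np.ones((nx, ny))
        gx, gy = self.lateral_grids_mm()
        px, py = self.pit_center_mm
        xx = gx[:, None] - px
        yy = gy[None, :] - py
        r2 = xx**2 + yy**2
        sig = self.central_sigma_mm
        # mean of the Gaussian bump over the 0.5 mm central disc, closed form
        g0 = (2 * sig**2 / 0.25) * (1 - math.exp(-0.25 / (2 * sig**2)))
        a_c = (self.central_ratio.get(layer, 1.0) - 1.0) / g0
        # mean nasal coordinate over the nasal outer quadrant (1.5..3 mm ring)
        xbar = (2 / 3) * (27 - 1.5**3) / (9 - 1.5**2) * (math.sin(math.pi / 4) / (math.pi / 4))
        s_nt = self.nt_ratio.get(layer, 0.0) / (2 * xbar)
        nasal_sign = 1.0 if self.laterality == "OD" else -1.0
        return 1.0 + a_c * np.exp(-r2 / (2 * sig**2)) + s_nt * nasal_sign * xx

    def noiseless_field(self) -> np.ndarray:
        """The clean intensity volume (float), before blur and noise."""
        nx, ny, nz = self.shape
        s = self.truth_surfaces().z  # (11, nx, ny)
        zline = np.arange(nz)
        # band index per voxel: 0 = vitreous, 1..10 = tissue bands, 11 = choroid
        bidx = np.zeros((nx, ny, nz), dtype=np.uint8)
        for i in range(11):
            bidx += (zline[None, None, :] >= s[i][:, :, None]).astype(np.uint8)
        values = np.empty((nx, ny, 12))
        values[:, :, 0] = self.vitreous_au
        values[:, :, 11] = self.choroid_au
        for b, name in enumerate(BAND_NAMES):
            mod = self.modulation_field(BAND_TO_LAYER[b])
            values[:, :, b + 1] = self.band_au[name] * mod
        flat = values.reshape(nx * ny, 12)
        img = flat[np.arange(nx * ny)[:, None], bidx.reshape(nx * ny, nz)]
        return img.reshape(nx, ny, nz)

    def expected_layer_means(self) -> Dict[str, float]:
        """Thickness-weighted unmodulated mean intensity per reported layer."""
        thick = np.asarray(self.band_thickness_frac)
        out = {}
        for layer in LAYER_NAMES:
            bands = [b for b in range(len(BAND_NAMES)) if BAND_TO_LAYER[b] == layer]
            w = thick[bands]
            au = np.array([self.band_au[BAND_NAMES[b]] for b in bands])
            out[layer] = float((w * au).sum() / w.sum())
        return out


def _render(spec: PhantomSpec, rng: np.random.Generator, gain: float = 1.0) -> np.ndarray:
    img = spec.noiseless_field() * gain
    if spec.axial_blur_sigma > 0:
        img = gaussian_filter1d(img, spec.axial_blur_sigma, axis=2, mode="nearest")
    if spec.speckle_shape:
        k = float(spec.speckle_shape)
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    if spec.floor_sd:
        img = img + rng.normal(0.0, spec.floor_sd, size=img.shape)
    return np.clip(np.rint(img), 0, AU_MAX).astype(np.uint16)


def _as_volume(spec: PhantomSpec, voxels: np.ndarray, **ids) -> OCTVolume:
    nx, ny, nz = spec.shape
    return OCTVolume(
        voxels=voxels,
        dx_mm=spec.extent_mm[0] / nx,
        dy_mm=spec.extent_mm[1] / ny,
        dz_mm=2.3 / nz,  # nominal axial extent; metadata only
        laterality=spec.laterality,
        image_quality=spec.image_quality,
        **ids,
    )


def generate_phantom(spec: PhantomSpec, seed: int,
                     subject_id: Optional[str] = None) -> Tuple[OCTVolume, SurfaceSet]:
    """Render a phantom volume and return it with its ground-truth surfaces."""
    rng = np.random.default_rng(seed)
    truth = spec.truth_surfaces()
    vol = _as_volume(spec, _render(spec, rng), subject_id=subject_id)
    return vol, truth


@dataclasses.dataclass
class RescanJitter:
    """Between-scan variability of an operator re-scan on the same day.

    gain_sd is the SD of the log of a mean-one multiplicative intensity gain
    drawn independently per scan; the lateral shifts re-center the anatomy by
    an integer number of columns / B-scans; speckle is redrawn per scan.

    The default gain SD (1.2%) puts the ICC of per-layer means over a
    normative cohort near 0.85-0.9, the reproducibility range reported for
    two-operator optical-intensity measurements.
    """

    gain_sd: float = 0.012
    shift_cols_sd: float = 1.0
    shift_bscans_sd: float = 0.3


def generate_rescan_pair(spec: PhantomSpec, jitter: RescanJitter,
                         seed: int) -> Tuple[OCTVolume, OCTVolume]:
    """Two scans of the same anatomy differing only by the jitter model."""
    rng = np.random.default_rng(seed)
    gains = np.exp(rng.normal(0.0, jitter.gain_sd, 2) - jitter.gain_sd**2 / 2) \
        if jitter.gain_sd else np.ones(2)
    sx = round(rng.normal(0.0, jitter.shift_cols_sd)) if jitter.shift_cols_sd else 0
    sy = round(rng.normal(0.0, jitter.shift_bscans_sd)) if jitter.shift_bscans_sd else 0

    vol_a = _as_volume(spec, _render(spec, rng, gain=float(gains[0])), operator_id="A")
    spec_b = dataclasses.replace(
        spec,
        pit_center_mm=(spec.pit_center_mm[0] + sx * spec.extent_mm[0] / spec.shape[0],
                       spec.pit_center_mm[1] + sy * spec.extent_mm[1] / spec.shape[1]),
    )
    vol_b = _as_volume(spec_b, _render(spec_b, rng, gain=float(gains[1])), operator_id="B")
    return vol_a, vol_b


def spec_with_layer_means(spec: PhantomSpec, layer_means: Dict[str, float]) -> PhantomSpec:
    """A spec copy whose per-layer mean intensities equal ``layer_means``.

    Each layer's bands are rescaled by a common factor, so the photoreceptor
    sub-band contrast is preserved while the layer mean moves to the target.
    """
    base = spec.expected_layer_means()
    band_au = dict(spec.band_au)
    for b, name in enumerate(BAND_NAMES):
        layer = BAND_TO_LAYER[b]
        if layer in layer_means:
            band_au[name] = spec.band_au[name] * layer_means[layer] / base[layer]
    return dataclasses.replace(spec, band_au=band_au)
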