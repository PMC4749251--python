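"""Sequential detection of the 11 intraretinal surfaces and segmentation QC.

Each surface is found as an exact optimal surface (octmac.graph) in a cost
volume derived from the denoised scan: the negative signed axial derivative,
with the sign chosen per surface (dark-to-bright boundaries such as the ILM
and the IS/OS junction, bright-to-dark boundaries such as RNFL/GCL or the
outer RPE edge). Detection is surface-by-surface in a fixed order: the ILM
(S1) and the outer RPE boundary (S11) first over the full depth range, then
each remaining surface restricted to the band between its already-found
neighbors minus minimum-separation margins. Low-contrast boundaries (GCL/IPL
above all) additionally carry a quadratic anatomical-position prior between
their reference surfaces, as gradient information alone cannot localize them.

A simple automated quality-control proxy replaces the study's per-B-scan
visual inspection: B-scans with implausible mean layer thickness or large
inter-B-scan surface jumps are flagged, and flagged volumes are excluded
upstream.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

from .graph import InfeasibleError, banded_optimal_surface
from .io import OCTVolume
from .layers import BAND_THICKNESS_FRAC, LAYER_NAMES, LAYER_SPAN, N_SURFACES, SURFACE_NAMES
from .preprocess import denoise_cad
from .surfaces import SurfaceOrderError, SurfaceSet

DARK_TO_BRIGHT = "dark_to_bright"
BRIGHT_TO_DARK = "bright_to_dark"


class SegmentationError(RuntimeError):
    """Raised when a surface cannot be located; names the surface."""


@dataclasses.dataclass
class CostVolume:
    """Per-voxel on-surface cost with the gradient polarity it encodes."""

    values: np.ndarray  # (ncols, nbscans, ndepth) float32, finite
    polarity: str


def compute_surface_cost(voxels: np.ndarray, polarity: str) -> CostVolume:
    """Edge cost from the signed axial derivative, min-max scaled per B-scan.

    The backward difference I(z) - I(z-1) is used so a step edge (sharp or
    symmetrically blurred) has its unique cost minimum at the first voxel of
    the posterior band, matching the half-open [S_i, S_{i+1}) voxel-ownership
    convention. Lower cost = stronger matching edge; values are normalized to
    [0, 1] within each B-scan.
    """
    if polarity not in (DARK_TO_BRIGHT, BRIGHT_TO_DARK):
        raise ValueError(f"unknown polarity {polarity!r}")
    v = np.asarray(voxels, dtype=np.float32)
    if v.ndim != 3 or v.shape[2] < 3:
        raise ValueError("need a 3D volume with at least 3 depth samples")
    d = np.empty_like(v)
    d[:, :, 1:] = v[:, :, 1:] - v[:, :, :-1]
    d[:, :, 0] = 0.0
    sign = 1.0 if polarity == DARK_TO_BRIGHT else -1.0
    cost = -sign * d
    cmin = cost.min(axis=(0, 2), keepdims=True)
    cmax = cost.max(axis=(0, 2), keepdims=True)
    cost = (cost - cmin) / np.maximum(cmax - cmin, 1e-12)
    return CostVolume(values=cost, polarity=polarity)


# cumulative anatomical surface offsets as fractions of the S1..S11 stack
_OFF = np.concatenate([[0.0], np.cumsum(BAND_THICKNESS_FRAC)])
_OFF_FRAC = _OFF / _OFF[-1]


def _frac(i: int, a: int, b: int) -> float:
    return float((_OFF_FRAC[i] - _OFF_FRAC[a]) / (_OFF_FRAC[b] - _OFF_FRAC[a]))


@dataclasses.dataclass
class SurfaceRule:
    """How one surface is detected: polarity, reference band, position prior."""

    index: int                       # 0-based surface index (S1 = 0)
    polarity: str
    upper: Optional[int] = None      # reference surface above (None = volume top)
    lower: Optional[int] = None      # reference surface below (None = volume bottom)
    prior_frac: Optional[float] = None   # position between the prior refs, 0 = upper
    prior_weight: float = 0.0        # quadratic penalty per voxel^2 on [0,1] cost scale
    prior_deadzone: float = 1.0      # voxels around the prior with zero penalty, so
                                     # the prior never overrides a clean edge nearby
    # surfaces the prior interpolates between (default: the band refs). Kept
    # separate so a prior can interpolate between surfaces that share the
    # foveal-pit geometry (or are both flat) — interpolating across the pit
    # kink would bias the prior center at the fovea.
    prior_upper: Optional[int] = None
    prior_lower: Optional[int] = None
    # alternative prior: a fixed anatomical gap above one parallel reference
    # surface, zp = found[prior_ref] - prior_gap_frac * ndepth. Used for flat
    # outer surfaces, where it neither crosses the pit kink nor amplifies the
    # reference surface's own localization error.
    prior_ref: Optional[int] = None
    prior_gap_frac: float = 0.0


#: detection order: strong global boundaries first, then band-restricted ones.
#: Priors for the pit-carrying surfaces (S2..S6) interpolate between pit-zone
#: surfaces; priors for the flat outer surfaces (S7..S10) between flat ones.
DEFAULT_RULES: Tuple[SurfaceRule, ...] = (
    SurfaceRule(0, DARK_TO_BRIGHT),
    SurfaceRule(10, BRIGHT_TO_DARK, upper=0),
    SurfaceRule(7, DARK_TO_BRIGHT, upper=0, lower=10),
    SurfaceRule(1, BRIGHT_TO_DARK, upper=0, lower=7, prior_frac=_frac(1, 0, 7),
                prior_weight=0.1),
    SurfaceRule(6, DARK_TO_BRIGHT, upper=1, lower=7,
                prior_ref=10, prior_gap_frac=float(_OFF[10] - _OFF[6]),
                prior_weight=0.1),
    SurfaceRule(5, BRIGHT_TO_DARK, upper=1, lower=6, prior_frac=_frac(5, 1, 6),
                prior_weight=0.1),
    SurfaceRule(3, BRIGHT_TO_DARK, upper=1, lower=5, prior_frac=_frac(3, 1, 5),
                prior_weight=0.05),
    SurfaceRule(2, DARK_TO_BRIGHT, upper=1, lower=3, prior_frac=_frac(2, 1, 3),
                prior_weight=1.0),
    SurfaceRule(4, DARK_TO_BRIGHT, upper=3, lower=5, prior_frac=_frac(4, 3, 5),
                prior_weight=0.3),
    SurfaceRule(9, DARK_TO_BRIGHT, upper=7, lower=10, prior_frac=_frac(9, 7, 10),
                prior_weight=0.2),
    SurfaceRule(8, BRIGHT_TO_DARK, upper=7, lower=9, prior_frac=_frac(8, 7, 9),
                prior_weight=0.2),
)


@dataclasses.dataclass
class SegmentationConfig:
    dx: int = 2                      # max |dz| between adjacent columns
    dy: int = 6                      # max |dz| between adjacent B-scans
    min_separation: int = 1          # voxels between consecutive surfaces
    band_margin: int = 8             # DP presolve band half-width
    cost_scale: int = 32768          # integer quantization levels for the solver;
                                     # fine enough to resolve the GCL/IPL contrast
    cad_conductance: float = 2.0
    cad_iterations: int = 3          # fewer than the filter's own default: longer
                                     # diffusion shifts sloped weak boundaries sub-voxel
    cad_time_step: float = 0.0625
    rules: Tuple[SurfaceRule, ...] = DEFAULT_RULES


def segment_retina(vol: OCTVolume, config: Optional[SegmentationConfig] = None) -> SurfaceSet:
    """Detect all 11 surfaces on a raw volume (denoised internally)."""
    cfg = config or SegmentationConfig()
    den = denoise_cad(vol, cfg.cad_conductance, cfg.cad_iterations, cfg.cad_time_step)
    voxels = den.voxels.astype(np.float32)
    X, Y, D = voxels.shape

    costs = {
        DARK_TO_BRIGHT: compute_surface_cost(voxels, DARK_TO_BRIGHT),
        BRIGHT_TO_DARK: compute_surface_cost(voxels, BRIGHT_TO_DARK),
    }
    found: Dict[int, np.ndarray] = {}
    msep = cfg.min_separation
    for rule in cfg.rules:
        name = f"S{rule.index + 1} ({SURFACE_NAMES[rule.index]})"
        if rule.upper is None:
            lo = np.ones((X, Y), dtype=np.int64)
        else:
            gap = msep * (rule.index - rule.upper)
            lo = found[rule.upper] + gap
        if rule.lower is None:
            hi = np.full((X, Y), D - 2, dtype=np.int64)
        else:
            gap = msep * (rule.lower - rule.index)
            hi = found[rule.lower] - gap
        if (lo > hi).any():
            raise SegmentationError(f"empty search band for {name}")

        cost = costs[rule.polarity].values
        zp = None
        if rule.prior_ref is not None and rule.prior_weight > 0:
            zp = found[rule.prior_ref].astype(np.float64) - rule.prior_gap_frac * D
        elif rule.prior_frac is not None and rule.prior_weight > 0:
            pu = rule.prior_upper if rule.prior_upper is not None else rule.upper
            pl = rule.prior_lower if rule.prior_lower is not None else rule.lower
            upper = found[pu].astype(np.float64)
            lower = found[pl].astype(np.float64)
            zp = upper + rule.prior_frac * (lower - upper)
        if zp is not None:
            dev = np.abs(np.arange(D)[None, None, :] - zp[:, :, None])
            dev = np.maximum(dev - rule.prior_deadzone, 0.0)
            prior = np.minimum(rule.prior_weight * dev**2, 2.0).astype(np.float32)
            cost = cost + prior
        try:
            z = banded_optimal_surface(cost, cfg.dx, cfg.dy, zrange=(lo, hi),
                                       margin=cfg.band_margin, scale=cfg.cost_scale)
        except InfeasibleError as err:
            raise SegmentationError(f"infeasible search band for {name}: {err}") from err
        found[rule.index] = z

    stack = np.stack([found[i] for i in range(N_SURFACES)])
    ss = SurfaceSet(stack)
    try:
        ss.validate(D, min_separation=msep)
    except SurfaceOrderError as err:
        raise SegmentationError(str(err)) from err
    return ss


# -- quality control --------------------------------------------------------


@dataclasses.dataclass
class QCThresholds:
    """Plausibility bounds for the automated per-B-scan inspection proxy.

    Layer-thickness bounds are multiples of the nominal anatomical thickness
    (mean over a B-scan, so the foveal pinch of inner layers does not trip
    them); the jump bound limits surface displacement between adjacent
    B-scans.
    """

    thickness_lo: float = 0.2
    thickness_hi: float = 3.0
    max_bscan_jump: int = 12
    # the vitreous above the ILM must be much darker than the RNFL band; a
    # ratio near 1 means the volume carries no layered structure at all
    max_vitreous_rnfl_ratio: float = 0.5


@dataclasses.dataclass
class QCReport:
    ok: bool
    flags: List[Tuple[int, str]]     # (B-scan index, reason)

    def to_dict(self) -> dict:
        return {"ok": self.ok, "flags": [{"bscan": int(y), "reason": r} for y, r in self.flags]}


def qc_surfaces(ss: SurfaceSet, vol: OCTVolume,
                thresholds: Optional[QCThresholds] = None) -> QCReport:
    """Flag B-scans with implausible layer thickness or surface jumps."""
    thr = thresholds or QCThresholds()
    D = vol.shape[2]
    flags: List[Tuple[int, str]] = []
    nominal = {layer: (_OFF[LAYER_SPAN[layer][1]] - _OFF[LAYER_SPAN[layer][0]]) * D
               for layer in LAYER_NAMES}
    for layer in LAYER_NAMES:
        upper, lower = ss.layer_band(layer)
        mean_thick = (lower - upper).mean(axis=0)  # per B-scan
        for y in np.flatnonzero((mean_thick < thr.thickness_lo * nominal[layer])
                                | (mean_thick > thr.thickness_hi * nominal[layer])):
            flags.append((int(y), f"{layer} mean thickness {mean_thick[y]:.1f} voxels "
                                  f"outside plausible range"))
    jumps = np.abs(np.diff(ss.z, axis=2)).max(axis=(0, 1))  # per B-scan gap
    for y in np.flatnonzero(jumps > thr.max_bscan_jump):
        flags.append((int(y + 1), f"surface jump {jumps[y]} voxels from previous B-scan"))

    # vitreous contrast: intensity above the ILM vs the detected RNFL band
    X, Y, _ = vol.voxels.shape
    zline = np.arange(D)
    for y in range(Y):
        page = vol.voxels[:, y, :].astype(np.float64)
        above = zline[None, :] < (ss.z[0, :, y][:, None] - 1)
        rnfl = (zline[None, :] >= ss.z[0, :, y][:, None]) \
            & (zline[None, :] < ss.z[1, :, y][:, None])
        if above.any() and rnfl.any():
            ratio = page[above].mean() / max(page[rnfl].mean(), 1.0)
            if ratio > thr.max_vitreous_rnfl_ratio:
                flags.append((y, f"no vitreous-ILM contrast (ratio {ratio:.2f})"))
    flags.sort()
    return QCReport(ok=not flags, flags=flags)
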