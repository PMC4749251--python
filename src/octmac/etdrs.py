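"""Fovea localization and the 9-sector ETDRS grid.

The fovea is the deepest point of surface 1 (the foveal pit of the ILM). The
grid is the standard macular chart: circles of 1, 3 and 6 mm diameter centered
on the fovea, the two rings split into superior / inferior / nasal / temporal
quadrants at the +/-45 degree diagonals — nine sectors in all. Membership is
computed in millimetres (the 512x128 raster has strongly anisotropic pixels),
and the nasal/temporal assignment flips with laterality.

Orientation convention: within a B-scan, x increases temporal -> nasal for a
right eye (OD) and nasal -> temporal for a left eye (OS); y (the B-scan index)
increases superior -> inferior. Both are explicit here and assertable from the
volume sidecar.
"""

from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np
from scipy.ndimage import median_filter

RADII_MM = (0.5, 1.5, 3.0)

#: sector label values in mask arrays; 0 = outside the chart
SECTOR_NAMES = ["Cen", "Sin", "Nin", "Iin", "Tin", "Sout", "Nout", "Iout", "Tout"]
SECTOR_IDS = {name: i + 1 for i, name in enumerate(SECTOR_NAMES)}


class AmbiguousFoveaError(ValueError):
    """Raised when surface 1 is too flat to define a pit location."""


def locate_fovea(s1: np.ndarray, presmooth: Tuple[int, int] = (5, 3),
                 max_tie_frac: float = 0.25) -> Tuple[float, float]:
    """Grid position (x, y) of the deepest point of surface 1.

    The surface is median-presmoothed to suppress speckle-driven outliers;
    ties are resolved by the centroid of the argmax set. If the argmax set
    covers more than ``max_tie_frac`` of the grid the surface is considered
    flat and an :class:`AmbiguousFoveaError` is raised.
    """
    s1 = np.asarray(s1)
    sm = median_filter(s1.astype(np.float64), size=presmooth, mode="nearest") \
        if presmooth else s1.astype(np.float64)
    deepest = sm.max()
    tie = np.argwhere(sm == deepest)
    if tie.shape[0] > max_tie_frac * s1.size:
        raise AmbiguousFoveaError(
            f"{tie.shape[0]} of {s1.size} A-scans share the deepest ILM depth; "
            "no unambiguous foveal pit")
    cx, cy = tie.mean(axis=0)
    return float(cx), float(cy)


@dataclasses.dataclass
class ETDRSGrid:
    """Fovea-centered sector labels over the en-face grid.

    ``labels[x, y]`` holds a sector id (see SECTOR_IDS) or 0 outside the 6-mm
    disc. Sectors are pairwise disjoint and cover exactly the in-disc pixels.
    """

    labels: np.ndarray
    center: Tuple[float, float]       # grid indices (may be fractional)
    center_mm: Tuple[float, float]
    laterality: str
    spacing: Tuple[float, float]      # (dx_mm, dy_mm)
    coverage_warnings: List[str]

    def mask(self, sector: str) -> np.ndarray:
        return self.labels == SECTOR_IDS[sector]

    def sector_area_mm2(self, sector: str) -> float:
        return float(self.mask(sector).sum()) * self.spacing[0] * self.spacing[1]


def _expected_areas() -> dict:
    import math

    r0, r1, r2 = RADII_MM
    areas = {"Cen": math.pi * r0**2}
    for q in ("S", "N", "I", "T"):
        areas[q + "in"] = math.pi * (r1**2 - r0**2) / 4
        areas[q + "out"] = math.pi * (r2**2 - r1**2) / 4
    return areas


def build_etdrs_masks(center: Tuple[float, float], laterality: str,
                      dims: Tuple[int, int], spacing: Tuple[float, float],
                      coverage_tol: float = 0.02) -> ETDRSGrid:
    """Rasterize the nine ETDRS sector masks around a fovea center.

    Parameters
    ----------
    center : (cx, cy)
        Fovea position in grid indices (fractional allowed).
    laterality : {"OD", "OS"}
        Flips the nasal/temporal sides.
    dims : (ncols, nbscans)
    spacing : (dx_mm, dy_mm)

    Ring membership uses the Euclidean mm distance of each pixel center
    (half-open ring intervals), quadrants the half-open 90-degree wedges
    around the +/-45 degree diagonals. If the chart extends beyond the
    scanned area the masks are clipped and a coverage warning is recorded
    per short-falling sector.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")
    nx, ny = dims
    dxm, dym = spacing
    if dxm <= 0 or dym <= 0:
        raise ValueError("spacing must be positive")
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"center {center} outside the grid {dims}")

    u = (np.arange(nx) - cx) * dxm          # +x direction
    v = (np.arange(ny) - cy) * dym
    uu = u[:, None]
    vv = v[None, :]
    r = np.hypot(uu, vv)

    nasal = uu if laterality == "OD" else -uu   # nasal coordinate, mm
    sup = -vv                                   # superior coordinate, mm
    ang = np.degrees(np.arctan2(np.broadcast_to(sup, r.shape),
                                np.broadcast_to(nasal, r.shape)))
    quad = np.full(r.shape, "T", dtype="U1")
    quad[(ang >= -45) & (ang < 45)] = "N"
    quad[(ang >= 45) & (ang < 135)] = "S"
    quad[(ang >= -135) & (ang < -45)] = "I"

    labels = np.zeros(r.shape, dtype=np.int8)
    cen = r <= RADII_MM[0]
    labels[cen] = SECTOR_IDS["Cen"]
    inner = (r > RADII_MM[0]) & (r <= RADII_MM[1])
    outer = (r > RADII_MM[1]) & (r <= RADII_MM[2])
    for q in ("S", "N", "I", "T"):
        labels[inner & (quad == q)] = SECTOR_IDS[q + "in"]
        labels[outer & (quad == q)] = SECTOR_IDS[q + "out"]

    grid = ETDRSGrid(
        labels=labels, center=(float(cx), float(cy)),
        center_mm=(float(cx) * dxm, float(cy) * dym),
        laterality=laterality, spacing=(dxm, dym), coverage_warnings=[],
    )
    pix = dxm * dym
    for name, expected in _expected_areas().items():
        got = grid.sector_area_mm2(name)
        if got < (1 - coverage_tol) * expected - pix:
            grid.coverage_warnings.append(
                f"sector {name} covers {got:.3f} mm2 of the expected "
                f"{expected:.3f} mm2 (chart clipped by the scan border)")
    return grid


def locate_and_build(s1: np.ndarray, laterality: str,
                     spacing: Tuple[float, float],
                     presmooth: Tuple[int, int] = (5, 3)) -> ETDRSGrid:
    """Convenience: fovea localization followed by mask construction."""
    center = locate_fovea(s1, presmooth=presmooth)
    return build_etdrs_masks(center, laterality, s1.shape, spacing)
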