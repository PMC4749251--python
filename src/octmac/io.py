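"""Reading and writing OCT volumes, surfaces and result tables in open formats.

Volumes travel as 16-bit multi-page TIFF (one page per B-scan) or NIfTI-1,
always accompanied by a JSON sidecar carrying the acquisition metadata the
proprietary export would normally hold: lateral spacing, laterality, and the
device image-quality score.

Coordinate convention (used everywhere in this package): ``voxels[x, y, z]``
where ``x`` is the column within a B-scan, ``y`` the B-scan index, and ``z``
depth, 0 at the vitreous side and increasing posteriorly. Surfaces are z-values
in this frame.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


AU_MAX = 65535  # 16-bit arbitrary-unit export scale

_REQUIRED_SIDECAR = ("dx_mm", "dy_mm", "laterality", "image_quality")


class FormatError(ValueError):
    """Raised for malformed containers or sidecars."""


@dataclasses.dataclass
class OCTVolume:
    """A 3D macular OCT scan on the 16-bit AU scale.

    Parameters
    ----------
    voxels : ndarray of uint16, shape (ncols, nbscans, ndepth)
        Backscatter intensity in arbitrary units (0-65535).
    dx_mm, dy_mm : float
        Lateral spacing: mm per column and mm per B-scan.
    dz_mm : float
        Axial voxel pitch. Metadata only; never used in computation.
    laterality : {"OD", "OS"}
    image_quality : float
        Device signal-strength score (dimensionless).
    subject_id, operator_id : str, optional
    """

    voxels: np.ndarray
    dx_mm: float
    dy_mm: float
    dz_mm: float = 0.0
    laterality: str = "OD"
    image_quality: float = 60.0
    subject_id: Optional[str] = None
    operator_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError("voxels must be 3D (ncols, nbscans, ndepth)")
        if self.voxels.dtype != np.uint16:
            if not np.issubdtype(self.voxels.dtype, np.integer):
                raise FormatError("voxels must be 16-bit integer data")
            if self.voxels.min() < 0 or self.voxels.max() > AU_MAX:
                raise FormatError("voxel values outside the 16-bit AU range")
            self.voxels = self.voxels.astype(np.uint16)
        nx, ny, nz = self.voxels.shape
        if nx < 8 or ny < 2 or nz < 16:
            raise FormatError(f"volume dims {self.voxels.shape} below minimum (8, 2, 16)")
        if self.dx_mm <= 0 or self.dy_mm <= 0:
            raise FormatError("lateral spacings must be positive")
        if self.laterality not in ("OD", "OS"):
            raise FormatError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def metadata(self) -> dict:
        md = {
            "shape": list(self.voxels.shape),
            "dx_mm": self.dx_mm,
            "dy_mm": self.dy_mm,
            "dz_mm": self.dz_mm,
            "laterality": self.laterality,
            "image_quality": self.image_quality,
        }
        if self.subject_id is not None:
            md["subject_id"] = self.subject_id
        if self.operator_id is not None:
            md["operator_id"] = self.operator_id
        return md


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: OCTVolume, path) -> None:
    """Write a volume plus its JSON sidecar. Lossless inverse of read_volume.

    The container format is chosen from the extension: ``.tif``/``.tiff`` for
    multi-page TIFF (one page per B-scan, rows = depth, cols = columns) or
    ``.nii``/``.nii.gz`` for NIfTI-1.
    """
    if not str(path):
        raise FormatError("empty output path")
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        # page y holds the B-scan as a (ndepth, ncols) image
        pages = np.ascontiguousarray(np.transpose(vol.voxels, (1, 2, 0)))
        tifffile.imwrite(path, pages, photometric="minisblack")
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(vol.voxels.astype(np.uint16), affine=np.eye(4))
        nib.save(img, str(path))
    else:
        raise FormatError(f"unsupported container {path.name!r} (use .tif/.tiff or .nii/.nii.gz)")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(vol.metadata(), fh, indent=1)


def read_volume(path, sidecar=None) -> OCTVolume:
    """Read a 16-bit volume and its JSON sidecar.

    Raises :class:`FormatError` for non-16-bit data, a dimension mismatch
    between container and sidecar, or missing required sidecar fields.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        md = json.load(fh)
    for field in _REQUIRED_SIDECAR:
        if field not in md:
            raise FormatError(f"sidecar missing required field {field!r}")

    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        pages = tifffile.imread(path)
        if pages.dtype != np.uint16:
            raise FormatError(f"expected 16-bit TIFF, got {pages.dtype}")
        if pages.ndim == 2:
            pages = pages[None]
        voxels = np.transpose(pages, (2, 0, 1))  # (ncols, nbscans, ndepth)
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.dtype != np.uint16:
            raise FormatError(f"expected 16-bit NIfTI, got {data.dtype}")
        voxels = data
    else:
        raise FormatError(f"unsupported container {path.name!r}")

    if "shape" in md and tuple(md["shape"]) != voxels.shape:
        raise FormatError(f"sidecar shape {md['shape']} != container shape {voxels.shape}")
    return OCTVolume(
        voxels=voxels,
        dx_mm=float(md["dx_mm"]),
        dy_mm=float(md["dy_mm"]),
        dz_mm=float(md.get("dz_mm", 0.0)),
        laterality=md["laterality"],
        image_quality=float(md["image_quality"]),
        subject_id=md.get("subject_id"),
        operator_id=md.get("operator_id"),
    )


def write_surfaces(surfaces: np.ndarray, path) -> None:
    """Write a surface stack (nsurf, ncols, nbscans) as CSV: one row per
    (x, y) A-scan, one column per surface."""
    surfaces = np.asarray(surfaces)
    nsurf, nx, ny = surfaces.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel()})
    for i in range(nsurf):
        df[f"S{i + 1}"] = surfaces[i].ravel()
    df.to_csv(path, index=False)


def read_surfaces(path) -> np.ndarray:
    df = pd.read_csv(path)
    scols = [c for c in df.columns if c.startswith("S")]
    nx = int(df["x"].max()) + 1
    ny = int(df["y"].max()) + 1
    out = np.zeros((len(scols), nx, ny), dtype=np.int32)
    for i, c in enumerate(scols):
        out[i] = df[c].to_numpy().reshape(nx, ny)
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with a fixed column order and header.

    Non-finite cells (e.g. the undefined mean of a zero-count sector) are
    serialized as empty cells; read-back restores them as NaN.
    """
    if not str(path):
        raise FormatError("empty output path")
    table.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
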