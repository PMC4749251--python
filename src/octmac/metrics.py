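"""Mean optical intensity per retinal layer and ETDRS sector.

Optical intensity is the mean gray value, in arbitrary units on the 16-bit
export scale, of all raw voxels in a target region: a (layer, sector) cell,
a layer over the whole ETDRS chart, or a layer over the whole scan raster.
Voxel ownership along depth is half-open, [S_i, S_{i+1}).

Statistics are always computed on the RAW volume; denoising exists only to
support boundary detection. No normalization is applied here — image-quality
adjustment belongs to the cohort statistics.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .etdrs import ETDRSGrid, SECTOR_NAMES
from .io import OCTVolume
from .layers import LAYER_NAMES
from .surfaces import SurfaceSet

#: pseudo-sectors appended per layer: all nine sectors pooled, and the full raster
POOLED_CHART = "AllETDRS"
POOLED_SCAN = "WholeScan"

TABLE_COLUMNS = ["layer", "sector", "mean_au", "sd_au", "n_voxels"]


def layer_sector_intensity(vol: OCTVolume, surfaces: SurfaceSet,
                           grid: ETDRSGrid,
                           subject_id: Optional[str] = None) -> pd.DataFrame:
    """Mean / SD / voxel count of raw intensity per (layer, sector).

    Returns a tidy table with 8 layers x (9 sectors + pooled chart + whole
    scan). Zero-count cells (a clipped chart) carry an undefined (NaN) mean.
    SDs are population SDs of the voxel values within the cell — a per-volume
    diagnostic, not the across-subject SD a normative table would report.
    """
    voxels = vol.voxels
    X, Y, D = voxels.shape
    if surfaces.z.shape[1:] != (X, Y) or grid.labels.shape != (X, Y):
        raise ValueError("volume, surfaces and grid shapes disagree")

    labels = grid.labels.astype(np.int64)  # 0 = outside chart
    nsec = len(SECTOR_NAMES)
    sums = np.zeros((len(LAYER_NAMES), nsec + 1))
    sqs = np.zeros_like(sums)
    cnt = np.zeros_like(sums, dtype=np.int64)

    # accumulate per B-scan to keep the working set small on 512x128 rasters
    for y in range(Y):
        page = voxels[:, y, :].astype(np.float64)
        c1 = np.concatenate([np.zeros((X, 1)), np.cumsum(page, axis=1)], axis=1)
        c2 = np.concatenate([np.zeros((X, 1)), np.cumsum(page**2, axis=1)], axis=1)
        lab = labels[:, y]
        for li, layer in enumerate(LAYER_NAMES):
            upper, lower = surfaces.layer_band(layer)
            a = upper[:, y]
            b = lower[:, y]
            s = c1[np.arange(X), b] - c1[np.arange(X), a]
            q = c2[np.arange(X), b] - c2[np.arange(X), a]
            n = (b - a).astype(np.int64)
            sums[li] += np.bincount(lab, weights=s, minlength=nsec + 1)
            sqs[li] += np.bincount(lab, weights=q, minlength=nsec + 1)
            cnt[li] += np.bincount(lab, weights=n, minlength=nsec + 1).astype(np.int64)

    rows = []
    for li, layer in enumerate(LAYER_NAMES):
        cells = list(zip(SECTOR_NAMES, sums[li, 1:], sqs[li, 1:], cnt[li, 1:]))
        cells.append((POOLED_CHART, sums[li, 1:].sum(), sqs[li, 1:].sum(),
                      cnt[li, 1:].sum()))
        cells.append((POOLED_SCAN, sums[li].sum(), sqs[li].sum(), cnt[li].sum()))
        for sector, s, q, n in cells:
            if n > 0:
                mean = s / n
                sd = float(np.sqrt(max(q / n - mean**2, 0.0)))
            else:
                mean, sd = np.nan, np.nan
            rows.append((layer, sector, mean, sd, int(n)))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def layer_means(table: pd.DataFrame, sector: str = POOLED_CHART) -> pd.Series:
    """Per-layer mean intensity for one sector, indexed by layer name."""
    sub = table[table["sector"] == sector]
    return sub.set_index("layer")["mean_au"].reindex(LAYER_NAMES)


def triple_loop_intensity(vol: OCTVolume, surfaces: SurfaceSet,
                          grid: ETDRSGrid) -> pd.DataFrame:
    """Naive per-voxel reference implementation (test oracle; small volumes only)."""
    from .layers import LAYER_SPAN

    X, Y, D = vol.shape
    acc = {(layer, sector): [] for layer in LAYER_NAMES
           for sector in SECTOR_NAMES + [POOLED_CHART, POOLED_SCAN]}
    inv_sector = {v: k for k, v in
                  {name: i + 1 for i, name in enumerate(SECTOR_NAMES)}.items()}
    for x in range(X):
        for y in range(Y):
            sector = inv_sector.get(int(grid.labels[x, y]))
            for layer in LAYER_NAMES:
                i, j = LAYER_SPAN[layer]
                for z in range(int(surfaces.z[i, x, y]), int(surfaces.z[j, x, y])):
                    val = float(vol.voxels[x, y, z])
                    if sector is not None:
                        acc[(layer, sector)].append(val)
                        acc[(layer, POOLED_CHART)].append(val)
                    acc[(layer, POOLED_SCAN)].append(val)
    rows = []
    for layer in LAYER_NAMES:
        for sector in SECTOR_NAMES + [POOLED_CHART, POOLED_SCAN]:
            vals = np.array(acc[(layer, sector)])
            if vals.size:
                rows.append((layer, sector, vals.mean(), vals.std(), vals.size))
            else:
                rows.append((layer, sector, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
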