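"""Speckle denoising by curvature anisotropic diffusion.

The filter runs per B-scan in 2D (the lateral raster is strongly anisotropic,
so 3D diffusion across B-scans would mix tissue at very different positions).
Intensities are rescaled to [0, 1] before filtering so the conductance
parameter is expressed on a fixed gradient scale, and mapped back afterwards.

The denoised volume is used only to compute surface costs; intensity
statistics are always taken on the raw voxels (see octmac.metrics).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import SimpleITK as sitk

from .io import AU_MAX, OCTVolume

#: stability bound for the explicit 2D scheme (4-neighbor stencil)
MAX_TIME_STEP_2D = 0.125


def denoise_cad(vol: OCTVolume, conductance: float = 2.0, iterations: int = 5,
                time_step: float = 0.0625) -> OCTVolume:
    """Apply curvature anisotropic diffusion per B-scan.

    Parameters
    ----------
    conductance : float
        Edge-preservation threshold on the [0, 1]-rescaled gradient scale;
        larger values diffuse more across edges.
    iterations : int
        Explicit diffusion steps; 0 returns the input unchanged.
    time_step : float
        Must satisfy the 2D stability bound (<= 0.125); checked before any
        computation.
    """
    if time_step <= 0 or time_step > MAX_TIME_STEP_2D:
        raise ValueError(
            f"time_step {time_step} violates the 2D stability bound (0, {MAX_TIME_STEP_2D}]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return dataclasses.replace(vol, voxels=vol.voxels.copy())

    filt = sitk.CurvatureAnisotropicDiffusionImageFilter()
    filt.SetTimeStep(time_step)
    filt.SetConductanceParameter(conductance)
    filt.SetNumberOfIterations(int(iterations))

    out = np.empty_like(vol.voxels)
    nx, ny, nz = vol.voxels.shape
    for y in range(ny):
        page = vol.voxels[:, y, :].astype(np.float32) / AU_MAX
        img = sitk.GetImageFromArray(page)
        sm = sitk.GetArrayFromImage(filt.Execute(img))
        out[:, y, :] = np.clip(np.rint(sm * AU_MAX), 0, AU_MAX).astype(np.uint16)
    return dataclasses.replace(vol, voxels=out)
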