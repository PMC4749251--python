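"""Surface and surface-set containers shared by the generator and the segmenter."""

from __future__ import annotations

import dataclasses

import numpy as np

from .layers import LAYER_SPAN, N_SURFACES, SURFACE_NAMES


class SurfaceOrderError(ValueError):
    """Raised when a surface stack violates the anterior->posterior ordering."""


@dataclasses.dataclass
class SurfaceSet:
    """Eleven ordered height maps, one depth value per A-scan per surface.

    ``z`` has shape (11, ncols, nbscans); ``z[i, x, y]`` is the depth (voxel
    index) of surface i+1 at A-scan (x, y). Voxel ownership is half-open: a
    voxel at depth d belongs to the band [S_i, S_{i+1}) with S_i <= d < S_{i+1}.
    """

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        if self.z.ndim != 3 or self.z.shape[0] != N_SURFACES:
            raise ValueError(f"expected (11, ncols, nbscans) surface stack, got {self.z.shape}")
        self.z = self.z.astype(np.int32)

    def validate(self, ndepth: int, min_separation: int = 1) -> None:
        """Check ordering, separation and depth bounds; raise naming the pair."""
        if self.z.min() < 0 or self.z.max() >= ndepth:
            raise SurfaceOrderError("surface depth outside the volume depth range")
        gaps = np.diff(self.z, axis=0)
        for i in range(N_SURFACES - 1):
            if gaps[i].min() < min_separation:
                raise SurfaceOrderError(
                    f"surfaces S{i + 1} ({SURFACE_NAMES[i]}) and S{i + 2} "
                    f"({SURFACE_NAMES[i + 1]}) violate the minimum separation "
                    f"{min_separation} (closest gap {gaps[i].min()})"
                )

    def layer_band(self, layer: str) -> tuple:
        """(upper, lower) height maps bounding a named layer, half-open."""
        i, j = LAYER_SPAN[layer]
        return self.z[i], self.z[j]

    @property
    def ncols(self) -> int:
        return self.z.shape[1]

    @property
    def nbscans(self) -> int:
        return self.z.shape[2]
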