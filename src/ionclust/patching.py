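"""Patch-grid planning and extraction.

Square patches are planned at a target physical side length (default 1.5 mm);
when the resulting side in pixels falls below the embedder's minimum input
size, the image is upsampled by the smallest sufficient integer factor.
Strides guarantee a 40-50% overlap between neighbouring patches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ParameterError


@dataclass
class PatchGrid:
    side_px: int
    upsample_factor: int
    stride_px: int
    row_starts: list[int]
    col_starts: list[int]
    effective_pitch_um: float
    upsampled_shape: tuple[int, int]
    needs_padding: bool = False

    @property
    def n_patches(self) -> int:
        return len(self.row_starts) * len(self.col_starts)

    def summary(self) -> str:
        return (f"side_px={self.side_px};stride_px={self.stride_px};"
                f"upsample={self.upsample_factor};n_patches={self.n_patches}")


def _axis_starts(extent: int, side: int, stride: int) -> list[int]:
    starts = list(range(0, extent - side + 1, stride))
    if starts[-1] + side < extent:
        starts.append(extent - side)  # clamp final patch to the border
    return starts


def plan_patch_grid(image_shape: tuple[int, int], pixel_size_um: float,
                    target_mm: float = 1.5, min_side: int = 71,
                    overlap_target: float = 0.5) -> PatchGrid:
    """Plan an overlapping patch grid at a target physical patch side.

    ``side0 = round(target_mm * 1000 / pixel_size_um)`` pixels; if that falls
    short of ``min_side`` the image is upsampled by ``ceil(min_side / side0)``.
    The stride is ``ceil(side * (1 - overlap_target))``, which keeps the
    realized overlap within the 40-50% band for ``overlap_target = 0.5``.
    """
    rows, cols = image_shape
    if rows < 2 or cols < 2:
        raise ParameterError("image must be at least 2x2")
    if not 0.5 <= target_mm <= 3.0:
        raise ParameterError("target_mm must lie in [0.5, 3]")
    if min_side < 1:
        raise ParameterError("min_side must be >= 1")
    if not 0 < overlap_target < 1:
        raise ParameterError("overlap_target must be in (0, 1)")
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be positive")

    side0 = max(int(math.floor(target_mm * 1000.0 / pixel_size_um + 0.5)), 1)
    factor = 1 if side0 >= min_side else math.ceil(min_side / side0)
    side = side0 * factor
    stride = math.ceil(side * (1 - overlap_target))
    up_shape = (rows * factor, cols * factor)

    if up_shape[0] < side or up_shape[1] < side:
        warnings.warn("image smaller than one patch; emitting a single "
                      "reflect-padded patch", stacklevel=2)
        return PatchGrid(side_px=side, upsample_factor=factor, stride_px=stride,
                         row_starts=[0], col_starts=[0],
                         effective_pitch_um=pixel_size_um / factor,
                         upsampled_shape=up_shape, needs_padding=True)

    return PatchGrid(side_px=side, upsample_factor=factor, stride_px=stride,
                     row_starts=_axis_starts(up_shape[0], side, stride),
                     col_starts=_axis_starts(up_shape[1], side, stride),
                     effective_pitch_um=pixel_size_um / factor,
                     upsampled_shape=up_shape)


def upsample_image(image: np.ndarray, factor: int, method: str = "bilinear") -> np.ndarray:
    """Upsample by an integer factor using half-pixel-center bilinear sampling."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ParameterError("factor must be a positive integer")
    if method != "bilinear":
        raise ParameterError(f"unsupported method: {method}")
    image = np.asarray(image, dtype=float)
    if factor == 1:
        return image.copy()
    rows = (np.arange(image.shape[0] * factor) + 0.5) / factor - 0.5
    cols = (np.arange(image.shape[1] * factor) + 0.5) / factor - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(image, [rr, cc], order=1, mode="nearest")


def extract_patches(image: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Slice out the planned patches, row-major by (row_start, col_start)."""
    image = np.asarray(image, dtype=float)
    if image.shape != grid.upsampled_shape:
        raise ParameterError(f"image shape {image.shape} does not match the "
                             f"planned grid {grid.upsampled_shape}")
    if grid.needs_padding:
        # iterate because numpy limits a single reflect pad to the image size
        while image.shape[0] < grid.side_px or image.shape[1] < grid.side_px:
            pad_r = min(max(grid.side_px - image.shape[0], 0), image.shape[0])
            pad_c = min(max(grid.side_px - image.shape[1], 0), image.shape[1])
            image = np.pad(image, ((0, pad_r), (0, pad_c)), mode="symmetric")
    side = grid.side_px
    return [image[r:r + side, c:c + side]
            for r in grid.row_starts for c in grid.col_starts]
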