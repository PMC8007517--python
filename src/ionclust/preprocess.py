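"""Spectral and ion-image preprocessing.

Spectra are TIC-normalized and optionally baseline-corrected with a running
median; individual ion images are then winsorized above an upper quantile and
affinely scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .errors import ParameterError, ValidationError
from .msi_io import IonImage, MSIDataset


@dataclass
class PreprocessConfig:
    winsor_quantile: float = 0.95
    baseline_window: int = 51
    tic_enabled: bool = True

    def __post_init__(self):
        if not 0 < self.winsor_quantile < 1:
            raise ParameterError("winsor_quantile must be in (0, 1)")
        if self.baseline_window < 3 or self.baseline_window % 2 == 0:
            raise ParameterError("baseline_window must be odd and >= 3")


def tic_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Divide a spectrum by its total ion current so it sums to 1.

    A zero-TIC spectrum is returned unchanged with a warning.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if np.any(spectrum < 0):
        raise ValidationError("spectrum intensities must be non-negative")
    tic = spectrum.sum()
    if tic == 0:
        warnings.warn("zero-TIC spectrum left unchanged", stacklevel=2)
        return spectrum.copy()
    return spectrum / tic


def tic_normalize_dataset(dataset: MSIDataset) -> tuple[MSIDataset, int]:
    """TIC-normalize every pixel spectrum; returns (dataset, zero-TIC count)."""
    tics = dataset.intensities.sum(axis=1)
    n_zero = int((tics == 0).sum())
    safe = np.where(tics > 0, tics, 1.0)
    out = dataset.intensities / safe[:, None]
    return MSIDataset(coords=dataset.coords, mz_axis=dataset.mz_axis, intensities=out,
                      pixel_size_um=dataset.pixel_size_um,
                      meta={**dataset.meta, "tic_normalized": "true"}), n_zero


def median_baseline_correct(spectrum: np.ndarray, window: int) -> np.ndarray:
    """Subtract a running-median baseline (replicate edge padding), floor at 0."""
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ParameterError("window must be odd and positive")
    if window > len(spectrum):
        raise ParameterError("window exceeds spectrum length")
    baseline = median_filter(spectrum, size=window, mode="nearest")
    return np.maximum(spectrum - baseline, 0.0)


def winsorize_upper(image: IonImage, q: float = 0.95) -> IonImage:
    """Clip pixels above the q-quantile of the masked pixels to that quantile.

    The quantile uses linear interpolation between order statistics and is
    computed over acquired pixels only; the lower tail is never clipped.
    """
    if not 0 < q < 1:
        raise ParameterError("q must be in (0, 1)")
    if not image.mask.any():
        raise ValidationError("image has an empty mask")
    cap = np.quantile(image.pixels[image.mask], q)
    pixels = np.where(image.mask, np.minimum(image.pixels, cap), 0.0)
    return IonImage(pixels=pixels, mz=image.mz, pixel_size_um=image.pixel_size_um,
                    mask=image.mask)


def scale_unit(image: IonImage) -> IonImage:
    """Affinely map masked pixels to [0, 1]; constant images map to all zeros."""
    if not image.mask.any():
        raise ValidationError("image has an empty mask")
    vals = image.pixels[image.mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        pixels = np.zeros_like(image.pixels)
    else:
        pixels = np.where(image.mask, (image.pixels - lo) / (hi - lo), 0.0)
    return IonImage(pixels=pixels, mz=image.mz, pixel_size_um=image.pixel_size_um,
                    mask=image.mask)


def standardize_image(image: IonImage, q: float = 0.95) -> IonImage:
    """Winsorize above the q-quantile, then scale to [0, 1]."""
    return scale_unit(winsorize_upper(image, q))
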