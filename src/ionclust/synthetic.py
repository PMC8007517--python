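"""Seeded synthetic MSI datasets with known pattern labels and isotope pairs.

Channels come in three flavours: base channels expressing one of a small
library of spatial patterns, isotope companions placed at exactly +1.003 Da
with the same pattern at reduced amplitude, and pure-noise channels. Base m/z
positions sit on a jittered 2.5 Da grid so that no unintended channel pair
lands within an isotope-search window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .evaluation import pearson_corr
from .msi_io import MSIDataset

_SLOT_SPACING = 2.5  # Da between candidate base m/z slots
_ISOTOPE_SHIFT = 1.003


@dataclass
class SyntheticConfig:
    shape: tuple[int, int] = (64, 64)
    n_patterns: int = 4
    channels_per_pattern: int = 10
    isotope_fraction: float = 0.5
    isotope_ratio: float = 0.4
    noise_channels: int = 8
    noise_sigma: float = 0.02
    mz_range: tuple[float, float] = (620.0, 1200.0)
    pixel_size_um: float = 50.0
    seed: int = 7

    def __post_init__(self):
        if self.n_patterns < 0 or self.channels_per_pattern < 0 or self.noise_channels < 0:
            raise ParameterError("counts must be >= 0")
        if not 0 < self.isotope_ratio < 1:
            raise ParameterError("isotope_ratio must be in (0, 1)")
        if not 0 <= self.isotope_fraction <= 1:
            raise ParameterError("isotope_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-channel pattern labels (-1 = pure noise) and engineered pairs."""

    pattern_label: np.ndarray
    isotope_pairs: list[tuple[int, int]]
    partner: np.ndarray = field(default=None)  # companion channel index or -1

    def to_frame(self, mzs: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": np.arange(len(self.pattern_label)),
            "mz": mzs,
            "pattern": self.pattern_label,
            "partner_channel": self.partner,
        })


def _gaussian_blob(shape, rng):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    cy = rng.uniform(0.2, 0.8) * shape[0]
    cx = rng.uniform(0.2, 0.8) * shape[1]
    s = rng.uniform(0.08, 0.18) * min(shape)
    return np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * s ** 2))


def _ring(shape, rng):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    cy = rng.uniform(0.3, 0.7) * shape[0]
    cx = rng.uniform(0.3, 0.7) * shape[1]
    r0 = rng.uniform(0.2, 0.35) * min(shape)
    w = rng.uniform(0.04, 0.08) * min(shape)
    dist = np.hypot(rr - cy, cc - cx)
    return np.exp(-((dist - r0) ** 2) / (2 * w ** 2))


def _half_plane(shape, rng):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    theta = rng.uniform(0, 2 * np.pi)
    proj = np.cos(theta) * rr + np.sin(theta) * cc
    off = rng.uniform(0.35, 0.65) * (proj.max() + proj.min())
    w = 0.05 * min(shape)
    return 1.0 / (1.0 + np.exp(-(proj - off) / w))


def _stripe_band(shape, rng):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    theta = rng.uniform(0, 2 * np.pi)
    proj = np.cos(theta) * rr + np.sin(theta) * cc
    center = rng.uniform(0.3, 0.7) * (proj.max() + proj.min())
    w = rng.uniform(0.06, 0.12) * min(shape)
    return np.exp(-((proj - center) ** 2) / (2 * w ** 2))


_FAMILIES = (_gaussian_blob, _ring, _half_plane, _stripe_band)


def _to_unit(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def generate_pattern_library(shape: tuple[int, int], n_patterns: int,
                             seed: int = 0, max_corr: float = 0.5) -> list[np.ndarray]:
    """Distinct [0,1] spatial patterns with pairwise Pearson correlation <= 0.5."""
    if min(shape) < 16:
        raise ParameterError("shape must be at least 16x16")
    if n_patterns > 12:
        raise ParameterError("at most 12 patterns supported")
    rng = np.random.default_rng(seed)
    patterns: list[np.ndarray] = []
    attempts = 0
    while len(patterns) < n_patterns:
        if attempts > 200 * max(n_patterns, 1):
            raise ParameterError("could not place sufficiently uncorrelated patterns")
        attempts += 1
        family = _FAMILIES[len(patterns) % len(_FAMILIES)]
        cand = _to_unit(family(shape, rng))
        if all(abs(pearson_corr(cand, p)) <= max_corr for p in patterns):
            patterns.append(cand)
    return patterns


def generate_msi_dataset(config: SyntheticConfig) -> tuple[MSIDataset, GroundTruth]:
    """Generate a dataset plus ground truth; deterministic per config."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    n_base = config.n_patterns * config.channels_per_pattern
    n_slots_needed = n_base + config.noise_channels

    lo, hi = config.mz_range
    slots = np.arange(lo + 1.0, hi - _ISOTOPE_SHIFT - 0.2, _SLOT_SPACING)
    if len(slots) < n_slots_needed:
        raise ParameterError(f"mz_range too narrow: need {n_slots_needed} slots "
                             f"at {_SLOT_SPACING} Da spacing, have {len(slots)}")
    chosen = rng.choice(len(slots), size=n_slots_needed, replace=False)
    base_mzs = slots[np.sort(chosen)] + rng.uniform(-0.1, 0.1, size=n_slots_needed)

    patterns = generate_pattern_library(config.shape, config.n_patterns, seed=config.seed)
    n_iso = round(config.isotope_fraction * config.channels_per_pattern)

    channels = []  # (mz, image, pattern_label, base_key or None, key)
    slot_idx = 0
    for p, pattern in enumerate(patterns):
        for c in range(config.channels_per_pattern):
            mz = base_mzs[slot_idx]
            slot_idx += 1
            amp = rng.uniform(0.5, 1.5)
            noise = rng.normal(0, config.noise_sigma, size=config.shape)
            img = np.clip(amp * pattern + noise, 0, None)
            key = f"p{p}c{c}"
            channels.append((mz, img, p, None, key))
            if c < n_iso:
                cnoise = rng.normal(0, config.noise_sigma, size=config.shape)
                cimg = np.clip(amp * config.isotope_ratio * pattern + cnoise, 0, None)
                channels.append((mz + _ISOTOPE_SHIFT, cimg, p, key, key + "+1"))
    for _ in range(config.noise_channels):
        mz = base_mzs[slot_idx]
        slot_idx += 1
        img = np.clip(rng.normal(0.1, max(config.noise_sigma, 0.05), size=config.shape),
                      0, None)
        channels.append((mz, img, -1, None, f"n{slot_idx}"))

    channels.sort(key=lambda ch: ch[0])
    mz_axis = np.array([ch[0] for ch in channels])
    labels = np.array([ch[2] for ch in channels])
    key_to_idx = {ch[4]: k for k, ch in enumerate(channels)}
    partner = np.full(len(channels), -1, dtype=int)
    pairs = []
    for k, ch in enumerate(channels):
        if ch[3] is not None:
            base = key_to_idx[ch[3]]
            pairs.append((min(base, k), max(base, k)))
            partner[base], partner[k] = k, base

    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    intensities = np.column_stack([ch[1].ravel() for ch in channels])

    dataset = MSIDataset(coords=coords, mz_axis=mz_axis, intensities=intensities,
                         pixel_size_um=config.pixel_size_um,
                         meta={"source": "synthetic", "seed": str(config.seed)})
    truth = GroundTruth(pattern_label=labels, isotope_pairs=sorted(pairs),
                        partner=partner)
    return dataset, truth
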