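"""Clustering evaluation: isotope-pair detection, the relative isotope ratio
with its bootstrap null, and the expert-score ranking benchmark.

Two m/z channels form an isotope pair iff their spectral distance is within
``delta`` of 1.003 Da and their ion images correlate (Pearson) at >= 0.85.
The isotope fraction F of a clustering is the fraction of pairs whose members
share a non-noise label; the relative isotope ratio R divides F by its
expectation under size-preserving random relabelings, estimated by bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .msi_io import IonImage

NOISE_LABEL = -1


@dataclass
class IsotopeCriteria:
    mass_shift: float = 1.003
    delta: float = 0.01
    min_corr: float = 0.85

    def __post_init__(self):
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")
        if not -1 <= self.min_corr <= 1:
            raise ParameterError("min_corr must lie in [-1, 1]")


class IsotopePair(NamedTuple):
    i: int
    j: int
    corr: float


@dataclass
class RIRResult:
    F_clust: float
    F_random_mean: float
    F_random_sd: float
    B: int
    R: float
    n_pairs: int


@dataclass
class RankingSegment:
    cutoff: float
    N: int
    hits: int
    fraction: float


def pearson_corr(a: IonImage | np.ndarray, b: IonImage | np.ndarray) -> float:
    """Pearson correlation over jointly masked pixels; NaN for constant input."""
    if isinstance(a, IonImage) and isinstance(b, IonImage):
        if a.shape != b.shape:
            raise ParameterError("images differ in shape")
        mask = a.mask & b.mask
        x, y = a.pixels[mask], b.pixels[mask]
    else:
        x = np.asarray(a, dtype=float).ravel()
        y = np.asarray(b, dtype=float).ravel()
        if x.shape != y.shape:
            raise ParameterError("inputs differ in shape")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")  # constant input: correlation undefined
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def find_isotope_pairs(mzs: Sequence[float], images: Sequence[IonImage],
                       criteria: IsotopeCriteria | None = None) -> list[IsotopePair]:
    """All channel pairs meeting the mass-shift and spatial-correlation criteria."""
    criteria = criteria or IsotopeCriteria()
    mzs = np.asarray(mzs, dtype=float)
    if len(mzs) != len(images):
        raise ParameterError("mzs and images must be aligned")
    if np.any(np.diff(mzs) < 0):
        raise ParameterError("mzs must be sorted ascending")
    pairs = []
    for i in range(len(mzs)):
        for j in range(i + 1, len(mzs)):
            diff = mzs[j] - mzs[i]
            if diff > criteria.mass_shift + criteria.delta:
                break
            if abs(diff - criteria.mass_shift) <= criteria.delta:
                r = pearson_corr(images[i], images[j])
                if np.isfinite(r) and r >= criteria.min_corr:
                    pairs.append(IsotopePair(i, j, r))
    return pairs


def isotope_fraction(pairs: Sequence[IsotopePair | tuple], labels) -> float:
    """Fraction of isotope pairs whose members share a non-noise cluster."""
    if len(pairs) == 0:
        raise UndefinedMetricError("no isotope pairs: fraction undefined")
    labels = np.asarray(labels)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    grouped = (labels[i] == labels[j]) & (labels[i] != NOISE_LABEL)
    return float(grouped.mean())


def random_baseline_fraction(labels, pairs: Sequence, B: int = 1000,
                             seed: int = 0) -> tuple[float, float]:
    """Bootstrap mean/sd of F under uniform label permutations.

    Permuting the label vector preserves every cluster size, including the
    noise block, matching a random clustering with the same cluster sizes.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if len(pairs) == 0:
        raise UndefinedMetricError("no isotope pairs: baseline undefined")
    labels = np.asarray(labels)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    rng = np.random.default_rng(seed)
    fractions = np.empty(B)
    for b in range(B):
        perm = rng.permutation(labels)
        fractions[b] = np.mean((perm[i] == perm[j]) & (perm[i] != NOISE_LABEL))
    return float(fractions.mean()), float(fractions.std())


def relative_isotope_ratio(F_clust: float, F_random_mean: float) -> float:
    """R = F_clust / F_random_mean; higher means better-than-random grouping."""
    if F_random_mean < 0:
        raise ParameterError("F_random_mean must be >= 0")
    if F_random_mean == 0:
        if F_clust == 0:
            raise UndefinedMetricError("0/0: relative isotope ratio undefined")
        warnings.warn("zero random baseline; ratio is infinite", stacklevel=2)
        return float("inf")
    return F_clust / F_random_mean


def evaluate_rir(mzs, images, labels, criteria: IsotopeCriteria | None = None,
                 B: int = 1000, seed: int = 0) -> RIRResult:
    """Convenience wrapper: detect pairs, compute F, baseline, and R."""
    pairs = find_isotope_pairs(mzs, images, criteria)
    F = isotope_fraction(pairs, labels)
    mean, sd = random_baseline_fraction(labels, pairs, B=B, seed=seed)
    return RIRResult(F_clust=F, F_random_mean=mean, F_random_sd=sd, B=B,
                     R=relative_isotope_ratio(F, mean), n_pairs=len(pairs))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ParameterError("cosine similarity undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def ranking_benchmark(target_sets: Mapping[str, tuple[Sequence[float], Sequence[float]]],
                      cutoffs: Sequence[float]) -> list[RankingSegment]:
    """Segment-wise top-N overlap between similarity rankings and expert scores.

    ``target_sets`` maps a set id to ``(similarities, expert_scores)`` aligned
    over candidates. Per cutoff c and per set: the ground-truth set holds the
    candidates scored <= c (N of them); the top N candidates by similarity
    (ties broken by ascending candidate index) are compared against it, and
    hit/N totals are pooled across sets. Sets with N = 0 are skipped.
    """
    segments = []
    for cutoff in cutoffs:
        total_hits = 0
        total_n = 0
        for set_id, (sims, scores) in target_sets.items():
            sims = np.asarray(sims, dtype=float)
            scores = np.asarray(scores, dtype=float)
            if sims.shape != scores.shape:
                raise ParameterError(f"set {set_id!r}: similarities and expert "
                                     "scores are misaligned")
            truth = set(np.nonzero(scores <= cutoff)[0])
            n = len(truth)
            if n == 0:
                continue
            order = np.argsort(-sims, kind="stable")  # stable: index-ascending ties
            top = set(order[:n].tolist())
            total_hits += len(truth & top)
            total_n += n
        if total_n > 0:
            segments.append(RankingSegment(cutoff=float(cutoff), N=total_n,
                                           hits=total_hits,
                                           fraction=total_hits / total_n))
    return segments
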