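"""Acoustic-feature-space utilities.

Syllable renditions carry vectors of named acoustic features (e.g. mean
frequency, duration, spectrotemporal entropy, amplitude entropy,
spectral entropy).  This module selects representative tokens (the
rendition nearest the z-scored centroid), summarizes per-feature
distributions, and compares distributions between birds with the
Bhattacharyya distance — used to quantify acoustic similarity without
any syllable classification step.  Feature extraction from audio is out
of scope: features arrive via the corpus feature CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import SongCorpus


@dataclass
class FeatureDistribution:
    """Gaussian summary of one acoustic feature over syllable renditions."""

    feature_name: str
    mean: float
    variance: float
    n: int
    values: Optional[np.ndarray] = None

    @classmethod
    def from_values(cls, feature_name: str,
                    values: Sequence[float]) -> "FeatureDistribution":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("no values")
        var = float(arr.var(ddof=1)) if arr.size >= 2 else 0.0
        return cls(feature_name, float(arr.mean()), var, int(arr.size), arr)


def median_token(renditions: Sequence[Sequence[float]]) -> int:
    """Index of the rendition closest to the z-scored feature centroid.

    Each feature is z-scored across renditions (a zero-variance feature
    contributes z = 0 for every rendition); the returned index minimizes
    the Euclidean distance to the origin of z-space, ties broken by
    lowest index.
    """
    mat = np.asarray(renditions, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.size == 0:
        raise ValueError("no renditions")
    sd = mat.std(axis=0, ddof=0)
    centered = mat - mat.mean(axis=0)
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    dist = np.sqrt((z ** 2).sum(axis=1))
    return int(np.argmin(dist))  # argmin takes the first minimum


def bhattacharyya_distance(d1: FeatureDistribution,
                           d2: FeatureDistribution) -> float:
    """Bhattacharyya distance between two univariate Gaussians.

    D = 1/4 (mu1-mu2)^2 / (s1^2+s2^2) + 1/2 ln[(s1^2+s2^2) / (2 s1 s2)];
    zero iff the distributions are identical.
    """
    v1, v2 = d1.variance, d2.variance
    if v1 <= 0 or v2 <= 0:
        raise ValueError("variances must be positive")
    dm2 = (d1.mean - d2.mean) ** 2
    return float(0.25 * dm2 / (v1 + v2)
                 + 0.5 * np.log((v1 + v2) / (2.0 * np.sqrt(v1 * v2))))


def bhattacharyya_coefficient_hist(values1: Sequence[float],
                                   values2: Sequence[float],
                                   bins: int = 32) -> float:
    """Empirical-histogram Bhattacharyya distance (shape-robust variant).

    Shared-range histograms; D = -ln sum_k sqrt(p_k q_k).  Offered as an
    alternative to the Gaussian closed form for non-Gaussian features.
    """
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1.0
    p, edges = np.histogram(a, bins=bins, range=(lo, hi), density=False)
    q, _ = np.histogram(b, bins=edges, density=False)
    p = p / p.sum()
    q = q / q.sum()
    bc = float(np.sqrt(p * q).sum())
    return float(-np.log(max(bc, 1e-300)))


def _pooled_feature_values(corpus: SongCorpus) -> dict[str, np.ndarray]:
    names = corpus.feature_names
    if names is None:
        raise ValueError(f"corpus {corpus.bird_id!r} carries no features")
    cols: dict[str, list[float]] = {n: [] for n in names}
    for bout in corpus.bouts:
        for ev in bout.events:
            if ev.features is None:
                continue
            for n in names:
                cols[n].append(ev.features[n])
    return {n: np.asarray(v) for n, v in cols.items()}


def feature_distance_profile(pupil: SongCorpus, reference: SongCorpus,
                             method: str = "gaussian") -> dict:
    """Per-feature Bhattacharyya distances between two corpora.

    Syllable renditions are pooled across types within each corpus (no
    classification step), one distance is computed per shared feature,
    and the mean across features gives the scalar similarity index.
    """
    pv = _pooled_feature_values(pupil)
    rv = _pooled_feature_values(reference)
    if set(pv) != set(rv):
        raise ValueError("corpora carry different feature sets")
    distances: dict[str, float] = {}
    for name in pv:
        if method == "gaussian":
            distances[name] = bhattacharyya_distance(
                FeatureDistribution.from_values(name, pv[name]),
                FeatureDistribution.from_values(name, rv[name]))
        elif method == "histogram":
            distances[name] = bhattacharyya_coefficient_hist(pv[name],
                                                             rv[name])
        else:
            raise ValueError(f"unknown method {method!r}")
    return {"distances": distances,
            "mean_distance": float(np.mean(list(distances.values())))}
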