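"""First-order histogram statistics of a parameter map within a gland ROI.

Captures gland heterogeneity beyond the mean: percentiles (P10, P25,
median, P75, P90), Fisher–Pearson skewness g1, excess kurtosis g2, and
histogram energy/entropy over equal-width bins spanning the observed
range.  Left and right parotid voxels are pooled before statistics, so
one value per patient is produced per (parameter, statistic) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

DEFAULT_N_BINS = 64

PERCENTILE_STATS = {"P10": 10, "P25": 25, "median": 50, "P75": 75, "P90": 90}


@dataclass
class HistogramFeatureSet:
    median: float
    p10: float
    p25: float
    p75: float
    p90: float
    skewness: float  # Fisher–Pearson g1
    kurtosis: float  # excess g2 (normal -> 0)
    energy: float  # in (0, 1]
    entropy: float  # bits, in [0, log2(n_bins)]
    n_voxels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "median": self.median,
            "P10": self.p10,
            "P25": self.p25,
            "P75": self.p75,
            "P90": self.p90,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "energy": self.energy,
            "entropy": self.entropy,
        }


def compute_histogram_features(
    values: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> HistogramFeatureSet:
    """First-order statistics of a voxel-value sample.

    Percentiles use linear interpolation between order statistics.  A
    zero-variance sample yields skewness 0, kurtosis 0, energy 1 and
    entropy 0 by convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    n_bad = int(np.sum(~np.isfinite(v)))
    if n_bad:
        raise ValueError(f"{n_bad} non-finite values in parameter map")
    if v.size < 2:
        raise ValueError("need at least 2 values for histogram features")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    if np.ptp(v) == 0.0:
        skew, kurt, energy, entropy = 0.0, 0.0, 1.0, 0.0
    else:
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, fisher=True, bias=True))
        counts, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
        p = counts / v.size
        energy = float(np.sum(p**2))
        pnz = p[p > 0]
        entropy = float(-np.sum(pnz * np.log2(pnz)))
    return HistogramFeatureSet(
        median=float(p50),
        p10=float(p10),
        p25=float(p25),
        p75=float(p75),
        p90=float(p90),
        skewness=skew,
        kurtosis=kurt,
        energy=energy,
        entropy=entropy,
        n_voxels=int(v.size),
    )


def feature_vector(
    maps: dict[str, np.ndarray | tuple], n_bins: int = DEFAULT_N_BINS
) -> dict[str, float]:
    """Flat `<param>_<stat>` features for one patient.

    Each entry of ``maps`` is either a single voxel-value array or a
    (left, right) pair of per-gland arrays, which are concatenated
    (both-parotid pooling) before statistics.
    """
    out: dict[str, float] = {}
    for name, values in maps.items():
        if isinstance(values, tuple):
            values = np.concatenate([np.asarray(a, dtype=float) for a in values])
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise KeyError(f"parameter map {name!r} is empty")
        feats = compute_histogram_features(values, n_bins=n_bins)
        for stat, val in feats.as_dict().items():
            out[f"{name}_{stat}"] = val
    return out
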