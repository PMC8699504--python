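"""Dose-volume histogram construction, combination, metrics and
time-point interpolation for salivary-gland dosimetry.

A cumulative DVH records, per dose bin, the percentage of the structure
volume receiving at least that dose.  The clinically used scalars here
are the mean dose D_mean (from the differential DVH) and Vx, the volume
percentage receiving ≥ x Gy (V65 for the parotids).  Left and right
glands are combined by volume-weighted averaging of their cumulative
curves; DVHs re-evaluated mid-treatment are interpolated linearly per
bin in fraction number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_WIDTH = 0.1  # Gy


@dataclass
class CumulativeDVH:
    dose_bins: np.ndarray  # Gy, ascending, starting at 0
    cum_volume: np.ndarray  # %, non-increasing, cum_volume[0] == 100
    structure_id: str = "parotid_combined"
    absolute_volume: float | None = None  # cm^3
    time_tag: str | int = "baseline"

    def __post_init__(self) -> None:
        self.dose_bins = np.asarray(self.dose_bins, dtype=float)
        self.cum_volume = np.asarray(self.cum_volume, dtype=float)
        if self.dose_bins.shape != self.cum_volume.shape:
            raise ValueError("dose_bins and cum_volume must have equal length")
        if self.dose_bins[0] != 0.0:
            raise ValueError("dose_bins must start at 0 Gy")
        if np.any(np.diff(self.dose_bins) <= 0):
            raise ValueError("dose_bins must be strictly ascending")
        if np.any(np.diff(self.cum_volume) > 1e-9):
            raise ValueError("cum_volume must be non-increasing")
        if abs(self.cum_volume[0] - 100.0) > 1e-9:
            raise ValueError("cum_volume must start at 100%")
        if np.any((self.cum_volume < -1e-9) | (self.cum_volume > 100 + 1e-9)):
            raise ValueError("cum_volume must lie in [0, 100]")


@dataclass
class GlandVolumeSeries:
    """Structure volume at baseline, the 10th fraction and post-treatment."""

    vol_baseline: float  # cm^3
    vol_10fr: float
    vol_post: float

    def __post_init__(self) -> None:
        if min(self.vol_baseline, self.vol_10fr, self.vol_post) <= 0:
            raise ValueError("gland volumes must be positive")


def dvh_from_doses(
    voxel_doses: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    structure_id: str = "structure",
    absolute_volume: float | None = None,
) -> CumulativeDVH:
    """Cumulative DVH from per-voxel doses: cum[k] = 100·|{d ≥ bin_k}|/n."""
    d = np.asarray(voxel_doses, dtype=float)
    if d.size == 0:
        raise ValueError("empty dose list")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(d.max() / bin_width)) + 2
    bins = np.arange(n_bins) * bin_width
    ds = np.sort(d)
    cum = 100.0 * (d.size - np.searchsorted(ds, bins, side="left")) / d.size
    return CumulativeDVH(bins, cum, structure_id=structure_id,
                         absolute_volume=absolute_volume)


def d_mean(dvh: CumulativeDVH) -> float:
    """Mean dose from the differential DVH (midpoint rule per bin)."""
    dv = -np.diff(dvh.cum_volume)  # % of volume in [bin_k, bin_{k+1})
    mid = (dvh.dose_bins[:-1] + dvh.dose_bins[1:]) / 2.0
    # volume still at/above the last bin edge contributes at that edge
    tail = dvh.cum_volume[-1]
    return float(np.sum(mid * dv) / 100.0 + dvh.dose_bins[-1] * tail / 100.0)


def v_dose(dvh: CumulativeDVH, threshold: float) -> float:
    """Volume percentage receiving ≥ ``threshold`` Gy (linear interpolation)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold > dvh.dose_bins[-1]:
        return 0.0
    return float(np.interp(threshold, dvh.dose_bins, dvh.cum_volume))


def _resample(dvh: CumulativeDVH, bins: np.ndarray) -> np.ndarray:
    return np.interp(bins, dvh.dose_bins, dvh.cum_volume, right=0.0)


def combine_dvhs(a: CumulativeDVH, b: CumulativeDVH,
                 structure_id: str | None = None) -> CumulativeDVH:
    """Volume-weighted combination of two structures' cumulative DVHs."""
    if a.absolute_volume is None or b.absolute_volume is None:
        raise ValueError("both structures need an absolute volume to combine")
    if a.dose_bins.size >= b.dose_bins.size and a.dose_bins[-1] >= b.dose_bins[-1]:
        bins = a.dose_bins
    else:
        bins = b.dose_bins
    va, vb = a.absolute_volume, b.absolute_volume
    cum = (va * _resample(a, bins) + vb * _resample(b, bins)) / (va + vb)
    sid = structure_id or f"{a.structure_id}+{b.structure_id}"
    return CumulativeDVH(bins, cum, structure_id=sid, absolute_volume=va + vb)


def interpolate_dvh(
    a: CumulativeDVH, b: CumulativeDVH, f_a: float, f_b: float, f_target: float
) -> CumulativeDVH:
    """Per-bin linear interpolation/extrapolation between two DVHs in
    fraction number; clipped to [0, 100] with monotonicity repaired (and a
    warning) if extrapolation breaks it."""
    if f_a == f_b:
        raise ValueError("f_a and f_b must differ")
    bins = a.dose_bins
    cb = _resample(b, bins)
    lam = (f_target - f_a) / (f_b - f_a)
    cum = (1 - lam) * a.cum_volume + lam * cb
    cum = np.clip(cum, 0.0, 100.0)
    repaired = np.maximum.accumulate(cum[::-1])[::-1]
    if np.any(repaired != cum):
        warnings.warn("interpolated DVH monotonicity repaired", stacklevel=2)
        cum = repaired
    cum[0] = 100.0
    return CumulativeDVH(bins, cum, structure_id=a.structure_id,
                         absolute_volume=a.absolute_volume,
                         time_tag=f"fraction_{f_target:g}")


def compute_shrinkage(vols: GlandVolumeSeries) -> tuple[float, float]:
    """Relative volume change vs baseline: (ΔVol_10fr %, ΔVol_post %).

    Negative values mean shrinkage.
    """
    base = vols.vol_baseline
    return (
        100.0 * (vols.vol_10fr - base) / base,
        100.0 * (vols.vol_post - base) / base,
    )
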