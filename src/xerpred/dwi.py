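"""Mono-exponential diffusion fitting for multi-b DWI signals.

Two clinical coefficients are produced from the same fitting machinery:

* **ADC** — apparent diffusion coefficient, fitted on b = 0, 500, 800 s/mm²;
  contaminated by perfusion (pseudo-diffusion) at low b.
* **D_t** — perfusion-free tissue diffusion coefficient, fitted on
  b = 300, 500, 800 s/mm² where the pseudo-diffusion compartment has
  decayed away (exp(-b·D*) ≤ e⁻³ for D* ≥ 0.01 mm²/s at b ≥ 300).

The primary estimator is damped nonlinear least squares on the raw signal
(Levenberg–Marquardt), initialised from the log-linear ordinary
least-squares solution.  Negative diffusion estimates are clipped to zero
and flagged rather than rejected, so voxel accounting is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

ADC_B_SUBSET = (0.0, 500.0, 800.0)
DT_B_SUBSET = (300.0, 500.0, 800.0)

_MAX_ITER = 200
_TOL = 1e-12


@dataclass
class BValueSignal:
    """DWI signal of one voxel (or an ROI mean) at multiple b-values."""

    b_values: np.ndarray  # s/mm², strictly increasing
    signals: np.ndarray  # arbitrary units
    voxel_id: str | int = 0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.b_values.shape != self.signals.shape:
            raise ValueError("b_values and signals must have equal length")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if np.any(self.b_values < 0):
            raise ValueError("b_values must be non-negative")


@dataclass
class DiffusionFit:
    """Result of a mono-exponential fit S(b) = s0·exp(−b·d)."""

    s0_hat: float
    d_hat: float  # mm²/s, ≥ 0 (clipped)
    b_subset_used: tuple[float, ...]
    residual_norm: float
    converged: bool
    clipped: bool = False
    voxel_id: str | int = 0
    model_tag: str = "mono"


def fit_monoexponential(
    sig: BValueSignal, b_subset: list[float] | tuple[float, ...] | None = None
) -> DiffusionFit:
    """Fit S(b) = s0·exp(−b·d) on a subset of the acquired b-values.

    Minimises the sum of squared residuals on the raw signal with
    Levenberg–Marquardt, starting from the log-linear OLS solution.
    """
    if b_subset is None:
        b_subset = tuple(sig.b_values)
    b_subset = tuple(float(b) for b in b_subset)
    mask = np.isin(sig.b_values, b_subset)
    missing = sorted(set(b_subset) - set(sig.b_values[mask]))
    if missing:
        raise ValueError(
            f"voxel {sig.voxel_id}: required b-values missing from signal: {missing}"
        )
    b = sig.b_values[mask]
    s = sig.signals[mask]
    if b.size < 2:
        raise ValueError(f"voxel {sig.voxel_id}: need at least 2 b-values to fit")
    if np.any(s <= 0):
        raise ValueError(
            f"voxel {sig.voxel_id}: non-positive signals cannot be fitted"
        )

    # log-linear OLS initialisation: ln S = ln s0 − b·d
    slope, intercept = np.polyfit(b, np.log(s), 1)
    x0 = np.array([np.exp(intercept), -slope])

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-b * p[1]) - s

    sol = least_squares(
        resid, x0, method="lm", xtol=_TOL, ftol=_TOL, gtol=_TOL, max_nfev=_MAX_ITER * 3
    )
    s0_hat, d_hat = float(sol.x[0]), float(sol.x[1])
    clipped = False
    if d_hat < 0:
        warnings.warn(
            f"voxel {sig.voxel_id}: negative diffusion estimate clipped to 0",
            stacklevel=2,
        )
        d_hat = 0.0
        clipped = True
    return DiffusionFit(
        s0_hat=s0_hat,
        d_hat=d_hat,
        b_subset_used=tuple(b),
        residual_norm=float(np.linalg.norm(resid(sol.x))),
        converged=bool(sol.status > 0),
        clipped=clipped,
        voxel_id=sig.voxel_id,
    )


def compute_adc(sig: BValueSignal) -> DiffusionFit:
    """Conventional ADC: mono-exponential fit on b = 0, 500, 800 s/mm²."""
    fit = fit_monoexponential(sig, ADC_B_SUBSET)
    fit.model_tag = "ADC"
    return fit


def compute_dt(sig: BValueSignal) -> DiffusionFit:
    """Perfusion-free D_t: mono-exponential fit on b = 300, 500, 800 s/mm²."""
    fit = fit_monoexponential(sig, DT_B_SUBSET)
    fit.model_tag = "Dt"
    return fit


def roi_summary(fits: list[DiffusionFit]) -> dict:
    """Median diffusion coefficient over the converged voxels of a gland.

    Returns the median, the number of voxels used and the number excluded
    because their fit did not converge.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to summarise")
    d = np.array([f.d_hat for f in converged])
    return {
        "median_d": float(np.median(d)),
        "n_used": len(converged),
        "n_excluded": len(fits) - len(converged),
    }
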