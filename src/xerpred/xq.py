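"""Xerostomia-questionnaire (XQ) trajectory summarisation.

The XQ comprises eight items scored 0–10 each, so the weekly total lies
in [0, 80].  The total-score curve over treatment weeks is fitted by a
second-degree polynomial a0 + a1·t + a2·t², from which three summary
indicators are derived:

* ``XQ_Grad1`` — curve gradient after week 1 of radiotherapy,
* ``XQ_Grad2`` — curve gradient after week 4,
* ``XQ_Int_mid`` — analytic integral of the fitted curve from the start
  of treatment to mid-course (week 3, i.e. after the 15th of 35
  fractions at 5 per week), in score·weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

N_ITEMS = 8
ITEM_MAX = 10
TOTAL_MAX = N_ITEMS * ITEM_MAX
MID_WEEK = 3.0


def total_xq(answers) -> float:
    """Total XQ score: sum of the eight item scores (each in 0–10)."""
    a = np.asarray(answers, dtype=float)
    if a.shape != (N_ITEMS,):
        raise ValueError(f"expected exactly {N_ITEMS} item scores, got {a.shape}")
    bad = np.nonzero((a < 0) | (a > ITEM_MAX))[0]
    if bad.size:
        raise ValueError(f"item {bad[0]} out of range [0, {ITEM_MAX}]: {a[bad[0]]}")
    return float(a.sum())


def fit_quadratic(weeks, totals) -> tuple[float, float, float]:
    """OLS quadratic fit of total score vs treatment week -> (a0, a1, a2).

    Exactly interpolates when there are exactly three distinct weeks;
    missing weeks are simply absent rows (no imputation).
    """
    w = np.asarray(weeks, dtype=float)
    y = np.asarray(totals, dtype=float)
    if np.unique(w).size < 3:
        raise ValueError("need at least 3 distinct weeks for a quadratic fit")
    a2, a1, a0 = np.polyfit(w, y, 2)
    return float(a0), float(a1), float(a2)


def xq_gradients(coeffs) -> tuple[float, float]:
    """Curve gradient a1 + 2·a2·t at weeks 1 and 4 -> (XQ_Grad1, XQ_Grad2)."""
    a0, a1, a2 = coeffs
    return float(a1 + 2 * a2 * 1.0), float(a1 + 2 * a2 * 4.0)


def xq_int_mid(coeffs, mid_week: float = MID_WEEK) -> float:
    """Analytic integral of the fitted curve over [0, mid_week].

    ∫₀ᵐ (a0 + a1·t + a2·t²) dt = a0·m + a1·m²/2 + a2·m³/3; floored at 0
    (with a warning) if the analytic integral is negative.
    """
    if mid_week <= 0:
        raise ValueError("mid_week must be positive")
    a0, a1, a2 = coeffs
    m = float(mid_week)
    val = a0 * m + a1 * m**2 / 2.0 + a2 * m**3 / 3.0
    if val < 0:
        warnings.warn("negative XQ integral floored at 0", stacklevel=2)
        return 0.0
    return float(val)


@dataclass
class XQTrajectory:
    """Weekly total XQ scores with fitted coefficients and indicators."""

    weeks: np.ndarray
    totals: np.ndarray  # each in [0, 80]
    coeffs: tuple[float, float, float] | None = None
    indicators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if self.weeks.shape != self.totals.shape:
            raise ValueError("weeks and totals must have equal length")
        if np.any((self.totals < 0) | (self.totals > TOTAL_MAX)):
            raise ValueError(f"totals must lie in [0, {TOTAL_MAX}]")

    def summarize(self, mid_week: float = MID_WEEK) -> dict[str, float]:
        """Fit the quadratic (if not already fitted) and derive indicators."""
        if self.coeffs is None:
            self.coeffs = fit_quadratic(self.weeks, self.totals)
        g1, g2 = xq_gradients(self.coeffs)
        self.indicators = {
            "XQ_Grad1": g1,
            "XQ_Grad2": g2,
            "XQ_Int_mid": xq_int_mid(self.coeffs, mid_week),
        }
        return dict(self.indicators)
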