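"""DCE-MRI pharmacokinetics: signal-to-concentration conversion, standard
Tofts model fitting and the model-free IAUGC.

The standard Tofts model describes tracer exchange between plasma and the
extravascular extracellular space (EES):

    C_t(t) = Ktrans · ∫₀ᵗ C_p(τ) · exp(−Kep·(t−τ)) dτ

with Ktrans (min⁻¹) the plasma→EES transfer constant, Kep (min⁻¹) the
back-transfer rate and v_e = Ktrans/Kep the fractional EES volume, which
is kept ≤ 1 by the fit parameterisation.  C_p is a population arterial
input function (bi-exponential Weinmann form by default) since no
patient-specific AIF is measured.

Signal is converted to concentration by the linear relative-enhancement
proxy C(t) = κ·(S(t) − S_base)/S_base (no T1 map); κ is a calibration
constant absorbed into the AIF convention, so fitted parameters are
consistent under round-trip but not absolute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

# Weinmann population plasma curve, amplitudes in kg/L, rates in min^-1,
# scaled by a standard 0.1 mmol/kg dose.
WEINMANN_PARAMS = {"a1": 3.99, "a2": 4.78, "m1": 0.144, "m2": 0.0111, "dose": 0.1}


@dataclass
class DynamicSeries:
    """A dynamic time series for one voxel: signal or concentration."""

    times: np.ndarray  # s from acquisition start
    values: np.ndarray
    n_baseline: int = 3  # pre-bolus phases
    is_concentration: bool = False
    voxel_id: str | int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")


@dataclass
class AIFModel:
    """Population arterial input function C_p(t).

    ``form`` is 'weinmann' (bi-exponential decay from the bolus arrival)
    or 'impulse' (a unit-area spike on one sample, useful for tests).
    """

    form: str = "weinmann"
    bolus_arrival: float = 15.0  # s; after 3 baseline phases on a 5 s grid
    params: dict = field(default_factory=lambda: dict(WEINMANN_PARAMS))

    def concentration(self, times_s: np.ndarray) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        if t.size == 0:
            raise ValueError("empty AIF evaluation grid")
        if self.form == "weinmann":
            tm = (t - self.bolus_arrival) / 60.0  # minutes since arrival
            p = self.params
            cp = p["dose"] * (
                p["a1"] * np.exp(-p["m1"] * np.maximum(tm, 0.0))
                + p["a2"] * np.exp(-p["m2"] * np.maximum(tm, 0.0))
            )
            return np.where(tm < 0, 0.0, cp)
        if self.form == "impulse":
            # unit-area impulse on the sample closest to the arrival time
            cp = np.zeros_like(t)
            idx = int(np.argmin(np.abs(t - self.bolus_arrival)))
            dt_min = np.median(np.diff(t)) / 60.0 if t.size > 1 else 1.0
            cp[idx] = 1.0 / dt_min
            return cp
        raise ValueError(f"unknown AIF form: {self.form!r}")


@dataclass
class ToftsFit:
    ktrans_hat: float  # min^-1
    kep_hat: float  # min^-1
    ve_hat: float  # fraction, == ktrans/kep
    iaugc_hat: float  # concentration·s
    residual_norm: float
    converged: bool
    voxel_id: str | int = 0


def signal_to_concentration(series: DynamicSeries, kappa: float = 1.0) -> DynamicSeries:
    """Relative-enhancement conversion C = κ·(S − S_base)/S_base.

    S_base is the mean of the first ``n_baseline`` phases; by construction
    the baseline concentrations average to zero.
    """
    if series.is_concentration:
        raise ValueError("series is already concentration-flagged")
    s_base = float(np.mean(series.values[: series.n_baseline]))
    if s_base <= 0:
        raise ValueError("baseline signal mean must be positive")
    conc = kappa * (series.values - s_base) / s_base
    return DynamicSeries(
        times=series.times.copy(),
        values=conc,
        n_baseline=series.n_baseline,
        is_concentration=True,
        voxel_id=series.voxel_id,
    )


def detect_bolus_arrival(conc: DynamicSeries, threshold_frac: float = 0.1) -> float:
    """Time of bolus arrival: one sample interval before the first sample
    exceeding ``threshold_frac`` of the concentration maximum, floored at 0."""
    if not conc.is_concentration:
        raise ValueError("bolus detection requires a concentration series")
    cmax = float(np.max(conc.values))
    if cmax <= 0:
        raise ValueError("all-zero concentration series: no bolus to detect")
    above = np.nonzero(conc.values > threshold_frac * cmax)[0]
    idx = int(above[0])
    dt = float(np.median(np.diff(conc.times)))
    return max(0.0, float(conc.times[idx]) - dt)


def tofts_concentration(
    times_s: np.ndarray,
    ktrans: float,
    kep: float,
    aif: AIFModel,
    oversample: int = 10,
) -> np.ndarray:
    """Evaluate the Tofts convolution at the acquisition time points.

    Rates are per minute; the convolution integral is computed by
    trapezoidal quadrature on an ``oversample``-times refined uniform
    grid (the AIF is evaluated analytically on the fine grid) and then
    read off at the acquisition samples, which keeps the quadrature
    error of the sharp bolus onset negligible.
    """
    t = np.asarray(times_s, dtype=float)
    t_fine, take = _refined_grid(t, oversample)
    cp = aif.concentration(t_fine)
    return _tofts_from_cp(t_fine / 60.0, cp, ktrans, kep)[take]


def _refined_grid(t: np.ndarray, oversample: int) -> tuple[np.ndarray, np.ndarray]:
    if oversample <= 1 or t.size < 2:
        return t, np.arange(t.size)
    k = int(oversample)
    n_fine = (t.size - 1) * k + 1
    t_fine = np.interp(np.arange(n_fine) / k, np.arange(t.size), t)
    return t_fine, np.arange(0, n_fine, k)


def _tofts_from_cp(
    t_min: np.ndarray, cp: np.ndarray, ktrans: float, kep: float
) -> np.ndarray:
    n = t_min.size
    if n == 1:
        return np.zeros(1)
    dt = np.diff(t_min)
    # Recurrence equivalent to trapezoidal quadrature of cp(τ)·exp(−kep(t_i−τ)):
    #   I_i = r_i·I_{i−1} + Δ_i/2·(cp_{i−1}·r_i + cp_i),   r_i = exp(−kep·Δ_i)
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        from scipy.signal import lfilter

        r = float(np.exp(-kep * dt[0]))
        b = dt[0] / 2.0 * (cp[:-1] * r + cp[1:])
        integral = np.concatenate(([0.0], lfilter([1.0], [1.0, -r], b)))
    else:
        integral = np.zeros(n)
        for i in range(1, n):
            r = np.exp(-kep * dt[i - 1])
            integral[i] = r * integral[i - 1] + dt[i - 1] / 2.0 * (
                cp[i - 1] * r + cp[i]
            )
    return ktrans * integral


def fit_tofts(
    conc: DynamicSeries,
    aif: AIFModel,
    ktrans_max: float = 5.0,
    kep_max: float = 50.0,
    n_starts: int = 3,
) -> ToftsFit:
    """Fit the standard Tofts model to a concentration series.

    Parameterised as (Ktrans, δ) with Kep = Ktrans + δ, δ ≥ 0, which
    enforces v_e = Ktrans/Kep ≤ 1 by construction.  Three multi-start
    initialisations guard against local minima.
    """
    if not conc.is_concentration:
        raise ValueError("fit_tofts requires a concentration series")
    if not (conc.times[0] <= aif.bolus_arrival <= conc.times[-1]):
        raise ValueError("AIF bolus arrival outside the acquisition window")

    t = conc.times
    y = conc.values
    t_fine, take = _refined_grid(t, 10)
    t_min = t_fine / 60.0
    cp = aif.concentration(t_fine)

    def resid(x: np.ndarray) -> np.ndarray:
        ktrans, delta = x
        return _tofts_from_cp(t_min, cp, ktrans, ktrans + delta)[take] - y

    starts = [(0.1, 0.5), (0.5, 2.0), (1.5, 8.0)][: max(1, n_starts)]
    best = None
    for x0 in starts:
        sol = least_squares(
            resid,
            np.array(x0),
            bounds=([0.0, 0.0], [ktrans_max, kep_max]),
            xtol=1e-12,
            ftol=1e-14,
            gtol=1e-12,
            max_nfev=200,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-18:
            break
    ktrans_hat = float(best.x[0])
    kep_hat = float(best.x[0] + best.x[1])
    converged = bool(best.status > 0)
    # boundary candidate: a flat zero curve beats the interior solution
    if 0.5 * float(y @ y) <= best.cost:
        ktrans_hat, kep_hat = 0.0, 0.0
    ve_hat = ktrans_hat / kep_hat if kep_hat > 0 else 0.0
    try:
        arrival = detect_bolus_arrival(conc)
        iaugc = compute_iaugc(conc, arrival)
    except ValueError:
        iaugc = 0.0
    return ToftsFit(
        ktrans_hat=ktrans_hat,
        kep_hat=kep_hat,
        ve_hat=ve_hat,
        iaugc_hat=iaugc,
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=converged,
        voxel_id=conc.voxel_id,
    )


def compute_iaugc(conc: DynamicSeries, arrival: float, window: float = 90.0) -> float:
    """Initial area under the concentration curve over [arrival, arrival+window].

    Trapezoidal integral with linear interpolation at window edges that
    fall between samples.  Units: concentration · s.
    """
    if not conc.is_concentration:
        raise ValueError("IAUGC requires a concentration series")
    t0, t1 = float(arrival), float(arrival) + float(window)
    if t0 < conc.times[0] - 1e-9 or t1 > conc.times[-1] + 1e-9:
        raise ValueError("IAUGC window exceeds the acquired series")
    inside = (conc.times > t0) & (conc.times < t1)
    ts = np.concatenate(([t0], conc.times[inside], [t1]))
    cs = np.interp(ts, conc.times, conc.values)
    return float(np.trapezoid(cs, ts))
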