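"""Synthetic cohort generator for the xerostomia-prediction pipeline.

Emulates, per patient, every raw input the downstream stages consume:

* voxel-level parotid ground-truth parameter fields (Ktrans, Kep, v_e,
  tissue diffusion D_t, perfusion fraction f, pseudo-diffusion D*) with
  log-normal within-gland heterogeneity;
* multi-b DWI decays (IVIM bi-compartment form) and DCE dynamic signal
  series (standard Tofts convolution with a population AIF);
* cumulative DVHs with controllable mean dose and V65;
* weekly 8-item questionnaire trajectories following a quadratic trend;
* a binary 12-month toxicity label (XER_12) drawn from a logistic model
  on z-scored features, with the intercept solved numerically so the
  expected prevalence matches the configured value (33.3% by default).

Group-level calibration: the generator's feature marginals are
log-normal with medians/IQRs set to published group statistics for
head-and-neck cohorts (grade < 2 vs grade 2 medians such as
Ktrans P10 0.28/0.21 min⁻¹, v_e P25 0.15/0.13, V65 6.5/10.1%).  Effect
sizes are solved from the requested group-median separations under a
probit approximation of the logistic selection, so the generated
group-conditional medians approximate the configured targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dce import AIFModel, DynamicSeries, tofts_concentration
from .dosimetry import CumulativeDVH, dvh_from_doses
from .dwi import BValueSignal
from .xq import TOTAL_MAX, XQTrajectory, N_ITEMS, ITEM_MAX

DEFAULT_B_VALUES = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 300.0, 500.0, 800.0)
DCE_N_PHASES = 60
DCE_DT_S = 5.0
DCE_N_BASELINE = 3

FEATURES = ("ve_P25", "Ktrans_P10", "Dmean_Gy", "V65_pct", "Dmean_SMG_Gy", "XQ_Int_mid")

# group medians (grade < 2, grade 2) and grade<2 IQR per feature
GROUP_MEDIANS: dict[str, tuple[float, float]] = {
    "ve_P25": (0.15, 0.13),
    "Ktrans_P10": (0.28, 0.21),
    "Dmean_Gy": (35.8, 41.0),
    "V65_pct": (6.5, 10.1),
    "Dmean_SMG_Gy": (62.5, 64.2),
    "XQ_Int_mid": (51.5, 82.9),
}
GROUP_IQRS: dict[str, float] = {
    "ve_P25": 0.08,
    "Ktrans_P10": 0.20,
    "Dmean_Gy": 6.0,
    "V65_pct": 8.6,
    "Dmean_SMG_Gy": 4.6,
    "XQ_Int_mid": 41.5,
}

# plausible dependence structure of the log-features: dose variables move
# together, the two perfusion summaries move together, acute symptom burden
# tracks the high-dose volume
_R = {
    ("ve_P25", "Ktrans_P10"): 0.6,
    ("Dmean_Gy", "V65_pct"): 0.7,
    ("Dmean_Gy", "Dmean_SMG_Gy"): 0.5,
    ("V65_pct", "Dmean_SMG_Gy"): 0.4,
    ("Dmean_Gy", "XQ_Int_mid"): 0.35,
    ("V65_pct", "XQ_Int_mid"): 0.3,
    ("Dmean_SMG_Gy", "XQ_Int_mid"): 0.25,
}

_Z10 = -1.2815515655446004  # standard-normal 10th percentile
_Z25 = -0.6744897501960817  # standard-normal 25th percentile
_PROBIT_SCALE = 1.7  # logistic(x) ~ Phi(x / 1.7)

# within-gland voxel heterogeneity (log-SD) of the perfusion parameters
VOXEL_SIGMA_KTRANS = 0.4
VOXEL_SIGMA_VE = 0.25


@dataclass
class GroundTruthVoxel:
    """Generative parameters of a single parotid voxel."""

    ktrans_true: float  # min^-1
    kep_true: float  # min^-1
    ve_true: float  # fraction in (0, 1)
    dt_true: float  # mm^2/s
    f_true: float  # perfusion fraction in [0, 1)
    dstar_true: float  # mm^2/s
    s0_true: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.ktrans_true, self.kep_true, self.dt_true, self.dstar_true) < 0:
            raise ValueError("rates and diffusivities must be non-negative")
        if not (0.0 <= self.f_true < 1.0):
            raise ValueError("perfusion fraction must lie in [0, 1)")
        if self.kep_true > 0 and abs(self.ve_true - self.ktrans_true / self.kep_true) > 1e-12:
            raise ValueError("ve_true must equal ktrans_true / kep_true")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 63
    prevalence: float = 1.0 / 3.0
    effect_sizes: dict[str, float] | None = None  # per-feature log-odds betas
    group_medians: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_MEDIANS)
    )
    group_iqrs: dict[str, float] = field(default_factory=lambda: dict(GROUP_IQRS))
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"dwi": 0.02, "dce": 0.01, "xq": 4.0}
    )
    seed: int = 0
    voxels_per_gland: int = 100
    weeks: int = 7  # weekly samples at integer weeks 0..weeks-1

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_patients < 10:
            raise ValueError("need at least 10 patients")


def _sigma_log(median: float, iqr: float) -> float:
    """Log-normal log-SD from a (median, IQR) pair."""
    return float(np.arcsinh(iqr / (2.0 * median)) / -_Z25)


def _correlation_matrix() -> np.ndarray:
    k = len(FEATURES)
    r = np.eye(k)
    idx = {f: i for i, f in enumerate(FEATURES)}
    for (a, b), v in _R.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


def solve_effect_sizes(cfg: CohortConfig) -> dict[str, float]:
    """Log-odds coefficients (on z-scored log-features) that reproduce the
    configured group-median separations.

    Under a probit approximation of the logistic link, the separation of
    the group-conditional means of a standardised feature vector x is
    (Σβ)·φ(h)/(p(1−p)√V), with V = s² + βᵀΣβ and h = Φ⁻¹(p).  Solving
    for β given the target standardised log-median separations d gives
    β ∝ Σ⁻¹d, with the norm fixed self-consistently.  If the requested
    separation exceeds what a logistic mechanism can generate, β is
    scaled down (with a warning).
    """
    p = cfg.prevalence
    d = np.array(
        [
            (np.log(cfg.group_medians[f][1]) - np.log(cfg.group_medians[f][0]))
            / _sigma_log(cfg.group_medians[f][0], cfg.group_iqrs[f])
            for f in FEATURES
        ]
    )
    corr = _correlation_matrix()
    from scipy.stats import norm

    h = norm.ppf(p)
    gain = norm.pdf(h) / (p * (1 - p))  # shift per unit beta/sqrt(V)
    u = np.linalg.solve(corr, d)
    q = float(d @ u)  # = betaᵀΣβ · (gain/√V)⁻²-free quadratic form
    s2 = _PROBIT_SCALE**2
    denom = gain**2 - q
    if denom <= 0.05 * gain**2:
        scale = np.sqrt(0.95 * gain**2 / q)
        warnings.warn(
            "requested group separations exceed the logistic mechanism's "
            f"capacity; effect sizes scaled by {scale:.3f}",
            stacklevel=2,
        )
        d = d * scale
        u = u * scale
        q = float(d @ u)
        denom = gain**2 - q
    v = s2 * gain**2 / denom  # V = s² + βᵀΣβ, solved self-consistently
    beta = np.sqrt(v) / gain * u
    return {f: float(b) for f, b in zip(FEATURES, beta)}


def generate_dwi_signal(
    gt: GroundTruthVoxel,
    b_values=DEFAULT_B_VALUES,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> BValueSignal:
    """IVIM signal S(b) = s0·[f·exp(−b·D*) + (1−f)·exp(−b·D_t)] with
    additive Gaussian noise (SD given as a fraction of s0)."""
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if gt.s0_true <= 0:
        raise ValueError("baseline signal s0 must be positive")
    s = gt.s0_true * (
        gt.f_true * np.exp(-b * gt.dstar_true)
        + (1.0 - gt.f_true) * np.exp(-b * gt.dt_true)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        s = s + rng.normal(0.0, noise_sd * gt.s0_true, size=s.shape)
    return BValueSignal(b_values=b, signals=s, voxel_id=0)


def default_timing(n_phases: int = DCE_N_PHASES, dt_s: float = DCE_DT_S) -> np.ndarray:
    return np.arange(n_phases) * dt_s


def generate_dce_series(
    gt: GroundTruthVoxel,
    timing: np.ndarray | None = None,
    aif: AIFModel | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    as_signal: bool = True,
) -> DynamicSeries:
    """Dynamic series from the Tofts convolution of the ground truth with
    the AIF; the bolus arrives after the baseline phases, so the first
    samples carry zero concentration.

    With ``as_signal`` the concentration is mapped back to signal via the
    inverse relative-enhancement convention S = s0·(1 + C); noise is
    Gaussian with SD a fraction of s0.
    """
    timing = default_timing() if timing is None else np.asarray(timing, dtype=float)
    aif = aif or AIFModel(bolus_arrival=timing[min(DCE_N_BASELINE, timing.size - 1)])
    conc = tofts_concentration(timing, gt.ktrans_true, gt.kep_true, aif)
    if as_signal:
        values = gt.s0_true * (1.0 + conc)
    else:
        values = conc
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        scale = noise_sd * (gt.s0_true if as_signal else 1.0)
        values = values + rng.normal(0.0, scale, size=values.shape)
    return DynamicSeries(
        times=timing,
        values=values,
        n_baseline=DCE_N_BASELINE,
        is_concentration=not as_signal,
    )


def generate_gland_maps(
    cfg: CohortConfig,
    outcome_group: int,
    rng: np.random.Generator | int | None = None,
    ktrans_p10: float | None = None,
    ve_p25: float | None = None,
) -> list[GroundTruthVoxel]:
    """Voxel parameter field of one gland, group-conditionally calibrated.

    Voxel Ktrans and v_e are log-normal with locations chosen so the
    population P10(Ktrans) and P25(v_e) equal the configured group
    targets (overridable per patient via ``ktrans_p10``/``ve_p25``).
    """
    if cfg.voxels_per_gland < 100:
        raise ValueError("voxels_per_gland must be >= 100")
    rng = np.random.default_rng(rng)
    group_idx = 1 if outcome_group else 0
    p10 = ktrans_p10 if ktrans_p10 is not None else cfg.group_medians["Ktrans_P10"][group_idx]
    p25 = ve_p25 if ve_p25 is not None else cfg.group_medians["ve_P25"][group_idx]
    n = cfg.voxels_per_gland
    mu_k = np.log(p10) - _Z10 * VOXEL_SIGMA_KTRANS
    mu_v = np.log(p25) - _Z25 * VOXEL_SIGMA_VE
    ktrans = np.exp(rng.normal(mu_k, VOXEL_SIGMA_KTRANS, n))
    ve = np.clip(np.exp(rng.normal(mu_v, VOXEL_SIGMA_VE, n)), 1e-4, 0.95)
    dt = np.exp(rng.normal(np.log(1.0e-3), 0.10, n))
    f = np.clip(np.exp(rng.normal(np.log(0.10), 0.30, n)), 0.0, 0.4)
    dstar = np.exp(rng.normal(np.log(0.05), 0.30, n))
    return [
        GroundTruthVoxel(
            ktrans_true=float(k),
            kep_true=float(k / v),
            ve_true=float(v),
            dt_true=float(d),
            f_true=float(fi),
            dstar_true=float(ds),
        )
        for k, v, d, fi, ds in zip(ktrans, ve, dt, f, dstar)
    ]


def generate_dvh_pair(
    target_dmean: float,
    target_v65: float,
    bin_width: float = 0.1,
    n_voxels: int = 1000,
    structure_id: str = "parotid_combined",
) -> CumulativeDVH:
    """DVH of a two-component dose distribution hitting the requested
    (D_mean, V65) pair: a ≥ 65 Gy boost component with weight V65/100 and
    a low-dose bath whose level is solved from the mean-dose target.
    """
    if not (0.0 <= target_v65 <= 100.0):
        raise ValueError("V65 target must lie in [0, 100]%")
    if target_dmean < 0:
        raise ValueError("D_mean target must be non-negative")
    w = target_v65 / 100.0
    n_hi = int(round(w * n_voxels))
    if n_hi == n_voxels:
        if target_dmean < 65.0:
            raise ValueError("infeasible: V65=100% requires D_mean >= 65 Gy")
        doses = np.full(n_voxels, target_dmean)
        return dvh_from_doses(doses, bin_width, structure_id=structure_id)
    hi = np.linspace(66.0, 74.0, n_hi) if n_hi > 1 else np.full(n_hi, 70.0)
    lo_mean = (target_dmean * n_voxels - hi.sum()) / (n_voxels - n_hi)
    if lo_mean < -1e-9 or lo_mean > 63.0:
        raise ValueError(
            f"infeasible (D_mean={target_dmean}, V65={target_v65}): "
            f"low-dose component would need mean {lo_mean:.1f} Gy"
        )
    lo_mean = max(lo_mean, 0.0)
    spread = min(5.0, lo_mean, 63.0 - lo_mean)
    lo = np.linspace(lo_mean - spread, lo_mean + spread, n_voxels - n_hi)
    doses = np.concatenate([lo, hi])
    return dvh_from_doses(doses, bin_width, structure_id=structure_id)


def generate_xq_trajectory(
    a0: float,
    a1: float,
    a2: float,
    weeks: int = 7,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> XQTrajectory:
    """Weekly total scores a0 + a1·t + a2·t² at integer weeks 0..weeks−1,
    plus Gaussian noise, clipped to the valid total range [0, 80]."""
    t = np.arange(weeks, dtype=float)
    totals = a0 + a1 * t + a2 * t**2
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        totals = totals + rng.normal(0.0, noise_sd, size=totals.shape)
    totals = np.clip(totals, 0.0, TOTAL_MAX)
    return XQTrajectory(weeks=t, totals=totals)


def coeffs_for_int_mid(target_int_mid: float) -> tuple[float, float, float]:
    """A rising quadratic (zero at week 0, peak at week 6) whose analytic
    integral over [0, 3] equals the target: a2 = −a1/12, ∫ = 3.75·a1."""
    a1 = target_int_mid / 3.75
    return 0.0, a1, -a1 / 12.0


def split_items(total: float, rng: np.random.Generator) -> np.ndarray:
    """Integer 8-item scores summing to round(total), each in [0, 10]."""
    tot = int(round(min(max(total, 0.0), float(TOTAL_MAX))))
    items = np.zeros(N_ITEMS, dtype=int)
    base = tot // N_ITEMS
    items[:] = base
    remainder = tot - base * N_ITEMS
    extra = rng.choice(N_ITEMS, size=remainder, replace=False)
    items[extra] += 1
    return np.clip(items, 0, ITEM_MAX)


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Per-patient feature table with XER_12 labels, plus provenance.

    Features are drawn from correlated log-normal marginals; the label is
    Bernoulli(logistic(α + Σ β·z)) with the intercept α solved by root
    finding so the cohort's expected prevalence equals the configured one.
    """
    rng = np.random.default_rng(cfg.seed)
    beta = cfg.effect_sizes or solve_effect_sizes(cfg)
    beta_vec = np.array([beta.get(f, 0.0) for f in FEATURES])
    sigma = np.array(
        [_sigma_log(cfg.group_medians[f][0], cfg.group_iqrs[f]) for f in FEATURES]
    )
    # marginal log-median between the group targets, placed so the realized
    # conditional medians land on them: mu = ln(med_lt2) + p·Δlog
    dlog = np.array(
        [np.log(cfg.group_medians[f][1] / cfg.group_medians[f][0]) for f in FEATURES]
    )
    mu = np.array([np.log(cfg.group_medians[f][0]) for f in FEATURES]) + cfg.prevalence * dlog

    corr = _correlation_matrix()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((cfg.n_patients, len(FEATURES))) @ chol.T
    x = np.exp(mu + sigma * z)

    eta = z @ beta_vec

    def excess(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta)) - cfg.prevalence)

    try:
        alpha = brentq(excess, -50.0, 50.0)
    except ValueError as err:
        raise ArithmeticError("cannot solve intercept for requested prevalence") from err
    labels = (rng.uniform(size=cfg.n_patients) < expit(alpha + eta)).astype(int)

    table = pd.DataFrame(x, columns=list(FEATURES))
    table.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(cfg.n_patients)])
    table["XER_12"] = labels
    provenance = {
        "seed": cfg.seed,
        "intercept": float(alpha),
        "effect_sizes": {f: float(b) for f, b in zip(FEATURES, beta_vec)},
        "sigma_log": {f: float(s) for f, s in zip(FEATURES, sigma)},
        "mu_log": {f: float(m) for f, m in zip(FEATURES, mu)},
        "prevalence_target": cfg.prevalence,
    }
    return table, provenance


def write_cohort(cfg: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Materialise a full cohort on disk: per-patient raw signals, DVHs
    and questionnaires plus the assembled ``cohort.csv`` feature table.

    Layout: one directory per patient with ``dwi_signals.csv``
    (voxel_id, b, signal), ``dce_series.csv`` (voxel_id, t_s, signal),
    ``dvh_<structure>.csv`` (dose_Gy, cum_volume_pct), ``xq.csv``
    (week, q1..q8) and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, provenance = generate_cohort(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    aif = AIFModel(bolus_arrival=DCE_N_BASELINE * DCE_DT_S)
    timing = default_timing()

    for _, row in table.iterrows():
        pdir = out / str(row["patient_id"])
        pdir.mkdir(exist_ok=True)
        label = int(row["XER_12"])

        voxels = generate_gland_maps(
            cfg, label, rng=rng,
            ktrans_p10=float(row["Ktrans_P10"]), ve_p25=float(row["ve_P25"]),
        ) + generate_gland_maps(
            cfg, label, rng=rng,
            ktrans_p10=float(row["Ktrans_P10"]), ve_p25=float(row["ve_P25"]),
        )

        n_b = len(DEFAULT_B_VALUES)
        dwi_sig = np.empty((len(voxels), n_b))
        dce_sig = np.empty((len(voxels), timing.size))
        for vid, gt in enumerate(voxels):
            dwi_sig[vid] = generate_dwi_signal(
                gt, noise_sd=cfg.noise_sd["dwi"], rng=rng
            ).signals
            dce_sig[vid] = generate_dce_series(
                gt, timing=timing, aif=aif, noise_sd=cfg.noise_sd["dce"], rng=rng
            ).values
        pd.DataFrame(
            {
                "voxel_id": np.repeat(np.arange(len(voxels)), n_b),
                "b": np.tile(np.asarray(DEFAULT_B_VALUES), len(voxels)),
                "signal": dwi_sig.ravel(),
            }
        ).to_csv(pdir / "dwi_signals.csv", index=False)
        pd.DataFrame(
            {
                "voxel_id": np.repeat(np.arange(len(voxels)), timing.size),
                "t_s": np.tile(timing, len(voxels)),
                "signal": dce_sig.ravel(),
            }
        ).to_csv(pdir / "dce_series.csv", index=False)

        dmean, v65 = float(row["Dmean_Gy"]), float(row["V65_pct"])
        v65_max = 97.0 * dmean / 70.0  # keep the low-dose component mean >= 0
        if v65 > v65_max:
            warnings.warn("V65 draw clamped to feasible region", stacklevel=2)
            v65 = v65_max
        dvh = generate_dvh_pair(dmean, v65)
        pd.DataFrame(
            {"dose_Gy": dvh.dose_bins, "cum_volume_pct": dvh.cum_volume}
        ).to_csv(pdir / "dvh_parotid_combined.csv", index=False)

        smg_mean = float(row["Dmean_SMG_Gy"])
        smg_doses = np.linspace(smg_mean - 4.0, smg_mean + 4.0, 400)
        smg = dvh_from_doses(smg_doses, structure_id="smg_combined")
        pd.DataFrame(
            {"dose_Gy": smg.dose_bins, "cum_volume_pct": smg.cum_volume}
        ).to_csv(pdir / "dvh_smg_combined.csv", index=False)

        a0, a1, a2 = coeffs_for_int_mid(float(row["XQ_Int_mid"]))
        traj = generate_xq_trajectory(
            a0, a1, a2, weeks=cfg.weeks, noise_sd=cfg.noise_sd["xq"], rng=rng
        )
        xq_rows = []
        for week, tot in zip(traj.weeks, traj.totals):
            items = split_items(tot, rng)
            xq_rows.append(
                {"week": int(week), **{f"q{i + 1}": int(q) for i, q in enumerate(items)}}
            )
        pd.DataFrame(xq_rows).to_csv(pdir / "xq.csv", index=False)

        gt_json = {
            "label": label,
            "latent_features": {f: float(row[f]) for f in FEATURES},
            "n_voxels": len(voxels),
        }
        (pdir / "ground_truth.json").write_text(json.dumps(gt_json, indent=1))

    table.to_csv(out / "cohort.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return table
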