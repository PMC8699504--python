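"""End-to-end orchestration: simulate → quantify → extract features →
univariate screen → model catalog → pairwise comparison.

Every stage reads and writes plain CSV/JSON artifacts inside one run
directory, and a manifest with SHA-256 checksums makes reruns
verifiable: the same configuration and seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dce, dosimetry, dwi, histogram, model, stats, synthetic, xq

log = logging.getLogger("xerpred")

SCREEN_FEATURES = list(synthetic.FEATURES)


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    seed: int = 0
    n_boot: int = 2000
    auc_min: float = model.AUC_SCREEN_MIN
    use_measured_features: bool = True
    aif_bolus_arrival_s: float = synthetic.DCE_N_BASELINE * synthetic.DCE_DT_S

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_raw = raw.pop("cohort", {})
        ck = set(cohort_raw) - set(synthetic.CohortConfig.__dataclass_fields__)
        if ck:
            raise ValueError(f"unknown cohort config keys: {sorted(ck)}")
        group_medians = cohort_raw.pop("group_medians", None)
        cohort = synthetic.CohortConfig(**cohort_raw)
        if group_medians:
            cohort.group_medians.update(
                {k: tuple(v) for k, v in group_medians.items()}
            )
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path: str | Path) -> None:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(listify(asdict(self)), sort_keys=True))


def quantify_dwi_file(path: str | Path, subset: str = "both") -> pd.DataFrame:
    """Fit ADC and/or D_t for every voxel of a ``dwi_signals.csv`` file."""
    df = pd.read_csv(path)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipped-voxel warnings
        for vid, grp in df.groupby("voxel_id"):
            grp = grp.sort_values("b")
            sig = dwi.BValueSignal(
                grp["b"].to_numpy(), grp["signal"].to_numpy(), voxel_id=vid
            )
            fits = []
            if subset in ("adc", "both"):
                fits.append(dwi.compute_adc(sig))
            if subset in ("dt", "both"):
                fits.append(dwi.compute_dt(sig))
            rows.extend(
                {
                    "voxel_id": vid,
                    "s0_hat": f.s0_hat,
                    "d_hat": f.d_hat,
                    "model_tag": f.model_tag,
                    "converged": f.converged,
                }
                for f in fits
            )
    return pd.DataFrame(rows)


def quantify_dce_file(
    path: str | Path, aif: dce.AIFModel | None = None
) -> pd.DataFrame:
    """Convert each voxel's dynamic signal to concentration and fit the
    Tofts model; returns one row per voxel."""
    df = pd.read_csv(path)
    aif = aif or dce.AIFModel()
    rows = []
    for vid, grp in df.groupby("voxel_id"):
        grp = grp.sort_values("t_s")
        series = dce.DynamicSeries(
            grp["t_s"].to_numpy(), grp["signal"].to_numpy(),
            n_baseline=synthetic.DCE_N_BASELINE, voxel_id=vid,
        )
        conc = dce.signal_to_concentration(series)
        fit = dce.fit_tofts(conc, aif)
        rows.append(
            {
                "voxel_id": vid,
                "ktrans_hat": fit.ktrans_hat,
                "kep_hat": fit.kep_hat,
                "ve_hat": fit.ve_hat,
                "iaugc_hat": fit.iaugc_hat,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def _read_dvh(path: Path, structure_id: str) -> dosimetry.CumulativeDVH:
    df = pd.read_csv(path)
    return dosimetry.CumulativeDVH(
        df["dose_Gy"].to_numpy(), df["cum_volume_pct"].to_numpy(),
        structure_id=structure_id,
    )


def extract_patient_features(pdir: Path, aif: dce.AIFModel | None = None) -> dict:
    """Measured predictor set of one patient from its raw artifacts."""
    tofts = quantify_dce_file(pdir / "dce_series.csv", aif=aif)
    ok = tofts[tofts["converged"]]
    perfusion = histogram.feature_vector(
        {"Ktrans": ok["ktrans_hat"].to_numpy(), "ve": ok["ve_hat"].to_numpy()}
    )
    dvh = _read_dvh(pdir / "dvh_parotid_combined.csv", "parotid_combined")
    smg = _read_dvh(pdir / "dvh_smg_combined.csv", "smg_combined")
    xq_df = pd.read_csv(pdir / "xq.csv")
    totals = [
        xq.total_xq(row[[f"q{i + 1}" for i in range(xq.N_ITEMS)]].to_numpy())
        for _, row in xq_df.iterrows()
    ]
    traj = xq.XQTrajectory(xq_df["week"].to_numpy(dtype=float), np.asarray(totals))
    indicators = traj.summarize()
    return {
        "patient_id": pdir.name,
        "Ktrans_P10": perfusion["Ktrans_P10"],
        "ve_P25": perfusion["ve_P25"],
        "Dmean_Gy": dosimetry.d_mean(dvh),
        "V65_pct": dosimetry.v_dose(dvh, 65.0),
        "Dmean_SMG_Gy": dosimetry.d_mean(smg),
        "XQ_Int_mid": indicators["XQ_Int_mid"],
        "XQ_Grad1": indicators["XQ_Grad1"],
        "XQ_Grad2": indicators["XQ_Grad2"],
    }


def extract_features(cohort_dir: str | Path, aif: dce.AIFModel | None = None) -> pd.DataFrame:
    """Measured feature table for every patient directory in a cohort."""
    cohort_dir = Path(cohort_dir)
    labels = pd.read_csv(cohort_dir / "cohort.csv")[["patient_id", "XER_12"]]
    rows = [
        extract_patient_features(p, aif=aif)
        for p in sorted(cohort_dir.iterdir())
        if p.is_dir()
    ]
    feats = pd.DataFrame(rows)
    return feats.merge(labels, on="patient_id", validate="1:1")


def screen_univariate(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Mann–Whitney univariate screen: median/IQR per outcome group and p."""
    features = features or [f for f in SCREEN_FEATURES if f in table.columns]
    y = table["XER_12"].to_numpy()
    rows = []
    for f in features:
        a = table.loc[y == 0, f].to_numpy()
        b = table.loc[y == 1, f].to_numpy()
        res = stats.mann_whitney(a, b)
        rows.append(
            {
                "feature": f,
                "median_grade_lt2": float(np.median(a)),
                "iqr_grade_lt2": float(np.subtract(*np.percentile(a, [75, 25]))),
                "median_grade2": float(np.median(b)),
                "iqr_grade2": float(np.subtract(*np.percentile(b, [75, 25]))),
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow into ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aif = dce.AIFModel(bolus_arrival=cfg.aif_bolus_arrival_s)

    log.info("stage=simulate n=%d", cfg.cohort.n_patients)
    cohort_dir = out / "cohort"
    latent = synthetic.write_cohort(cfg.cohort, cohort_dir)

    log.info("stage=quantify+features")
    if cfg.use_measured_features:
        feats = extract_features(cohort_dir, aif=aif)
    else:
        feats = latent.copy()
    feats.to_csv(out / "features.csv", index=False)

    log.info("stage=screen")
    screen = screen_univariate(feats)
    screen.to_csv(out / "screen.csv", index=False)

    log.info("stage=catalog")
    reports, retained = model.run_catalog(
        feats.set_index("patient_id"), seed=cfg.seed, n_boot=cfg.n_boot,
        auc_min=cfg.auc_min,
    )
    rows = []
    for i, rep in reports.items():
        row = rep.as_row()
        row["retained"] = i in retained
        rows.append(row)
        payload = {
            "metrics": {k: v for k, v in rep.as_row().items() if k != "model"},
            "ci_95": {k: list(v) for k, v in rep.ci_95.items()},
            "seed": rep.seed,
            "predictions": rep.predictions.to_dict(orient="records"),
        }
        (out / f"report_model{i}.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame(rows).to_csv(out / "models.csv", index=False)

    log.info("stage=compare retained=%s", retained)
    comp_rows = [
        {
            "model_a": i,
            "model_b": j,
            "midp_mcnemar_p": model.compare_models(reports[i], reports[j]).p_value,
        }
        for i in retained
        for j in retained
        if i < j
    ]
    pd.DataFrame(comp_rows, columns=["model_a", "model_b", "midp_mcnemar_p"]).to_csv(
        out / "comparisons.csv", index=False
    )

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "n_patients": cfg.cohort.n_patients,
        "retained_models": retained,
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def render_tables(run_dir: str | Path) -> dict[str, Path]:
    """Render the univariate-screen and model-performance tables from a
    completed run directory as markdown (alongside the CSVs)."""
    run = Path(run_dir)
    missing = [f for f in ("screen.csv", "models.csv") if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing artifacts: {missing}")
    screen = pd.read_csv(run / "screen.csv")
    models = pd.read_csv(run / "models.csv")
    out = {}
    for name, df in [("screen", screen), ("models", models)]:
        path = run / f"{name}.md"
        path.write_text(df.to_markdown(index=False, floatfmt=".3f") + "\n")
        out[name] = path
    return out
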