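"""Prediction-model harness for late xerostomia (XER_12 = RTOG grade ≥ 2
at 12 months after radiotherapy).

The modelling procedure, applied identically to every candidate feature
subset:

1. stratified 5-fold cross-validation with a fixed seed;
2. per fold: z-score normalisation fitted on the training rows only;
3. ADASYN oversampling of the minority (toxicity) class on the
   standardised training rows only — test folds never see synthetic
   points or training statistics;
4. a CART decision-tree classifier (Gini impurity);
5. test-fold scores pooled across folds before metric computation.

Metrics: AUC as the normalised Mann–Whitney rank statistic of the pooled
scores (BCa bootstrap CI); accuracy/sensitivity/specificity/PPV/NPV from
the 0.5-thresholded confusion matrix (Wilson score CIs), with the
toxicity class (label 1) as positive.  Candidate models with pooled
AUC ≤ 0.6 are screened out.  Pairs of models are compared with the
mid-p McNemar test on per-patient correct/incorrect pooled predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.proportion import proportion_confint

from .stats import TestResult, midp_mcnemar

LABEL_COL = "XER_12"
AUC_SCREEN_MIN = 0.6

FEATURE_VE_P25 = "ve_P25"
FEATURE_KTRANS_P10 = "Ktrans_P10"
FEATURE_DMEAN = "Dmean_Gy"
FEATURE_V65 = "V65_pct"
FEATURE_DMEAN_SMG = "Dmean_SMG_Gy"
FEATURE_XQ_INT_MID = "XQ_Int_mid"


@dataclass
class TreeHyper:
    max_depth: int = 4
    min_leaf: int = 5
    criterion: str = "gini"
    random_state: int = 0


@dataclass
class AdasynSettings:
    k: int = 5
    target_ratio: float = 1.0


@dataclass
class ModelSpec:
    features: tuple[str, ...]
    name: str = ""
    stage: str = "baseline"  # 'baseline' or 'in_treatment'
    tree: TreeHyper = field(default_factory=TreeHyper)
    adasyn: AdasynSettings = field(default_factory=AdasynSettings)
    folds: int = 5
    auc_min: float = AUC_SCREEN_MIN

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset must be non-empty")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class PerformanceReport:
    name: str
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float  # %
    sensitivity: float  # %
    specificity: float  # %
    ppv: float  # %
    npv: float  # %
    ci_95: dict[str, tuple[float, float]]
    predictions: pd.DataFrame  # patient_id, fold, score, predicted, true
    seed: int = 0

    def as_row(self) -> dict:
        return {
            "model": self.name,
            "AUC": self.auc,
            "AUC_lo": self.auc_ci[0],
            "AUC_hi": self.auc_ci[1],
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
        }


def zscore_fit_apply(
    train: pd.DataFrame, eval_: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Z-score both frames with mean/SD fitted on the training rows only.

    Zero-variance features are dropped (with a warning) from both frames.
    Returns (train_z, eval_z, dropped_features).
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to standardise")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"zero-variance features dropped: {dropped}", stacklevel=2)
    keep = [c for c in train.columns if c not in dropped]
    train_z = (train[keep] - mu[keep]) / sd[keep]
    eval_z = (eval_[keep] - mu[keep]) / sd[keep]
    return train_z, eval_z, dropped


def adasyn(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class.

    G = (n_maj − n_min)·target_ratio synthetic points are allocated to
    minority points in proportion to r_i, the fraction of majority
    samples among each point's k nearest neighbours (density weighting
    toward harder regions).  Each synthetic point is x_i + λ·(x_z − x_i)
    with λ ~ U(0, 1) and x_z one of x_i's k nearest minority neighbours,
    so every synthetic point lies on a minority–minority segment.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("ADASYN requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class too small for ADASYN (need >= 2); skip balancing")
    G = int(round((n_maj - n_min) * target_ratio))
    if G <= 0:
        return X.copy(), y.copy()

    Xmin = X[y == minority]
    # majority fraction among the k nearest neighbours (self excluded)
    k_all = min(k + 1, len(X))
    nn_all = NearestNeighbors(n_neighbors=k_all).fit(X)
    _, idx = nn_all.kneighbors(Xmin)
    maj_frac = np.array(
        [np.mean(y[row[1:]] != minority) if len(row) > 1 else 0.0 for row in idx]
    )
    if maj_frac.sum() == 0:
        warnings.warn(
            "no majority neighbours anywhere; uniform synthetic allocation",
            stacklevel=2,
        )
        weights = np.full(len(Xmin), 1.0 / len(Xmin))
    else:
        weights = maj_frac / maj_frac.sum()

    # largest-remainder allocation of exactly G points
    raw = weights * G
    g = np.floor(raw).astype(int)
    short = G - g.sum()
    if short > 0:
        order = np.argsort(-(raw - g))
        g[order[:short]] += 1

    k_min = min(k + 1, len(Xmin))
    nn_min = NearestNeighbors(n_neighbors=k_min).fit(Xmin)
    _, idx_min = nn_min.kneighbors(Xmin)

    synth = []
    for i, gi in enumerate(g):
        neighbours = idx_min[i][1:]  # exclude self
        if len(neighbours) == 0:
            neighbours = np.array([i])
        for _ in range(gi):
            z = rng.choice(neighbours)
            lam = rng.uniform()
            synth.append(Xmin[i] + lam * (Xmin[z] - Xmin[i]))
    X_new = np.vstack([X, np.asarray(synth)]) if synth else X.copy()
    y_new = np.concatenate([y, np.full(len(synth), minority, dtype=y.dtype)])
    return X_new, y_new


class _ConstantModel:
    """Fallback when a training fold holds a single class."""

    def __init__(self, score: float):
        self.score = float(score)

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.score)


def train_tree(X: np.ndarray, y: np.ndarray, hyper: TreeHyper | None = None):
    """Fit the CART decision-tree classifier (Gini impurity)."""
    hyper = hyper or TreeHyper()
    if np.unique(y).size < 2:
        warnings.warn("single-class training data: constant model", stacklevel=2)
        return _ConstantModel(float(np.mean(y)))
    tree = DecisionTreeClassifier(
        criterion=hyper.criterion,
        max_depth=hyper.max_depth,
        min_samples_leaf=hyper.min_leaf,
        random_state=hyper.random_state,
    )
    tree.fit(X, y)
    return tree


def _score_positive(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, _ConstantModel):
        return model.predict_proba_pos(X)
    proba = model.predict_proba(X)
    pos_col = int(np.nonzero(model.classes_ == 1)[0][0]) if 1 in model.classes_ else None
    if pos_col is None:
        return np.zeros(len(X))
    return proba[:, pos_col]


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalised Mann–Whitney U statistic (ties averaged)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: pooled truth holds a single class")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def stratified_cv(
    table: pd.DataFrame, spec: ModelSpec, seed: int = 0,
    n_boot: int = 2000,
) -> PerformanceReport:
    """Leakage-safe stratified k-fold CV of one feature subset.

    Per fold: z-score fit on train → ADASYN on standardised train only →
    tree fit → score the untouched test fold; pooled test predictions
    feed the metrics.
    """
    missing = [f for f in spec.features if f not in table.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    y_all = table[LABEL_COL].to_numpy()
    counts = np.bincount(y_all.astype(int), minlength=2)
    if counts.min() < spec.folds:
        raise ValueError(
            f"class with {counts.min()} members cannot be stratified into "
            f"{spec.folds} folds"
        )
    X_df = table[list(spec.features)]
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X_df, y_all)):
        train_z, test_z, _ = zscore_fit_apply(X_df.iloc[tr], X_df.iloc[te])
        Xb, yb = adasyn(
            train_z.to_numpy(), y_all[tr],
            k=spec.adasyn.k, target_ratio=spec.adasyn.target_ratio,
            rng=rng,
        )
        model = train_tree(Xb, yb, spec.tree)
        scores = _score_positive(model, test_z.to_numpy())
        for i, s in zip(te, scores):
            rows.append(
                {
                    "patient_id": table.index[i]
                    if "patient_id" not in table.columns
                    else table["patient_id"].iloc[i],
                    "fold": fold,
                    "score": float(s),
                    "predicted": int(s >= 0.5),
                    "true": int(y_all[i]),
                }
            )
    preds = pd.DataFrame(rows)
    report = compute_metrics(preds, seed=seed, n_boot=n_boot)
    report.name = spec.name or "+".join(spec.features)
    return report


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (0.0, 100.0)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return (100.0 * float(lo), 100.0 * float(hi))


def compute_metrics(
    preds: pd.DataFrame, threshold: float = 0.5, seed: int = 0, n_boot: int = 2000
) -> PerformanceReport:
    """Classification metrics from pooled CV predictions.

    AUC by the rank statistic with a BCa bootstrap CI; proportion metrics
    (as %) with Wilson score CIs.
    """
    y = preds["true"].to_numpy()
    s = preds["score"].to_numpy()
    yhat = (s >= threshold).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: pooled truth holds a single class")
    auc = auc_rank(y, s)

    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    n = len(y)

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    ci = {
        "accuracy": _wilson(tp + tn, n),
        "sensitivity": _wilson(tp, tp + fn),
        "specificity": _wilson(tn, tn + fp),
        "ppv": _wilson(tp, tp + fp),
        "npv": _wilson(tn, tn + fn),
    }
    auc_ci = _auc_bca_ci(y, s, seed=seed, n_boot=n_boot)
    ci["auc"] = auc_ci
    return PerformanceReport(
        name="",
        auc=auc,
        auc_ci=auc_ci,
        accuracy=pct(tp + tn, n),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        ci_95=ci,
        predictions=preds,
        seed=seed,
    )


def _auc_bca_ci(
    y: np.ndarray, s: np.ndarray, seed: int = 0, n_boot: int = 2000
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for the AUC (paired
    resampling of (truth, score))."""
    if n_boot <= 0:
        return (float("nan"), float("nan"))

    def stat(yy, ss):
        yy = np.asarray(yy)
        if np.unique(yy).size < 2:
            return np.nan
        return auc_rank(yy, ss)

    res = sps.bootstrap(
        (y, s),
        stat,
        paired=True,
        vectorized=False,
        n_resamples=n_boot,
        confidence_level=0.95,
        method="BCa",
        rng=np.random.default_rng(seed),
    )
    return (float(res.confidence_interval.low), float(res.confidence_interval.high))


def compare_models(report_a: PerformanceReport, report_b: PerformanceReport) -> TestResult:
    """Mid-p McNemar comparison of two models' pooled CV accuracies."""
    a = report_a.predictions.set_index("patient_id")
    b = report_b.predictions.set_index("patient_id")
    if set(a.index) != set(b.index):
        raise ValueError("reports cover different patient sets")
    b = b.loc[a.index]
    a_ok = (a["predicted"] == a["true"]).to_numpy()
    b_ok = (b["predicted"] == b["true"]).to_numpy()
    return midp_mcnemar(int(np.sum(a_ok & ~b_ok)), int(np.sum(~a_ok & b_ok)))


def model_catalog(**kwargs) -> dict[int, ModelSpec]:
    """The 16 candidate feature subsets: Models 1–7 use baseline-only
    variables; Models 8–16 add the in-treatment XQ integral."""
    ve, kt = FEATURE_VE_P25, FEATURE_KTRANS_P10
    dm, v65, smg, xq = FEATURE_DMEAN, FEATURE_V65, FEATURE_DMEAN_SMG, FEATURE_XQ_INT_MID
    subsets: dict[int, tuple[str, ...]] = {
        1: (ve, dm),
        2: (kt, dm),
        3: (ve, v65),
        4: (kt, v65),
        5: (ve, smg),
        6: (kt, smg),
        7: (ve, v65, smg),
        8: (v65, xq),
        9: (dm, xq),
        10: (ve, v65, xq),
        11: (kt, v65, xq),
        12: (ve, kt, v65, xq),
        13: (ve, v65, smg, xq),
        14: (ve, kt, dm, xq),
        15: (ve, kt, dm, v65, xq),
        16: (ve, kt, dm, v65, smg, xq),
    }
    return {
        i: ModelSpec(
            features=feats,
            name=f"Model {i}",
            stage="baseline" if i <= 7 else "in_treatment",
            **kwargs,
        )
        for i, feats in subsets.items()
    }


def run_catalog(
    table: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 2000,
    auc_min: float = AUC_SCREEN_MIN,
    **spec_kwargs,
) -> tuple[dict[int, PerformanceReport], list[int]]:
    """Cross-validate every catalog model; return all reports and the ids
    retained by the AUC > ``auc_min`` screen."""
    reports = {
        i: stratified_cv(table, spec, seed=seed, n_boot=n_boot)
        for i, spec in model_catalog(**spec_kwargs).items()
    }
    retained = [i for i, r in reports.items() if r.auc > auc_min]
    return reports, retained
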