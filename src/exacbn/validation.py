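"""Internal-external validation: cross-validation, discrimination, calibration.

The outcome is 3-level (0 / 1 / ≥2 severe exacerbations in 12 months); risk
models emit a probability vector per patient.  Discrimination is evaluated at
the two clinically meaningful cuts (≥1 and ≥2) with the rank-based AUC (ties
count one half); confusion metrics use the maximum-probability class
collapsed at the cut.  Calibration follows the logistic-recalibration
convention: the slope is the coefficient of the predicted log-odds in a
refitted logistic model, and the intercept (calibration-in-the-large) comes
from the offset model with the slope fixed at one.  Cross-validation runs
the entire preprocessing and learning pipeline inside each training fold —
discretization maps, imputation models and any rebalancing never see test
patients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import preprocessing as prep
from .bayesnet import fit_cpts, predict_exacerbation_risk
from .data import DiscreteData
from .ensemble import (ExpertConstraints, averaged_network,
                       bootstrap_strengths)
from .graphs import NetworkStructure, pdag_to_dag
from .learners import hill_climb

__all__ = [
    "FoldPlan", "ValidationReport", "PipelineSettings", "make_folds",
    "classification_metrics", "calibration_metrics", "cross_validate",
    "train_test_split_report", "fit_pipeline", "predict_cohort",
]

OUTCOME = "future_exac"
PREDICTORS = ["age", "sex", "crs", "bec", "feno", "fev1pp", "ige",
              "macrolide", "prior_exac"]


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    fold: np.ndarray                     # fold id per row
    scheme: str                          # "kfold(k)" | "loco"
    seed: int | None = None

    @property
    def ids(self) -> list:
        return sorted(pd.unique(self.fold).tolist())


def make_folds(cohort: pd.DataFrame, scheme: str = "kfold", k: int = 10,
               seed: int = 0) -> FoldPlan:
    """Stratified k-fold (by outcome level) or leave-one-country-out folds."""
    n = len(cohort)
    if scheme == "kfold":
        y = cohort[OUTCOME].to_numpy()
        rng = np.random.default_rng(seed)
        fold = np.empty(n, dtype=np.int64)
        start = 0           # rotate remainders so fold sizes differ by <= 1
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            fold[idx] = (np.arange(len(idx)) + start) % k
            start += len(idx)
        return FoldPlan(fold, f"kfold({k})", seed)
    if scheme == "loco":
        countries = cohort["country"].astype(str).to_numpy()
        unique = np.unique(countries)
        if len(unique) < 2:
            raise ValueError("leave-one-country-out needs >= 2 countries")
        mapping = {c: i for i, c in enumerate(unique)}
        return FoldPlan(np.array([mapping[c] for c in countries]), "loco", seed)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _auc(scores: np.ndarray, positive: np.ndarray) -> float | None:
    """Rank (Mann-Whitney) AUC with half credit for ties."""
    n_pos = int(positive.sum())
    n_neg = int(len(positive) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(predictions: np.ndarray, outcomes: np.ndarray,
                           cut: int) -> dict:
    """Discrimination and confusion metrics at a risk cut (1 → ≥1, 2 → ≥2).

    ``predictions`` is an (n, 3) array of class probabilities; class
    assignment for the confusion metrics is by maximum probability, then
    collapsed at the cut.
    """
    if cut not in (1, 2):
        raise ValueError("cut must be 1 (>=1) or 2 (>=2)")
    predictions = np.asarray(predictions, dtype=float)
    outcomes = np.asarray(outcomes)
    pos = outcomes >= cut
    score = predictions[:, cut:].sum(axis=1)
    auc = _auc(score, pos)
    pred_class = predictions.argmax(axis=1) >= cut
    tp = int(np.sum(pred_class & pos))
    tn = int(np.sum(~pred_class & ~pos))
    fp = int(np.sum(pred_class & ~pos))
    fn = int(np.sum(~pred_class & pos))
    return {
        "auc": auc,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "precision": tp / (tp + fp) if tp + fp else None,
        "recall": tp / (tp + fn) if tp + fn else None,
        "accuracy": (tp + tn) / len(outcomes),
        "n_positive": int(pos.sum()),
        "undefined": auc is None,
    }


def calibration_metrics(predicted_probabilities: np.ndarray,
                        binary_outcomes: np.ndarray,
                        tol: float = 1e-8, max_iter: int = 100) -> dict:
    """Logistic-recalibration slope and intercept.

    Slope b from fitting ``y ~ a + b·logit(p)`` by Newton-Raphson; intercept
    from the offset model ``y ~ a + logit(p)`` with the slope fixed at one
    (calibration-in-the-large).  Probabilities at 0/1 are clipped with a
    warning.  A constant predictor leaves the slope undefined (flagged).
    """
    p = np.asarray(predicted_probabilities, dtype=float)
    y = np.asarray(binary_outcomes, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        import warnings
        warnings.warn("probabilities at 0/1 clipped to [1e-6, 1-1e-6]")
        p = np.clip(p, 1e-6, 1 - 1e-6)
    x = np.log(p / (1 - p))
    if np.std(x) < 1e-12:
        a0 = _newton_logistic(np.zeros((len(y), 1)), y, offset=x, tol=tol,
                              max_iter=max_iter)
        return {"slope": None, "intercept": float(a0[0]), "undefined": True}
    X = np.column_stack([np.ones_like(x), x])
    beta = _newton_logistic(X, y, tol=tol, max_iter=max_iter)
    a0 = _newton_logistic(np.ones((len(y), 1)), y, offset=x, tol=tol,
                          max_iter=max_iter)
    return {"slope": float(beta[1]), "intercept": float(a0[0]),
            "undefined": False}


def _newton_logistic(X: np.ndarray, y: np.ndarray, offset=None,
                     tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    off = offset if offset is not None else 0.0
    for _ in range(max_iter):
        eta = X @ beta + off
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -10, 10)
        beta = beta + step
    return beta


# ---------------------------------------------------------------------------
# pipeline over folds
# ---------------------------------------------------------------------------

@dataclass
class PipelineSettings:
    """Per-fold preprocessing + learning configuration."""
    predictors: list[str] = field(default_factory=lambda: list(PREDICTORS))
    recode: prep.RecodeRules | None = None
    impute: bool = True
    discretization: prep.DiscretizationMap | None = None   # default clinical
    rebalance: bool = False
    adasyn_k: int = 5
    structure: str = "hc"                # "hc" | "consensus" | "fixed"
    fixed_structure: NetworkStructure | None = None
    ensemble_algorithms: tuple = ("hc", "tabu", "pc_stable", "gs", "mmpc")
    B: int = 100
    threshold: float = 0.75
    constraints: ExpertConstraints | None = None
    smoothing_alpha: float = 1.0
    seed: int = 0


def fit_pipeline(train: pd.DataFrame, settings: PipelineSettings):
    """Run recode → impute → discretize → (optional) rebalance → learn → fit.

    Returns ``(net, dmap)``: the fitted network and the discretization map to
    reapply to held-out patients.
    """
    cols = settings.predictors + [OUTCOME]
    work = train[cols].copy()
    rules = settings.recode or prep.RecodeRules(
        zero_to_missing=tuple(c for c in ("bec", "feno", "ige")
                              if c in settings.predictors),
        bounds={c: b for c, b in prep.RecodeRules().bounds.items()
                if c in settings.predictors})
    work, _ = prep.recode_zeros_and_outliers(work, rules)
    if settings.impute and work[settings.predictors].isna().any().any():
        work = prep.impute_iterative_forest(
            work, columns=settings.predictors,
            seed=settings.seed).completed
    dmap = settings.discretization or prep.default_clinical_cuts()
    dmap = prep.DiscretizationMap(
        {c: v for c, v in dmap.cuts.items() if c in settings.predictors},
        {c: v for c, v in dmap.labels.items() if c in settings.predictors},
        dmap.method)
    disc = prep.apply_discretization(work, dmap)
    # every predictor is categorical after discretization; int-coded flags
    # must not look numeric to downstream steps (ADASYN would interpolate)
    for c in settings.predictors:
        if not isinstance(disc[c].dtype, pd.CategoricalDtype):
            disc[c] = pd.Categorical(disc[c].astype(str))
    if settings.rebalance:
        X, y = prep.adasyn_balance(disc[settings.predictors],
                                   disc[OUTCOME].astype(str),
                                   k_neighbors=settings.adasyn_k,
                                   seed=settings.seed)
        disc = X.copy()
        disc[OUTCOME] = y

    d = DiscreteData.from_dataframe(disc, cols)
    wl = set(settings.constraints.whitelist) if settings.constraints else set()
    bl = set(settings.constraints.blacklist) if settings.constraints else set()
    if settings.structure == "fixed":
        dag = settings.fixed_structure
        if dag is None:
            raise ValueError("structure='fixed' needs fixed_structure")
    elif settings.structure == "hc":
        dag = hill_climb(d, whitelist=wl, blacklist=bl, seed=settings.seed)
    elif settings.structure == "consensus":
        st = bootstrap_strengths(
            d, algorithms=settings.ensemble_algorithms, B=settings.B,
            constraints=settings.constraints, seed=settings.seed)
        avg = averaged_network(st, settings.threshold)
        dag = pdag_to_dag(avg)
    else:
        raise ValueError(f"unknown structure mode {settings.structure!r}")
    # the outcome must stay in the model even if learning isolated it
    net = fit_cpts(dag, disc, settings.smoothing_alpha)
    return net, dmap


def predict_cohort(net, dmap, test: pd.DataFrame,
                   predictors: list[str]) -> np.ndarray:
    """Outcome probability vectors for held-out patients.

    Missing predictor cells are handled by marginalization (no imputation of
    test data is needed for a generative model).
    """
    disc = prep.apply_discretization(test[predictors], dmap)
    out = np.zeros((len(test), 3))
    levels_cache: dict[tuple, np.ndarray] = {}
    for i, (_, row) in enumerate(disc.iterrows()):
        ev = {}
        for c in predictors:
            if c not in net.dag.nodes:
                continue
            v = row[c]
            if pd.isna(v) or str(v) not in net.levels[c]:
                continue          # marginalize missing / unseen levels
            ev[c] = str(v)
        key = tuple(sorted(ev.items()))
        if key not in levels_cache:
            pred = predict_exacerbation_risk(net, ev)
            probs = np.zeros(3)
            for j, lab in enumerate(pred.levels):
                probs[int(float(lab))] = pred.probabilities[j]
            levels_cache[key] = probs
        out[i] = levels_cache[key]
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    scheme: str
    per_fold: list[dict]
    pooled: dict
    calibration: dict
    config: dict
    predictions: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {"scheme": self.scheme, "per_fold": self.per_fold,
                   "pooled": self.pooled, "calibration": self.calibration,
                   "config": self.config}
        return json.dumps(payload, indent=1, default=_jsonify)

    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _metric_block(pred, y):
    m1 = classification_metrics(pred, y, cut=1)
    m2 = classification_metrics(pred, y, cut=2)
    aucs = [a for a in (m1["auc"], m2["auc"]) if a is not None]
    return {"ge1": m1, "ge2": m2,
            "auc_macro": float(np.mean(aucs)) if aucs else None}


def cross_validate(cohort: pd.DataFrame, settings: PipelineSettings,
                   fold_plan: FoldPlan) -> ValidationReport:
    """Full-pipeline cross-validation; test folds stay untouched."""
    y_all = cohort[OUTCOME].to_numpy().astype(int)
    pred_all = np.full((len(cohort), 3), np.nan)
    per_fold = []
    for fid in fold_plan.ids:
        test_mask = fold_plan.fold == fid
        train = cohort.loc[~test_mask]
        test = cohort.loc[test_mask]
        net, dmap = fit_pipeline(train, settings)
        pred = predict_cohort(net, dmap, test, settings.predictors)
        pred_all[test_mask] = pred
        block = _metric_block(pred, y_all[test_mask])
        block["fold"] = fid if not isinstance(fid, np.generic) else fid.item()
        block["n_test"] = int(test_mask.sum())
        per_fold.append(block)
    pooled = _metric_block(pred_all, y_all)
    calib = {
        "ge1": calibration_metrics(
            np.clip(pred_all[:, 1:].sum(1), 1e-6, 1 - 1e-6), y_all >= 1),
        "ge2": calibration_metrics(
            np.clip(pred_all[:, 2], 1e-6, 1 - 1e-6), y_all >= 2),
    }
    preds = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy()
        if "patient_id" in cohort else np.arange(len(cohort)),
        "fold": fold_plan.fold,
        "P0": pred_all[:, 0], "P1": pred_all[:, 1], "P2": pred_all[:, 2],
        "outcome": y_all,
    })
    config = {"scheme": fold_plan.scheme, "seed": fold_plan.seed,
              "structure": settings.structure, "B": settings.B,
              "threshold": settings.threshold,
              "rebalance": settings.rebalance,
              "predictors": settings.predictors}
    return ValidationReport(fold_plan.scheme, per_fold, pooled, calib,
                            config, preds)


def train_test_split_report(cohort: pd.DataFrame,
                            settings: PipelineSettings,
                            fraction: float = 0.70,
                            seed: int = 0) -> ValidationReport:
    """Single stratified 70:30-style split with calibration on the test part."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    y = cohort[OUTCOME].to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(cohort), dtype=bool)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_tr = int(round(fraction * len(idx)))
        train_mask[idx[:n_tr]] = True
    test = cohort.loc[~train_mask]
    unstable = int((~train_mask).sum()) < 30
    net, dmap = fit_pipeline(cohort.loc[train_mask], settings)
    pred = predict_cohort(net, dmap, test, settings.predictors)
    y_te = y[~train_mask]
    pooled = _metric_block(pred, y_te)
    calib = {
        "ge1": calibration_metrics(
            np.clip(pred[:, 1:].sum(1), 1e-6, 1 - 1e-6), y_te >= 1),
        "ge2": calibration_metrics(
            np.clip(pred[:, 2], 1e-6, 1 - 1e-6), y_te >= 2),
        "unstable": unstable,
    }
    config = {"scheme": f"split({fraction:.2f})", "seed": seed,
              "n_train": int(train_mask.sum()), "n_test": int((~train_mask).sum()),
              "structure": settings.structure}
    report = ValidationReport(f"split({fraction:.2f})", [], pooled, calib,
                              config)
    return report
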