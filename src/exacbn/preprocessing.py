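"""Data-preparation chain: recode → impute → discretize → (train-only) rebalance.

``recode_zeros_and_outliers`` maps zero biomarker readings and out-of-bounds
values to missing.  ``impute_iterative_forest`` is an iterative nonparametric
imputer in the missForest mould: columns are imputed in order of increasing
missingness with a pluggable fit/predict base learner (random forests by
default), looping until the difference statistic between successive
imputations first rises, at which point the previous iteration's table is
returned.  Discretization offers information-preserving Hartemink merging and
fixed clinical cut points; rebalancing is adaptive synthetic (ADASYN)
oversampling of the minority outcome classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "RecodeRules", "recode_zeros_and_outliers",
    "ImputationResult", "impute_iterative_forest",
    "DiscretizationMap", "discretize_hartemink", "fixed_clinical_cuts",
    "apply_discretization", "default_clinical_cuts", "adasyn_balance",
]


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

@dataclass
class RecodeRules:
    """Zero-to-missing targets and per-column plausibility bounds."""
    zero_to_missing: tuple[str, ...] = ("bec", "feno", "ige")
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "age": (18.0, 110.0),
        "bec": (0.0, 10_000.0),
        "feno": (0.0, 500.0),
        "ige": (0.0, 20_000.0),
        "fev1pp": (5.0, 200.0),
    })


def recode_zeros_and_outliers(cohort: pd.DataFrame,
                              rules: RecodeRules | None = None
                              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Return the recoded table and a {column: n recoded} log."""
    rules = rules or RecodeRules()
    for col in set(rules.zero_to_missing) | set(rules.bounds):
        if col not in cohort.columns:
            raise KeyError(f"recode rule references unknown column {col!r}")
    out = cohort.copy()
    log: dict[str, int] = {}
    for col in rules.zero_to_missing:
        mask = out[col] == 0
        if mask.any():
            out.loc[mask, col] = np.nan
            log[col] = log.get(col, 0) + int(mask.sum())
    for col, (lo, hi) in rules.bounds.items():
        vals = out[col]
        mask = vals.notna() & ((vals < lo) | (vals > hi))
        if mask.any():
            out.loc[mask, col] = np.nan
            log[col] = log.get(col, 0) + int(mask.sum())
    return out, log


# ---------------------------------------------------------------------------
# iterative nonparametric imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    completed: pd.DataFrame
    iterations: int
    trace: list[dict[str, float]]          # per-iteration difference statistic


def _default_regressor(seed):
    return RandomForestRegressor(n_estimators=20, max_depth=12,
                                 min_samples_leaf=5, random_state=seed,
                                 n_jobs=1)


def _default_classifier(seed):
    return RandomForestClassifier(n_estimators=20, max_depth=12,
                                  min_samples_leaf=5, random_state=seed,
                                  n_jobs=1)


def impute_iterative_forest(cohort: pd.DataFrame, columns=None,
                            max_iter: int = 10, seed: int = 0,
                            regressor_factory=None, classifier_factory=None,
                            exclude=("patient_id",)) -> ImputationResult:
    """Iteratively impute missing predictor cells.

    Columns are visited in order of increasing missingness (ties broken
    lexicographically).  Continuous columns use the regressor, categorical
    ones the classifier; both honour the fit/predict contract and are
    pluggable.  The loop stops when the difference statistic (squared change
    of imputed values for continuous columns, disagreement fraction for
    categorical ones) first increases for every variable type present, and
    the previous iteration's table is returned; otherwise it runs to
    ``max_iter``.  Columns more than 50% missing are refused.
    """
    regressor_factory = regressor_factory or _default_regressor
    classifier_factory = classifier_factory or _default_classifier
    df = cohort.copy()
    work_cols = [c for c in (columns or df.columns) if c not in exclude]
    miss = {c: df[c].isna().mean() for c in work_cols}
    for c, frac in miss.items():
        if frac > 0.5:
            raise ValueError(
                f"column {c!r} is {frac:.0%} missing (> 50%); refusing to impute")
    targets = sorted((c for c in work_cols if miss[c] > 0),
                     key=lambda c: (miss[c], c))
    if not targets:
        return ImputationResult(df, 0, [])

    masks = {c: df[c].isna().to_numpy() for c in targets}
    numeric = {c: pd.api.types.is_numeric_dtype(df[c]) and
               df[c].dropna().nunique() > 10 for c in work_cols}
    # categorical encoding for predictors
    enc: dict[str, pd.Categorical] = {}
    X = pd.DataFrame(index=df.index)
    for c in work_cols:
        if pd.api.types.is_numeric_dtype(df[c]):
            X[c] = df[c].astype(float)
        else:
            cat = pd.Categorical(df[c])
            enc[c] = cat
            X[c] = cat.codes.astype(float)
            X.loc[df[c].isna(), c] = np.nan

    # initial fill: mean / mode
    for c in work_cols:
        if X[c].isna().any():
            if numeric.get(c, False):
                X[c] = X[c].fillna(X[c].mean())
            else:
                X[c] = X[c].fillna(X[c].mode().iloc[0])

    trace: list[dict[str, float]] = []
    prev = {c: X[c].to_numpy().copy() for c in targets}
    prev_stat = {"continuous": np.inf, "categorical": np.inf}
    iterations = 0
    rng = np.random.SeedSequence(seed)
    for it in range(1, max_iter + 1):
        child_seed = int(rng.spawn(1)[0].generate_state(1)[0] % (2**31))
        for c in targets:
            mask = masks[c]
            feats = [f for f in work_cols if f != c]
            Xtr = X.loc[~mask, feats].to_numpy()
            ytr = X.loc[~mask, c].to_numpy()
            Xmis = X.loc[mask, feats].to_numpy()
            if numeric[c]:
                model = regressor_factory(child_seed)
                model.fit(Xtr, ytr)
                X.loc[mask, c] = model.predict(Xmis)
            else:
                model = classifier_factory(child_seed)
                model.fit(Xtr, ytr.astype(int))
                X.loc[mask, c] = model.predict(Xmis).astype(float)
        # difference statistic per variable type
        dcont_num = dcont_den = 0.0
        dcat_num = dcat_den = 0.0
        for c in targets:
            cur = X[c].to_numpy()[masks[c]]
            old = prev[c][masks[c]]
            if numeric[c]:
                dcont_num += float(np.sum((cur - old) ** 2))
                dcont_den += float(np.sum(cur ** 2))
            else:
                dcat_num += float(np.sum(cur != old))
                dcat_den += float(len(cur))
        stat = {}
        if dcont_den > 0:
            stat["continuous"] = dcont_num / dcont_den
        if dcat_den > 0:
            stat["categorical"] = dcat_num / dcat_den
        trace.append(stat)
        increased = all(stat[k] >= prev_stat.get(k, np.inf) for k in stat)
        if increased and it > 1:
            # first increase: return the previous iteration's imputation
            for c in targets:
                X[c] = prev[c]
            iterations = it - 1
            break
        prev_stat = {k: stat[k] for k in stat}
        for c in targets:
            prev[c] = X[c].to_numpy().copy()
        iterations = it

    out = df.copy()
    for c in targets:
        vals = X[c].to_numpy()
        if c in enc:
            cats = enc[c].categories
            out[c] = pd.Series(
                cats[np.clip(vals.astype(int), 0, len(cats) - 1)],
                index=df.index)
        elif pd.api.types.is_integer_dtype(df[c].dtype) or not numeric[c]:
            out[c] = np.round(vals).astype(float)
        else:
            out[c] = vals
    # observed cells must be untouched
    for c in targets:
        obs = ~masks[c]
        if numeric[c]:
            out.loc[obs, c] = df.loc[obs, c]
        else:
            out.loc[obs, c] = df.loc[obs, c]
    return ImputationResult(out, iterations, trace)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationMap:
    """Ordered cut points and labels per continuous column."""
    cuts: dict[str, tuple[float, ...]]
    labels: dict[str, tuple[str, ...]]
    method: str = "fixed_clinical"

    def __post_init__(self):
        for col, cs in self.cuts.items():
            if any(b <= a for a, b in zip(cs, cs[1:])):
                raise ValueError(f"cuts for {col!r} must be strictly increasing")
            if len(self.labels[col]) != len(cs) + 1:
                raise ValueError(f"{col!r}: need {len(cs) + 1} labels")

    def apply(self, column: pd.Series, col: str) -> pd.Categorical:
        codes = np.searchsorted(np.asarray(self.cuts[col]),
                                column.to_numpy(dtype=float), side="right")
        codes = np.where(column.isna().to_numpy(), -1, codes)
        return pd.Categorical.from_codes(codes.astype(int),
                                         categories=list(self.labels[col]),
                                         ordered=True)

    def to_json(self) -> str:
        import json
        return json.dumps({"method": self.method,
                           "cuts": {c: list(v) for c, v in self.cuts.items()},
                           "labels": {c: list(v) for c, v in self.labels.items()}},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        import json
        d = json.loads(text)
        return cls({c: tuple(v) for c, v in d["cuts"].items()},
                   {c: tuple(v) for c, v in d["labels"].items()},
                   d.get("method", "fixed_clinical"))


def default_clinical_cuts() -> DiscretizationMap:
    """Standard clinical bands for the registry predictors (overridable)."""
    cuts = {
        "age": (40.0, 60.0),
        "bec": (150.0, 300.0),
        "feno": (25.0, 50.0),
        "fev1pp": (60.0, 80.0),
        "ige": (150.0, 600.0),
    }
    labels = {c: _range_labels(v) for c, v in cuts.items()}
    return DiscretizationMap(cuts, labels, "fixed_clinical")


def _range_labels(cuts) -> tuple[str, ...]:
    out = [f"<{cuts[0]:g}"]
    for a, b in zip(cuts, cuts[1:]):
        out.append(f"{a:g}-{b:g}")
    out.append(f">={cuts[-1]:g}")
    return tuple(out)


def fixed_clinical_cuts(column: pd.Series, cuts: tuple[float, ...],
                        labels: tuple[str, ...] | None = None
                        ) -> pd.Categorical:
    """Half-open binning: level i ⇔ value ∈ [cut_{i−1}, cut_i); boundary up."""
    cuts = tuple(cuts)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cuts must be strictly increasing")
    labels = tuple(labels) if labels is not None else _range_labels(cuts)
    dmap = DiscretizationMap({"_": cuts}, {"_": labels})
    return dmap.apply(column, "_")


def _pairwise_mi(cols: list[np.ndarray]) -> float:
    """Total mutual information over all unordered column pairs."""
    total = 0.0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            total += _mi(cols[i], cols[j])
    return total


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    ka, kb = a.max() + 1, b.max() + 1
    tab = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    tab = tab / tab.sum()
    pa = tab.sum(1, keepdims=True)
    pb = tab.sum(0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = tab * np.log(tab / (pa * pb))
    return float(np.nansum(term))


def discretize_hartemink(cohort: pd.DataFrame, columns: list[str],
                         target_levels: int = 3, initial_bins: int = 6
                         ) -> tuple[pd.DataFrame, DiscretizationMap]:
    """Information-preserving discretization (Hartemink's criterion).

    Each continuous column is first quantile-binned into ``initial_bins``;
    then, in round-robin over the columns, adjacent bins are merged greedily,
    each step collapsing the pair whose merge loses the least total pairwise
    mutual information with all other variables, until ``target_levels``
    remain.
    """
    if target_levels < 2:
        raise ValueError("target_levels must be >= 2")
    if initial_bins < target_levels:
        raise ValueError("initial_bins must be >= target_levels")
    work: dict[str, np.ndarray] = {}
    edges: dict[str, list[float]] = {}
    other_codes: list[np.ndarray] = []
    other_names: list[str] = []
    for c in cohort.columns:
        s = cohort[c]
        if c in columns:
            if not pd.api.types.is_numeric_dtype(s):
                raise TypeError(f"column {c!r} is not numeric")
            if s.isna().any():
                raise ValueError(f"column {c!r} has missing values; impute first")
            vals = s.to_numpy(dtype=float)
            if np.unique(vals).size <= 1:
                import warnings
                warnings.warn(f"column {c!r} is constant; single level emitted")
                work[c] = np.zeros(len(vals), dtype=np.int64)
                edges[c] = []
                continue
            qs = np.quantile(vals, np.linspace(0, 1, initial_bins + 1)[1:-1])
            qs = np.unique(qs)
            codes = np.searchsorted(qs, vals, side="right")
            work[c] = codes.astype(np.int64)
            edges[c] = list(qs)
        else:
            other_codes.append(pd.Categorical(s).codes.astype(np.int64))
            other_names.append(c)

    def context(col):
        return [work[o] for o in work if o != col] + other_codes

    pending = True
    while pending:
        pending = False
        for c in sorted(work):
            k = work[c].max() + 1
            if k <= target_levels or not edges[c]:
                continue
            pending = True
            ctx = context(c)
            best = None
            for cut_idx in range(len(edges[c])):      # merge bins cut_idx|cut_idx+1
                merged = work[c].copy()
                merged[merged > cut_idx] -= 1
                mi = sum(_mi(merged, o) for o in ctx)
                if best is None or mi > best[0] + 1e-15:
                    best = (mi, cut_idx)
            _, cut_idx = best
            edges[c].pop(cut_idx)
            work[c][work[c] > cut_idx] -= 1

    out = cohort.copy()
    cuts, labels = {}, {}
    for c in work:
        cs = tuple(edges[c])
        if cs:
            labs = _range_labels(cs)
            cuts[c] = cs
            labels[c] = labs
            out[c] = pd.Categorical.from_codes(
                work[c], categories=list(labs), ordered=True)
        else:
            cuts[c] = ()
            labels[c] = ("all",)
            out[c] = pd.Categorical.from_codes(
                np.zeros(len(out), dtype=int), categories=["all"], ordered=True)
    return out, DiscretizationMap(cuts, labels, "hartemink")


def apply_discretization(cohort: pd.DataFrame, dmap: DiscretizationMap
                         ) -> pd.DataFrame:
    """Apply a fitted map (train-time cuts) to a new table."""
    out = cohort.copy()
    for c in dmap.cuts:
        if c in out.columns and dmap.cuts[c]:
            out[c] = dmap.apply(out[c], c)
    return out


# ---------------------------------------------------------------------------
# ADASYN
# ---------------------------------------------------------------------------

def adasyn_balance(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                   k_neighbors: int = 5, target_ratio: float = 1.0,
                   seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Adaptive synthetic oversampling of minority classes.

    For each minority class, G = (N_majority − N_minority) × ``target_ratio``
    synthetic rows are generated.  Generation is allocated across minority
    seed rows proportionally to the fraction of majority-class points among
    each seed's k nearest neighbours (largest-remainder rounding, so the total
    is exact).  Continuous features are interpolated between the seed and a
    random same-class neighbour; categorical features are copied from the
    seed.  Original rows are preserved.
    """
    labels = np.asarray(labels)
    if features.isna().any().any():
        raise ValueError("features must be fully observed")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    maj = classes[np.argmax(counts)]
    n_maj = counts.max()
    rng = np.random.default_rng(seed)

    num_cols = [c for c in features.columns
                if pd.api.types.is_numeric_dtype(features[c])
                and not isinstance(features[c].dtype, pd.CategoricalDtype)]
    Xnum = features[num_cols].to_numpy(dtype=float) if num_cols else None
    # neighbour metric: numeric columns (standardised) + one-hot of the rest
    parts = []
    if num_cols:
        Z = features[num_cols].to_numpy(dtype=float)
        sd = Z.std(axis=0)
        parts.append((Z - Z.mean(0)) / np.where(sd > 0, sd, 1.0))
    cat_cols = [c for c in features.columns if c not in num_cols]
    for c in cat_cols:
        codes = pd.get_dummies(features[c]).to_numpy(dtype=float)
        parts.append(codes)
    M = np.hstack(parts)

    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(M)
    new_rows: list[pd.DataFrame] = []
    new_labels: list[np.ndarray] = []
    for cls, n_cls in zip(classes, counts):
        if cls == maj or n_cls >= n_maj:
            continue
        if n_cls < k_neighbors + 1:
            raise ValueError(
                f"minority class {cls!r} has {n_cls} rows; needs at least "
                f"k_neighbors + 1 = {k_neighbors + 1}")
        G = int(round((n_maj - n_cls) * target_ratio))
        if G <= 0:
            continue
        idx_cls = np.flatnonzero(labels == cls)
        _, nbr = nn_all.kneighbors(M[idx_cls])
        nbr = nbr[:, 1:]
        r = (labels[nbr] == maj).mean(axis=1)
        if r.sum() <= 0:
            alloc_frac = np.full(len(idx_cls), 1.0 / len(idx_cls))
        else:
            alloc_frac = r / r.sum()
        g = np.floor(alloc_frac * G).astype(int)
        rem = G - g.sum()
        if rem > 0:
            frac = alloc_frac * G - g
            order = np.argsort(-frac)
            g[order[:rem]] += 1
        # same-class neighbours for interpolation
        nn_cls = NearestNeighbors(
            n_neighbors=min(k_neighbors + 1, len(idx_cls))).fit(M[idx_cls])
        _, nbr_cls = nn_cls.kneighbors(M[idx_cls])
        seed_pos = np.repeat(np.arange(len(idx_cls)), g)       # within-class
        if nbr_cls.shape[1] > 1:
            pick = rng.integers(1, nbr_cls.shape[1], size=len(seed_pos))
            partner_pos = nbr_cls[seed_pos, pick]
        else:
            partner_pos = seed_pos
        synth = features.iloc[idx_cls[seed_pos]].copy().reset_index(drop=True)
        if num_cols:
            lam = rng.random(len(seed_pos))[:, None]
            a = Xnum[idx_cls[seed_pos]]
            b = Xnum[idx_cls[partner_pos]]
            synth[num_cols] = a + lam * (b - a)
        if len(synth):
            new_rows.append(synth)
            new_labels.append(np.full(len(synth), cls, dtype=labels.dtype))

    if not new_rows:
        return features.copy(), labels.copy()
    out_X = pd.concat([features, *new_rows], ignore_index=True)
    out_y = np.concatenate([labels, *new_labels])
    return out_X, out_y
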