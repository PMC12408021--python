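"""Random-forest case/control classification protocol.

Features are species (or genus) relative abundances with mean abundance
above 1%, optionally excluding therapeutically administered probiotic
species. Evaluation is stratified 5-fold cross-validation; within each
training fold features are standardised, a class-weighted forest is fit,
and the lowest-Gini-importance decile of features is dropped iteratively
until at most ``n_keep`` remain, before predicting the held-out fold.
Attribution is signed permutation importance (an adapter point is left for
exact Shapley values).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .cohort import CohortTable
from .tables import FeatureTable

DEFAULT_EXCLUDE = ("Lacticaseibacillus_rhamnosus",)

#: age strata on sample collection age (months); samples in (4, 6] appear
#: only in the all-samples stratum
AGE_STRATA = {"le4m": (0.0, 4.0), "gt6m": (6.0, np.inf), "all": (0.0, np.inf)}


@dataclass
class ClassifierReport:
    stratum: str
    per_class_accuracy: dict
    confusion: pd.DataFrame
    selected_features: list
    attributions: pd.DataFrame
    n_samples: int


def prepare_features(table: FeatureTable, cohort: CohortTable,
                     min_mean_abundance: float = 0.01,
                     exclude=DEFAULT_EXCLUDE,
                     age_range: tuple | None = None
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (samples x features) and case/control labels.

    Keeps features with mean relative abundance strictly above the
    threshold and drops excluded names. Standardisation happens inside the
    training folds of :func:`train_evaluate`, never here.
    """
    rel = table.to_relative()
    meta = cohort.merged.set_index("sample_id")
    samples = [s for s in rel.sample_ids if s in meta.index]
    if age_range is not None:
        lo, hi = age_range
        ages = meta.loc[samples, "age_months"]
        samples = [s for s in samples if lo <= ages[s] <= hi]
    data = rel.data[samples]
    means = data.mean(axis=1)
    keep = [f for f in data.index
            if means[f] > min_mean_abundance and f not in set(exclude)]
    if not keep:
        raise ValueError("no features survive the abundance filter")
    x = data.loc[keep].T
    zero_var = x.columns[x.std(axis=0) == 0].tolist()
    if zero_var:
        x.attrs["zero_variance"] = zero_var
    y = meta.loc[samples, "group"]
    return x, y


def _eliminate(x_train: np.ndarray, y_train, features: list, n_keep: int,
               rng_seed: int, n_estimators: int) -> tuple[list, RandomForestClassifier]:
    """Drop the lowest-Gini decile of features per iteration until
    <= n_keep remain; return surviving features and the refit forest."""
    current = list(range(len(features)))
    rf = None
    while True:
        rf = RandomForestClassifier(n_estimators=n_estimators,
                                    class_weight="balanced",
                                    random_state=rng_seed, n_jobs=1)
        rf.fit(x_train[:, current], y_train)
        if len(current) <= n_keep:
            break
        imp = rf.feature_importances_
        n_drop = min(math.ceil(0.1 * len(current)), len(current) - n_keep)
        order = np.argsort(imp, kind="stable")
        drop = set(order[:n_drop])
        current = [c for i, c in enumerate(current) if i not in drop]
    return [features[i] for i in current], rf


def train_evaluate(features: pd.DataFrame, labels: pd.Series,
                   n_keep: int = 120, folds: int = 5, seed: int = 0,
                   n_estimators: int = 500,
                   stratum: str = "all") -> ClassifierReport:
    """Stratified k-fold cross-validated random forest with in-fold
    standardisation and Gini-based feature elimination.

    Per-class correct-classification rates are aggregated over held-out
    folds. A final model on all samples (same elimination schedule)
    provides the selected features and permutation attributions.
    Deterministic given ``seed``.
    """
    x = features.values.astype(float)
    y = labels.values
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError("need >= folds samples per class")
    names = list(features.columns)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true_all, y_pred_all = [], []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        scaler = StandardScaler().fit(x[tr])
        x_tr, x_te = scaler.transform(x[tr]), scaler.transform(x[te])
        kept, rf = _eliminate(x_tr, y[tr], names, n_keep, seed + fold,
                              n_estimators)
        idx = [names.index(f) for f in kept]
        y_pred_all.extend(rf.predict(x_te[:, idx]))
        y_true_all.extend(y[te])
    cm = confusion_matrix(y_true_all, y_pred_all, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    per_class = {c: float(cm[i, i] / cm[i].sum()) for i, c in enumerate(classes)}

    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    kept, rf = _eliminate(xs, y, names, n_keep, seed, n_estimators)
    idx = [names.index(f) for f in kept]
    attr = attribution(rf, pd.DataFrame(xs[:, idx], columns=kept),
                       pd.Series(y), seed=seed)
    return ClassifierReport(stratum, per_class, confusion, kept, attr, len(y))


def attribution(model, features: pd.DataFrame, labels: pd.Series,
                seed: int = 0, n_repeats: int = 10) -> pd.DataFrame:
    """Signed permutation attribution.

    Importance = mean increase in log loss of the predicted class
    probabilities when the feature is permuted; sign = sign of the
    correlation between the feature and the predicted case probability.
    """
    rng = np.random.default_rng(seed)
    x = features.values.astype(float)
    y = labels.values
    case_idx = list(model.classes_).index("case") if "case" in model.classes_ \
        else int(np.argmax(model.classes_))
    proba = model.predict_proba(x)[:, case_idx]
    y_bin = (y == model.classes_[case_idx]).astype(int)
    baseline = log_loss(y_bin, proba, labels=[0, 1])
    rows = []
    for j, name in enumerate(features.columns):
        drops = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            drops.append(log_loss(
                y_bin, model.predict_proba(xp)[:, case_idx], labels=[0, 1])
                - baseline)
        col = x[:, j]
        sign = 0.0
        if np.std(col) > 0 and np.std(proba) > 0:
            sign = float(np.sign(np.corrcoef(col, proba)[0, 1]))
        mean_drop = float(np.mean(drops))
        rows.append({"feature": name, "importance": mean_drop,
                     "signed_importance": mean_drop * (sign if sign != 0 else 1.0),
                     "direction": "case-associated" if sign > 0
                     else ("control-associated" if sign < 0 else "neutral")})
    return (pd.DataFrame(rows)
            .sort_values("importance", ascending=False)
            .reset_index(drop=True))


def classify_strata(table: FeatureTable, cohort: CohortTable,
                    n_keep: int = 120, folds: int = 5, seed: int = 0,
                    n_estimators: int = 500,
                    exclude=DEFAULT_EXCLUDE) -> dict[str, ClassifierReport]:
    """Run the full protocol for the <=4 months, >6 months and all-samples
    strata."""
    out = {}
    for name, (lo, hi) in AGE_STRATA.items():
        x, y = prepare_features(table, cohort, exclude=exclude,
                                age_range=(lo, hi))
        out[name] = train_evaluate(x, y, n_keep=n_keep, folds=folds,
                                   seed=seed, n_estimators=n_estimators,
                                   stratum=name)
    return out
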