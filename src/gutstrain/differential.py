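"""Per-feature multivariable association model for compositional tables.

Relative abundances are arcsine-square-root transformed and regressed on
clinical fixed effects (case/control group, delivery mode, age, probiotic
use) by ordinary least squares, one model per feature; per-covariate Wald
p-values are Benjamini-Hochberg adjusted across features. Works identically
for taxonomic and pathway tables.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .tables import FeatureTable

log = logging.getLogger(__name__)

#: design-matrix encodings: covariate -> (column builder, reference note)
DEFAULT_COVARIATES = ("group", "delivery", "age", "probiotic")


def ast_transform(x):
    """Arcsine square-root transform arcsin(sqrt(x)) for proportions."""
    x = np.asarray(x, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(x))


def filter_features(table: FeatureTable, min_abundance: float = 0.001,
                    min_prevalence: float = 0.10) -> FeatureTable:
    """Keep features reaching ``min_abundance`` relative abundance in at
    least a ``min_prevalence`` fraction of samples."""
    for t in (min_abundance, min_prevalence):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    frac = (table.data >= min_abundance).mean(axis=1)
    keep = frac[frac >= max(min_prevalence, np.finfo(float).tiny)].index
    if min_prevalence == 0:  # limit: max-abundance rule
        keep = table.data.index[(table.data >= min_abundance).any(axis=1)]
    return table.subset_features(list(keep))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _design_matrix(meta: pd.DataFrame, covariates) -> pd.DataFrame:
    """Treatment coding: control / vaginal / no-probiotic are references."""
    cols = {"const": np.ones(len(meta))}
    for cov in covariates:
        if cov == "group":
            cols["group"] = (meta["group"] == "case").astype(float).values
        elif cov == "delivery":
            cols["delivery"] = (meta["delivery_mode"] != "vaginal").astype(float).values
        elif cov == "age":
            cols["age"] = meta["age_months"].astype(float).values
        elif cov == "probiotic":
            cols["probiotic"] = meta["probiotic_first_year"].astype(bool).astype(float).values
        else:
            cols[cov] = pd.to_numeric(meta[cov]).values
    return pd.DataFrame(cols, index=meta.index)


def _check_rank(design: pd.DataFrame):
    x = design.values
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return
    constant = [c for c in design.columns if c != "const"
                and np.ptp(design[c].values) == 0]
    if constant:
        raise ValueError("design matrix rank-deficient; covariates with no "
                         f"variation in the subset: {constant}")
    for col in design.columns:
        if col == "const":
            continue
        reduced = design.drop(columns=[col]).values
        if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
            raise ValueError(f"design matrix rank-deficient; covariate {col!r} "
                             "is collinear with the others")
    raise ValueError("design matrix rank-deficient")


def _aggregate_window(meta: pd.DataFrame, age_window) -> pd.DataFrame:
    """One sample per infant per window: closest to the window midpoint
    (ties by sample_id)."""
    lo, hi = age_window
    meta = meta[(meta["age_months"] >= lo) & (meta["age_months"] < hi)].copy()
    mid = (lo + hi) / 2.0
    meta["dev"] = (meta["age_months"] - mid).abs()
    meta = meta.sort_values(["dev", "sample_id"])
    return meta.groupby("infant_id", as_index=False).first()


def fit_associations(table: FeatureTable, cohort: CohortTable,
                     covariates=DEFAULT_COVARIATES,
                     samples=None, age_window=None,
                     mode: str = "aggregate",
                     min_abundance: float = 0.001,
                     min_prevalence: float = 0.10) -> pd.DataFrame:
    """Per-feature OLS of AST-transformed abundance on clinical covariates.

    Longitudinal handling: pass ``samples`` (e.g. a one-per-infant disease
    state subset) or an ``age_window`` with ``mode="aggregate"`` which keeps
    each infant's sample closest to the window midpoint. ``mode="mixed"``
    instead fits a per-infant random-intercept model on all window samples.

    Returns one row per (feature, covariate) with coefficient (AST scale),
    p, BH q across features per covariate, n, a direction label for the
    group term, and a significance flag at p<0.05 and q<0.25.
    """
    meta = cohort.merged
    if samples is not None:
        meta = meta[meta["sample_id"].isin(list(samples))]
    if age_window is not None:
        if mode == "aggregate":
            meta = _aggregate_window(meta, age_window)
        else:
            lo, hi = age_window
            meta = meta[(meta["age_months"] >= lo) & (meta["age_months"] < hi)]
    meta = meta[meta["sample_id"].isin(table.sample_ids)].reset_index(drop=True)
    counts = meta["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples per group in the subset")

    sub = table.subset_samples(list(meta["sample_id"]))
    sub = filter_features(sub, min_abundance, min_prevalence)
    design = _design_matrix(meta, covariates)
    _check_rank(design)

    rows = []
    for feat in sub.feature_ids:
        y = ast_transform(np.clip(sub.data.loc[feat].values, 0.0, 1.0))
        if np.ptp(y) == 0:
            log.info("feature %s constant across samples, skipped", feat)
            continue
        if mode == "mixed" and age_window is not None:
            model = sm.MixedLM(y, design, groups=meta["infant_id"].values)
            with np.errstate(all="ignore"):
                res = model.fit(reml=True, method="lbfgs")
            params, pvals = res.params, res.pvalues
        else:
            res = sm.OLS(y, design).fit()
            params, pvals = res.params, res.pvalues
        for cov in design.columns:
            if cov == "const":
                continue
            coef = float(params[cov] if hasattr(params, "__getitem__") else params)
            p = float(pvals[cov])
            rows.append({"feature": feat, "covariate": cov, "coefficient": coef,
                         "p": p, "n": len(meta)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for cov, idx in out.groupby("covariate").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].values)
    out["direction"] = np.where(out["coefficient"] > 0,
                                "case-enriched", "control-enriched")
    out.loc[out["covariate"] != "group", "direction"] = ""
    out["significant"] = (out["p"] < 0.05) & (out["q"] < 0.25)
    return out.sort_values(["covariate", "p"]).reset_index(drop=True)
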