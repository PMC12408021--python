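"""Community-level metrics.

Alpha diversity (Chao1, Shannon), beta diversity (Bray-Curtis, Aitchison),
principal coordinates analysis, diversity-age correlations, top-taxa
summaries, prevalence curves, and the within- vs between-infant
longitudinal stability analysis.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, f_oneway, ttest_ind

from .cohort import AgeBinning, CohortTable, DEFAULT_BINNING, assign_age_bin
from .tables import DistanceMatrix, FeatureTable

log = logging.getLogger(__name__)


# ----------------------------------------------------------------- alpha

def chao1(counts) -> float:
    """Chao1 richness: S_obs + f1^2/(2 f2), singletons f1 and doubletons f2.

    When f2 = 0 the bias-corrected form S_obs + f1(f1-1)/2 is used.
    Requires integer counts; relative abundances degrade to observed
    richness (f1 = f2 = 0) with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if not np.allclose(counts, np.round(counts)):
        warnings.warn("chao1 on non-integer abundances degrades to observed "
                      "richness", stacklevel=2)
        return float((counts > 0).sum())
    s_obs = float((counts > 0).sum())
    f1 = float((counts == 1).sum())
    f2 = float((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 ** 2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1.0) / 2.0


def shannon(abundances) -> float:
    """Shannon diversity, natural log, after internal renormalisation."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon indices."""
    rows = {}
    with warnings.catch_warnings():
        if table.kind != "counts":
            warnings.simplefilter("once")
        for s in table.sample_ids:
            col = table.data[s].values
            rows[s] = {"chao1": chao1(col), "shannon": shannon(col)}
    return pd.DataFrame(rows).T.rename_axis("sample_id")


# ------------------------------------------------------------------ beta

def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    x = table.data.values.T  # samples x features
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(table.sample_ids, d, metric="braycurtis")


def clr_transform(table: FeatureTable, pseudocount: float | None = None) -> pd.DataFrame:
    """Centred log-ratio transform after pseudocount zero replacement.

    Default pseudocount is half the minimum non-zero value in the table.
    """
    x = table.data.values.astype(float)
    if pseudocount is None:
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError("table is all zero")
        pseudocount = nz.min() / 2.0
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.where(x > 0, x, pseudocount)
    x = x / x.sum(axis=0, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.feature_ids, columns=table.sample_ids)


def aitchison(table: FeatureTable, pseudocount: float | None = None) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance of CLR-transformed compositions."""
    clr = clr_transform(table, pseudocount).values.T
    d = squareform(pdist(clr, metric="euclidean"))
    return DistanceMatrix(table.sample_ids, d, metric="aitchison")


# ------------------------------------------------------------------ pcoa

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x axes
    explained: np.ndarray              # variance fraction per axis
    anova_f: float | None = None
    anova_p: float | None = None


def pcoa(dm: DistanceMatrix, n_axes: int = 2,
         groups: pd.Series | dict | None = None) -> PcoaResult:
    """Classical MDS via double-centred Gram eigendecomposition.

    Negative eigenvalues are dropped from both the axes and the variance
    denominator. Axis sign convention: the largest-magnitude loading of
    each axis is made positive. When ``groups`` is given, a one-way ANOVA
    of axis-1 scores by group is reported.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals[0]))
    rank = int(pos.sum())
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds rank {rank}")
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    for a in range(n_axes):  # deterministic sign
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    explained = evals[:n_axes] / evals[pos].sum()
    coords = pd.DataFrame(coords, index=dm.ids,
                          columns=[f"PC{i + 1}" for i in range(n_axes)])
    anova_f = anova_p = None
    if groups is not None:
        g = pd.Series(groups)
        axis1 = coords["PC1"]
        samples = [axis1[g[g == lev].index].values for lev in sorted(g.unique())]
        anova_f, anova_p = (float(v) for v in f_oneway(*samples))
    return PcoaResult(coords, explained, anova_f, anova_p)


# ----------------------------------------------------- age correlations

def age_diversity_correlation(table: FeatureTable, cohort: CohortTable) -> pd.DataFrame:
    """Pearson r and p of each alpha-diversity index against sample age."""
    div = alpha_diversity(table)
    ages = cohort.samples.set_index("sample_id")["age_months"]
    common = [s for s in div.index if s in ages.index]
    if len(common) < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for index in div.columns:
        y = div.loc[common, index].values
        x = ages.loc[common].values
        if np.std(y) == 0 or np.std(x) == 0:
            raise ValueError(f"zero variance for index {index}")
        r, p = pearsonr(x, y)
        rows.append({"index": index, "r": float(r), "p": float(p),
                     "n": len(common)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ stability

def _bin_representatives(merged: pd.DataFrame, binning: AgeBinning) -> pd.DataFrame:
    """One sample per infant per bin: the sample closest to the bin's
    target visit age (ties by sample_id)."""
    merged = merged.copy()
    merged["bin"] = [assign_age_bin(a, binning) for a in merged["age_months"]]
    target = dict(zip(binning.labels, binning.targets))
    merged["dev"] = [abs(a - target[b]) for a, b in
                     zip(merged["age_months"], merged["bin"])]
    merged = merged.sort_values(["dev", "sample_id"])
    return merged.groupby(["infant_id", "bin"], as_index=False).first()


def stability_analysis(table: FeatureTable, cohort: CohortTable,
                       binning: AgeBinning = DEFAULT_BINNING) -> pd.DataFrame:
    """Within- vs between-infant Bray-Curtis distances per age transition.

    For each consecutive bin pair, the within-infant distance uses each
    infant's representative sample in the two bins; between-infant
    distances pair representatives of different infants across the bins.
    Welch t-tests: within vs between, and within-infant distances of case
    vs control infants. Transitions with no eligible within pairs are
    skipped with a log notice.
    """
    dm = bray_curtis(table)
    d = dm.to_frame()
    reps = _bin_representatives(cohort.merged, binning)
    group_of = dict(zip(cohort.infants["infant_id"], cohort.infants["group"]))
    rows = []
    for b1, b2 in zip(binning.labels, binning.labels[1:]):
        r1 = reps[reps["bin"] == b1].set_index("infant_id")["sample_id"]
        r2 = reps[reps["bin"] == b2].set_index("infant_id")["sample_id"]
        shared = sorted(set(r1.index) & set(r2.index))
        if not shared:
            log.info("transition %s -> %s: no infant spans it, skipped", b1, b2)
            continue
        within = {i: d.loc[r1[i], r2[i]] for i in shared}
        between = [d.loc[r1[i], r2[j]]
                   for i in r1.index for j in r2.index if i != j]
        wvals = np.array(list(within.values()))
        bvals = np.array(between)
        t_wb, p_wb = (np.nan, np.nan)
        if len(wvals) >= 2 and len(bvals) >= 2:
            t_wb, p_wb = ttest_ind(wvals, bvals, equal_var=False)
        case_w = np.array([v for i, v in within.items() if group_of[i] == "case"])
        ctrl_w = np.array([v for i, v in within.items() if group_of[i] == "control"])
        t_cc, p_cc = (np.nan, np.nan)
        if len(case_w) >= 2 and len(ctrl_w) >= 2:
            t_cc, p_cc = ttest_ind(case_w, ctrl_w, equal_var=False)
        rows.append({"transition": f"{b1} -> {b2}",
                     "n_within": len(wvals), "n_between": len(bvals),
                     "mean_within": wvals.mean(),
                     "mean_between": bvals.mean() if len(bvals) else np.nan,
                     "t_within_vs_between": float(t_wb), "p_within_vs_between": float(p_wb),
                     "mean_within_case": case_w.mean() if len(case_w) else np.nan,
                     "mean_within_control": ctrl_w.mean() if len(ctrl_w) else np.nan,
                     "t_case_vs_control": float(t_cc), "p_case_vs_control": float(p_cc)})
    columns = ["transition", "n_within", "n_between", "mean_within",
               "mean_between", "t_within_vs_between", "p_within_vs_between",
               "mean_within_case", "mean_within_control", "t_case_vs_control",
               "p_case_vs_control"]
    return pd.DataFrame(rows, columns=columns)


# ----------------------------------------------------------- summaries

def top_taxa_summary(table: FeatureTable, cohort: CohortTable | None = None,
                     k: int = 15,
                     binning: AgeBinning = DEFAULT_BINNING) -> pd.DataFrame:
    """Collapse to the k most abundant taxa (overall mean) plus an
    "Others" row; optionally stratified by group and age bin.

    Column sums of the collapsed table equal the original column sums.
    """
    if k > table.shape[0]:
        raise ValueError(f"k={k} exceeds number of features {table.shape[0]}")
    means = table.data.mean(axis=1).sort_values(ascending=False)
    top = list(means.index[:k])
    rest = [f for f in table.feature_ids if f not in top]
    collapsed = table.data.loc[top].copy()
    collapsed.loc["Others"] = table.data.loc[rest].sum(axis=0) if rest else 0.0
    if cohort is None:
        return collapsed
    merged = cohort.merged.set_index("sample_id")
    bins = [assign_age_bin(a, binning) for a in merged["age_months"]]
    merged = merged.assign(bin=bins)
    out = {}
    for (grp, b), sub in merged.groupby(["group", "bin"]):
        cols = [s for s in sub.index if s in collapsed.columns]
        if cols:
            out[(grp, b)] = collapsed[cols].mean(axis=1)
    return pd.DataFrame(out)


def prevalence_curve(table: FeatureTable, cohort: CohortTable, feature: str,
                     by: str = "group", detection_threshold: float = 0.0,
                     binning: AgeBinning = DEFAULT_BINNING) -> pd.DataFrame:
    """Detection prevalence of one feature per age bin per stratum.

    Prevalence = fraction of stratum x bin samples with abundance strictly
    above the threshold. Empty strata are reported as NaN (missing), not 0.
    """
    if feature not in table.data.index:
        raise KeyError(f"feature {feature!r} not in table")
    col_map = {"group": "group", "feeding": "initial_feeding"}
    strat_col = col_map.get(by, by)
    merged = cohort.merged.set_index("sample_id")
    merged = merged.loc[[s for s in table.sample_ids if s in merged.index]]
    merged["bin"] = [assign_age_bin(a, binning) for a in merged["age_months"]]
    detected = table.data.loc[feature, merged.index] > detection_threshold
    merged["detected"] = detected.values
    prev = merged.groupby([strat_col, "bin"], observed=True)["detected"].mean()
    out = prev.unstack(strat_col).reindex(list(binning.labels))
    return out
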