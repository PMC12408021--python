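"""Clinical cohort model.

Age binning around scheduled pediatric visits, symptom-state labelling,
disease-state sample subsets (last pre-symptomatic / first symptomatic /
first resolved), optimal one-to-one age matching of case and control
samples, and Fisher contingency tests on demographics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import fisher_exact

STATES = ("control", "pre_symptomatic", "symptomatic", "resolved")

# per-infant columns of the metadata schema
INFANT_COLUMNS = ["infant_id", "group", "sex", "delivery_mode",
                  "initial_feeding", "probiotic_first_year"]
SAMPLE_COLUMNS = ["sample_id", "infant_id", "age_months", "symptom_state"]


class CohortTable:
    """Infant- and sample-level clinical metadata.

    ``infants``: one row per infant with group (case/control), sex,
    delivery mode, initial feeding and first-year probiotic use.
    ``samples``: one row per stool sample with collection age (months)
    and symptom state. Control infants carry only the "control" state;
    within a case infant, states follow pre_symptomatic -> symptomatic ->
    resolved along age.
    """

    def __init__(self, infants: pd.DataFrame, samples: pd.DataFrame):
        for col in INFANT_COLUMNS:
            if col not in infants.columns:
                raise ValueError(f"missing infant metadata column: {col}")
        for col in SAMPLE_COLUMNS:
            if col not in samples.columns:
                raise ValueError(f"missing sample metadata column: {col}")
        unknown = set(samples["infant_id"]) - set(infants["infant_id"])
        if unknown:
            raise ValueError(f"samples reference unknown infants: {sorted(unknown)[:5]}")
        bad_state = set(samples["symptom_state"]) - set(STATES)
        if bad_state:
            raise ValueError(f"unknown symptom states: {sorted(bad_state)}")
        if (samples["age_months"] < 0).any():
            raise ValueError("negative sample ages")
        self.infants = infants.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self._validate_state_order()

    def _validate_state_order(self):
        grp = dict(zip(self.infants["infant_id"], self.infants["group"]))
        order = {"pre_symptomatic": 0, "symptomatic": 1, "resolved": 2}
        for iid, sub in self.samples.groupby("infant_id"):
            if grp[iid] == "control":
                if (sub["symptom_state"] != "control").any():
                    raise ValueError(f"control infant {iid} has non-control state")
            else:
                sub = sub.sort_values("age_months")
                ranks = [order[s] for s in sub["symptom_state"]]
                if any(b < a for a, b in zip(ranks, ranks[1:])):
                    raise ValueError(f"infant {iid}: symptom states out of order")

    @property
    def merged(self) -> pd.DataFrame:
        """Samples joined with their infant's metadata."""
        return self.samples.merge(self.infants, on="infant_id", how="left")

    def case_infants(self) -> list[str]:
        return list(self.infants.loc[self.infants["group"] == "case", "infant_id"])

    def __repr__(self) -> str:  # pragma: no cover
        n_case = (self.infants["group"] == "case").sum()
        return (f"CohortTable({len(self.infants)} infants "
                f"[{n_case} case], {len(self.samples)} samples)")


@dataclass(frozen=True)
class AgeBinning:
    """Half-open age bins [lo, hi) around scheduled visit ages."""

    thresholds: tuple = (0.0, 0.35, 0.75, 1.5, 3.0, 5.0, 8.0, 10.5, 14.0)
    labels: tuple = ("birth", "0.5 months", "1 month", "2 months",
                     "4 months", "6 months", "9 months", "12 months")
    targets: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 12.0)

    def __post_init__(self):
        t = self.thresholds
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(t) - 1:
            raise ValueError("need one label per interval")
        if len(self.targets) != len(self.labels):
            raise ValueError("need one target visit age per bin")


DEFAULT_BINNING = AgeBinning()


def assign_age_bin(age_months: float, binning: AgeBinning = DEFAULT_BINNING) -> str:
    """Label of the half-open interval [lo, hi) containing ``age_months``."""
    t = binning.thresholds
    if age_months < t[0] or age_months >= t[-1]:
        raise ValueError(f"age {age_months} outside binning range [{t[0]}, {t[-1]})")
    idx = int(np.searchsorted(t, age_months, side="right")) - 1
    return binning.labels[idx]


def assign_age_bins(ages, binning: AgeBinning = DEFAULT_BINNING) -> pd.Series:
    ages = pd.Series(ages)
    return ages.map(lambda a: assign_age_bin(a, binning))


def select_state_subsets(cohort: CohortTable) -> dict[str, pd.DataFrame]:
    """One sample per case infant per disease phase.

    last_pre_symptomatic: the max-age pre-symptomatic sample;
    first_symptomatic / first_resolved: the min-age sample of that phase.
    Age ties are broken by lexicographic sample_id. Infants lacking a phase
    are omitted from that subset.
    """
    merged = cohort.merged
    cases = merged[merged["group"] == "case"]
    out = {}
    specs = [("last_pre_symptomatic", "pre_symptomatic", "last"),
             ("first_symptomatic", "symptomatic", "first"),
             ("first_resolved", "resolved", "first")]
    for name, state, which in specs:
        sub = cases[cases["symptom_state"] == state]
        rows = []
        for _, grp in sub.groupby("infant_id"):
            grp = grp.sort_values(["age_months", "sample_id"])
            rows.append(grp.iloc[-1] if which == "last" else grp.iloc[0])
        out[name] = (pd.DataFrame(rows).reset_index(drop=True)
                     if rows else cases.iloc[0:0].copy())
    return out


@dataclass
class MatchResult:
    """One-to-one age matching between case and control samples."""

    pairs: list  # (case_id, control_id)
    total_cost: float
    unmatched_cases: list
    unmatched_controls: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


def match_by_age(case_ages, control_ages,
                 case_ids=None, control_ids=None) -> MatchResult:
    """Minimum-total-|age difference| one-to-one matching (Hungarian method).

    When the sides are unequal the larger side's surplus is left unmatched.
    """
    case_ages = np.asarray(case_ages, dtype=float)
    control_ages = np.asarray(control_ages, dtype=float)
    if case_ages.size == 0 or control_ages.size == 0:
        raise ValueError("both age lists must be non-empty")
    if case_ids is None:
        case_ids = [f"case_{i}" for i in range(case_ages.size)]
    if control_ids is None:
        control_ids = [f"control_{i}" for i in range(control_ages.size)]
    cost = np.abs(case_ages[:, None] - control_ages[None, :])
    ri, ci = linear_sum_assignment(cost)
    pairs = [(case_ids[i], control_ids[j]) for i, j in zip(ri, ci)]
    total = float(cost[ri, ci].sum())
    unmatched_cases = [case_ids[i] for i in range(case_ages.size) if i not in set(ri)]
    unmatched_controls = [control_ids[j] for j in range(control_ages.size)
                          if j not in set(ci)]
    return MatchResult(pairs, total, unmatched_cases, unmatched_controls)


def match_state_subset(cohort: CohortTable, subset: pd.DataFrame) -> MatchResult:
    """Match each selected case sample to a control sample by age.

    Controls contribute all their samples; each control sample is used at
    most once (one-to-one over samples).
    """
    merged = cohort.merged
    controls = merged[merged["group"] == "control"]
    if subset.empty or controls.empty:
        raise ValueError("need non-empty case subset and control samples")
    return match_by_age(subset["age_months"].values, controls["age_months"].values,
                        list(subset["sample_id"]), list(controls["sample_id"]))


def _fisher_2x2(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact p and odds ratio with Haldane correction."""
    _, p = fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane-Anscombe
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


def demographic_tests(cohort: CohortTable,
                      covariates=("sex", "delivery_mode", "initial_feeding",
                                  "probiotic_first_year")) -> pd.DataFrame:
    """2x2 case/control contingency tests per covariate level.

    Multi-level covariates are tested one level vs the rest. Returns one
    row per (covariate, level) with counts, odds ratio and two-sided
    Fisher exact p (hypergeometric enumeration via scipy).
    """
    inf = cohort.infants
    is_case = (inf["group"] == "case").values
    rows = []
    for cov in covariates:
        values = inf[cov]
        levels = sorted(values.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level")
        if len(levels) > 2:
            test_levels = levels
        elif levels == ["False", "True"]:
            test_levels = ["True"]  # report the affirmative level
        else:
            test_levels = levels[:1]
        for level in test_levels:
            has = (values.astype(str) == level).values
            table = np.array([[int((has & is_case).sum()),
                               int((~has & is_case).sum())],
                              [int((has & ~is_case).sum()),
                               int((~has & ~is_case).sum())]])
            odds, p = _fisher_2x2(table)
            rows.append({"covariate": cov, "level": level,
                         "case_with": table[0, 0], "case_without": table[0, 1],
                         "control_with": table[1, 0], "control_without": table[1, 1],
                         "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)
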