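"""Replicate aggregation and between-stage hypothesis testing.

The study design: per biological replicate (one embryo, N) three same-size
ROIs are measured as technical replicates (n = 3) and averaged; each stage
contributes at least N = 3 biological replicates. Between-stage comparison
uses one-way ANOVA with Tukey's post hoc after a D'Agostino–Pearson
normality check, falling back to Kruskal–Wallis (with Dunn's pairwise test,
Holm-adjusted — an implementation choice, the original post hoc being
unstated) when normality is rejected. Significance is α = 0.05.

The D'Agostino–Pearson omnibus statistic is mathematically defined only for
n ≥ 8; groups smaller than that cannot be tested and are treated as "cannot
reject normality" (recorded per group), which keeps the parametric branch
reachable at the study's replicate counts. Groups below n = 3 force the
non-parametric branch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

#: Developmental day -> Hamburger–Hamilton stage for the d9–d19 design.
DAY_TO_HH = {9: 35, 11: 37, 13: 39, 15: 41, 17: 43, 19: 45}

#: Smallest group size for which the D'Agostino–Pearson test is defined.
NORMALITY_MIN_N = 8

STUDY_COLUMNS = (
    "tendon", "stage_day", "biological_id", "technical_id", "metric", "value"
)


def stage_to_hh(day: int) -> int:
    """Map a developmental day to its Hamburger–Hamilton stage."""
    try:
        return DAY_TO_HH[day]
    except KeyError:
        raise ValueError(
            f"day {day} is not in the study design; known days: "
            f"{sorted(DAY_TO_HH)}"
        ) from None


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table invariants.

    Keys (tendon, stage_day, biological_id, technical_id, metric) must be
    unique; stage days must belong to the d9–d19 design (the hh_stage column,
    if present, must match the day↔HH table). Warns when a biological
    replicate deviates from the n = 3 technical-replicate design.
    """
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table lacks column(s) {missing}")
    keys = list(STUDY_COLUMNS[:5])
    dup = table.duplicated(subset=keys)
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (tendon, stage, N, n, metric) rows"
        )
    bad_days = set(table["stage_day"]) - set(DAY_TO_HH)
    if bad_days:
        raise ValueError(f"stage_day values outside the design: {sorted(bad_days)}")
    if "hh_stage" in table.columns:
        expect = table["stage_day"].map(DAY_TO_HH)
        if not (table["hh_stage"] == expect).all():
            raise ValueError("hh_stage column contradicts the day-to-HH table")
    n_tech = (
        table.groupby(["tendon", "stage_day", "biological_id", "metric"])
        ["technical_id"].nunique()
    )
    off = n_tech[n_tech != 3]
    if len(off):
        warnings.warn(
            f"{len(off)} biological replicate/metric groups deviate from the "
            "n = 3 technical-replicate design",
            stacklevel=2,
        )
    return table


def aggregate_biological(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates into one value per biological replicate.

    Missing values are dropped from the mean (with a warning reporting how
    many); output has one row per (tendon, stage_day, biological_id, metric).
    """
    validate_study_table(table)
    n_missing = int(table["value"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} missing technical-replicate values excluded from means",
            stacklevel=2,
        )
    out = (
        table.dropna(subset=["value"])
        .groupby(["tendon", "stage_day", "biological_id", "metric"], as_index=False)
        ["value"].mean()
    )
    return out


@dataclass
class PairwiseComparison:
    group_a: object
    group_b: object
    mean_diff: float
    p_adjusted: float
    significant: bool

    def as_row(self) -> dict:
        return {
            "group_a": self.group_a, "group_b": self.group_b,
            "mean_diff": self.mean_diff, "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


@dataclass
class TestReport:
    """Outcome of one between-stage comparison, decision path included."""

    metric: str
    tendon: str
    omnibus_test: str  # "anova" | "kruskal_wallis"
    statistic: float
    p_value: float
    alpha: float
    normality: dict = field(default_factory=dict)  # group -> "pass"/"fail"/"too_small"
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    pairwise_method: str = ""
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric, "tendon": self.tendon,
            "omnibus_test": self.omnibus_test, "statistic": self.statistic,
            "p_value": self.p_value, "alpha": self.alpha,
            "significant": self.significant, "normality": self.normality,
            "pairwise_method": self.pairwise_method,
            "pairwise": [p.as_row() for p in self.pairwise],
            "notes": self.notes,
        }


def _dunn_pairwise(groups: dict, alpha: float) -> list[PairwiseComparison]:
    """Dunn's rank-based z test for all pairs, Holm-adjusted.

    Standard construction: joint ranks with midrank ties, tie-corrected
    variance N(N+1)/12 − T/(12(N−1)), z on rank-mean differences.
    """
    names = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = sps.rankdata(all_vals)
    n_total = len(all_vals)
    rank_means, sizes = {}, {}
    pos = 0
    for g in names:
        k = len(groups[g])
        rank_means[g] = ranks[pos : pos + k].mean()
        sizes[g] = k
        pos += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    raw_p, diffs = [], []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (rank_means[a] - rank_means[b]) / se if se > 0 else 0.0
        raw_p.append(2.0 * sps.norm.sf(abs(z)))
        diffs.append(float(np.mean(groups[a]) - np.mean(groups[b])))
    if not pairs:
        return []
    reject, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    return [
        PairwiseComparison(a, b, d, float(p), bool(r))
        for (a, b), d, p, r in zip(pairs, diffs, p_adj, reject)
    ]


def compare_stages(
    groups: dict, alpha: float = 0.05, metric: str = "", tendon: str = ""
) -> TestReport:
    """Between-stage omnibus + post-hoc testing with the normality gate.

    ``groups`` maps stage labels to 1-D arrays of biological-replicate
    values. All groups passing (or too small to run) the D'Agostino–Pearson
    check -> one-way ANOVA + Tukey HSD (Tukey–Kramer for unequal sizes);
    any rejection, or any group below n = 3 -> Kruskal–Wallis + Dunn/Holm.
    The branch taken and per-group normality outcomes are recorded.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 stage groups to compare")
    for k, v in groups.items():
        if v.ndim != 1 or len(v) == 0:
            raise ValueError(f"group {k!r} must be a non-empty 1-D array")

    notes: list[str] = []
    normality: dict = {}
    parametric = True
    for k, v in groups.items():
        if len(v) < 3:
            normality[k] = "too_small"
            parametric = False
            notes.append(f"group {k!r} has n={len(v)} < 3: non-parametric branch")
        elif len(v) < NORMALITY_MIN_N:
            normality[k] = "too_small"
            notes.append(
                f"group {k!r} has n={len(v)} < {NORMALITY_MIN_N}: normality "
                "test not defined, treated as not rejected"
            )
        elif np.ptp(v) == 0:
            normality[k] = "degenerate"
            parametric = False
            notes.append(f"group {k!r} is constant: non-parametric branch")
        else:
            p = float(sps.normaltest(v).pvalue)
            normality[k] = "pass" if p >= alpha else "fail"
            if p < alpha:
                parametric = False

    names = list(groups)
    arrays = [groups[k] for k in names]
    if parametric:
        f_stat, p = sps.f_oneway(*arrays)
        pairwise = _tukey_pairwise(groups, alpha)
        return TestReport(metric, tendon, "anova", float(f_stat), float(p),
                          alpha, normality, pairwise, "tukey_hsd", notes)
    try:
        h_stat, p = sps.kruskal(*arrays)
    except ValueError:  # all values identical across every group
        h_stat, p = 0.0, 1.0
        notes.append("all observations identical; H set to 0, p to 1")
    pairwise = _dunn_pairwise(groups, alpha)
    notes.append("pairwise method after Kruskal-Wallis is an implementation "
                 "choice (Dunn + Holm); the original post hoc is unstated")
    return TestReport(metric, tendon, "kruskal_wallis", float(h_stat), float(p),
                      alpha, normality, pairwise, "dunn_holm", notes)


def _tukey_pairwise(groups: dict, alpha: float) -> list[PairwiseComparison]:
    names = list(groups)
    values = np.concatenate([groups[k] for k in names])
    labels = np.concatenate([[str(k)] * len(groups[k]) for k in names])
    if np.ptp(values) == 0:  # Tukey undefined on all-equal data: no signif pairs
        return [
            PairwiseComparison(a, b, 0.0, 1.0, False)
            for a, b in itertools.combinations(names, 2)
        ]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    out = []
    by_name = {str(k): k for k in names}
    for (a, b), diff, p, rej in zip(
        itertools.combinations(res.groupsunique, 2),
        res.meandiffs, res.pvalues, res.reject,
    ):
        # zero within-group variance: equal means -> p 1, unequal -> p 0
        if np.isnan(p):
            p, rej = (1.0, False) if diff == 0 else (0.0, True)
        out.append(
            PairwiseComparison(by_name[str(a)], by_name[str(b)],
                               float(diff), float(p), bool(rej))
        )
    return out


def run_study_tests(
    biological: pd.DataFrame, alpha: float = 0.05
) -> list[TestReport]:
    """One :func:`compare_stages` per (metric, tendon) of an aggregated table."""
    reports = []
    for (metric, tendon), sub in biological.groupby(["metric", "tendon"]):
        groups = {
            int(day): d["value"].to_numpy()
            for day, d in sub.groupby("stage_day")
        }
        if len(groups) < 2:
            continue
        reports.append(compare_stages(groups, alpha, metric, tendon))
    return reports


def reports_to_frame(reports: list[TestReport]) -> pd.DataFrame:
    """Flatten pairwise results of many reports into one tidy table."""
    rows = []
    for rep in reports:
        base = {"metric": rep.metric, "tendon": rep.tendon,
                "omnibus_test": rep.omnibus_test, "omnibus_statistic": rep.statistic,
                "omnibus_p": rep.p_value}
        if not rep.pairwise:
            rows.append(base)
        for pw in rep.pairwise:
            rows.append({**base, **pw.as_row()})
    return pd.DataFrame(rows)
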