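"""Group-level statistics: side-aligned paired tests, three-group ANOVA
with Bonferroni post-hoc, and PROM correlations.

Because healthy controls have no paretic side, sides are aligned before any
comparison: the paretic side of patients lines up with the LEFT side of
controls (``paretic_like``) and the contralateral side with the RIGHT side
(``contra_like``).  Paired side comparisons use the Wilcoxon signed-rank
test; independent three-group comparisons use one-way ANOVA with pairwise
Welch tests Bonferroni-corrected by a factor of 3; blink-PROM associations
use Spearman's rho with no multiplicity adjustment (exploratory).  The
significance threshold throughout is 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import SUMMARY_PARAMETERS, EyeBlinkSummary, summary_to_dict

__all__ = [
    "SubjectRecord",
    "TestResult",
    "align_sides",
    "paired_wilcoxon",
    "anova_bonferroni",
    "spearman_prom",
    "build_comparison_tables",
    "GROUPS",
    "PROM_COLUMNS",
]

GROUPS = ("healthy", "acute", "synkinesis")

#: PROM scores carried into the correlation grid
PROM_COLUMNS = ("face_eye_comfort", "face_total", "fdi_physical", "fdi_social", "fdi_total")

ALPHA = 0.05


@dataclass
class SubjectRecord:
    """One subject: group membership, side assignment, both eye summaries
    and the already-scored PROM values (instrument scoring itself is
    clinical input, not recomputed here)."""

    subject_id: str
    group: str
    paretic_side: str  # "left" | "right" | "none"
    summary_left: EyeBlinkSummary
    summary_right: EyeBlinkSummary
    prom: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.group == "healthy") != (self.paretic_side == "none"):
            raise ValueError("healthy subjects (and only they) have paretic_side='none'")
        for key, val in self.prom.items():
            lo = -25.0 if key == "fdi_physical" else 0.0
            if np.isfinite(val) and not (lo <= val <= 100.0):
                raise ValueError(f"PROM {key}={val} outside [{lo}, 100]")


@dataclass
class TestResult:
    """One hypothesis test: label, statistic, p, and whether a Bonferroni
    adjustment was applied."""

    comparison: str
    parameter: str
    statistic: float
    p_value: float
    adjusted: bool
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def align_sides(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Side-aligned per-subject table.

    Patients map paretic -> ``paretic_like`` and contralateral ->
    ``contra_like``; healthy controls map left -> ``paretic_like`` and
    right -> ``contra_like``.  Every eye summary appears exactly once.
    Columns are ``<role>:<parameter>`` plus subject metadata.
    """
    rows = []
    if not cohort:
        raise ValueError("empty cohort")
    for rec in cohort:
        if rec.group != "healthy" and rec.paretic_side not in ("left", "right"):
            raise ValueError(f"patient {rec.subject_id} lacks a paretic side")
        if rec.paretic_side == "right":
            par, con = rec.summary_right, rec.summary_left
        else:  # paretic left, or healthy (left plays the paretic-like role)
            par, con = rec.summary_left, rec.summary_right
        row: dict = {"subject_id": rec.subject_id, "group": rec.group, "paretic_side": rec.paretic_side}
        for role, summ in (("paretic_like", par), ("contra_like", con)):
            for key, val in summary_to_dict(summ).items():
                if key == "side":
                    continue
                row[f"{role}:{key}"] = val
        for key, val in rec.prom.items():
            row[key] = val
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def paired_wilcoxon(x, y, comparison: str = "", parameter: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired values.

    Zero differences are dropped (Wilcoxon's original treatment), ties are
    mid-ranked.  Requires at least 5 nonzero differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    nonzero = int(np.sum(d != 0))
    if nonzero == 0:
        raise ValueError("all paired differences are zero")
    if nonzero < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {nonzero}")
    res = sps.wilcoxon(x[keep], y[keep], zero_method="wilcox", alternative="two-sided")
    return TestResult(comparison, parameter, float(res.statistic), float(res.pvalue), False, nonzero)


def anova_bonferroni(groups: Mapping[str, Sequence[float]], parameter: str = "") -> list[TestResult]:
    """One-way ANOVA omnibus plus Bonferroni-corrected pairwise tests.

    Pairwise comparisons are Welch two-sample t-tests with p multiplied by
    the number of pairs (3 for three groups) and capped at 1.
    """
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        clean[name] = v
    names = list(clean)
    f_stat, p_omni = sps.f_oneway(*clean.values())
    out = [
        TestResult("ANOVA " + " vs ".join(names), parameter, float(f_stat), float(p_omni), False,
                   int(sum(v.size for v in clean.values())))
    ]
    pairs = list(itertools.combinations(names, 2))
    k = len(pairs)
    for a, b in pairs:
        t_stat, p_raw = sps.ttest_ind(clean[a], clean[b], equal_var=False)
        out.append(
            TestResult(f"{a} vs {b}", parameter, float(t_stat), min(1.0, float(p_raw) * k), True,
                       int(clean[a].size + clean[b].size))
        )
    return out


def spearman_prom(blink_values, prom_values, comparison: str = "", parameter: str = "") -> TestResult:
    """Spearman rank correlation between a blink parameter and a PROM score.

    Ties mid-ranked, two-sided p, no multiplicity adjustment (the
    correlation analysis is exploratory).
    """
    x = np.asarray(blink_values, dtype=float)
    y = np.asarray(prom_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant sequence")
    rho, p = sps.spearmanr(x, y)
    return TestResult(comparison, parameter, float(rho), float(p), False, int(x.size))


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return np.nan, np.nan
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def build_comparison_tables(
    cohort: Sequence[SubjectRecord],
    parameters: Sequence[str] = SUMMARY_PARAMETERS,
    require_all_groups: bool = False,
) -> dict[str, pd.DataFrame]:
    """Assemble the four report tables of the analysis.

    ``side_comparison``  per group and parameter: paretic-like vs
        contra-like mean +- SD with the paired Wilcoxon p.
    ``paretic_group_comparison`` / ``contra_group_comparison``  per
        parameter: three-group means +- SD with ANOVA omnibus p and the
        three Bonferroni-corrected pairwise p's (needs all three groups).
    ``prom_correlation``  per group, blink parameter and PROM score:
        Spearman rho and p on the paretic-like side.
    """
    aligned = align_sides(cohort)
    present = [g for g in GROUPS if (aligned["group"] == g).any()]
    if not present:
        raise ValueError("empty cohort")
    if require_all_groups and len(present) < len(GROUPS):
        missing = sorted(set(GROUPS) - set(present))
        raise ValueError(f"three-group tables need every group; missing {missing}")

    side_rows = []
    for group in present:
        sub = aligned[aligned["group"] == group]
        for param in parameters:
            x = sub[f"paretic_like:{param}"].to_numpy(float)
            y = sub[f"contra_like:{param}"].to_numpy(float)
            mp, sp_ = _mean_sd(x)
            mc, sc = _mean_sd(y)
            try:
                p_val = paired_wilcoxon(x, y, group, param).p_value
            except ValueError:
                p_val = np.nan
            side_rows.append(
                {
                    "group": group,
                    "parameter": param,
                    "paretic_like_mean": mp,
                    "paretic_like_sd": sp_,
                    "contra_like_mean": mc,
                    "contra_like_sd": sc,
                    "wilcoxon_p": p_val,
                    "n": len(sub),
                }
            )
    tables = {"side_comparison": pd.DataFrame(side_rows)}

    for role, name in (("paretic_like", "paretic_group_comparison"), ("contra_like", "contra_group_comparison")):
        if len(present) < len(GROUPS):
            continue  # three-group tables need all three groups
        rows = []
        for param in parameters:
            groups = {
                g: aligned.loc[aligned["group"] == g, f"{role}:{param}"].to_numpy(float)
                for g in GROUPS
            }
            results = anova_bonferroni(groups, parameter=param)
            row: dict = {"parameter": param}
            for g, vals in groups.items():
                m, s = _mean_sd(vals)
                row[f"{g}_mean"], row[f"{g}_sd"] = m, s
            row["anova_p"] = results[0].p_value
            for res in results[1:]:
                key = "p_" + res.comparison.replace(" vs ", "_vs_")
                row[key] = res.p_value
            rows.append(row)
        tables[name] = pd.DataFrame(rows)

    corr_rows = []
    for group in present:
        sub = aligned[aligned["group"] == group]
        for param in parameters:
            for prom_col in PROM_COLUMNS:
                if prom_col not in sub.columns:
                    continue
                try:
                    res = spearman_prom(
                        sub[f"paretic_like:{param}"], sub[prom_col], group, param
                    )
                    rho, p = res.statistic, res.p_value
                except ValueError:
                    rho, p = np.nan, np.nan
                corr_rows.append(
                    {"group": group, "parameter": param, "prom": prom_col, "rho": rho, "p": p}
                )
    tables["prom_correlation"] = pd.DataFrame(corr_rows)
    return tables
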