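"""Per-gene group comparisons and cycle-wise milk-yield analysis.

The test-selection policy mirrors routine veterinary-residue practice:
normality per group by Lilliefors-corrected Kolmogorov-Smirnov, equality
of variances by Levene; two normal groups are compared by t-test (pooled
or Welch depending on Levene), otherwise by Mann-Whitney U (exact p for
small groups, tie-corrected normal approximation otherwise); three or
more groups by one-way ANOVA.  Significance is star-coded at
0.05/0.01/0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .design import StudyDesign, DoseSchedule, build_dose_schedule, assign_cycle

__all__ = [
    "TestResult",
    "CycleYieldSummary",
    "stars",
    "ks_normality",
    "levene",
    "compare_two_groups",
    "one_way_anova",
    "cycle_yield_table",
    "gene_day_comparisons",
]

ALPHA_GATE = 0.05


@dataclass(frozen=True)
class TestResult:
    context: str
    test: str                     # t | welch_t | mann_whitney_u | anova
    statistic: float
    p: float
    stars: str                    # ns | * | ** | ***
    normality_p: tuple[float, ...] = ()
    variance_p: float = np.nan


@dataclass(frozen=True)
class CycleYieldSummary:
    cycle: int
    mean_rbst: float
    sd_rbst: float
    mean_control: float
    sd_control: float
    pct_diff_mean: float
    pct_diff_sd: float
    p: float
    stars: str
    test: str
    days: tuple[int, int]


def stars(p: float) -> str:
    """Significance star coding: *** <0.001, ** <0.01, * <0.05, else ns."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ks_normality(values: np.ndarray, lilliefors_corrected: bool = True
                 ) -> float:
    """Kolmogorov-Smirnov normality p against a fitted normal.

    Default uses the Lilliefors correction (parameters estimated from the
    sample); the uncorrected variant plugs the sample mean/sd into a
    plain KS test.  Zero-variance input returns p = 0.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need n >= 4 for the normality test")
    if np.std(v) == 0:
        return 0.0
    if lilliefors_corrected:
        _, p = lilliefors(v, dist="norm")
    else:
        _, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return float(p)


def levene(*groups: np.ndarray) -> float:
    """Levene's test p (center = mean) for equality of variances."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(a) == 0 for a in arrs):
        return 1.0
    _, p = stats.levene(*arrs, center="mean")
    return float(p)


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when min(n) <= 8 and no ties,
    tie-corrected normal approximation otherwise."""
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 8 and not has_ties:
        res = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
    else:
        res = stats.mannwhitneyu(a, b, method="asymptotic",
                                 alternative="two-sided", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(a: np.ndarray, b: np.ndarray, context: str = "",
                       force: str | None = None) -> TestResult:
    """Two-group comparison with the normality-gated test policy.

    Both groups normal (KS p >= 0.05 each): t-test, pooled when Levene
    p >= 0.05, Welch otherwise.  Any non-normal group: Mann-Whitney U.
    ``force`` overrides the gate ("t", "welch_t" or "mann_whitney_u").
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    norm_p: tuple[float, ...] = ()
    var_p = np.nan
    if force is None:
        try:
            norm_p = (ks_normality(a), ks_normality(b))
            normal = all(p >= ALPHA_GATE for p in norm_p)
        except ValueError:
            normal = False
        if normal:
            var_p = levene(a, b)
            choice = "t" if var_p >= ALPHA_GATE else "welch_t"
        else:
            choice = "mann_whitney_u"
    else:
        choice = force
        if choice in ("t", "welch_t"):
            var_p = levene(a, b)

    if choice == "t":
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif choice == "welch_t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif choice == "mann_whitney_u":
        stat, p = _mann_whitney(a, b)
    else:
        raise ValueError(f"unknown test {choice!r}")
    return TestResult(context, choice, float(stat), float(p), stars(p),
                      norm_p, float(var_p) if np.isfinite(var_p) else np.nan)


def one_way_anova(*groups: np.ndarray, context: str = "") -> TestResult:
    """One-way ANOVA for three or more groups (e.g. treated, farm control,
    external-farm control)."""
    if len(groups) < 3:
        raise ValueError("one-way ANOVA needs >= 3 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    if np.ptp(np.concatenate(arrs)) == 0:
        return TestResult(context, "anova", 0.0, 1.0, "ns")
    f, p = stats.f_oneway(*arrs)
    return TestResult(context, "anova", float(f), float(p), stars(p))


def cycle_yield_table(yields: pd.DataFrame, design: StudyDesign,
                      schedule: DoseSchedule | None = None,
                      on: str = "animal_days") -> pd.DataFrame:
    """Cycle-wise milk-yield comparison between treated and control groups.

    ``yields``: daily table (animal, group, day, kg).  Per cycle the group
    mean +/- sd over animal-days is reported; the % production difference
    is computed per day as 100*(mean_rbst - mean_control)/mean_control
    and then averaged (+/- sd) over the cycle's days; groups are compared
    by :func:`compare_two_groups` on animal-day values (``on="animal_days"``)
    or per-animal cycle means (``on="animal_means"``).
    """
    if schedule is None:
        schedule = build_dose_schedule(design)
    y = yields.copy()
    y["cycle"] = [assign_cycle(d, design, schedule) for d in y["day"]]
    rows = []
    for cyc, g in y.groupby("cycle"):
        rb = g[g["group"] == "rbst"]
        ct = g[g["group"] == "control"]
        if rb.empty or ct.empty:
            continue
        daily = g.pivot_table(index="day", columns="group", values="kg",
                              aggfunc="mean")
        pct = 100.0 * (daily["rbst"] - daily["control"]) / daily["control"]
        if on == "animal_means":
            a = rb.groupby("animal")["kg"].mean().to_numpy()
            b = ct.groupby("animal")["kg"].mean().to_numpy()
        else:
            a, b = rb["kg"].to_numpy(), ct["kg"].to_numpy()
        res = compare_two_groups(a, b, context=f"cycle {cyc}")
        rows.append({
            "cycle": cyc,
            "mean_rbst": rb["kg"].mean(), "sd_rbst": rb["kg"].std(ddof=1),
            "mean_control": ct["kg"].mean(),
            "sd_control": ct["kg"].std(ddof=1),
            "pct_diff_mean": pct.mean(),
            "pct_diff_sd": pct.std(ddof=1),
            "p": res.p, "stars": res.stars, "test": res.test,
            "day_first": int(g["day"].min()), "day_last": int(g["day"].max()),
        })
    return pd.DataFrame(rows).sort_values("cycle").reset_index(drop=True)


def gene_day_comparisons(records: pd.DataFrame) -> pd.DataFrame:
    """Treated-vs-control comparison per gene per sampling day.

    ``records``: long expression table with sample, animal, group, day,
    gene, abundance (NaN = undetected).  Days where either group has
    fewer than 3 detected values are skipped.
    """
    rows = []
    for (gene, day), g in records.groupby(["gene", "day"]):
        a = g.loc[(g["group"] == "rbst") & g["abundance"].notna(),
                  "abundance"].to_numpy()
        b = g.loc[(g["group"] == "control") & g["abundance"].notna(),
                  "abundance"].to_numpy()
        if len(a) < 3 or len(b) < 3:
            continue
        res = compare_two_groups(a, b, context=f"{gene} day {day}")
        rows.append({"gene": gene, "day": day, "test": res.test,
                     "statistic": res.statistic, "p": res.p,
                     "stars": res.stars,
                     "mean_rbst": a.mean(), "sd_rbst": a.std(ddof=1),
                     "mean_control": b.mean(), "sd_control": b.std(ddof=1)})
    return pd.DataFrame(rows)
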