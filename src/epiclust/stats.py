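"""Cohort cleaning, imputation, and cluster-characterization statistics.

Cleaning drops subjects with more than half their (non-identifier) cells
missing, then fills the remaining holes by random hot-deck imputation: each
missing value is replaced by a uniformly drawn observed value of the same
variable, preserving the empirical distribution.

Characterization compares the two severity clusters variable by variable:
chi-square tests (with Yates continuity correction, Phi effect size from
the uncorrected statistic) for binary variables (sex, stressful life
events, perinatal risk) and two-sample t-tests (Welch by default, Cohen's d
with pooled SD) for continuous ones (age, SES, T-scores, and every CpG's
methylation percentage).  P-values are Bonferroni-adjusted within a
configurable comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import ID_COLUMNS, METHYLATION_SITES

__all__ = [
    "TestResult",
    "StatsConfig",
    "ClusterReport",
    "clean_and_impute",
    "two_sample_t",
    "summary_t",
    "chi2_2x2",
    "bonferroni_adjust",
    "shapiro_wilk",
    "characterize",
]


@dataclass
class TestResult:
    kind: str                 # "welch_t" | "pooled_t" | "chi2_2x2"
    statistic: float
    df: float
    p_raw: float
    p_bonferroni: float | None = None
    effect: float | None = None   # Cohen's d (t) or Phi (chi2)
    group_summaries: dict = field(default_factory=dict)


def clean_and_impute(
    table: pd.DataFrame,
    max_missing: float = 0.5,
    seed: int = 0,
    id_columns: tuple[str, ...] = ID_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects with > ``max_missing`` fraction missing, then hot-deck.

    Returns the cleaned table and a removal log (subject id, missing
    fraction).  Imputed values are uniform draws from the same variable's
    observed values, so the observed support is preserved exactly.
    """
    if table.empty:
        raise ValueError("table is empty")
    data_cols = [c for c in table.columns if c not in id_columns]
    frac = table[data_cols].isna().mean(axis=1)
    removed = table.loc[frac > max_missing, list(id_columns)].copy()
    removed["missing_fraction"] = frac[frac > max_missing].to_numpy()
    out = table.loc[frac <= max_missing].reset_index(drop=True).copy()

    rng = np.random.default_rng(seed)
    for c in data_cols:
        miss = out[c].isna()
        if not miss.any():
            continue
        observed = out.loc[~miss, c].to_numpy()
        if observed.size == 0:
            raise ValueError(f"variable {c!r} has no observed values to impute from")
        out.loc[miss, c] = rng.choice(observed, size=int(miss.sum()), replace=True)
    return out, removed.reset_index(drop=True)


def _pooled_sd(n1, s1, n2, s2) -> float:
    return np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))


def summary_t(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    variant: str = "welch",
) -> TestResult:
    """Two-sample t-test from group summary statistics.

    The statistic's sign follows ``mean1 - mean2``.  Cohen's d always uses
    the pooled SD, whichever t variant is chosen.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 <= 0 and sd2 <= 0 and mean1 == mean2:
        stat, p, df = 0.0, 1.0, float(n1 + n2 - 2)
    elif sd1 <= 0 and sd2 <= 0:
        raise ValueError("degenerate: zero variance in both groups, unequal means")
    elif variant == "welch":
        res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    elif variant == "pooled":
        res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
        stat, p, df = float(res.statistic), float(res.pvalue), float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    d = (mean1 - mean2) / _pooled_sd(n1, sd1, n2, sd2) if (sd1 > 0 or sd2 > 0) else 0.0
    return TestResult(
        kind=f"{variant}_t",
        statistic=stat,
        df=float(df),
        p_raw=p,
        effect=float(d),
        group_summaries={
            "n": (n1, n2), "mean": (mean1, mean2), "sd": (sd1, sd2)
        },
    )


def two_sample_t(x, y, variant: str = "welch") -> TestResult:
    """Two-sample t-test on raw values (sign follows ``mean(x) - mean(y)``)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    return summary_t(
        len(x), float(x.mean()), float(x.std(ddof=1)),
        len(y), float(y.mean()), float(y.std(ddof=1)),
        variant=variant,
    )


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> TestResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Yates continuity correction is applied to the reported statistic and
    p-value when ``yates``; the Phi effect size is always computed from the
    uncorrected statistic, Phi = sqrt(chi2 / N).
    """
    tab = np.array([[a, b], [c, d]], float)
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: zero margin")
    res = sps.chi2_contingency(tab, correction=yates)
    raw = sps.chi2_contingency(tab, correction=False)
    phi = float(np.sqrt(raw.statistic / tab.sum()))
    return TestResult(
        kind="chi2_2x2",
        statistic=float(res.statistic),
        df=1.0,
        p_raw=float(res.pvalue),
        effect=phi,
        group_summaries={"table": [[a, b], [c, d]]},
    )


def bonferroni_adjust(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p-values (min(1, m*p)) and significance flags."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.array([], bool)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return p_adj, reject


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic and approximate p)."""
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    if len(x) < 3 or len(x) > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StatsConfig:
    variant: str = "welch"          # t-test flavor for continuous variables
    alpha: float = 0.05
    yates: bool = True
    # Bonferroni family: "methylation" corrects the 54 CpG comparisons as
    # one family; "all" corrects every comparison together.
    bonferroni_family: str = "methylation"


@dataclass
class ClusterReport:
    table: pd.DataFrame
    cluster_sizes: tuple[int, int]
    errors: list[str] = field(default_factory=list)


def characterize(
    table: pd.DataFrame,
    labels,
    config: StatsConfig = StatsConfig(),
    methylation_columns: tuple[str, ...] = METHYLATION_SITES,
) -> ClusterReport:
    """Cluster-characterization report in the style of a two-group table.

    ``labels`` are per-subject cluster indices (0 = LOW, 1 = HIGH) or
    "LOW"/"HIGH" strings.  Continuous statistics are signed HIGH - LOW.
    Per-test failures become NA rows and are listed in ``errors``.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = (labels == "HIGH").astype(int)
    if len(labels) != len(table):
        raise ValueError("labels must cover all subjects")
    low = table.loc[labels == 0]
    high = table.loc[labels == 1]

    binary_vars = [("sex", "M"), ("sle", 1), ("perinatal_risk", 1)]
    continuous = ["age", "ses", "internalizing", "externalizing"]
    meth = [c for c in methylation_columns if c in table.columns]

    rows, errors = [], []

    def _add(variable, group, result, extra=None):
        row = {"variable": variable, "group": group}
        if result is None:
            row.update({"kind": None, "statistic": np.nan, "df": np.nan,
                        "p_raw": np.nan, "effect": np.nan})
        else:
            row.update({"kind": result.kind, "statistic": result.statistic,
                        "df": result.df, "p_raw": result.p_raw,
                        "effect": result.effect})
        row.update(extra or {})
        rows.append(row)

    for var, present_level in binary_vars:
        try:
            a = int((low[var] == present_level).sum())
            b = int((low[var] != present_level).sum())
            c = int((high[var] == present_level).sum())
            d = int((high[var] != present_level).sum())
            res = chi2_2x2(a, b, c, d, yates=config.yates)
            _add(var, "binary", res,
                 {"low_present": a, "high_present": c,
                  "low_n": a + b, "high_n": c + d})
        except ValueError as exc:
            errors.append(f"{var}: {exc}")
            _add(var, "binary", None)

    for var in continuous + meth:
        group = "methylation" if var in meth else "continuous"
        try:
            res = two_sample_t(high[var], low[var], variant=config.variant)
            _add(var, group, res,
                 {"low_mean": float(np.nanmean(low[var])),
                  "low_sd": float(np.nanstd(low[var], ddof=1)),
                  "high_mean": float(np.nanmean(high[var])),
                  "high_sd": float(np.nanstd(high[var], ddof=1))})
        except ValueError as exc:
            errors.append(f"{var}: {exc}")
            _add(var, group, None)

    report = pd.DataFrame(rows)
    report["abs_statistic"] = report["statistic"].abs()

    if config.bonferroni_family == "all":
        family_mask = report["p_raw"].notna()
    else:
        family_mask = (report["group"] == "methylation") & report["p_raw"].notna()
    p_adj = np.full(len(report), np.nan)
    signif = np.zeros(len(report), bool)
    if family_mask.any():
        adj, rej = bonferroni_adjust(
            report.loc[family_mask, "p_raw"].to_numpy(), alpha=config.alpha
        )
        p_adj[family_mask.to_numpy()] = adj
        signif[family_mask.to_numpy()] = rej
    # variables outside the correction family are judged at raw alpha
    outside = report["p_raw"].notna() & ~family_mask
    signif[outside.to_numpy()] = report.loc[outside, "p_raw"] < config.alpha
    report["p_bonferroni"] = p_adj
    report["significant"] = signif

    return ClusterReport(
        table=report,
        cluster_sizes=(int((labels == 0).sum()), int((labels == 1).sum())),
        errors=errors,
    )
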