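"""Cohort-level statistics: sham normalization, comparisons, correlation.

Values are *expressed* as percent of matched sham controls (ipsilateral
cuff over ipsilateral sham mean, contralateral over contralateral sham
mean, day by day) while every hypothesis test runs on the absolute
values.  Group comparisons use two-sided t-tests (unpaired sham vs cuff
ipsilateral, paired ipsi vs contra within cuff animals) per stratum,
and a two-way group x day ANOVA with Bonferroni-corrected per-day
contrasts for behaviour.  The IB4-GAD65 relationship is a Spearman rank
correlation over per-animal mean densities pooled within a phase of the
time-course.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "normalize_to_sham",
    "compare_groups",
    "phase_correlation",
    "PhaseCorrelation",
    "DECREASING_PHASE_DAYS",
    "RECOVERY_PHASE_DAYS",
]

DECREASING_PHASE_DAYS = (5, 7, 10, 14)
RECOVERY_PHASE_DAYS = (21, 42, 56)


def aggregate_animals(records: pd.DataFrame, value_col: str = "density") -> pd.DataFrame:
    """Average section-level records to one value per animal x stratum."""
    keys = [c for c in ("day", "group", "animal", "side", "lamina", "marker", "endpoint") if c in records.columns]
    return records.groupby(keys, as_index=False)[value_col].mean()


def normalize_to_sham(
    records: pd.DataFrame,
    value_col: str = "value",
    strata: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Express per-animal endpoints as percent of the matched sham mean.

    ``records`` holds one row per animal and stratum with columns
    ``group`` (sham/cuff), the stratum keys and ``value_col``.  Each
    (day, side, ...) stratum is normalized by its own sham mean —
    ipsilateral by sham ipsilateral, contralateral by sham contralateral.
    Returns mean percent, SEM and n per group and stratum.
    """
    if strata is None:
        strata = tuple(
            c for c in ("day", "side", "lamina", "marker", "endpoint") if c in records.columns
        )
    out = []
    for key, sub in records.groupby(list(strata), dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        sham = sub.loc[sub["group"] == "sham", value_col]
        if len(sham) == 0:
            raise ValueError(f"no sham animals in stratum {dict(zip(strata, key))}")
        sham_mean = float(sham.mean())
        for group, gsub in sub.groupby("group"):
            if sham_mean == 0:
                pct = np.full(len(gsub), np.nan)
                warnings.warn(f"sham mean is zero in stratum {dict(zip(strata, key))}")
            else:
                pct = 100.0 * gsub[value_col].to_numpy() / sham_mean
            n = len(pct)
            out.append(
                dict(
                    zip(strata, key),
                    group=group,
                    mean_pct_of_sham=float(np.mean(pct)),
                    sem_pct=float(np.std(pct, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                    n_animals=n,
                    sham_mean_abs=sham_mean,
                )
            )
    return pd.DataFrame(out)


def compare_groups(records: pd.DataFrame, design: str, value_col: str = "value") -> pd.DataFrame:
    """Hypothesis tests on absolute per-animal values.

    ``design='behavior'``: two-way (group x day) ANOVA plus per-day
    unpaired contrasts with Bonferroni correction over days.
    ``design='histology'``: per stratum (day, lamina, marker), an
    unpaired sham-vs-cuff test on ipsilateral values and a paired
    ipsi-vs-contra test within cuff animals.  Strata with fewer than two
    animals per cell are skipped with a warning.
    """
    if design == "behavior":
        return _compare_behavior(records, value_col)
    if design == "histology":
        return _compare_histology(records, value_col)
    raise ValueError(f"unknown design {design!r}")


def _compare_behavior(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for endpoint, sub in records.groupby("endpoint") if "endpoint" in records.columns else [("value", records)]:
        sub = sub.rename(columns={value_col: "y"})
        # the full two-way model needs >=2 levels of each factor
        if sub["day"].nunique() >= 2 and sub["group"].nunique() >= 2:
            model = ols("y ~ C(group) * C(day)", data=sub).fit()
            an = sm.stats.anova_lm(model, typ=2)
            for term in ("C(group)", "C(day)", "C(group):C(day)"):
                rows.append(
                    dict(endpoint=endpoint, test="anova", term=term, day=None,
                         statistic=float(an.loc[term, "F"]), p_raw=float(an.loc[term, "PR(>F)"]),
                         p_adj=float(an.loc[term, "PR(>F)"]))
                )
        else:
            warnings.warn(
                f"{endpoint}: need at least two days and two groups for the "
                "two-way ANOVA; reporting per-day contrasts only"
            )
        days = sorted(sub["day"].unique())
        m = len(days)
        for day in days:
            a = sub.loc[(sub["day"] == day) & (sub["group"] == "sham"), "y"]
            b = sub.loc[(sub["day"] == day) & (sub["group"] == "cuff"), "y"]
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"day {day}: fewer than 2 animals per group; skipped")
                continue
            t, p = sps.ttest_ind(a, b)
            rows.append(
                dict(endpoint=endpoint, test="bonferroni_contrast", term="sham_vs_cuff",
                     day=day, statistic=float(t), p_raw=float(p), p_adj=float(min(1.0, m * p)))
            )
    return pd.DataFrame(rows)


def _compare_histology(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    rows = []
    for (day, lamina, marker), sub in records.groupby(["day", "lamina", "marker"]):
        ipsi = sub[sub["side"] == "ipsilateral"]
        sham = ipsi.loc[ipsi["group"] == "sham", value_col]
        cuff = ipsi.loc[ipsi["group"] == "cuff", value_col]
        if len(sham) >= 2 and len(cuff) >= 2:
            t, p = sps.ttest_ind(sham, cuff)
            rows.append(
                dict(day=day, lamina=lamina, marker=marker, test="sham_vs_cuff_ipsi",
                     statistic=float(t), p_raw=float(p), p_adj=float(p))
            )
        else:
            warnings.warn(f"{day}/{lamina}/{marker}: too few animals for sham-vs-cuff; skipped")
        cuff_sub = sub[sub["group"] == "cuff"].pivot_table(
            index="animal", columns="side", values=value_col
        )
        if {"ipsilateral", "contralateral"} <= set(cuff_sub.columns) and len(cuff_sub.dropna()) >= 2:
            cc = cuff_sub.dropna()
            t, p = sps.ttest_rel(cc["ipsilateral"], cc["contralateral"])
            rows.append(
                dict(day=day, lamina=lamina, marker=marker, test="ipsi_vs_contra_cuff",
                     statistic=float(t), p_raw=float(p), p_adj=float(p))
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhaseCorrelation:
    phase: str
    r: float
    p: float
    n: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("rho out of range")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for |rho| >= |observed| (small n)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def phase_correlation(
    per_animal: pd.DataFrame,
    phase_days: tuple[int, ...],
    phase: str = "",
    x_col: str = "ib4_density",
    y_col: str = "gad65_density",
) -> PhaseCorrelation:
    """Spearman correlation of per-animal IB4 vs GAD65 mean densities.

    One (IB4, GAD65) pair per animal per day, pooled over the phase's
    days.  The p-value is an exact permutation probability for n <= 8
    and the t-approximation otherwise.
    """
    sub = per_animal[per_animal["day"].isin(phase_days)]
    x = sub[x_col].to_numpy(dtype=float)
    y = sub[y_col].to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs for a meaningful correlation")
    r, p = sps.spearmanr(x, y)
    if n <= 8:
        p = _spearman_exact_p(x, y, r)
    return PhaseCorrelation(phase=phase or f"days {phase_days}", r=float(r), p=float(p), n=n)
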