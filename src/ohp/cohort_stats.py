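"""Cohort-level statistics for the odor hedonic questionnaire.

Covers the full descriptive/inferential battery run on a scored cohort:

* per-item means and SDs;
* Spearman rank correlations of each item with TS, T+ and T-;
* the across-item correlation between |mean| and SD (strongly hedonic
  items tend to be rated homogeneously, weakly hedonic ones diversely);
* Spearman correlations of the self-rated sense of smell with items and
  totals;
* independent-samples Student t comparisons between men and women;
* the pre-test item screening rules (per-item normality; share of
  respondents who never experienced the situation).

All p-values in a battery are Bonferroni-adjusted within that battery
(family sizes are explicit and configurable); significance is declared at
adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ITEM_COLUMNS, attach_scores, item_column
from .scoring import N_ITEMS

__all__ = [
    "ALPHA",
    "CorrelationResult",
    "bonferroni",
    "item_summaries",
    "spearman_rho",
    "item_total_correlations",
    "mean_sd_correlation",
    "sex_comparison",
    "self_smell_correlations",
    "screen_items",
]

ALPHA = 0.05
TOTAL_COLUMNS = ("ts", "t_plus", "t_minus")


class ConstantInputError(ValueError):
    """Correlation is undefined because one input vector is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_raw: float
    p_adjusted: float
    significant: bool
    n: int


def bonferroni(p: float, family_size: int) -> float:
    """Multiplicative family-wise adjustment, capped at 1."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, float(p) * family_size)


def item_summaries(cohort: pd.DataFrame, *, ddof: int = 1) -> pd.DataFrame:
    """Per-item mean and sample SD over the cohort.

    Returns a DataFrame with columns ``item_id, mean, sd, n``.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 respondents for an SD")
    rows = []
    for i in range(1, N_ITEMS + 1):
        col = cohort[item_column(i)].to_numpy(dtype=float)
        rows.append({"item_id": i, "mean": col.mean(), "sd": col.std(ddof=ddof), "n": n})
    return pd.DataFrame(rows)


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    *,
    family_size: int = 1,
    exact: bool = False,
) -> CorrelationResult:
    """Spearman rank correlation with a Bonferroni-adjusted p-value.

    Rho is Pearson's r on mid-ranks (ties get average ranks).  The default
    two-sided p-value comes from the t approximation
    ``t = rho * sqrt((n-2) / (1 - rho^2))`` with n-2 df; ``exact=True``
    uses the permutation-based exact null (small n only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    if exact:
        res = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=np.inf,
            alternative="two-sided",
        )
        rho, p = float(stats.spearmanr(x, y).statistic), float(res.pvalue)
    else:
        r = stats.spearmanr(x, y)
        rho, p = float(r.statistic), float(r.pvalue)
    p_adj = bonferroni(p, family_size)
    return CorrelationResult(rho=rho, p_raw=p, p_adjusted=p_adj,
                             significant=p_adj < ALPHA, n=n)


def _corr_row(x, y, name: str, target: str, family_size: int) -> dict:
    r = spearman_rho(x, y, family_size=family_size)
    return {"variable": name, "total": target, "rho": r.rho, "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted, "significant": r.significant, "n": r.n}


def item_total_correlations(cohort: pd.DataFrame, *, family_size: Optional[int] = None) -> pd.DataFrame:
    """Spearman correlation of every item with TS, T+ and T- (42 tests).

    The Bonferroni family defaults to the full 14 x 3 table.
    """
    scored = cohort if "ts" in cohort.columns else attach_scores(cohort)
    m = family_size if family_size is not None else N_ITEMS * len(TOTAL_COLUMNS)
    rows = []
    for i in range(1, N_ITEMS + 1):
        x = scored[item_column(i)].to_numpy(dtype=float)
        for target in TOTAL_COLUMNS:
            rows.append(_corr_row(x, scored[target].to_numpy(dtype=float),
                                  item_column(i), target, m))
    return pd.DataFrame(rows)


def mean_sd_correlation(summaries: pd.DataFrame, *, family_size: int = 1) -> CorrelationResult:
    """Spearman correlation between |item mean| and item SD across items.

    A negative value means strongly hedonic items (large |mean|) are rated
    more homogeneously (small SD) than weakly hedonic ones.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 items")
    return spearman_rho(summaries["mean"].abs().to_numpy(),
                        summaries["sd"].to_numpy(), family_size=family_size)


def sex_comparison(
    cohort: pd.DataFrame,
    *,
    family_size: Optional[int] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Men-vs-women comparison of every item and total (18 tests).

    Uses the pooled-variance (Student) independent two-sample t-test by
    default; ``welch=True`` drops the equal-variance assumption.  The
    Bonferroni family defaults to the 14 items + TS, T+, T-, delta.
    """
    scored = cohort if "ts" in cohort.columns else attach_scores(cohort)
    men = scored[scored["sex"] == "M"]
    women = scored[scored["sex"] == "F"]
    if len(men) < 2 or len(women) < 2:
        raise ValueError("each sex group needs at least 2 respondents")
    variables = list(ITEM_COLUMNS) + ["ts", "t_plus", "t_minus", "delta"]
    m = family_size if family_size is not None else len(variables)
    rows = []
    for var in variables:
        xm = men[var].to_numpy(dtype=float)
        xf = women[var].to_numpy(dtype=float)
        t, p = stats.ttest_ind(xm, xf, equal_var=not welch)
        p_adj = bonferroni(float(p), m)
        rows.append({
            "variable": var, "mean_m": xm.mean(), "mean_f": xf.mean(),
            "t": float(t), "p_raw": float(p), "p_adjusted": p_adj,
            "significant": p_adj < ALPHA,
        })
    return pd.DataFrame(rows)


def self_smell_correlations(cohort: pd.DataFrame, *, family_size: Optional[int] = None) -> pd.DataFrame:
    """Spearman correlation of self-rated smell with items and totals.

    Respondents missing the self-rating are excluded; the reported ``n``
    and ``n_excluded`` columns make the exclusion explicit.  The family
    defaults to the 14 items + TS, T+, T-, delta (19 tests).
    """
    scored = cohort if "ts" in cohort.columns else attach_scores(cohort)
    present = scored[scored["self_smell"].notna()]
    n_excluded = len(scored) - len(present)
    if len(present) < 3:
        raise ValueError("need at least 3 respondents with a self-smell rating")
    variables = list(ITEM_COLUMNS) + ["ts", "t_plus", "t_minus", "delta"]
    m = family_size if family_size is not None else len(variables)
    ss = present["self_smell"].to_numpy(dtype=float)
    rows = []
    for var in variables:
        row = _corr_row(ss, present[var].to_numpy(dtype=float), var, "self_smell", m)
        row["n_excluded"] = n_excluded
        rows.append(row)
    return pd.DataFrame(rows)


def screen_items(
    item_scores: pd.DataFrame,
    never_experienced: pd.DataFrame,
    *,
    alpha: float = ALPHA,
    max_never_proportion: float = 2 / 30,
) -> pd.DataFrame:
    """Apply the pre-test item screening rules.

    An item is excluded when (1) a Shapiro-Wilk test rejects normality of
    its scores at ``alpha``, or (2) the share of respondents who never
    experienced the situation exceeds ``max_never_proportion`` — by
    default more than two out of 30, the instrument's original cutoff
    (nominally "more than 5%").  ``item_scores`` and ``never_experienced``
    are respondents x items frames with matching columns (the latter
    boolean).  Returns one row per item with the decision and reasons.
    """
    if list(item_scores.columns) != list(never_experienced.columns):
        raise ValueError("score and flag tables must have matching item columns")
    if len(item_scores) < 3:
        raise ValueError("need at least 3 respondents for a normality test")
    rows = []
    for col in item_scores.columns:
        scores = item_scores[col].to_numpy(dtype=float)
        flags = never_experienced[col].to_numpy(dtype=bool)
        reasons = []
        if np.ptp(scores) == 0:
            # Degenerate: a constant item carries no distribution to test.
            p_normal = np.nan
            reasons.append("constant scores")
        else:
            p_normal = float(stats.shapiro(scores).pvalue)
            if p_normal < alpha:
                reasons.append(f"non-normal distribution (Shapiro-Wilk p={p_normal:.3g})")
        never_prop = float(flags.mean())
        if never_prop > max_never_proportion:
            reasons.append(
                f"never experienced by {flags.sum()}/{flags.size} "
                f"({100 * never_prop:.1f}% > {100 * max_never_proportion:.1f}%)"
            )
        rows.append({
            "item": col, "keep": not reasons, "shapiro_p": p_normal,
            "never_proportion": never_prop,
            "reason": "; ".join(reasons) if reasons else "",
        })
    return pd.DataFrame(rows)
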