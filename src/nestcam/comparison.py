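"""Species comparison of camouflage metrics.

For each metric: assumption checks (Levene's test on medians for variance
homogeneity, Shapiro-Wilk per group for normality), an optional log
transform, Welch's unequal-variance two-sample t-test (fractional
Welch-Satterthwaite degrees of freedom), and multiplicity control across
the metric set (Benjamini-Hochberg step-up by default; Holm step-down
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Metrics the original analysis log-transformed before testing.
DEFAULT_LOG_VARS = ["DisRat", "CompRat", "DeltaE", "egg_a", "eggbg_a", "macul_a"]

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm"}


@dataclass
class ComparisonResult:
    variable: str
    transform: str
    mean_sd: dict  # species -> (mean, sd) on the original scale
    n: dict  # species -> sample size
    t: float
    df: float
    p_raw: float
    p_adjusted: float = np.nan
    levene_p: float = np.nan
    shapiro_p: dict | None = None
    flagged: bool = False
    note: str = ""


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Welch-Satterthwaite df, and two-sided p."""
    res = stats.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    df = (vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compare_groups(
    records: pd.DataFrame,
    variables: list[str],
    log_vars: list[str] | None = None,
    group_col: str = "species",
    adjust: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison table over camouflage metrics.

    Missing values are dropped per variable; a variable with fewer than
    two observations in either group is flagged and excluded from testing
    (and from the multiplicity adjustment).  Log-transformed variables
    must be positive; non-positive values are dropped with a note.
    Returns one row per variable with group means +/- SD on the original
    scale, Welch t, fractional df, raw and adjusted p, and the
    assumption-check p-values.
    """
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(_ADJUST_METHODS)}")
    log_vars = DEFAULT_LOG_VARS if log_vars is None else log_vars
    groups = sorted(records[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")

    results: list[ComparisonResult] = []
    for var in variables:
        use_log = var in log_vars
        sub = records[[group_col, var]].dropna()
        note = ""
        if use_log:
            bad = sub[var] <= 0
            if bad.any():
                note = f"dropped {int(bad.sum())} non-positive values before log transform"
                logger.warning("%s: %s", var, note)
                sub = sub[~bad]
        samples = {g: sub.loc[sub[group_col] == g, var].to_numpy(dtype=float) for g in groups}
        mean_sd = {g: (float(np.mean(s)) if len(s) else np.nan, float(np.std(s, ddof=1)) if len(s) > 1 else np.nan) for g, s in samples.items()}
        ns = {g: len(s) for g, s in samples.items()}
        if min(ns.values()) < 2:
            results.append(
                ComparisonResult(
                    variable=var, transform="log" if use_log else "none", mean_sd=mean_sd,
                    n=ns, t=np.nan, df=np.nan, p_raw=np.nan, flagged=True,
                    note=note + "; insufficient observations in one group",
                )
            )
            continue
        tx = {g: (np.log(s) if use_log else s) for g, s in samples.items()}
        x, y = tx[groups[0]], tx[groups[1]]
        lev_p = float(stats.levene(x, y, center="median").pvalue)
        shapiro_p = {g: float(stats.shapiro(s).pvalue) if 3 <= len(s) <= 5000 else np.nan for g, s in tx.items()}
        t, df, p = welch_t(x, y)
        # degenerate samples (zero variance in both groups, non-finite
        # transformed values) give a non-finite p: flag rather than let
        # NaN poison the multiplicity adjustment
        flagged = not (np.isfinite(p) and np.isfinite(t))
        if flagged:
            note = (note + "; " if note else "") + "degenerate sample, test undefined"
            logger.warning("%s: %s", var, note)
        results.append(
            ComparisonResult(
                variable=var, transform="log" if use_log else "none", mean_sd=mean_sd,
                n=ns, t=t, df=df, p_raw=p, levene_p=lev_p, shapiro_p=shapiro_p,
                flagged=flagged, note=note,
            )
        )

    tested = [r for r in results if not r.flagged]
    if tested:
        _, p_adj, _, _ = multipletests([r.p_raw for r in tested], alpha=alpha, method=_ADJUST_METHODS[adjust])
        for r, pa in zip(tested, p_adj):
            r.p_adjusted = float(pa)

    rows = []
    for r in results:
        row = {
            "variable": r.variable,
            "transform": r.transform,
            "t": r.t,
            "df": r.df,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "levene_p": r.levene_p,
            "adjust_method": adjust,
            "flagged": r.flagged,
            "note": r.note,
        }
        for g in groups:
            row[f"mean_{g}"], row[f"sd_{g}"] = r.mean_sd[g]
            row[f"n_{g}"] = r.n[g]
            row[f"shapiro_p_{g}"] = (r.shapiro_p or {}).get(g, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def quadratic_deviation(comp_rat: np.ndarray) -> np.ndarray:
    """Squared log-scale deviation of CompRat from perfect matching.

    Pattern-complexity matching is best when CompRat = 1, so the relevant
    survival covariate is (log CompRat)^2: zero at perfect matching,
    symmetric in over- vs under-complexity (CompRat of 0.5 and 2 score
    equally).  Non-positive inputs yield NaN.
    """
    x = np.asarray(comp_rat, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = x > 0
    out[ok] = np.log(x[ok]) ** 2
    return out
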