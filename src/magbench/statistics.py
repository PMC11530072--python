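"""Statistical comparison layer for benchmark metric panels.

Pairwise differences between design-factor levels (sequencing depth,
relatedness, abundance distribution, pipeline) are tested with classic
equal-variance two-sample t-tests under a Bonferroni correction over all
level pairs of one call, and — as the complementary route — with one-way
ANOVA followed by Tukey's HSD.  The three replicate species groups supply
the observations within each level.  Significance is declared at adjusted
p < 0.05.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InsufficientReplicationError

ALPHA = 0.05


def _level_values(
    panel: pd.DataFrame, factor: str, metric: str, value_col: str
) -> dict[str, np.ndarray]:
    if factor not in panel.columns:
        raise KeyError(f"factor column {factor!r} not in panel")
    sub = panel[panel["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    out: dict[str, np.ndarray] = {}
    for level, grp in sub.groupby(factor, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            raise InsufficientReplicationError(
                f"level {level!r} of factor {factor!r} has {vals.size} observation(s); "
                "at least 2 are required"
            )
        out[str(level)] = vals
    if len(out) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels for metric {metric!r}")
    return out


def pairwise_tests(
    panel: pd.DataFrame,
    factor: str,
    metric: str,
    value_col: str = "value",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Bonferroni-adjusted Student's t-tests over every pair of factor levels.

    Returns one row per level pair with the t statistic, raw and adjusted
    (min(1, m·p) for m comparisons) two-sided p-values, and a significance
    flag at *alpha*.  Results do not depend on the row order of the panel.
    """
    groups = _level_values(panel, factor, metric, value_col)
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        p_adj = min(1.0, m * p) if not math.isnan(p) else math.nan
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha) if not math.isnan(p_adj) else False,
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(
    panel: pd.DataFrame,
    factor: str,
    metric: str,
    value_col: str = "value",
    alpha: float = ALPHA,
) -> tuple[dict[str, float], pd.DataFrame]:
    """One-way ANOVA across factor levels, then Tukey's HSD per pair.

    Returns ``(anova, tukey)`` where *anova* holds the F statistic and
    p-value and *tukey* is a tidy frame of pairwise results.  When the
    between-level sum of squares is zero (all level means identical) F is
    0 by definition and p is 1.
    """
    groups = _level_values(panel, factor, metric, value_col)
    samples = [groups[k] for k in sorted(groups)]
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    if ss_between == 0.0:
        anova = {"F": 0.0, "p": 1.0}
    else:
        f, p = sps.f_oneway(*samples)
        anova = {"F": float(f), "p": float(p)}

    values = np.concatenate(samples)
    labels = np.concatenate([[k] * len(groups[k]) for k in sorted(groups)])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return anova, tukey


def summarize_profiles(
    panel: pd.DataFrame,
    by: tuple[str, ...] = ("abundance_kind", "relatedness", "depth", "pipeline"),
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± sd of every metric per design-factor combination.

    Returns ``(summary, grand)``: the per-combination table (sample sd,
    0 for singletons) and the grand means per (pipeline, metric).
    """
    keys = [c for c in by if c in panel.columns]
    summary = (
        panel.groupby([*keys, "metric"], sort=True, dropna=False)[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    summary["sd"] = summary["sd"].fillna(0.0)
    grand_keys = [k for k in ("pipeline",) if k in panel.columns]
    grand = (
        panel.groupby([*grand_keys, "metric"], sort=True)[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grand["sd"] = grand["sd"].fillna(0.0)
    return summary, grand
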