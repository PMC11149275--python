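"""Group comparison of outcome measures: ANOVA, Tukey HSD, mean +/- SD.

One- and two-way fixed-effects ANOVA are delegated to statsmodels OLS;
two-way fits include the interaction and require a balanced design
(unbalanced input falls back to one-way per factor with a logged warning,
refusing the silent Type-I/II/III ambiguity).  Tukey's HSD is computed from
the studentized-range distribution with Tukey-Kramer standard errors;
significance uses strict ``p < alpha``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def _validate(df: pd.DataFrame, value_col: str, group_col: str) -> pd.DataFrame:
    if value_col not in df.columns or group_col not in df.columns:
        raise ValidationError(f"table needs columns {value_col!r} and {group_col!r}")
    d = df[[c for c in df.columns]].dropna(subset=[value_col, group_col])
    counts = d.groupby(group_col, observed=True)[value_col].count()
    if len(counts) < 2:
        raise ValidationError("need at least 2 groups")
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(
            f"groups with < 2 observations: {list(small.index)}")
    if float(np.var(d[value_col].to_numpy(float))) == 0.0:
        raise ValidationError("zero total variance in outcome")
    return d


def anova(df: pd.DataFrame, factors: list[str] | str = "group",
          value_col: str = "value") -> pd.DataFrame:
    """Fixed-effects ANOVA table (sum_sq, df, F, p) for one or two factors."""
    if isinstance(factors, str):
        factors = [factors]
    if len(factors) not in (1, 2):
        raise ValidationError("anova supports one or two factors")
    d = _validate(df, value_col, factors[0])
    d = d.rename(columns={value_col: "_y"})
    if len(factors) == 1:
        model = smf.ols(f"_y ~ C(Q('{factors[0]}'))", data=d).fit()
        table = sm.stats.anova_lm(model, typ=1)
    else:
        f1, f2 = factors
        cells = d.groupby([f1, f2], observed=True)["_y"].count()
        full = d[f1].nunique() * d[f2].nunique()
        if len(cells) < full or cells.nunique() != 1:
            log.warning("unbalanced two-way design; falling back to one-way per factor")
            parts = []
            for f in factors:
                t = anova(df, factors=f, value_col=value_col)
                t.index = [f"{f}:{i}" for i in t.index]
                parts.append(t)
            return pd.concat(parts)
        model = smf.ols(f"_y ~ C(Q('{f1}')) * C(Q('{f2}'))", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(columns={"PR(>F)": "p"})
    return table


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    difference: float
    p_adjusted: float
    significant: bool


def tukey_hsd(df: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
              value_col: str = "value", group_col: str = "group") -> pd.DataFrame:
    """All-pairs Tukey HSD on a one-way layout.

    Adjusted p-values come from the studentized-range distribution with
    ``k`` groups and the pooled within-group degrees of freedom; unequal
    group sizes use the Tukey-Kramer standard error.
    """
    d = _validate(df, value_col, group_col)
    g = d.groupby(group_col, observed=True)[value_col]
    means = g.mean()
    counts = g.count()
    k = len(means)
    n_total = int(counts.sum())
    dof = n_total - k
    sse = float(((d[value_col] - d[group_col].map(means)) ** 2).sum())
    mse = sse / dof
    if mse == 0.0:
        raise ValidationError("zero within-group variance; Tukey HSD undefined")
    rows = []
    for a, b in itertools.combinations(means.index, 2):
        diff = float(means[b] - means[a])
        se = np.sqrt(mse / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
        q = abs(diff) / se
        p = float(studentized_range.sf(q, k, dof))
        p = min(max(p, 0.0), 1.0)
        rows.append(PairwiseComparison(group1=str(a), group2=str(b),
                                       difference=diff, p_adjusted=p,
                                       significant=bool(p < alpha)))
    return pd.DataFrame([r.__dict__ for r in rows])


def max_studentized_range(values: np.ndarray, groups_n: int) -> tuple[float, int]:
    """Largest pairwise |mean difference| / SE for a balanced layout.

    ``values`` has shape (..., k, n).  Returns the max q statistic per
    leading index and the within dof; rejecting any pair at level alpha is
    equivalent to ``q_max > studentized_range.ppf(1 - alpha, k, dof)``.
    Used for fast family-wise error simulations; agrees with
    :func:`tukey_hsd` decisions by construction.
    """
    v = np.asarray(values, dtype=float)
    k, n = v.shape[-2], v.shape[-1]
    means = v.mean(axis=-1)
    mse = v.var(axis=-1, ddof=1).mean(axis=-1)
    dof = k * (n - 1)
    diffs = np.abs(means[..., :, None] - means[..., None, :])
    qmax = diffs.max(axis=(-2, -1)) / np.sqrt(mse / n)
    return qmax, dof


def summarize(df: pd.DataFrame, value_col: str = "value",
              group_col: str = "group") -> pd.DataFrame:
    """Per-group mean +/- sample SD (n-1 denominator) table."""
    if value_col not in df.columns or group_col not in df.columns:
        raise ValidationError(f"table needs columns {value_col!r} and {group_col!r}")
    g = df.groupby(group_col, observed=True)[value_col]
    out = pd.DataFrame({"n": g.count(), "mean": g.mean(), "sd": g.std(ddof=1)})
    out["formatted"] = [f"{m:.2f} ± {s:.2f}" if np.isfinite(s) else f"{m:.2f}"
                        for m, s in zip(out["mean"], out["sd"])]
    return out
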