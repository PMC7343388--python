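"""Descriptive and inferential statistics used around the position pipeline:
Pearson correlations with df-style reporting, Welch's heteroscedastic ANOVA,
two-way ANCOVA with interaction (Type III sums of squares), Welch's t-test
and the coefficient of variation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "CorrelationResult",
    "AncovaTable",
    "pearson",
    "welch_anova",
    "ancova_two_way",
    "cv_stat",
    "welch_t",
]


@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int

    def __post_init__(self):
        if self.df != self.n - 2:
            raise ValueError("df must equal n - 2")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")

    def __str__(self):
        return f"r({self.df}) = {self.r:.2f}, p = {self.p:.4g}"


@dataclass
class AncovaTable:
    rows: list  # of dicts {term, df, sum_of_squares, F, p}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["term", "df", "sum_of_squares", "F", "p"])


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with df = n - 2 and a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input")
    r, p = _stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), df=x.size - 2, p=float(p), n=x.size)


def welch_anova(groups) -> dict:
    """Welch's heteroscedastic one-way ANOVA.

    Returns {"F", "df1", "df2", "p"} with the fractional Satterthwaite-style
    denominator degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    if np.any(var == 0):
        raise ValueError("a group has zero variance")
    w = n / var
    w_sum = w.sum()
    grand = np.sum(w * means) / w_sum
    a = np.sum(w * (means - grand) ** 2) / (k - 1)
    lam = np.sum((1 - w / w_sum) ** 2 / (n - 1))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = float(a / b)
    df1 = k - 1
    df2 = float((k**2 - 1) / (3 * lam))
    return {"F": f, "df1": df1, "df2": df2,
            "p": float(_stats.f.sf(f, df1, df2))}


def ancova_two_way(y, class_label, covariate) -> AncovaTable:
    """Two-way ANCOVA: class (categorical), covariate (continuous) and their
    interaction, with Type III sums of squares (sum-to-zero contrasts)."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "g": np.asarray(class_label).astype(str),
        "x": np.asarray(covariate, dtype=float),
    })
    levels = df["g"].unique()
    if len(levels) < 2:
        raise ValueError("need at least two classes")
    for lvl in levels:
        if df.loc[df["g"] == lvl, "x"].nunique() < 2:
            raise ValueError(f"class {lvl!r} has no spread in the covariate; "
                             "class is confounded with the covariate")
    fit = smf.ols("y ~ C(g, Sum) * x", data=df).fit()
    table = anova_lm(fit, typ=3)
    name_map = {"C(g, Sum)": "class", "x": "covariate",
                "C(g, Sum):x": "interaction", "Residual": "residual"}
    rows = []
    for raw, pretty in name_map.items():
        rec = table.loc[raw]
        rows.append({
            "term": pretty,
            "df": int(rec["df"]),
            "sum_of_squares": float(rec["sum_sq"]),
            "F": float(rec["F"]) if np.isfinite(rec["F"]) else None,
            "p": float(rec["PR(>F)"]) if np.isfinite(rec["PR(>F)"]) else None,
        })
    return AncovaTable(rows=rows)


def cv_stat(values) -> float:
    """Coefficient of variation: sample SD (ddof=1) divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def welch_t(a, b) -> dict:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per sample")
    res = _stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue)}
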