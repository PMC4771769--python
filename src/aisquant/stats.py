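"""The inferential stack: factorial and one-way ANOVA, Bonferroni planned
comparisons, Tukey-Kramer HSD, and Bonferroni-corrected t-tests.

Two-way ANOVA on cluster density/size uses location (AIS, non-AIS) x brain
area with interaction.  Because ROI counts per cell are unequal, sums of
squares are Type III with sum-to-zero contrasts (the factorial default of the
commercial packages this replicates).  Missing responses — e.g. the missing
mean size of a zero-puncta ROI — are dropped listwise per analysis.

Degenerate inputs (zero residual variance) yield missing (NaN) statistics
with warnings rather than exceptions, so that pathological synthetic inputs
do not abort a pipeline run.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ComparisonResult",
    "two_way_anova",
    "one_way_anova",
    "bonferroni_planned",
    "tukey_kramer",
    "bonferroni_t_tests",
]

_EPS_VAR = 1e-12


@dataclass
class ComparisonResult:
    """One pairwise comparison with its raw and adjusted p-value."""

    pair: tuple[str, str]
    estimate: float  # mean difference (first minus second)
    p_raw: float
    p_adjusted: float
    method: str  # BONFERRONI or TUKEY_KRAMER


def _anova_table(rows: dict[str, dict]) -> pd.DataFrame:
    tab = pd.DataFrame.from_dict(rows, orient="index")[["df", "ss", "ms", "F", "p"]]
    tab.index.name = "effect"
    return tab


def two_way_anova(
    response: np.ndarray,
    location: np.ndarray,
    brain_area: np.ndarray,
) -> pd.DataFrame:
    """Full-factorial location x brain-area ANOVA (Type III, sum contrasts).

    Returns a table indexed by effect (location, brain_area, interaction,
    residual) with columns df, ss, ms, F, p.  Rows with missing responses are
    dropped listwise.
    """
    df = pd.DataFrame(
        {"y": np.asarray(response, dtype=float),
         "loc": np.asarray(location, dtype=object),
         "area": np.asarray(brain_area, dtype=object)}
    ).dropna()
    if df["loc"].nunique() < 2 or df["area"].nunique() < 2:
        raise ValueError("each factor needs >= 2 observed levels")
    cells = df.groupby(["loc", "area"], observed=True).size()
    if len(cells) < df["loc"].nunique() * df["area"].nunique():
        raise ValueError("empty cells make the interaction inestimable")
    model = smf.ols("y ~ C(loc, Sum) * C(area, Sum)", data=df).fit()
    raw = anova_lm(model, typ=3)
    resid_ss = float(raw.loc["Residual", "sum_sq"])
    resid_df = int(raw.loc["Residual", "df"])
    if resid_df < 1:
        raise ValueError("residual degrees of freedom < 1")
    resid_ms = resid_ss / resid_df
    degenerate = resid_ms < _EPS_VAR
    if degenerate:
        warnings.warn("zero residual variance: F statistics undefined", stacklevel=2)
    name_map = {
        "C(loc, Sum)": "location",
        "C(area, Sum)": "brain_area",
        "C(loc, Sum):C(area, Sum)": "interaction",
    }
    rows = {}
    for src, name in name_map.items():
        ss = float(raw.loc[src, "sum_sq"])
        d = int(raw.loc[src, "df"])
        ms = ss / d
        if degenerate:
            f = p = float("nan")
        else:
            f = ms / resid_ms
            p = float(sps.f.sf(f, d, resid_df))
        rows[name] = {"df": d, "ss": ss, "ms": ms, "F": f, "p": p}
    rows["residual"] = {
        "df": resid_df, "ss": resid_ss, "ms": resid_ms, "F": float("nan"), "p": float("nan"),
    }
    return _anova_table(rows)


def one_way_anova(response: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Between/within one-way ANOVA decomposition."""
    df = pd.DataFrame(
        {"y": np.asarray(response, dtype=float), "g": np.asarray(group, dtype=object)}
    ).dropna()
    groups = [v["y"].to_numpy() for _, v in df.groupby("g", observed=True)]
    k = len(groups)
    n = len(df)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if n - k < 1:
        raise ValueError("residual degrees of freedom < 1")
    grand = df["y"].mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_b = ss_between / (k - 1)
    ms_w = ss_within / (n - k)
    if ms_w < _EPS_VAR:
        warnings.warn("zero within-group variance: F undefined", stacklevel=2)
        f = p = float("nan")
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, k - 1, n - k))
    return _anova_table(
        {
            "group": {"df": k - 1, "ss": ss_between, "ms": ms_b, "F": f, "p": p},
            "residual": {"df": n - k, "ss": ss_within, "ms": ms_w,
                         "F": float("nan"), "p": float("nan")},
        }
    )


def bonferroni_planned(p_values, n_comparisons: int | None = None) -> list[float]:
    """Bonferroni adjustment for planned comparisons: min(1, p * n)."""
    p_values = list(p_values)
    n = len(p_values) if n_comparisons is None else int(n_comparisons)
    if n < len(p_values):
        raise ValueError("n_comparisons must be >= number of p-values")
    return [min(1.0, p * n) for p in p_values]


def tukey_kramer(groups: dict[str, np.ndarray]) -> list[ComparisonResult]:
    """Tukey-Kramer pairwise comparisons (unequal-n HSD).

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)); p from the
    studentized range distribution with k groups and the pooled residual df.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    arrays = [a[~np.isnan(a)] for a in arrays]
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([len(a) for a in arrays])
    if (ns < 1).any():
        raise ValueError("empty group")
    n_total = int(ns.sum())
    dof = n_total - k
    if dof < 1:
        raise ValueError("pooled residual df < 1")
    means = np.array([a.mean() for a in arrays])
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / dof
    if mse < _EPS_VAR:
        warnings.warn("zero residual variance: Tukey-Kramer undefined", stacklevel=2)
        mse = float("nan")
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else float("nan")
        p = float(sps.studentized_range.sf(q, k, dof)) if np.isfinite(q) else float("nan")
        out.append(
            ComparisonResult(
                pair=(labels[i], labels[j]),
                estimate=float(diff),
                p_raw=p,
                p_adjusted=p,  # Tukey-Kramer p is already family-wise
                method="TUKEY_KRAMER",
            )
        )
    return out


def bonferroni_t_tests(
    samples: dict[str, tuple[np.ndarray, np.ndarray]],
    n_comparisons: int | None = None,
) -> list[ComparisonResult]:
    """Two-sample t-test per metric, Bonferroni-corrected over the family.

    ``samples`` maps metric name -> (AIS values, non-AIS values).  Identical
    degenerate samples (zero pooled variance, equal means) give t = 0 and
    adjusted p = 1; zero pooled variance with unequal means is undefined.
    """
    n_family = len(samples) if n_comparisons is None else int(n_comparisons)
    if n_family < len(samples):
        raise ValueError("n_comparisons must be >= number of metrics")
    out = []
    for name, (x, y) in samples.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"{name}: need >= 2 observations per location")
        pooled = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (
            len(x) + len(y) - 2
        )
        if pooled < _EPS_VAR:
            if np.isclose(x.mean(), y.mean()):
                p_raw, est = 1.0, float(x.mean() - y.mean())
            else:
                warnings.warn(f"{name}: zero pooled variance, t undefined", stacklevel=2)
                p_raw, est = float("nan"), float(x.mean() - y.mean())
        else:
            t = sps.ttest_ind(x, y, equal_var=True)
            p_raw, est = float(t.pvalue), float(x.mean() - y.mean())
        out.append(
            ComparisonResult(
                pair=(f"{name}:AIS", f"{name}:NON_AIS"),
                estimate=est,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * n_family) if np.isfinite(p_raw) else float("nan"),
                method="BONFERRONI",
            )
        )
    return out
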