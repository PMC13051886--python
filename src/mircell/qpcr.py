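"""RT-qPCR validation arithmetic and statistics.

Implements the standard relative-quantification workflow: housekeeping
selection by coefficient of variation among stable, highly expressed
candidates; amplification-efficiency fits on dilution-series standards
(E% = (10^(-1/slope) - 1) * 100, a slope of -3.3219 Ct per decade is 100%);
the 2^-ddCt method baselined to the control group; Welch group tests with a
Shapiro-Wilk normality screen; and Pearson correlation of dCt values between
miRNA-target pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mircell.diffexpr import ExpressionMatrix

__all__ = [
    "EfficiencyFit",
    "select_housekeeping",
    "fit_efficiency",
    "ddct",
    "group_test",
    "pair_correlation",
]


@dataclass
class EfficiencyFit:
    assay: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float

    @property
    def passes(self) -> bool:
        """Usable standard curve: linear fit with r^2 > 0.99."""
        return self.r_squared > 0.99


def select_housekeeping(
    m: ExpressionMatrix,
    candidates: Sequence[str] | str = "all",
    stability_p: float = 0.5,
    expression_quantile: float = 0.75,
) -> pd.DataFrame:
    """Rank housekeeping candidates by stability and expression.

    For each candidate the coefficient of variation is computed on the linear
    scale (2^log2 values), together with a two-sided Welch p between groups
    and the mean-expression rank.  The selected normalizer minimizes CV among
    candidates that are invariable between conditions (Welch p >
    ``stability_p``) and highly expressed (mean log2 expression at or above
    the ``expression_quantile`` quantile of all features).
    """
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    feats = list(m.values.index) if candidates == "all" else list(candidates)
    missing = [f for f in feats if f not in m.values.index]
    if missing:
        raise ValueError(f"candidates absent from matrix: {missing}")
    groups = m.groups()
    case = m.values.loc[:, (groups == "case").to_numpy()]
    ctrl = m.values.loc[:, (groups == "control").to_numpy()]
    all_means = m.values.mean(axis=1)
    expr_cut = all_means.quantile(expression_quantile)
    rows = []
    for f in feats:
        linear = np.exp2(m.values.loc[f].to_numpy(dtype=float))
        cv = float(linear.std(ddof=1) / linear.mean()) if linear.mean() > 0 else np.inf
        if case.shape[1] >= 2 and ctrl.shape[1] >= 2:
            a, b = case.loc[f], ctrl.loc[f]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                # constant within both groups: no evidence of a group effect
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append({"feature": f, "cv": cv, "group_p": p,
                     "mean_expr": float(all_means[f])})
    report = pd.DataFrame(rows).set_index("feature")
    report["expr_rank"] = report["mean_expr"].rank(ascending=False).astype(int)
    eligible = (report["group_p"] > stability_p) & (report["mean_expr"] >= expr_cut)
    report["selected"] = False
    if not eligible.any():
        near = report.sort_values("cv").head(3)
        raise ValueError(
            "no housekeeping candidate passes the stability/expression filters; "
            f"best near-misses: {near[['cv', 'group_p']].to_dict('index')}"
        )
    best = report.loc[eligible, "cv"].idxmin()
    report.loc[best, "selected"] = True
    return report.sort_values(["selected", "cv"], ascending=[False, True])


def fit_efficiency(standards: pd.DataFrame, assay: str | None = None) -> EfficiencyFit:
    """OLS standard curve Ct ~ log10(dilution) and amplification efficiency.

    E% = (10^(-1/slope) - 1) * 100.  Requires >= 3 distinct dilutions; the
    ``passes`` flag demands r^2 > 0.99.
    """
    df = standards.dropna(subset=["dilution"])
    if assay is not None:
        df = df[df["assay"] == assay]
    else:
        assays = df["assay"].unique()
        if len(assays) != 1:
            raise ValueError("multiple assays present; pass assay explicitly")
        assay = assays[0]
    if df["dilution"].nunique() < 3:
        raise ValueError("need >= 3 distinct dilutions for a standard curve")
    x = np.log10(df["dilution"].to_numpy(dtype=float))
    y = df["ct"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return EfficiencyFit(
        assay=assay,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_percent=float(eff),
    )


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str = "control",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Replicate Cts are averaged per (sample, assay); dCt = Ct_target -
    Ct_reference; ddCt = dCt - mean(dCt over control-group samples); fold =
    2^-ddCt.  The geometric mean of control-group folds is 1 by construction.
    """
    df = table[table["dilution"].isna()] if "dilution" in table.columns else table
    mean_ct = (
        df[df["assay"].isin([target, reference])]
        .groupby(["sample", "group", "assay"], sort=False)["ct"]
        .mean()
        .unstack("assay")
    )
    for assay in (target, reference):
        if assay not in mean_ct.columns:
            raise ValueError(f"assay {assay!r} absent from the table")
        missing = mean_ct.index[mean_ct[assay].isna()].tolist()
        if missing:
            raise ValueError(f"samples missing assay {assay!r}: {missing}")
    mean_ct = mean_ct.reset_index().set_index("sample")
    dct = mean_ct[target] - mean_ct[reference]
    ctrl = dct[mean_ct["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    dd = dct - ctrl.mean()
    return pd.DataFrame(
        {
            "group": mean_ct["group"],
            "dct": dct,
            "ddct": dd,
            "fold": np.exp2(-dd),
        }
    )


def group_test(
    values: pd.Series, groups: pd.Series, case: str = "case", control: str = "control"
) -> dict:
    """Welch's t-test between groups with a Shapiro-Wilk normality screen.

    Normality is reported, not enforced: ``normality_flag`` is set when either
    group's Shapiro-Wilk p falls below 0.05 (needs >= 3 values per group).
    """
    x = values[groups == case].to_numpy(dtype=float)
    y = values[groups == control].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.array_equal(np.sort(x), np.sort(y)):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
    # Satterthwaite df
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        df = float(len(x) + len(y) - 2)
    else:
        num = (vx / len(x) + vy / len(y)) ** 2
        den = (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
        df = float(num / den)
    sw = {}
    for name, arr in (("case", x), ("control", y)):
        if len(arr) >= 3 and np.ptp(arr) > 0:
            sw[name] = float(stats.shapiro(arr).pvalue)
        else:
            sw[name] = np.nan
    flag = any(p_ < 0.05 for p_ in sw.values() if not math.isnan(p_))
    return {
        "t": t_stat,
        "df": df,
        "p": p,
        "shapiro_p": sw,
        "normality_flag": flag,
    }


def pair_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation of paired dCt values with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
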