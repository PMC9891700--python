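"""Association statistics and small quantification formulas.

Covers the gene-versus-score analyses (Pearson/Spearman correlation with
a t-approximation p-value), two-group comparisons (pooled or Welch t
test with group means and fold change), qPCR relative quantification
(delta-delta-Ct) and Western-blot densitometry normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AssociationResult:
    """Correlation between two per-sample quantities.

    ``r``/``r_squared`` are the Pearson product-moment statistics and
    ``spearman_rho`` the rank correlation; ``t_stat``/``df``/``p_value``
    follow the method requested (t approximation, two-sided).
    """

    x_name: str
    y_name: str
    n: int
    r: float
    r_squared: float
    spearman_rho: float
    t_stat: float
    df: int
    p_value: float
    method: str


@dataclass
class GroupComparison:
    """Two-group comparison summary (means, fold change, t, df, p)."""

    group_labels: tuple[str, str]
    means: tuple[float, float]
    n: tuple[int, int]
    fold_change: float  # mean_b / mean_a
    t_stat: float
    df: float
    p_value: float
    variant: str


@dataclass
class DdctResult:
    """Relative quantification by the delta-delta-Ct method."""

    delta_ct_treat: float
    delta_ct_ctrl: float
    ddct: float
    fold: float  # 2^(-ddct)
    ddct_sd: float  # propagated replicate SD of the ddct
    fold_ci: tuple[float, float]  # fold at ddct +/- 1 SD


def _t_pvalue(t: float, df: int) -> float:
    if not math.isfinite(t):
        return 0.0
    return float(2 * stats.t.sf(abs(t), df))


def correlate(
    x, y, method: str = "pearson", x_name: str = "x", y_name: str = "y"
) -> AssociationResult:
    """Correlate two paired per-sample vectors.

    Missing entries are dropped pairwise. Pearson r follows the standard
    product-moment formula with a two-sided p-value from
    ``t = r * sqrt((n-2)/(1-r^2))`` against a t distribution on n-2 df;
    Spearman uses average ranks. ``method`` selects which statistic drives
    the reported t/p; both correlations are always computed.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance in x or y")

    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    rho = float(stats.spearmanr(x, y).statistic)
    df = n - 2
    stat = r if method == "pearson" else rho
    if abs(stat) >= 1.0:
        t = math.copysign(math.inf, stat)
    else:
        t = stat * math.sqrt(df / (1.0 - stat * stat))
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        n=n,
        r=r,
        r_squared=r * r,
        spearman_rho=rho,
        t_stat=t,
        df=df,
        p_value=_t_pvalue(t, df),
        method=method,
    )


def group_ttest(values, labels, variant: str = "welch") -> GroupComparison:
    """Two-group, two-sided t test with group means and fold of means.

    ``labels`` must take exactly two values; groups are ordered by first
    appearance so the fold change is mean(second)/mean(first). Welch is
    the default (unequal variances); ``variant='pooled'`` gives the
    classic Student test.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"labels must define exactly two groups, found {uniq}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if mean_a == mean_b:
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            t = math.copysign(math.inf, mean_b - mean_a)
            df, p = float(len(a) + len(b) - 2), 0.0
    else:
        res = stats.ttest_ind(b, a, equal_var=(variant == "pooled"))
        t = float(res.statistic)
        df = float(res.df)
        p = float(res.pvalue)
    fold = mean_b / mean_a if mean_a != 0 else math.nan
    return GroupComparison(
        group_labels=(str(uniq[0]), str(uniq[1])),
        means=(mean_a, mean_b),
        n=(len(a), len(b)),
        fold_change=fold,
        t_stat=t,
        df=df,
        p_value=p,
        variant=variant,
    )


def fold_change_ddct(
    ct_target_treat, ct_hk_treat, ct_target_ctrl, ct_hk_ctrl
) -> DdctResult:
    """Relative expression by delta-delta-Ct.

    delta Ct = mean(Ct_target) - mean(Ct_housekeeper) per condition;
    delta-delta Ct = dCt_treatment - dCt_control; fold = 2^(-ddCt).
    Replicate SDs are propagated (variance of a mean = s^2/n, summed over
    the four replicate groups) and reported as an SD of the ddCt plus the
    fold at ddCt +/- 1 SD.
    """
    arrays = []
    for name, v in (
        ("ct_target_treat", ct_target_treat),
        ("ct_hk_treat", ct_hk_treat),
        ("ct_target_ctrl", ct_target_ctrl),
        ("ct_hk_ctrl", ct_hk_ctrl),
    ):
        v = np.asarray(v, dtype=float).ravel()
        if v.size == 0:
            raise ValueError(f"{name} is empty")
        if not np.isfinite(v).all():
            raise ValueError(f"{name} contains non-finite Ct values")
        arrays.append(v)
    tt, ht, tc, hc = arrays
    d_treat = float(tt.mean() - ht.mean())
    d_ctrl = float(tc.mean() - hc.mean())
    ddct = d_treat - d_ctrl
    var = sum(float(v.var(ddof=1)) / len(v) if len(v) > 1 else 0.0 for v in arrays)
    sd = math.sqrt(var)
    fold = 2.0 ** (-ddct)
    return DdctResult(
        delta_ct_treat=d_treat,
        delta_ct_ctrl=d_ctrl,
        ddct=ddct,
        fold=fold,
        ddct_sd=sd,
        fold_ci=(2.0 ** (-(ddct + sd)), 2.0 ** (-(ddct - sd))),
    )


def densitometry_normalize(
    band: float, hk: float, ctrl_band: float, ctrl_hk: float
) -> float:
    """Housekeeper-and-control normalized band densitometry fold.

    fold = (band/housekeeper) / (control band/control housekeeper); the
    control lane maps to exactly 1.0. All inputs must be positive
    intensities.
    """
    for name, v in (
        ("band", band),
        ("hk", hk),
        ("ctrl_band", ctrl_band),
        ("ctrl_hk", ctrl_hk),
    ):
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be a positive finite intensity, got {v!r}")
    return (band / hk) / (ctrl_band / ctrl_hk)
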