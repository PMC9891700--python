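"""Post-acquisition processing of targeted MRM lipidomics peak-area tables.

The processing chain, in the order the pipeline fixes:

1. drift correction — per feature, a LOWESS (or smoothing-spline) fit of
   pooled-QC peak area against injection index; every row's area is
   divided by the fitted curve relative to the QC median;
2. reproducibility filtering — features whose pooled-QC coefficient of
   variation exceeds 30% (strict) are removed;
3. dilution-series linearity — Pearson r of peak area against dilution
   fraction with a pass threshold standing in for visual inspection;
4. protein normalization — biological-sample areas divided by the
   sample's total protein (area per microgram); QCs are exempt;
5. lipid-class aggregation and two-group differential abundance with
   Benjamini-Hochberg q-values.

All stages are multiplicative per row, so they commute to floating-point
precision; drift correction applies a single factor per injection index
per feature and therefore never reorders samples within an injection.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from siglipid.io_formats import LipidFeatureTable, ValidationError

#: Lipid class vocabulary for shorthand-name parsing.
LIPID_CLASSES = (
    "PI", "PC", "PE", "PS", "PG", "PA",
    "LPI", "LPC", "LPE", "LPS", "LPG", "LPA",
    "TG", "DG", "MG", "CE", "FFA",
    "SM", "CER", "HEXCER", "LACCER", "DHCER",
    "PIP", "PIP2",
)

_NAME_RE = re.compile(
    r"^\s*([A-Za-z][A-Za-z0-9]*)\s*[\s(]\s*(\d+):(\d+)\s*\)?\s*$"
)
_CHAIN_RE = re.compile(
    r"^\s*([A-Za-z][A-Za-z0-9]*)\s*\(\s*(\d+:\d+(?:\s*[/_]\s*\d+:\d+)+)\s*\)\s*$"
)


class LipidNameError(ValueError):
    """Unparseable lipid shorthand name."""


@dataclass(frozen=True)
class LipidName:
    """Parsed lipid shorthand: class plus acyl-chain composition."""

    raw: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[tuple[int, int], ...] | None = None


def parse_lipid_name(raw: str) -> LipidName:
    """Parse shorthand like ``PI 38:4``, ``PI(38:4)`` or ``PI(18:0/20:4)``.

    Species-level chain notation is summed to the total composition. The
    class token must belong to the declared vocabulary.
    """
    m = _CHAIN_RE.match(raw)
    if m:
        cls = m.group(1).upper()
        if cls not in LIPID_CLASSES:
            raise LipidNameError(f"unknown lipid class token {m.group(1)!r} in {raw!r}")
        chains = tuple(
            (int(c.split(":")[0]), int(c.split(":")[1]))
            for c in re.split(r"[/_]", m.group(2).replace(" ", ""))
        )
        tc = sum(c for c, _ in chains)
        db = sum(d for _, d in chains)
        if tc <= 0:
            raise LipidNameError(f"non-positive carbon count in {raw!r}")
        return LipidName(raw, cls, tc, db, chains)
    m = _NAME_RE.match(raw)
    if m:
        cls = m.group(1).upper()
        if cls not in LIPID_CLASSES:
            raise LipidNameError(f"unknown lipid class token {m.group(1)!r} in {raw!r}")
        tc, db = int(m.group(2)), int(m.group(3))
        if tc <= 0:
            raise LipidNameError(f"non-positive carbon count in {raw!r}")
        return LipidName(raw, cls, tc, db)
    raise LipidNameError(f"malformed lipid name {raw!r}")


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------


@dataclass
class QCCorrectionModel:
    """Per-feature injection-order drift model fitted to pooled QCs.

    ``factor(i)`` returns the multiplicative correction divisor at
    injection index ``i``: fitted(i) / median(QC areas), held constant
    beyond the first/last QC and floored at ``eps``.
    """

    feature_id: str
    qc_injection_indices: np.ndarray
    qc_areas: np.ndarray
    smoother: str
    span: float
    fitted: np.ndarray  # fitted QC areas at qc_injection_indices
    eps: float = 1e-6
    flags: list[str] = field(default_factory=list)

    def factor(self, injection_index) -> np.ndarray:
        idx = np.asarray(injection_index, dtype=float)
        med = float(np.median(self.qc_areas))
        fitted_at = np.interp(idx, self.qc_injection_indices, self.fitted)
        return np.maximum(fitted_at / med, self.eps)


def fit_drift(
    table: LipidFeatureTable,
    feature: str,
    smoother: str = "lowess",
    span: float = 0.5,
    min_qc: int = 4,
    eps: float = 1e-6,
) -> QCCorrectionModel | None:
    """Fit a drift model for one feature from its pooled-QC injections.

    Returns ``None`` (and flags the feature ``uncorrectable``) when fewer
    than ``min_qc`` QC injections exist; raises on all-zero QC areas.
    """
    if smoother not in ("lowess", "spline"):
        raise ValueError(f"unknown smoother {smoother!r}")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    df = table.data
    qc = df[(df["feature_id"] == feature) & (df["sample_type"] == "qc")]
    qc = qc.sort_values("injection_index")
    if len(qc) < min_qc:
        table.flags.setdefault(str(feature), []).append("uncorrectable")
        return None
    x = qc["injection_index"].to_numpy(dtype=float)
    y = qc["peak_area"].to_numpy(dtype=float)
    if (y == 0).all():
        raise ValidationError(f"feature {feature!r}: all QC areas are zero")
    if smoother == "lowess":
        # enforce >= 4 QC points per local regression window so the fit
        # smooths rather than interpolates sparse QC series
        frac_eff = max(span, min(1.0, 4.0 / len(y)))
        fitted = lowess(y, x, frac=frac_eff, return_sorted=False)
    else:
        # cubic smoothing spline; smoothing proportional to QC variance
        s = len(y) * float(np.var(y)) * (1 - span)
        spl = UnivariateSpline(x, y, k=min(3, len(y) - 1), s=s)
        fitted = spl(x)
    fitted = np.maximum(np.asarray(fitted, dtype=float), eps)
    return QCCorrectionModel(
        feature_id=str(feature),
        qc_injection_indices=x,
        qc_areas=y,
        smoother=smoother,
        span=span,
        fitted=fitted,
        eps=eps,
    )


def fit_drift_models(
    table: LipidFeatureTable,
    smoother: str = "lowess",
    span: float = 0.5,
    min_qc: int = 4,
    eps: float = 1e-6,
) -> dict[str, QCCorrectionModel]:
    """Fit drift models for every feature; uncorrectable ones are flagged."""
    models: dict[str, QCCorrectionModel] = {}
    for fid in table.feature_ids:
        m = fit_drift(table, fid, smoother=smoother, span=span, min_qc=min_qc, eps=eps)
        if m is not None:
            models[str(fid)] = m
    return models


def apply_drift_correction(
    table: LipidFeatureTable, models: dict[str, QCCorrectionModel]
) -> LipidFeatureTable:
    """Divide every row's peak area by its feature's drift factor.

    QC, dilution-QC and sample rows are all corrected; the original areas
    are kept in a ``peak_area_raw`` audit column. Flagged-uncorrectable
    features pass through unchanged; a correctable feature with no model
    is an error.
    """
    out = table.copy()
    df = out.data
    if "peak_area_raw" not in df.columns:
        df["peak_area_raw"] = df["peak_area"]
    for fid in out.feature_ids:
        key = str(fid)
        if key not in models:
            if "uncorrectable" in out.flags.get(key, []):
                continue
            raise ValueError(f"no drift model for correctable feature {key!r}")
        sel = df["feature_id"] == fid
        factors = models[key].factor(df.loc[sel, "injection_index"].to_numpy())
        df.loc[sel, "peak_area"] = df.loc[sel, "peak_area"].to_numpy() / factors
    out.data = df
    return out


# ---------------------------------------------------------------------------
# QC filtering and linearity
# ---------------------------------------------------------------------------


def qc_cv_percent(table: LipidFeatureTable) -> pd.Series:
    """Per-feature pooled-QC coefficient of variation in percent.

    CV = sample (n-1) SD / mean of raw-scale QC peak areas x 100.
    Features with fewer than 2 QC rows get NaN.
    """
    df = table.data
    qc = df[df["sample_type"] == "qc"]
    out = {}
    for fid in table.feature_ids:
        areas = qc.loc[qc["feature_id"] == fid, "peak_area"].to_numpy(dtype=float)
        if len(areas) < 2 or areas.mean() == 0:
            out[str(fid)] = np.nan
        else:
            out[str(fid)] = float(areas.std(ddof=1) / areas.mean() * 100.0)
    return pd.Series(out, name="qc_cv_percent")


def cv_filter(
    table: LipidFeatureTable, threshold_percent: float = 30.0
) -> tuple[LipidFeatureTable, pd.DataFrame]:
    """Remove features whose pooled-QC CV strictly exceeds the threshold.

    Returns the retained table and a removal report (feature, CV). A
    feature with fewer than 2 QCs cannot be assessed: it is retained and
    flagged ``cv_unassessable``.
    """
    cvs = qc_cv_percent(table)
    removed = cvs[cvs > threshold_percent]
    out = table.copy()
    for fid in cvs[cvs.isna()].index:
        out.flags.setdefault(str(fid), []).append("cv_unassessable")
    out.data = out.data[~out.data["feature_id"].astype(str).isin(removed.index)].reset_index(
        drop=True
    )
    report = removed.rename_axis("feature_id").reset_index()
    return out, report


@dataclass
class LinearityResult:
    """Dilution-series linearity verdict for one feature."""

    feature_id: str
    verdict: str  # "pass" | "fail" | "insufficient"
    r: float
    slope: float
    n_points: int


def dilution_linearity(
    table: LipidFeatureTable, feature: str, min_r: float = 0.9
) -> LinearityResult:
    """Check linear response over the dilution-QC series.

    Pearson r of peak area against dilution fraction; the feature passes
    when r >= ``min_r`` and the slope is positive. Fewer than 4 points
    yields an ``insufficient`` verdict. This threshold replaces the
    platform's manual visual inspection with an explicit rule.
    """
    df = table.data
    rows = df[(df["feature_id"] == feature) & (df["sample_type"] == "dilution_qc")]
    n = len(rows)
    if n < 4:
        return LinearityResult(str(feature), "insufficient", math.nan, math.nan, n)
    x = rows["dilution_fraction"].to_numpy(dtype=float)
    y = rows["peak_area"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return LinearityResult(str(feature), "fail", math.nan, 0.0, n)
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    verdict = "pass" if (r >= min_r and slope > 0) else "fail"
    return LinearityResult(str(feature), verdict, r, slope, n)


def linearity_report(table: LipidFeatureTable, min_r: float = 0.9) -> pd.DataFrame:
    rows = [dilution_linearity(table, fid, min_r=min_r) for fid in table.feature_ids]
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# Normalization and aggregation
# ---------------------------------------------------------------------------


def protein_normalize(table: LipidFeatureTable) -> LipidFeatureTable:
    """Divide biological-sample peak areas by per-sample total protein (ug).

    Pooled-QC and dilution-QC rows are exempt. A sample row lacking a
    protein amount is an error; units become area per microgram.
    """
    out = table.copy()
    df = out.data
    is_sample = df["sample_type"] == "sample"
    protein = df.loc[is_sample, "protein_ug"]
    if protein.isna().any() or (protein <= 0).any():
        bad = sorted(df.loc[is_sample & (protein.isna() | (protein <= 0)), "sample_id"].unique())
        raise ValidationError(f"missing/nonpositive protein_ug for samples: {bad[:5]}")
    df.loc[is_sample, "peak_area"] = (
        df.loc[is_sample, "peak_area"] / df.loc[is_sample, "protein_ug"]
    )
    out.data = df
    return out


def aggregate_by_class(table: LipidFeatureTable) -> pd.DataFrame:
    """Sum species areas into per-(class, sample) totals.

    Lipid names are parsed with :func:`parse_lipid_name`; the result has
    columns lipid_class, sample_id, group, total_area, n_species.
    """
    df = table.data[table.data["sample_type"] == "sample"].copy()
    df["lipid_class"] = [parse_lipid_name(n).lipid_class for n in df["lipid_name"]]
    agg = (
        df.groupby(["lipid_class", "sample_id", "group"], sort=True)
        .agg(total_area=("peak_area", "sum"), n_species=("feature_id", "nunique"))
        .reset_index()
    )
    return agg


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------


@dataclass
class LipidDifferential:
    """Two-group differential abundance for one species or class."""

    key: str
    level: str  # "species" | "class"
    groups: tuple[str, str]
    means: tuple[float, float]
    mean_fold: float  # mean_b / mean_a
    percent_change: float  # (mean_fold - 1) * 100
    t_stat: float
    p_value: float
    q_value: float
    n: tuple[int, int]
    n_species: int
    flags: str = ""


def differential_abundance(
    table: LipidFeatureTable,
    group_a: str,
    group_b: str,
    level: str = "species",
    variant: str = "welch",
) -> list[LipidDifferential]:
    """Per-species or per-class two-group differential abundance.

    Per key: fold of means (group_b over group_a), percent change,
    two-sided t test and BH q-values across keys. At class level the test
    runs on per-sample class totals. A key missing replicates in either
    group is skipped with a flag. Requires >= 2 replicates per group.
    """
    if level not in ("species", "class"):
        raise ValueError(f"unknown level {level!r}")
    if level == "species":
        df = table.data[table.data["sample_type"] == "sample"]
        keys = [(str(fid), grp) for fid, grp in df.groupby("feature_id", sort=False)]
        value_col = "peak_area"
        n_species = {k: 1 for k, _ in keys}
    else:
        agg = aggregate_by_class(table)
        keys = [(str(cls), grp) for cls, grp in agg.groupby("lipid_class", sort=True)]
        value_col = "total_area"
        n_species = {
            str(cls): int(grp["n_species"].max()) for cls, grp in agg.groupby("lipid_class")
        }

    results: list[LipidDifferential] = []
    pvals: list[float] = []
    for key, grp in keys:
        a = grp.loc[grp["group"] == group_a, value_col].to_numpy(dtype=float)
        b = grp.loc[grp["group"] == group_b, value_col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            results.append(
                LipidDifferential(
                    key, level, (group_a, group_b), (math.nan, math.nan),
                    math.nan, math.nan, math.nan, math.nan, math.nan,
                    (len(a), len(b)), n_species.get(key, 0), flags="insufficient_replicates",
                )
            )
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if mean_a == mean_b else (math.copysign(math.inf, mean_b - mean_a), 0.0)
        else:
            res = stats.ttest_ind(b, a, equal_var=(variant == "pooled"))
            t, p = float(res.statistic), float(res.pvalue)
        fold = mean_b / mean_a if mean_a != 0 else math.nan
        results.append(
            LipidDifferential(
                key, level, (group_a, group_b), (mean_a, mean_b),
                fold, (fold - 1.0) * 100.0 if math.isfinite(fold) else math.nan,
                t, p, math.nan, (len(a), len(b)), n_species.get(key, 0),
            )
        )
        pvals.append(p)
    tested = [r for r in results if not r.flags]
    if tested:
        qvals = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, qvals):
            r.q_value = float(q)
    return results


@dataclass
class ClassChangeSummary:
    """Species-level summary of change within one lipid class.

    ``avg_percent_change`` is the mean over member species of the
    per-species percent change of group means — the convention behind
    statements like "an average of 141% higher abundance".
    """

    lipid_class: str
    groups: tuple[str, str]
    n_species: int
    n_increased: int  # species with fold > 1
    avg_percent_change: float
    avg_fold: float


def class_change_summary(
    species_results: list[LipidDifferential],
    table: LipidFeatureTable,
) -> list[ClassChangeSummary]:
    """Summarize per-species differentials by lipid class."""
    name_by_fid = (
        table.data.drop_duplicates("feature_id").set_index("feature_id")["lipid_name"]
    )
    name_by_fid.index = name_by_fid.index.astype(str)
    by_class: dict[str, list[LipidDifferential]] = {}
    for r in species_results:
        if r.level != "species" or r.flags:
            continue
        cls = parse_lipid_name(name_by_fid[r.key]).lipid_class
        by_class.setdefault(cls, []).append(r)
    out = []
    for cls in sorted(by_class):
        rs = by_class[cls]
        folds = np.array([r.mean_fold for r in rs], dtype=float)
        out.append(
            ClassChangeSummary(
                lipid_class=cls,
                groups=rs[0].groups,
                n_species=len(rs),
                n_increased=int((folds > 1).sum()),
                avg_percent_change=float(np.mean([(f - 1) * 100 for f in folds])),
                avg_fold=float(folds.mean()),
            )
        )
    return out
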