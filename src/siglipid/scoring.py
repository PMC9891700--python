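"""Per-sample pathway-activity scores.

Two single-sample scores are provided:

* :func:`ar_signature_score` — the AR signaling score: for each sample,
  the Pearson correlation between that sample's log2 expression over a
  fixed set of AR-regulated genes and a reference vector describing the
  androgen-stimulated profile of those genes. Scores lie in [-1, 1]; high
  values mean the sample's signature-gene profile resembles the activated
  state.

* :func:`mtor_activation_score` — the mTOR activation score: for each
  sample, a two-sample t statistic contrasting that sample's log2
  expression over mTOR-activation-up genes against mTOR-activation-down
  genes, with genes as the observations. By default the absolute value of
  t is reported (the signed value is kept in the per-sample flags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from siglipid.io_formats import ExpressionMatrix, GeneSignature, PathwayGeneSets


@dataclass
class ScoreVector:
    """Per-sample score values with bookkeeping.

    ``n_genes_used`` records how many genes entered each sample's score
    after dropping missing values; ``flags`` holds per-sample notes such as
    dropped genes or degenerate-variance fallbacks.
    """

    sample_ids: list[str]
    scores: np.ndarray
    score_name: str
    n_genes_used: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.n_genes_used = np.asarray(self.n_genes_used, dtype=int)
        if not (len(self.sample_ids) == len(self.scores) == len(self.n_genes_used)):
            raise ValueError("sample_ids, scores and n_genes_used must align")
        if not self.flags:
            self.flags = [""] * len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "score": self.scores,
                "n_genes_used": self.n_genes_used,
                "flags": self.flags,
            }
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.score_name)


def _require_log2(expr: ExpressionMatrix) -> None:
    if not expr.is_log2:
        raise ValueError("expression matrix must be on log2 scale for scoring")


def ar_signature_score(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    min_genes_present: int | None = None,
) -> ScoreVector:
    """AR signaling score: per-sample Pearson r against the reference vector.

    Parameters
    ----------
    expr
        log2-scale expression matrix (genes x samples).
    sig
        Gene signature with reference vector.
    min_genes_present
        Hard floor on the number of signature genes that must be present in
        the matrix. Defaults to 80% of the signature (25 of 30 for the
        classic AR signature), never below 3.

    Missing genes are dropped pairwise and recorded in the per-sample
    flags; a sample with zero variance over the signature genes gets a NaN
    score with a ``zero_variance`` flag.
    """
    _require_log2(expr)
    if min_genes_present is None:
        min_genes_present = max(3, math.ceil(0.8 * len(sig)))
    present_mask = np.array([g in expr.data.index for g in sig.genes])
    missing = [g for g, m in zip(sig.genes, present_mask) if not m]
    n_present = int(present_mask.sum())
    if n_present < min_genes_present:
        raise ValueError(
            f"only {n_present} of {len(sig)} signature genes present "
            f"(need >= {min_genes_present}); missing: {missing}"
        )
    genes = [g for g, m in zip(sig.genes, present_mask) if m]
    ref = sig.reference[present_mask]
    sub = expr.data.loc[genes]  # signature order preserved

    scores = np.empty(sub.shape[1])
    n_used = np.empty(sub.shape[1], dtype=int)
    flags: list[str] = []
    base_flag = f"missing_genes:{','.join(missing)}" if missing else ""
    x = sub.to_numpy(dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = np.isfinite(col)
        v, r = col[ok], ref[ok]
        notes = [base_flag] if base_flag else []
        if ok.sum() < min_genes_present:
            scores[j], n_used[j] = np.nan, int(ok.sum())
            notes.append("too_few_finite_genes")
        elif np.ptp(v) == 0 or np.ptp(r) == 0:
            scores[j], n_used[j] = np.nan, int(ok.sum())
            notes.append("zero_variance")
        else:
            vc, rc = v - v.mean(), r - r.mean()
            scores[j] = float(vc @ rc / np.sqrt((vc @ vc) * (rc @ rc)))
            scores[j] = float(np.clip(scores[j], -1.0, 1.0))
            n_used[j] = int(ok.sum())
        flags.append(";".join(notes))
    return ScoreVector(expr.sample_ids, scores, f"AR_score[{sig.name}]", n_used, flags)


def mtor_activation_score(
    expr: ExpressionMatrix,
    sets: PathwayGeneSets,
    variant: str = "pooled",
    absolute: bool = True,
) -> ScoreVector:
    """mTOR activation score: per-sample up-vs-down gene-set t statistic.

    For each sample, the expression values of the up-regulated genes are
    compared to those of the down-regulated genes with a two-sample t test
    (``variant`` selects pooled/Student or Welch); genes are the
    observations. ``absolute=True`` (default) reports |t| and records the
    signed t in the flags; ``absolute=False`` reports the signed t.
    """
    _require_log2(expr)
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    up = [g for g in sets.up_genes if g in expr.data.index]
    down = [g for g in sets.down_genes if g in expr.data.index]
    if len(up) < 2 or len(down) < 2:
        raise ValueError(
            f"need >= 2 up and down genes present; found {len(up)} up, {len(down)} down"
        )
    up_x = expr.data.loc[up].to_numpy(dtype=float)
    dn_x = expr.data.loc[down].to_numpy(dtype=float)

    scores = np.empty(up_x.shape[1])
    flags: list[str] = []
    n_used = np.full(up_x.shape[1], len(up) + len(down), dtype=int)
    for j in range(up_x.shape[1]):
        a = up_x[:, j][np.isfinite(up_x[:, j])]
        b = dn_x[:, j][np.isfinite(dn_x[:, j])]
        notes: list[str] = []
        if len(a) < 2 or len(b) < 2:
            scores[j] = np.nan
            n_used[j] = len(a) + len(b)
            flags.append("too_few_finite_genes")
            continue
        var_a, var_b = a.var(ddof=1), b.var(ddof=1)
        use_variant = variant
        if var_a == 0 and var_b == 0:
            if a.mean() == b.mean():
                t = 0.0
                notes.append("degenerate_variance")
            else:
                t = math.copysign(math.inf, a.mean() - b.mean())
                notes.append("degenerate_variance")
        else:
            if variant == "pooled" and (var_a == 0 or var_b == 0):
                use_variant = "welch"
                notes.append("one_group_constant:welch_fallback")
            res = stats.ttest_ind(a, b, equal_var=(use_variant == "pooled"))
            t = float(res.statistic)
        n_used[j] = len(a) + len(b)
        if absolute:
            scores[j] = abs(t)
            notes.append(f"signed_t:{t:.6g}")
        else:
            scores[j] = t
        flags.append(";".join(notes))
    name = f"mTOR_score[{sets.name}]" + ("" if absolute else ":signed")
    return ScoreVector(expr.sample_ids, scores, name, n_used, flags)
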