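"""Readers, writers and validated domain containers for external formats.

Supported inputs:

* expression matrices — plain TSV (genes in rows, header row of sample
  labels) or GCT 1.2; values are FPKM, log2-transformed on read unless
  already logged;
* gene signatures — two-column TSV of gene id and reference value;
* gene sets — standard GMT;
* targeted-lipidomics long tables and qPCR Ct tables — CSV.

All readers validate their invariants eagerly so downstream modules never
see malformed data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (structure, types or header problems)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


#: Dilution-QC series used by the targeted platform (fractions of pooled QC).
DILUTION_SERIES = (1.0, 0.5, 0.25, 0.125, 0.0625)

SAMPLE_TYPES = ("sample", "qc", "dilution_qc")

LIPID_TABLE_COLUMNS = (
    "feature_id",
    "lipid_name",
    "injection_index",
    "sample_id",
    "sample_type",
    "dilution_fraction",
    "peak_area",
    "protein_ug",
    "group",
)

CT_TABLE_COLUMNS = ("gene", "sample", "condition", "ct")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample grid of log2(FPKM + pseudocount) values.

    ``data`` is a DataFrame indexed by uppercase gene identifiers with
    sample labels as columns; ``is_log2`` records whether the values are on
    log2 scale (scoring requires it).
    """

    data: pd.DataFrame
    is_log2: bool = True

    def __post_init__(self) -> None:
        idx = pd.Index(self.data.index)
        cols = pd.Index(self.data.columns)
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ValidationError("expression values must be finite (or NaN for missing)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneSignature:
    """Ordered gene list with a paired numeric reference vector.

    The reference vector is the expression profile of the signature genes
    in a fully activated (androgen-stimulated) state; per-sample scores
    correlate observed expression against it.
    """

    name: str
    genes: list[str]
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [g.strip().upper() for g in self.genes]
        self.reference = np.asarray(self.reference, dtype=float)
        if len(self.genes) != len(self.reference):
            raise ValidationError("signature genes and reference vector differ in length")
        if len(self.genes) < 3:
            raise ValidationError("signature needs at least 3 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("signature gene ids must be unique")
        if not np.isfinite(self.reference).all():
            raise ValidationError("reference vector must be finite")
        if np.ptp(self.reference) == 0:
            raise ValidationError(
                "reference vector is constant; correlation score undefined"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwayGeneSets:
    """Named pair of up-regulated and down-regulated gene sets."""

    name: str
    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        self.up_genes = [g.strip().upper() for g in self.up_genes]
        self.down_genes = [g.strip().upper() for g in self.down_genes]
        if len(self.up_genes) < 2 or len(self.down_genes) < 2:
            raise ValidationError("up and down sets each need at least 2 genes")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(f"up/down sets overlap: {sorted(overlap)[:5]}")


@dataclass
class LipidFeatureTable:
    """Long-format targeted-lipidomics measurements with QC annotations.

    One row per feature x injection. ``flags`` accumulates per-feature
    notes raised during validation or processing (e.g. ``insufficient_qc``
    for features with fewer than 3 pooled-QC injections).
    """

    data: pd.DataFrame
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = validate_lipid_frame(self.data)
        for fid, grp in self.data.groupby("feature_id", sort=False):
            n_qc = int((grp["sample_type"] == "qc").sum())
            if n_qc < 3:
                self.flags.setdefault(str(fid), []).append("insufficient_qc")

    @property
    def feature_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["feature_id"]))

    def copy(self) -> "LipidFeatureTable":
        out = object.__new__(LipidFeatureTable)
        out.data = self.data.copy()
        out.flags = {k: list(v) for k, v in self.flags.items()}
        return out


def validate_lipid_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Type-check and normalize a long lipidomics frame in place."""
    missing = [c for c in LIPID_TABLE_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise FormatError(f"lipid table missing mandatory columns: {missing}")
    df = df.copy()
    if "group" not in df.columns:
        df["group"] = ""
    df["sample_type"] = df["sample_type"].astype(str).str.strip().str.lower()
    bad_types = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
    if bad_types:
        raise ValidationError(f"unknown sample_type values: {bad_types}")
    for col in ("injection_index", "dilution_fraction", "peak_area", "protein_ug"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["peak_area"].dropna() < 0).any():
        raise ValidationError("peak_area must be nonnegative")
    dil = df.loc[df["sample_type"] == "dilution_qc", "dilution_fraction"]
    if ((dil <= 0) | (dil > 1)).any():
        raise ValidationError("dilution_fraction must lie in (0, 1] for dilution_qc rows")
    if (df["injection_index"] <= 0).any():
        raise ValidationError("injection_index must be a positive integer")
    dup = df.duplicated(subset=["feature_id", "injection_index"])
    if dup.any():
        raise ValidationError(
            "duplicate (feature_id, injection_index) rows: "
            f"{df.loc[dup, ['feature_id', 'injection_index']].head().to_dict('records')}"
        )
    return df


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------


def _parse_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError("GCT dimension line must have two fields")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    # first remaining column is the Description column
    if body.shape[1] != n_samples + 1:
        raise FormatError(
            f"GCT declares {n_samples} samples but found {body.shape[1] - 1}"
        )
    if body.shape[0] != n_genes:
        raise FormatError(f"GCT declares {n_genes} genes but found {body.shape[0]}")
    return body.iloc[:, 1:]


def read_expression_matrix(
    path: str | Path,
    pseudocount: float = 1.0,
    already_log2: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression table (TSV or GCT 1.2).

    Unless ``already_log2``, values are transformed to
    ``log2(x + pseudocount)``. Gene identifiers are upper-cased; duplicate
    gene rows are collapsed by mean with a logged warning; duplicate sample
    labels are an error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#1.2"):
            fh.readline()
            header = fh.readline().rstrip("\n").split("\t")[2:]
        else:
            header = first.rstrip("\n").split("\t")[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise FormatError(f"duplicate sample ids: {dupes}")
    if first.startswith("#1.2"):
        df = _parse_gct(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    # fail with row/column coordinates on non-numeric cells
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"non-numeric value in column {col!r}, row {row!r}") from None
    df.index = df.index.astype(str).str.strip().str.upper()
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing %d duplicate gene rows by mean: %s", len(dupes), dupes[:10])
        df = df.groupby(level=0, sort=False).mean()
    if not already_log2:
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        vals = df.to_numpy(dtype=float)
        if (vals + pseudocount <= 0).any():
            raise ValidationError("log2 transform undefined: x + pseudocount <= 0")
        df = pd.DataFrame(np.log2(vals + pseudocount), index=df.index, columns=df.columns)
    return ExpressionMatrix(df, is_log2=True)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name -> gene-list mapping."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = [g.strip().upper() for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise FormatError("GMT file contains no gene sets")
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def pathway_sets_from_gmt(
    sets: dict[str, list[str]], up: str, down: str, name: str | None = None
) -> PathwayGeneSets:
    """Assemble up/down pathway sets from two named GMT entries."""
    for key in (up, down):
        if key not in sets:
            raise KeyError(f"gene set {key!r} not found in GMT (have {sorted(sets)})")
    return PathwayGeneSets(name or f"{up}/{down}", sets[up], sets[down])


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a two-column (gene, reference value) TSV into a GeneSignature."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 2:
        raise FormatError(f"signature file must have 2 columns, found {df.shape[1]}")
    genes = df.iloc[:, 0].astype(str).tolist()
    try:
        ref = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        raise FormatError("signature reference column contains non-numeric values") from None
    return GeneSignature(name or path.stem, genes, ref)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g, r in zip(sig.genes, sig.reference):
            fh.write(f"{g}\t{r:g}\n")


# ---------------------------------------------------------------------------
# Lipidomics & Ct tables
# ---------------------------------------------------------------------------


def read_lipid_table(path: str | Path) -> LipidFeatureTable:
    """Read a long-format targeted-lipidomics CSV.

    Mandatory columns: feature_id, lipid_name, injection_index, sample_id,
    sample_type, dilution_fraction, peak_area, protein_ug. Extra columns
    are ignored with a warning.
    """
    df = pd.read_csv(path)
    extra = [c for c in df.columns if c not in LIPID_TABLE_COLUMNS]
    if extra:
        logger.warning("ignoring extra lipid-table columns: %s", extra)
        df = df.drop(columns=extra)
    return LipidFeatureTable(df)


def write_lipid_table(table: LipidFeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, lineterminator="\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct CSV (gene, sample, condition, ct) with validation."""
    df = pd.read_csv(path)
    missing = [c for c in CT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Ct table missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in CT_TABLE_COLUMNS]
    if extra:
        logger.warning("ignoring extra Ct-table columns: %s", extra)
        df = df.drop(columns=extra)
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if not np.isfinite(df["ct"]).all():
        raise ValidationError("Ct values must be finite")
    if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
        logger.warning("Ct values outside the typical (0, 45) cycle range present")
    counts = df.groupby(["gene", "sample"]).size()
    if (counts < 1).any():  # pragma: no cover - groupby cannot produce 0
        raise ValidationError("each (gene, sample) needs at least one replicate")
    return df
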