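"""Config-driven end-to-end runs with reproducibility manifests.

Two pipelines compose the library modules:

* transcriptomic — read expression + signature + gene sets, emit AR and
  mTOR score vectors, correlate focal genes against both scores
  (Pearson and Spearman are both reported), optionally compare scores or
  focal-gene expression between two sample groups;
* lipidomics — drift-correct, CV-filter, linearity-check, protein-
  normalize, aggregate and test a targeted run.

Every run writes a JSON manifest recording the tool version, SHA-256
digests of all inputs, the full parameter set and per-stage record
counts, so a run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

import siglipid
from siglipid import lipidomics
from siglipid.association import correlate, group_ttest
from siglipid.io_formats import (
    read_expression_matrix,
    read_gmt,
    read_lipid_table,
    read_signature,
    pathway_sets_from_gmt,
    write_lipid_table,
)
from siglipid.scoring import ar_signature_score, mtor_activation_score

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, inputs: dict, params: dict, counts: dict) -> Path:
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "tool": "siglipid",
        "tool_version": siglipid.__version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: _sha256(v) for k, v in inputs.items()},
        "parameters": params,
        "stage_counts": counts,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def run_transcriptomic_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Score samples and associate focal genes with the scores.

    Config keys: ``expression`` (path), ``signature`` (path), ``gmt``
    (path), ``up_set``/``down_set`` (GMT entry names), ``focal_genes``
    (list), optional ``groups`` (2-column TSV sample_id/group),
    ``pseudocount``, ``already_log2``, ``min_genes_present``,
    ``mtor_variant``, ``mtor_absolute``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr = read_expression_matrix(
        config["expression"],
        pseudocount=float(config.get("pseudocount", 1.0)),
        already_log2=bool(config.get("already_log2", False)),
    )
    sig = read_signature(config["signature"])
    sets = pathway_sets_from_gmt(
        read_gmt(config["gmt"]), config.get("up_set", "MTOR_UP"),
        config.get("down_set", "MTOR_DOWN"),
    )
    counts = {"samples": expr.shape[1], "genes": expr.shape[0]}

    ar = ar_signature_score(expr, sig, min_genes_present=config.get("min_genes_present"))
    mtor = mtor_activation_score(
        expr,
        sets,
        variant=config.get("mtor_variant", "pooled"),
        absolute=bool(config.get("mtor_absolute", True)),
    )
    ar.to_frame().to_csv(out_dir / "ar_scores.tsv", sep="\t", index=False)
    mtor.to_frame().to_csv(out_dir / "mtor_scores.tsv", sep="\t", index=False)

    focal = [g.upper() for g in config.get("focal_genes", [])]
    assoc_rows = []
    for gene in focal:
        if gene not in expr.data.index:
            logger.warning("focal gene %s absent from matrix; skipped", gene)
            continue
        gx = expr.data.loc[gene].to_numpy()
        for score in (ar, mtor):
            res = correlate(score.scores, gx, method="pearson",
                            x_name=score.score_name, y_name=gene)
            assoc_rows.append(dataclasses.asdict(res))
    assoc_cols = ["x_name", "y_name", "n", "r", "r_squared", "spearman_rho",
                  "t_stat", "df", "p_value", "method"]
    assoc = pd.DataFrame(assoc_rows, columns=assoc_cols)
    assoc.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    counts["associations"] = len(assoc)

    inputs = {k: config[k] for k in ("expression", "signature", "gmt")}
    if config.get("groups"):
        grp = pd.read_csv(config["groups"], sep="\t")
        grp = grp.set_index(grp.columns[0])[grp.columns[1]]
        rows = []
        for gene in focal:
            if gene not in expr.data.index:
                continue
            vals = expr.data.loc[gene, grp.index]
            cmp = group_ttest(vals.to_numpy(), grp.to_numpy(),
                              variant=config.get("group_variant", "welch"))
            d = dataclasses.asdict(cmp)
            d["variable"] = gene
            rows.append(d)
        pd.DataFrame(rows).to_csv(out_dir / "group_comparison.tsv", sep="\t", index=False)
        counts["group_comparisons"] = len(rows)
        inputs["groups"] = config["groups"]

    _write_manifest(out_dir, inputs, _jsonable(config), counts)
    return {"ar": ar, "mtor": mtor, "associations": assoc, "out_dir": out_dir}


def run_lipidomics_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the fixed lipidomics QC chain on a long-format run CSV.

    Order: fit/apply drift correction -> CV filter -> dilution-linearity
    report -> protein normalization -> class aggregation and two-group
    differential abundance. Config keys: ``table`` (path), ``smoother``,
    ``span``, ``cv_threshold``, ``min_dilution_r``, ``group_a``,
    ``group_b``, ``t_variant``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_lipid_table(config["table"])
    counts = {"features_in": len(table.feature_ids), "rows_in": len(table.data)}

    models = lipidomics.fit_drift_models(
        table,
        smoother=config.get("smoother", "lowess"),
        span=float(config.get("span", 0.5)),
    )
    corrected = lipidomics.apply_drift_correction(table, models)
    counts["features_corrected"] = len(models)

    filtered, removal = lipidomics.cv_filter(
        corrected, threshold_percent=float(config.get("cv_threshold", 30.0))
    )
    counts["features_removed_cv"] = len(removal)
    counts["features_after_cv"] = len(filtered.feature_ids)

    linearity = lipidomics.linearity_report(
        filtered, min_r=float(config.get("min_dilution_r", 0.9))
    )
    normalized = lipidomics.protein_normalize(filtered)

    write_lipid_table(normalized, out_dir / "corrected_table.csv")
    removal.to_csv(out_dir / "cv_removal_report.csv", index=False)
    linearity.to_csv(out_dir / "linearity_report.csv", index=False)

    group_a, group_b = config.get("group_a"), config.get("group_b")
    results = {"table": normalized, "removal": removal, "linearity": linearity}
    if group_a and group_b:
        variant = config.get("t_variant", "welch")
        species = lipidomics.differential_abundance(
            normalized, group_a, group_b, level="species", variant=variant
        )
        classes = lipidomics.differential_abundance(
            normalized, group_a, group_b, level="class", variant=variant
        )
        summary = lipidomics.class_change_summary(species, normalized)
        _diff_frame(species).to_csv(out_dir / "species_differential.csv", index=False)
        _diff_frame(classes).to_csv(out_dir / "class_differential.csv", index=False)
        pd.DataFrame([dataclasses.asdict(s) for s in summary]).to_csv(
            out_dir / "class_summary.csv", index=False
        )
        counts["species_tested"] = sum(1 for r in species if not r.flags)
        results.update(species=species, classes=classes, summary=summary)

    _write_manifest(out_dir, {"table": config["table"]}, _jsonable(config), counts)
    results["out_dir"] = out_dir
    return results


def _diff_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        d["group_a"], d["group_b"] = d.pop("groups")
        d["mean_a"], d["mean_b"] = d.pop("means")
        d["n_a"], d["n_b"] = d.pop("n")
        rows.append(d)
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
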