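"""Seeded synthetic-data generators with ground truth.

Two generators provide the statistical structure the analysis chains
assume, so that every stage can be checked against known truth:

* :func:`gen_expression` — a latent-factor bulk expression simulator. A
  standard-normal latent AR activity drives the signature genes with
  loadings proportional to the reference vector (the reference vector is
  the noiseless fully-activated profile) and anti-drives a focal gene
  (PIP4K2A by default); a latent mTOR activity drives the up set and
  suppresses the down set. Background genes are pure noise. All values
  are emitted on log2 scale.

* :func:`gen_lipid_run` — an injection-ordered targeted-lipidomics run:
  pooled QCs every 5-6 injections with bracketing QCs, a 100/50/25/12.5/
  6.25% dilution-QC series at the end, smooth multiplicative intensity
  drift per feature, multiplicative lognormal noise, per-sample protein
  amounts, group effects on chosen lipid classes or species, and a
  configurable fraction of features constructed irreproducible (pooled-QC
  CV above 30% by design).

Both generators are pure functions of their parameters and seed and
return their truth object alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from siglipid.io_formats import (
    DILUTION_SERIES,
    ExpressionMatrix,
    GeneSignature,
    LipidFeatureTable,
    PathwayGeneSets,
)
from siglipid import resources

# Sample sizes mirroring the dimensions of the cohorts the scores are
# typically applied to, and of a small in-vitro lipidomics experiment.
EXPRESSION_PRESETS = {
    "tcga-like": {"n_samples": 333},
    "su2c-like": {"n_samples": 149},
}

# Seven PI species whose planted group folds average a +141% change with
# six of seven species increased; the remaining features fill other
# classes up to 273 species total.
PI_SPECIES_FOLDS = {
    "PI 34:1": 2.8,
    "PI 34:2": 2.6,
    "PI 36:1": 2.9,
    "PI 36:2": 3.1,
    "PI 36:4": 2.5,
    "PI 38:3": 2.2,
    "PI 38:4": 0.77,
}

LIPID_PRESETS = {
    "lncap-lipid-like": {
        "n_samples_per_group": 6,
        "groups": ("CA", "CA_AD"),
        "species_folds": PI_SPECIES_FOLDS,
    },
}


@dataclass
class ExpressionSimTruth:
    """Ground truth for a simulated expression matrix."""

    seed: int
    sample_ids: list[str]
    latent_ar: np.ndarray
    latent_mtor: np.ndarray
    signature_genes: list[str]
    signature_loadings: np.ndarray
    focal_gene: str
    focal_gene_coupling: float  # gamma; the focal gene loads -gamma on latent AR
    noise_sd: float

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2)


@dataclass
class LipidSimTruth:
    """Ground truth for a simulated lipidomics run."""

    seed: int
    qc_every: int
    dilution_fractions: tuple[float, ...]
    noise_cv: float
    drift_amplitude: float
    feature_names: list[str]
    sample_ids: list[str]
    sample_groups: dict[str, str]
    true_concentration: pd.DataFrame  # features x samples
    drift_curves: pd.DataFrame  # features x injection indices
    species_folds: dict[str, float]  # planted per-species group fold (b/a)
    class_folds: dict[str, float]  # planted class-total fold (b/a)
    irreproducible_features: list[str]
    protein_ug: dict[str, float]

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "qc_every": self.qc_every,
            "dilution_fractions": list(self.dilution_fractions),
            "noise_cv": self.noise_cv,
            "drift_amplitude": self.drift_amplitude,
            "species_folds": self.species_folds,
            "class_folds": self.class_folds,
            "irreproducible_features": self.irreproducible_features,
            "protein_ug": self.protein_ug,
            "sample_groups": self.sample_groups,
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gen_expression(
    n_samples: int,
    signature: GeneSignature | None = None,
    mtor_sets: PathwayGeneSets | None = None,
    gamma: float = 0.8,
    noise_sd: float = 0.5,
    n_background_genes: int = 200,
    seed: int = 0,
    focal_gene: str = "PIP4K2A",
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
    signature_strength: float = 1.0,
    mtor_strength: float = 1.0,
) -> tuple[ExpressionMatrix, ExpressionSimTruth]:
    """Simulate a log2-scale expression matrix with latent AR/mTOR factors.

    Signature gene g in sample i is ``mu_g + load_g * ar_i + noise`` with
    ``load_g`` proportional to the signature's reference entry (scaled so
    loadings have unit SD times ``signature_strength``); mTOR up genes
    load ``+mtor_strength`` and down genes ``-mtor_strength`` on the mTOR
    latent; the focal gene is ``mu - gamma * ar_i + noise``; background
    genes are baseline plus noise.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if gamma < 0 or noise_sd < 0:
        raise ValueError("gamma and noise_sd must be nonnegative")
    signature = signature or resources.example_ar_signature()
    mtor_sets = mtor_sets or resources.example_mtor_sets()
    focal_gene = focal_gene.upper()

    sig_genes = list(signature.genes)
    up = list(mtor_sets.up_genes)
    down = list(mtor_sets.down_genes)
    used = set(sig_genes) | set(up) | set(down)
    if focal_gene in used:
        raise ValueError(f"focal gene {focal_gene} collides with signature/pathway genes")
    overlap = set(sig_genes) & (set(up) | set(down))
    if overlap:
        raise ValueError(f"signature and mTOR sets overlap: {sorted(overlap)[:5]}")
    bg = [f"BG{i:04d}" for i in range(1, n_background_genes + 1)]
    genes = sig_genes + up + down + [focal_gene] + bg
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]

    rng = np.random.default_rng(seed)
    latent_ar = rng.standard_normal(n_samples)
    latent_mtor = rng.standard_normal(n_samples)
    mu = rng.normal(baseline_mean, baseline_sd, size=len(genes))

    ref = signature.reference
    sig_load = signature_strength * ref / ref.std(ddof=0)

    loadings = np.zeros(len(genes))
    loadings[: len(sig_genes)] = sig_load
    x = mu[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    x[: len(sig_genes)] += sig_load[:, None] * latent_ar[None, :]
    o = len(sig_genes)
    x[o : o + len(up)] += mtor_strength * latent_mtor[None, :]
    x[o + len(up) : o + len(up) + len(down)] -= mtor_strength * latent_mtor[None, :]
    x[o + len(up) + len(down)] -= gamma * latent_ar

    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=sample_ids), is_log2=True)
    truth = ExpressionSimTruth(
        seed=seed,
        sample_ids=sample_ids,
        latent_ar=latent_ar,
        latent_mtor=latent_mtor,
        signature_genes=sig_genes,
        signature_loadings=sig_load,
        focal_gene=focal_gene,
        focal_gene_coupling=gamma,
        noise_sd=noise_sd,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Lipidomics
# ---------------------------------------------------------------------------

_FILL_CLASSES = (
    "PC", "PE", "PS", "PG", "PA", "LPC", "LPE", "TG", "DG", "SM", "CER", "CE", "FFA",
)


def default_species(n_total: int = 273) -> list[str]:
    """Deterministic species list: 7 PI species plus fillers to ``n_total``.

    Mirrors a high-coverage targeted panel in which 273 lipid species are
    semiquantified and seven PI species are assessed.
    """
    names = list(PI_SPECIES_FOLDS)
    carbons = list(range(30, 45, 2))
    dbs = list(range(0, 7))
    i = 0
    while len(names) < n_total:
        cls = _FILL_CLASSES[i % len(_FILL_CLASSES)]
        c = carbons[(i // len(_FILL_CLASSES)) % len(carbons)]
        d = dbs[(i // (len(_FILL_CLASSES) * len(carbons))) % len(dbs)]
        if cls in ("LPC", "LPE", "FFA", "CE"):
            c = c // 2
        name = f"{cls} {c}:{d}"
        if name not in names:
            names.append(name)
        i += 1
    return names[:n_total]


def _injection_schedule(
    sample_ids: list[str], qc_every: int, dilution_fractions, rng: np.random.Generator
) -> list[tuple[str, str, float]]:
    """(sample_id, sample_type, dilution_fraction) in injection order."""
    order = list(rng.permutation(sample_ids))
    schedule: list[tuple[str, str, float]] = [("QC", "qc", 1.0)]
    for k, sid in enumerate(order, start=1):
        schedule.append((sid, "sample", 1.0))
        if k % qc_every == 0:
            schedule.append(("QC", "qc", 1.0))
    if schedule[-1][1] != "qc":  # bracketing QC at run end
        schedule.append(("QC", "qc", 1.0))
    for frac in dilution_fractions:
        schedule.append((f"DQC_{frac:g}", "dilution_qc", float(frac)))
    return schedule


def gen_lipid_run(
    n_samples_per_group: int = 6,
    groups: tuple[str, str] = ("CA", "CA_AD"),
    species: list[str] | None = None,
    class_folds: dict[str, float] | None = None,
    species_folds: dict[str, float] | None = None,
    drift_amplitude: float = 1.5,
    noise_cv: float = 0.05,
    qc_every: int = 5,
    irreproducible_fraction: float = 0.1,
    irreproducible_cv: float = 0.5,
    dilution_fractions: tuple[float, ...] = DILUTION_SERIES,
    seed: int = 0,
) -> tuple[LipidFeatureTable, LipidSimTruth]:
    """Simulate an injection-ordered targeted-lipidomics run.

    Observed area = true amount x drift(injection) x lognormal noise; the
    second group's true concentrations are multiplied by the planted fold
    for their species (``species_folds``) or class (``class_folds``).
    Pooled-QC true value is the mean of the pooled samples' amounts;
    dilution QCs scale it by their fraction. ``irreproducible_fraction``
    of features additionally alternate +/-``irreproducible_cv`` across
    injections, pinning their pooled-QC CV above the 30% filter.
    """
    if qc_every not in (5, 6):
        raise ValueError("qc_every must be 5 or 6")
    if drift_amplitude < 1:
        raise ValueError("drift_amplitude must be >= 1")
    if n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    species = list(species) if species is not None else default_species()
    class_folds = dict(class_folds or {})
    species_folds = dict(species_folds if species_folds is not None else PI_SPECIES_FOLDS)

    from siglipid.lipidomics import parse_lipid_name  # avoid import cycle at module load

    rng = np.random.default_rng(seed)
    sample_ids = [
        f"{g}_{i:02d}" for g in groups for i in range(1, n_samples_per_group + 1)
    ]
    sample_groups = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    schedule = _injection_schedule(sample_ids, qc_every, dilution_fractions, rng)
    n_inj = len(schedule)
    if sum(1 for _, t, _ in schedule if t == "qc") < 2:
        raise ValueError("schedule would contain fewer than 2 pooled QCs")

    # planted fold per species: explicit species fold wins over class fold
    folds = {}
    for name in species:
        cls = parse_lipid_name(name).lipid_class
        folds[name] = float(species_folds.get(name, class_folds.get(cls, 1.0)))

    base = rng.lognormal(mean=math.log(1e5), sigma=1.0, size=len(species))
    protein = {s: float(rng.uniform(80.0, 120.0)) for s in sample_ids}

    # per-feature smooth positive drift: ramp + one low-frequency sinusoid
    idx = np.arange(1, n_inj + 1, dtype=float)
    ramp = (idx - 1) / max(n_inj - 1, 1)
    w = rng.uniform(0.3, 0.7, size=len(species))
    phase = rng.uniform(0, 2 * math.pi, size=len(species))
    cycles = rng.uniform(1.0, 2.0, size=len(species))
    drift = np.empty((len(species), n_inj))
    for f in range(len(species)):
        wave = 0.5 + 0.5 * np.sin(2 * math.pi * cycles[f] * ramp + phase[f])
        drift[f] = 1.0 + (drift_amplitude - 1.0) * (w[f] * ramp + (1 - w[f]) * wave)

    # irreproducible features are drawn outside the assessed (fold-planted)
    # panel so planted folds stay estimable after CV filtering
    eligible = [f for f, name in enumerate(species) if name not in species_folds]
    n_bad = min(int(round(irreproducible_fraction * len(species))), len(eligible))
    bad_idx = rng.choice(eligible, size=n_bad, replace=False) if n_bad else np.array([], dtype=int)
    bad_set = set(int(i) for i in bad_idx)
    # +/- alternation within each sample type: pins pooled-QC CV near the
    # constructed level no matter how QCs interleave with samples
    alt_sign = np.empty(n_inj)
    counters: dict[str, int] = {}
    for i, (_, stype, _) in enumerate(schedule):
        k = counters.get(stype, 0)
        alt_sign[i] = 1.0 if k % 2 == 0 else -1.0
        counters[stype] = k + 1

    # true amounts: concentration x protein aliquot for samples; QC pools them
    conc = np.empty((len(species), len(sample_ids)))
    for j, s in enumerate(sample_ids):
        grp_idx = groups.index(sample_groups[s])
        for f, name in enumerate(species):
            conc[f, j] = base[f] * (folds[name] if grp_idx == 1 else 1.0)
    amount = conc * np.array([protein[s] / 100.0 for s in sample_ids])[None, :]
    qc_amount = amount.mean(axis=1)

    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    noise = np.exp(rng.normal(0.0, sigma, size=(len(species), n_inj))) if sigma else np.ones(
        (len(species), n_inj)
    )

    rows = []
    col_of = {s: j for j, s in enumerate(sample_ids)}
    for i, (sid, stype, frac) in enumerate(schedule):
        for f, name in enumerate(species):
            if stype == "sample":
                truth_val = amount[f, col_of[sid]]
                prot = protein[sid]
            elif stype == "qc":
                truth_val = qc_amount[f]
                prot = np.nan
            else:
                truth_val = qc_amount[f] * frac
                prot = np.nan
            area = truth_val * drift[f, i] * noise[f, i]
            if f in bad_set:
                area *= 1.0 + irreproducible_cv * alt_sign[i]
            rows.append(
                {
                    "feature_id": f"F{f + 1:04d}",
                    "lipid_name": name,
                    "injection_index": i + 1,
                    "sample_id": sid,
                    "sample_type": stype,
                    "dilution_fraction": frac,
                    "peak_area": area,
                    "protein_ug": prot,
                    "group": sample_groups.get(sid, ""),
                }
            )
    table = LipidFeatureTable(pd.DataFrame(rows))

    feature_ids = [f"F{f + 1:04d}" for f in range(len(species))]
    class_totals_a: dict[str, float] = {}
    class_totals_b: dict[str, float] = {}
    for f, name in enumerate(species):
        cls = parse_lipid_name(name).lipid_class
        class_totals_a[cls] = class_totals_a.get(cls, 0.0) + base[f]
        class_totals_b[cls] = class_totals_b.get(cls, 0.0) + base[f] * folds[name]
    truth = LipidSimTruth(
        seed=seed,
        qc_every=qc_every,
        dilution_fractions=tuple(dilution_fractions),
        noise_cv=noise_cv,
        drift_amplitude=drift_amplitude,
        feature_names=list(species),
        sample_ids=sample_ids,
        sample_groups=sample_groups,
        true_concentration=pd.DataFrame(conc, index=feature_ids, columns=sample_ids),
        drift_curves=pd.DataFrame(
            drift, index=feature_ids, columns=[int(i) for i in idx]
        ),
        species_folds={name: folds[name] for name in species if folds[name] != 1.0},
        class_folds={
            cls: class_totals_b[cls] / class_totals_a[cls] for cls in class_totals_a
        },
        irreproducible_features=[feature_ids[i] for i in sorted(bad_set)],
        protein_ug=protein,
    )
    return table, truth
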