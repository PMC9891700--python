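import numpy as np
import pandas as pd
import pytest

from siglipid.io_formats import (
    ExpressionMatrix,
    GeneSignature,
    LipidFeatureTable,
    PathwayGeneSets,
)


@pytest.fixture
def small_signature():
    return GeneSignature("toy", ["G1", "G2", "G3", "G4", "G5"], [1.0, 2.0, 3.0, 4.0, 5.0])


@pytest.fixture
def small_sets():
    return PathwayGeneSets("toy_mtor", ["U1", "U2", "U3"], ["D1", "D2", "D3"])


def make_expr(values: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    """Build a genes x samples matrix from {sample_id: per-gene values}."""
    df = pd.DataFrame(values, index=[g.upper() for g in genes])
    return ExpressionMatrix(df.astype(float), is_log2=True)


@pytest.fixture
def expr_factory():
    return make_expr


def make_lipid_rows(
    feature_id="F1",
    lipid_name="PI 38:4",
    qc_areas=(100.0, 100.0, 100.0, 100.0),
    qc_indices=None,
    sample_areas=(),
    sample_ids=(),
    groups=(),
    protein=(),
    dilution=(),
    start_index=1,
):
    """Build long-format rows for one feature."""
    rows = []
    idx = start_index
    qc_indices = qc_indices or list(range(idx, idx + len(qc_areas)))
    for i, a in zip(qc_indices, qc_areas):
        rows.append(
            dict(feature_id=feature_id, lipid_name=lipid_name, injection_index=i,
                 sample_id="QC", sample_type="qc", dilution_fraction=1.0,
                 peak_area=a, protein_ug=np.nan, group="")
        )
    next_idx = max(qc_indices, default=idx - 1) + 1
    for k, a in enumerate(sample_areas):
        sid = sample_ids[k] if sample_ids else f"S{k+1}"
        grp = groups[k] if groups else "A"
        prot = protein[k] if protein else 100.0
        rows.append(
            dict(feature_id=feature_id, lipid_name=lipid_name,
                 injection_index=next_idx + k, sample_id=sid, sample_type="sample",
                 dilution_fraction=1.0, peak_area=a, protein_ug=prot, group=grp)
        )
    next_idx += len(sample_areas)
    for k, (frac, a) in enumerate(dilution):
        rows.append(
            dict(feature_id=feature_id, lipid_name=lipid_name,
                 injection_index=next_idx + k, sample_id=f"DQC_{frac:g}",
                 sample_type="dilution_qc", dilution_fraction=frac,
                 peak_area=a, protein_ug=np.nan, group="")
        )
    return rows


@pytest.fixture
def lipid_rows_factory():
    return make_lipid_rows


@pytest.fixture
def lipid_table_factory():
    def build(*row_groups):
        rows = [r for g in row_groups for r in g]
        return LipidFeatureTable(pd.DataFrame(rows))

    return build
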