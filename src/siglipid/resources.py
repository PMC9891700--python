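"""Bundled synthetic example inputs.

The shipped 30-gene AR signature and the mTOR up/down gene sets are
synthetic stand-ins with the documented shape of the published objects
(30 AR-regulated genes with a reference androgen-stimulated profile;
paired up/down mTOR-activation sets). Their reference values and set
memberships are invented for testing and simulation; real analyses
should supply the published files.
"""

from __future__ import annotations

from importlib import resources

from siglipid.io_formats import (
    GeneSignature,
    PathwayGeneSets,
    pathway_sets_from_gmt,
    read_gmt,
    read_signature,
)


def _data_path(name: str):
    return resources.files("siglipid.data").joinpath(name)


def example_ar_signature() -> GeneSignature:
    """Synthetic 30-gene AR signature with reference vector."""
    with resources.as_file(_data_path("synthetic_ar_signature.tsv")) as p:
        return read_signature(p, name="synthetic_ar_30")


def example_mtor_sets() -> PathwayGeneSets:
    """Synthetic mTOR-activation up/down gene sets (20 genes each)."""
    with resources.as_file(_data_path("synthetic_mtor_sets.gmt")) as p:
        sets = read_gmt(p)
    return pathway_sets_from_gmt(sets, "MTOR_UP", "MTOR_DOWN", name="synthetic_mtor")
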