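"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from sciso.simulate import FusionSpec, SimConfig, VariantSpec, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free, artifact-free dataset with an implanted fusion and SNVs."""
    config = SimConfig(
        seed=101,
        n_genes=8,
        cells_per_type=25,
        molecules_per_gene=60,
        error_rate=0.0,
        artifact_fraction=0.0,
        fusion_spec=FusionSpec(gene5="G0001", gene3="G0002", n_umis=12, cell_type="tumor"),
        variant_spec=[
            VariantSpec(carrier_cell_types=("tumor",), gene="G0003", name="somatic_1"),
            VariantSpec(
                carrier_cell_types=("tumor", "distal"), gene="G0004", name="germline_1"
            ),
        ],
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def plain_dataset():
    """Small dataset without fusion or variants (exact count round trips)."""
    config = SimConfig(
        seed=202,
        n_genes=6,
        cells_per_type=15,
        molecules_per_gene=40,
        error_rate=0.0,
        artifact_fraction=0.0,
    )
    return simulate_dataset(config)
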