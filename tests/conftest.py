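"""Shared fixtures: tiny in-memory datasets and toy structures."""

from __future__ import annotations

import pytest

from qxlms.quant_norm import AggregatedQuant
from qxlms.xlink_io import LinkSpecies, ResidueRef


def make_agg(
    control_values,
    treated_values,
    kind: str = "interpeptide",
    site_a=("P1", 10, "K"),
    site_b=("P2", 20, "K"),
) -> AggregatedQuant:
    """Build an aggregated link with given per-replicate intensities."""
    link = LinkSpecies(
        kind,
        ResidueRef(*site_a),
        ResidueRef(*site_b) if kind != "monolink" else None,
    )
    cells = {}
    for i, v in enumerate(control_values):
        cells[("control", str(i + 1))] = v
    for i, v in enumerate(treated_values):
        cells[("treated", str(i + 1))] = v
    return AggregatedQuant(link=link, normalized_intensity=cells, n_member_peptides=1)


@pytest.fixture
def agg_factory():
    return make_agg


@pytest.fixture(scope="session")
def hinge_pair():
    """A 12-degree toy hinge model pair with ground truth."""
    from qxlms.synthetic_data import generate_toy_hinge

    return generate_toy_hinge(12.0, n_per_arm=20, seed=0)


@pytest.fixture(scope="session")
def benchmark_zero_noise():
    """Zero-noise planted-category benchmark (quant table + model trio)."""
    from qxlms.synthetic_data import simulate_dynamics_benchmark

    return simulate_dynamics_benchmark(seed=11, cv=0.0)
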