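from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tgxddi import (
    CqTable,
    FoldChangeProfile,
    ReferencePanel,
    SimulationConfig,
    simulate_panel,
)


def make_profile(chemical: str, values: dict[str, float]) -> FoldChangeProfile:
    return FoldChangeProfile(chemical, pd.Series(values, dtype=float))


def make_panel(columns: dict[str, list[float]], labels: dict[str, str], genes=None) -> ReferencePanel:
    n = len(next(iter(columns.values())))
    genes = genes or [f"G{i + 1}" for i in range(n)]
    matrix = pd.DataFrame(columns, index=genes)
    return ReferencePanel(matrix, pd.Series(labels))


def make_cq(values: dict[str, dict[str, float]], sheet_rows: list[dict]) -> CqTable:
    """values: sample_id -> {gene: cq}; sheet_rows: dicts with sample metadata."""
    frame = pd.DataFrame(values)
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    return CqTable(frame, sheet)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def strong_cfg() -> SimulationConfig:
    """A well-separated synthetic study: strong signature, modest noise."""
    return SimulationConfig(effect_size=4.0, noise_sd=0.25, seed=11)


@pytest.fixture(scope="session")
def strong_panel(strong_cfg):
    return simulate_panel(strong_cfg)


@pytest.fixture
def toy_panel() -> ReferencePanel:
    """Two profiles per class over 3 genes; DDI up on G1, down on G2."""
    return make_panel(
        {
            "ddi_a": [3.0, -2.0, 0.1],
            "ddi_b": [3.4, -2.4, -0.1],
            "non_a": [0.2, 0.1, 0.0],
            "non_b": [-0.2, -0.1, 0.2],
        },
        {"ddi_a": "DDI", "ddi_b": "DDI", "non_a": "non-DDI", "non_b": "non-DDI"},
    )
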