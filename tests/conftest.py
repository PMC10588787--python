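import numpy as np
import pandas as pd
import pytest

from triomics import AnalyteMatrix, SampleMeta, SimulationConfig, generate_study
from triomics.containers import SCALE_LOG2


def make_matrix(
    values,
    block="metabolite",
    scale=SCALE_LOG2,
    sample_ids=None,
    analyte_ids=None,
    **kwargs,
):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    analyte_ids = analyte_ids or [f"a{j}" for j in range(p)]
    return AnalyteMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=analyte_ids),
        block_label=block,
        scale=scale,
        **kwargs,
    )


def make_meta(n_per_group=4, seed=0, sample_ids=None):
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    return SampleMeta(
        pd.DataFrame(
            {
                "group": np.repeat(["healthy", "remission", "active"], n_per_group),
                "age": rng.uniform(25, 65, n),
                "sex": rng.integers(0, 2, n).astype(float),
            },
            index=sample_ids,
        )
    )


@pytest.fixture(scope="session")
def planted_study():
    """A study with planted sub-networks, effects and trajectory classes."""
    cfg = SimulationConfig(
        n_per_group=12,
        block_sizes={"protein": 60, "eicosanoid": 24, "metabolite": 90},
        planted_blocks=[
            ("protein", tuple(range(5)), 0.9),
            ("metabolite", tuple(range(6)), 0.85),
        ],
        effects=[
            ("protein", tuple(range(5)), "healthy_vs_active", 1.5),
            ("metabolite", tuple(range(6)), "healthy_vs_active", 1.2),
            ("metabolite", (10, 11), "healthy_vs_remission", 2.0),
        ],
        trajectory_profiles={
            ("metabolite", 20): "normalising",
            ("metabolite", 21): "non_normalising",
            ("metabolite", 22): "exceptional",
        },
        lod_quantile=0.1,
        missing_rate=0.1,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """No planted structure at all: pure noise in every block."""
    cfg = SimulationConfig(
        n_per_group=12,
        block_sizes={"protein": 40, "eicosanoid": 20, "metabolite": 60},
        seed=5,
    )
    return generate_study(cfg)
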