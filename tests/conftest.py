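import numpy as np
import pytest

from tfsynergy import (
    DiscreteProfile,
    ExpressionMatrix,
    RunConfig,
    SubpopulationPartition,
    SyntheticSpec,
    generate,
)


@pytest.fixture
def xor_profiles():
    """Enumerated 8-outcome joint table with Z = XOR(X, Y), all (x, y) equiprobable."""
    x = np.array([0, 0, 1, 1] * 2)
    y = np.array([0, 1, 0, 1] * 2)
    z = x ^ y
    return (
        DiscreteProfile("X", x, 2),
        DiscreteProfile("Y", y, 2),
        DiscreteProfile("Z", z, 2),
    )


@pytest.fixture
def small_matrix():
    """3 cells × 2 genes, the round-trip workhorse."""
    return ExpressionMatrix(
        values=np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]]),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2"],
        unit_regime="fpkm_like",
    )


@pytest.fixture
def two_subpop_dataset():
    """Two 100-cell subpopulations, xor3 planted in S1, 12 background TFs."""
    spec = SyntheticSpec(
        n_cells=100,
        n_subpopulations=2,
        n_background_tfs=12,
        rng_seed=7,
    )
    return generate(spec)


@pytest.fixture
def recovery_config():
    """Search settings for small synthetic candidate pools (see docs/methods.md):
    motifs live within their subpopulation and the top-10% shortlist is
    disabled because 30-TF pools are far below the ~1500-TF annotations the
    fraction rule was sized for."""
    return RunConfig(top_frequency_fraction=1.0, mmi_population="within")


def make_matrix(values, unit_regime="fpkm_like", cell_prefix="c", gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"{cell_prefix}{i}" for i in range(values.shape[0])],
        gene_ids=[f"{gene_prefix}{j}" for j in range(values.shape[1])],
        unit_regime=unit_regime,
    )


def uniform_partition(cell_ids, n_groups=1, labels=None):
    labels = labels or [f"P{i + 1}" for i in range(n_groups)]
    per = len(cell_ids) // len(labels)
    assignment = {}
    for i, cell in enumerate(cell_ids):
        assignment[cell] = labels[min(i // per, len(labels) - 1)]
    return SubpopulationPartition(assignment)
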