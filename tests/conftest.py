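import numpy as np
import pandas as pd
import pytest

from stagetraj import CountMatrix, RunConfig, SampleTable, SimDesign, simulate_counts

STAGES = ["E18.5", "12wk", "39wk"]


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(8)]
    df = pd.DataFrame(
        rng.integers(0, 500, size=(20, 8)), index=genes, columns=samples
    )
    return CountMatrix(df)


@pytest.fixture
def small_meta() -> SampleTable:
    rows = []
    for i in range(8):
        rows.append(
            {
                "sample_id": f"s{i}",
                "stage": STAGES[i % 3 if i < 6 else 2],
                "condition": "Natural" if i % 2 == 0 else "IVF",
                "replicate": f"r{i}",
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable.from_frame(df, STAGES)


@pytest.fixture(scope="session")
def sim_default():
    """One default-design simulation shared across the session."""
    design = SimDesign(seed=7)
    counts, meta, truth = simulate_counts(design)
    return design, counts, meta, truth


@pytest.fixture(scope="session")
def tiny_sim():
    """A small, fast simulated dataset (3 archetypes x 40 genes)."""
    from stagetraj import default_archetypes

    design = SimDesign(
        archetypes=default_archetypes(3, 3),
        genes_per_archetype=40,
        samples_per_stage_per_condition=4,
        seed=3,
    )
    counts, meta, truth = simulate_counts(design)
    return design, counts, meta, truth


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig(seed=0)
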