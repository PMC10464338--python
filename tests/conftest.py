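import numpy as np
import pandas as pd
import pytest

from hexelute import QuantTable, SampleMeta


def make_samples(replicates=1):
    return [
        SampleMeta(f"{g}_r{r}", g, r)
        for g in ("IB", "HD2", "HD5", "HD10")
        for r in range(1, replicates + 1)
    ]


def make_table(values, protein_ids=None, samples=None, stages=()):
    """Build a QuantTable from a nested list / array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = make_samples()[: values.shape[1]]
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(
        values, index=pd.Index(protein_ids, name="protein_id"),
        columns=[s.sample_id for s in samples],
    )
    return QuantTable(abundance=frame, samples=samples, stages=tuple(stages))


@pytest.fixture
def four_group_table():
    """3 proteins x 4 samples (one per group), one missing cell."""
    return make_table(
        [
            [10.0, 40.0, 20.0, 30.0],
            [5.0, np.nan, 15.0, 10.0],
            [8.0, 16.0, 24.0, 32.0],
        ]
    )


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (generation is cheap but
    not free; session scope keeps the suite fast)."""
    from hexelute import SimConfig, simulate_elution, simulate_proteome

    config = SimConfig(n_proteins=250, seed=11)
    sequences, disorder, truth = simulate_proteome(config)
    table, evidence = simulate_elution(config, truth)
    return config, sequences, disorder, truth, table, evidence
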