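import numpy as np
import pandas as pd
import pytest

from ctsai import (
    ExpressionTable,
    SampleDesign,
    SimulationParams,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def design4() -> SampleDesign:
    return SampleDesign.paired(4)


@pytest.fixture(scope="session")
def design2() -> SampleDesign:
    return SampleDesign.paired(2)


def make_table(rows: dict, design: SampleDesign, gene_map: dict | None = None):
    """Build an ExpressionTable from {transcript_id: [values...]}.

    By default each transcript 'gX.tN' maps to gene 'gX'.
    """
    if gene_map is None:
        gene_map = {t: t.rsplit(".", 1)[0] for t in rows}
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(design.sample_ids), dtype=float
    )
    return ExpressionTable(values, gene_map, design)


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy simulated cohort with planted switch genes and convergent pairs."""
    params = SimulationParams(
        n_genes=60, n_ctsai=8, n_convergent_pairs=3,
        replicates_per_cell_type=4, seed=11,
    )
    models, truth, table, coverage = simulate_dataset(params)
    return params, models, truth, table, coverage


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Deterministic cohort (replicate_cv=0) for exact recovery checks."""
    params = SimulationParams(
        n_genes=50, n_ctsai=5, n_convergent_pairs=1,
        replicate_cv=0.0, seed=7,
    )
    models, truth, table, coverage = simulate_dataset(params)
    return params, models, truth, table, coverage
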