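"""Shared fixtures: the default synthetic experiment and pipeline run.

The heavy objects (default ~4,200-cell experiment, the full discovery run,
and the doublet-stress experiment) are session-scoped so the whole suite
pays for them once.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from rdnamag import (
    GeneExpressionMatrix,
    PipelineConfig,
    run_discovery,
)
from rdnamag.simulate import SimulationConfig, simulate_experiment

EXPERIMENT_SEED = 20138


@pytest.fixture(scope="session")
def default_experiment():
    """Default two-condition experiment with planted truth."""
    return simulate_experiment(SimulationConfig(seed=EXPERIMENT_SEED))


@pytest.fixture(scope="session")
def pipeline_result(default_experiment):
    """Full discovery cascade on the default experiment."""
    matrix, _ = default_experiment
    return run_discovery(matrix, PipelineConfig(seed=EXPERIMENT_SEED))


@pytest.fixture(scope="session")
def doublet_experiment():
    """Default experiment at an elevated doublet rate (delta = 0.1)."""
    return simulate_experiment(SimulationConfig(seed=EXPERIMENT_SEED + 1, doublet_rate=0.10))


def small_matrix(counts, prefix_gene="g", prefix_cell="c", meta=None):
    """Dense list-of-lists -> GeneExpressionMatrix with generated ids."""
    counts = np.asarray(counts)
    genes = [f"{prefix_gene}{i + 1}" for i in range(counts.shape[0])]
    cells = [f"{prefix_cell}{j + 1}" for j in range(counts.shape[1])]
    return GeneExpressionMatrix(genes, cells, sp.csr_matrix(counts), cell_meta=meta)
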