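import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from singlefiber import (
    FiberSample,
    NormalizedMatrix,
    SimConfig,
    acta1_normalize,
    filter_pure_fibers,
    filter_valid_values,
    ibaq_normalize,
    simulate,
    type_fibers,
)


def make_matrix(values, fiber_types, gene_names=None, protein_ids=None):
    """Build a NormalizedMatrix from a plain nested list / array.

    ``fiber_types`` is a list like ["1", "1", "2A", "2X"]; fiber ids are
    F1.., protein ids P1.. unless given.
    """
    values = np.asarray(values, dtype=float)
    n_prot, n_fib = values.shape
    fiber_ids = [f"F{i + 1}" for i in range(n_fib)]
    protein_ids = protein_ids or [f"P{i + 1}" for i in range(n_prot)]
    gene_names = gene_names or [f"G{i + 1}" for i in range(n_prot)]
    index = pd.Index(protein_ids, name="protein_id")
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=index, columns=fiber_ids),
        gene_names=pd.Series(gene_names, index=index, name="gene_name"),
        fiber_types=pd.Series(fiber_types, index=fiber_ids, name="fiber_type"),
    )


def pure_fiber_types(samples, purity_threshold=0.8):
    """fiber_id -> type Series for the pure fibers, in input order."""
    calls = type_fibers(samples, purity_threshold=purity_threshold)
    partition = filter_pure_fibers(calls)
    by_id = {fid: t.value for t in partition.kept for fid in partition.kept[t]}
    ordered = [s.fiber_id for s in samples if s.fiber_id in by_id]
    return pd.Series([by_id[f] for f in ordered], index=ordered, name="fiber_type")


def normalized_from_simulation(config: SimConfig, min_valid: int = 4):
    """Run simulate -> type -> normalize -> filter; returns (matrix, truth)."""
    fibers, table, truth = simulate(config)
    fiber_types = pure_fiber_types(fibers)
    matrix = acta1_normalize(ibaq_normalize(table), table.gene_names, fiber_types)
    matrix, _ = filter_valid_values(matrix, min_valid=min_valid)
    return matrix, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset shared across tests (fast to analyze)."""
    from singlefiber.synthetic import PatternSpec, TruthPattern

    config = SimConfig(
        n_type1=10,
        n_type2a=12,
        n_type2x=8,
        pattern_specs=(
            PatternSpec(TruthPattern.TYPE1_SPECIFIC, 15),
            PatternSpec(TruthPattern.TYPE2_SPECIFIC, 15),
            PatternSpec(TruthPattern.NULL, 120),
        ),
        dropout_slope=0.0,
        dropout_intercept=-np.inf,
        seed=11,
    )
    matrix, truth = normalized_from_simulation(config)
    return matrix, truth


@pytest.fixture
def tiny_samples():
    return [
        FiberSample("F1", "S1", 100.0, 10.0, 5.0),
        FiberSample("F2", "S1", 5.0, 90.0, 5.0),
        FiberSample("F3", "S2", 0.0, 10.0, 90.0),
        FiberSample("F4", "S2", 45.0, 45.0, 10.0),
    ]
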