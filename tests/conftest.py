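import numpy as np
import pandas as pd
import pytest

from geneflows import (
    ConditionSeries,
    ExpressionMatrix,
    GroupedProfile,
    MembershipTensor,
    PlantedPattern,
    SyntheticSpec,
    generate,
    pseudobulk,
)


def make_profile(
    mean_values: np.ndarray,
    clusters=("c0",),
    conditions=("t0", "t1"),
    frac: float = 1.0,
    n_cells: int = 10,
) -> GroupedProfile:
    """Grouped profile with prescribed mean expression for direct fuzzifier tests.

    ``mean_values`` is genes x (len(clusters) * len(conditions)), column order
    cluster-major.
    """
    mean_values = np.asarray(mean_values, dtype=float)
    columns = pd.MultiIndex.from_product([clusters, conditions],
                                         names=["cluster", "condition"])
    genes = [f"g{i:03d}" for i in range(mean_values.shape[0])]
    mean = pd.DataFrame(mean_values, index=genes, columns=columns)
    return GroupedProfile(
        mean_expr=mean,
        frac_expr=pd.DataFrame(frac, index=genes, columns=columns),
        n_cells=pd.Series(n_cells, index=columns),
        conditions=ConditionSeries(tuple(conditions)),
    )


def random_tensor(n_genes, n_clusters, n_conditions, n_levels, seed) -> MembershipTensor:
    """Random valid membership tensor (rows are Dirichlet draws)."""
    rng = np.random.default_rng(seed)
    mu = rng.dirichlet(np.ones(n_levels), size=(n_genes, n_clusters, n_conditions))
    return MembershipTensor(
        mu=mu,
        genes=[f"g{i:03d}" for i in range(n_genes)],
        clusters=[f"c{i}" for i in range(n_clusters)],
        conditions=ConditionSeries(tuple(f"t{i}" for i in range(n_conditions))),
        levels=tuple(f"L{i}" for i in range(n_levels)),
    )


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_genes=300,
        clusters=("c0", "c1", "c2"),
        cells_per_block=40,
        planted=(PlantedPattern(n_genes=12),),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def small_profile(small_spec, small_dataset):
    rna, _, annotation, _ = small_dataset
    return pseudobulk(rna, annotation, small_spec.condition_series)


def simple_expression(counts: np.ndarray) -> ExpressionMatrix:
    counts = np.asarray(counts)
    return ExpressionMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        cell_ids=[f"c{i}" for i in range(counts.shape[1])],
    )
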