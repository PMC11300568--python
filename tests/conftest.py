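import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from scattractor import (
    AttractorConfig,
    SyntheticSpec,
    default_benchmark_spec,
    filter_genes,
    normalize_log,
    run_attractor,
    simulate,
)
from scattractor.association import AssociationWorkspace

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def benchmark_sim():
    """The canonical planted-module simulation (2000x1000, |M|=30, pi=0.2)."""
    return simulate(default_benchmark_spec())


@pytest.fixture(scope="session")
def benchmark_prepared(benchmark_sim):
    matrix, _ = benchmark_sim
    return filter_genes(normalize_log(matrix), min_cell_fraction=0.02)


@pytest.fixture(scope="session")
def benchmark_truth(benchmark_sim):
    return benchmark_sim[1]


@pytest.fixture(scope="session")
def benchmark_workspace(benchmark_prepared):
    return AssociationWorkspace(benchmark_prepared)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_prepared, benchmark_truth, benchmark_workspace):
    """Attractor from the first planted-module gene on the benchmark."""
    return run_attractor(
        benchmark_prepared,
        benchmark_truth.module_gene_ids[0][0],
        AttractorConfig(),
        benchmark_workspace,
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small, quickly converging planted-module instance for unit tests."""
    spec = SyntheticSpec(
        n_genes=500,
        n_cells=300,
        module_sizes=(20,),
        population_fractions=(0.2,),
        fold=5.0,
        dispersion=2.0,
        rng_seed=11,
    )
    matrix, truth = simulate(spec)
    prepared = filter_genes(normalize_log(matrix), min_cell_fraction=0.02)
    return prepared, truth


@pytest.fixture(scope="session")
def two_module_prepared():
    """Benchmark variant with two disjoint 30-gene planted modules."""
    spec = dataclasses.replace(
        default_benchmark_spec(),
        module_sizes=(30, 30),
        population_fractions=(0.2, 0.2),
    )
    matrix, truth = simulate(spec)
    return filter_genes(normalize_log(matrix), min_cell_fraction=0.02), truth


@pytest.fixture(scope="session")
def two_module_scan(two_module_prepared):
    """Variance-seeded attractor scan of the two-module benchmark variant."""
    from scattractor import scan_attractors

    prepared, truth = two_module_prepared
    cfg = AttractorConfig(n_variance_seeds=60)
    return scan_attractors(prepared, cfg), truth, cfg
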