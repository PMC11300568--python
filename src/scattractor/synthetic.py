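"""Negative-binomial scRNA-seq simulator with planted co-expression modules.

The generator emulates a dissociated-tissue (SVF-like) counts matrix:
log-normal gene baseline means, log-normal cell size factors, and one or
more disjoint gene modules whose member genes are up-regulated by a common
fold inside a latent cell sub-population. Because the fold applies to all
module genes in exactly the cells of that sub-population, the module genes
co-express across cells — the structure the attractor is designed to find —
and the sub-population labels provide ground truth for scoring and
abundance recovery.

Counts follow NB(mean mu, dispersion theta) with variance mu + mu^2/theta;
theta -> infinity is the Poisson limit. All randomness flows through a
single seeded generator in a fixed order (gene means, size factors, cell
labels, counts), so a spec is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "simulate", "default_benchmark_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Simulation settings.

    module_sizes / population_fractions
        One entry per planted module: the number of member genes and the
        fraction of cells in the carrying sub-population (fractions sum
        to at most 1; remaining cells are background).
    fold
        Multiplier on the mean of module genes inside their sub-population.
    dispersion
        NB dispersion theta (variance = mu + mu^2/theta).
    baseline_meanlog, baseline_sdlog
        Log-normal parameters of per-gene baseline means.
    size_factor_sdlog
        Log-normal sigma of per-cell size factors (0 disables them).
    """

    n_genes: int = 2000
    n_cells: int = 1000
    module_sizes: tuple[int, ...] = (30,)
    population_fractions: tuple[float, ...] = (0.2,)
    fold: float = 4.0
    dispersion: float = 2.0
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    size_factor_sdlog: float = 0.3
    rng_seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        object.__setattr__(
            self, "population_fractions", tuple(self.population_fractions)
        )
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if len(self.module_sizes) != len(self.population_fractions):
            raise ValueError("one population fraction per module required")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module genes exceed n_genes (modules are disjoint)")
        if any(not 0 < p < 1 for p in self.population_fractions):
            raise ValueError("population fractions must be in (0, 1)")
        if sum(self.population_fractions) > 1:
            raise ValueError("population fractions must sum to <= 1")
        if self.fold <= 0 or self.dispersion <= 0:
            raise ValueError("fold and dispersion must be positive")
        if self.size_factor_sdlog < 0:
            raise ValueError("size_factor_sdlog must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted with a simulated matrix.

    ``cell_labels[c]`` is the module index carried by cell c, or -1 for
    background; ``module_gene_ids[m]`` lists the member genes of module m.
    """

    module_gene_ids: tuple[tuple[str, ...], ...]
    cell_labels: np.ndarray

    def module_cells(self, module: int = 0) -> np.ndarray:
        return np.asarray(self.cell_labels) == module


def default_benchmark_spec() -> SyntheticSpec:
    """The canonical benchmark: 2000 genes x 1000 cells, one 30-gene module
    carried by 20% of cells at fold 4, dispersion 2, seed 1."""
    return SyntheticSpec(
        n_genes=2000,
        n_cells=1000,
        module_sizes=(30,),
        population_fractions=(0.2,),
        fold=4.0,
        dispersion=2.0,
        baseline_meanlog=0.0,
        baseline_sdlog=1.0,
        size_factor_sdlog=0.3,
        rng_seed=1,
    )


def simulate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a counts matrix and its ground truth from ``spec``.

    Module m occupies the m-th consecutive block of gene indices; its
    carrying cells are drawn by permuting all cells and taking the first
    floor(pi_m * n_cells) unassigned ones. Identical specs give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    g, n = spec.n_genes, spec.n_cells
    # RNG order is part of the contract: means, size factors, labels, counts
    mu = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=g)
    if spec.size_factor_sdlog > 0:
        size_factors = rng.lognormal(0.0, spec.size_factor_sdlog, size=n)
    else:
        size_factors = np.ones(n)
    perm = rng.permutation(n)
    labels = np.full(n, -1, dtype=int)
    start = 0
    for m, frac in enumerate(spec.population_fractions):
        count = int(np.floor(frac * n))
        labels[perm[start : start + count]] = m
        start += count

    mean = np.outer(mu, size_factors)
    gene_ids = [f"G{i:04d}" for i in range(g)]
    cell_ids = [f"C{i:04d}" for i in range(n)]
    module_genes: list[tuple[str, ...]] = []
    gstart = 0
    for m, size in enumerate(spec.module_sizes):
        idx = np.arange(gstart, gstart + size)
        module_genes.append(tuple(gene_ids[i] for i in idx))
        mean[np.ix_(idx, labels == m)] *= spec.fold
        gstart += size

    theta = spec.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean)).astype(float)
    matrix = ExpressionMatrix(gene_ids, cell_ids, counts, layer="counts")
    return matrix, SyntheticTruth(tuple(module_genes), labels)
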