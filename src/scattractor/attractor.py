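"""Attractor metagene convergence: from a seed gene to a ranked signature.

The attractor iteration alternates two steps on a log-normalized matrix:

1. score every gene by its normalized association J with the current
   metagene;
2. rebuild the metagene as the weighted average of gene expression with
   weights w_i = J_i^a / sum_j J_j^a.

The exponent ``a`` sharpens the weighting: large ``a`` concentrates the
metagene on the most associated genes. Iteration stops when the top-K gene
set is identical between successive iterations (``converged``), a previous
top-K set recurs within a sliding window (``oscillating``), the signature
collapses — fewer than ``min_support`` genes with J > 0, or a single gene
holding more than ``dominance_threshold`` of the weight (``degenerate``) —
or the iteration cap is reached (``max_iter``).

The adaptive exponent sweeps a fixed grid from the smallest value upward
and keeps the converged, non-degenerate run whose rank-``min_support``
gene has the highest J ("signature strength": how strongly the core of the
signature co-expresses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import AssociationConfig, AssociationWorkspace
from .matrix_io import ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "AttractorConfig",
    "Metagene",
    "AttractorResult",
    "DegenerateInputError",
    "iterate_once",
    "run_attractor",
    "scan_attractors",
    "signature_strength",
]


class DegenerateInputError(ValueError):
    """The association profile gives no direction to iterate in."""


@dataclass(frozen=True)
class AttractorConfig:
    """Attractor iteration settings.

    exponent_grid
        Candidate exponents a, swept in increasing order.
    top_k
        Size of the gene set whose stability defines convergence.
    max_iter
        Iteration cap per exponent.
    dominance_threshold
        Maximum admissible weight of a single gene; above it the run is
        flagged degenerate (a one-gene "signature" is not co-expression).
    min_support
        Minimum number of genes with J > 0, and the rank whose J defines
        signature strength.
    cycle_window
        Length of the recent-history window used to detect oscillation.
    dedup_jaccard
        Jaccard similarity of top-K sets above which two scanned
        attractors are considered the same signature.
    n_variance_seeds
        Seed-set size (top genes by variance) when scanning without an
        explicit seed list.
    assoc
        Association estimator settings.
    """

    exponent_grid: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    top_k: int = 50
    max_iter: int = 50
    dominance_threshold: float = 0.5
    min_support: int = 10
    cycle_window: int = 4
    dedup_jaccard: float = 0.5
    n_variance_seeds: int = 2000
    assoc: AssociationConfig = field(default_factory=AssociationConfig)

    def __post_init__(self) -> None:
        if not self.exponent_grid or any(a <= 0 for a in self.exponent_grid):
            raise ValueError("exponent_grid must be non-empty and positive")
        if tuple(sorted(self.exponent_grid)) != tuple(self.exponent_grid):
            raise ValueError("exponent_grid must be increasing")
        if self.top_k < self.min_support:
            raise ValueError("top_k must be >= min_support")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.dominance_threshold <= 1:
            raise ValueError("dominance_threshold must be in (0, 1]")
        if not 0 < self.dedup_jaccard <= 1:
            raise ValueError("dedup_jaccard must be in (0, 1]")


@dataclass
class Metagene:
    """A weighted average of gene expression rows.

    ``cell_values`` is the metagene's expression across cells and equals
    ``weights @ matrix.values``; weights are nonnegative and sum to 1.
    """

    cell_values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.cell_values = np.asarray(self.cell_values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("metagene weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("metagene weights must sum to 1")


@dataclass
class AttractorResult:
    """Outcome of one attractor run.

    ``ranked_genes`` lists every gene of the (filtered) matrix with its J
    against the final metagene, J non-increasing, ties broken by gene id.
    ``metagene_cell_values`` is the metagene that produced those J values,
    so one further :func:`iterate_once` from it reproduces the ranking of
    a converged result.
    """

    seed_gene: str
    final_exponent: float
    ranked_genes: list[tuple[str, float]]
    iterations: int
    status: str  # converged | oscillating | degenerate | max_iter
    metagene_cell_values: np.ndarray | None = None

    def top_genes(self, k: int) -> list[str]:
        return [g for g, _ in self.ranked_genes[:k]]


def signature_strength(result: AttractorResult, min_support: int = 10) -> float:
    """J of the rank-``min_support`` gene; 0 if the ranking is shorter."""
    if len(result.ranked_genes) < min_support:
        return 0.0
    return result.ranked_genes[min_support - 1][1]


def _rank_order(profile: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Indices sorting genes by J descending, gene id ascending on ties."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-profile[i], gene_ids[i]))
    return np.asarray(order)


def iterate_once(
    matrix: ExpressionMatrix,
    metagene_cell_values: np.ndarray,
    a: float,
    cfg: AttractorConfig | None = None,
    workspace: AssociationWorkspace | None = None,
) -> Metagene:
    """One attractor step: re-weight genes by J^a and rebuild the metagene."""
    cfg = cfg or AttractorConfig()
    if a <= 0:
        raise ValueError("exponent a must be positive")
    if matrix.layer != "lognorm":
        raise ValueError("attractor iteration requires a log-normalized matrix")
    if workspace is None:
        workspace = AssociationWorkspace(matrix, cfg.assoc)
    profile = workspace.profile(np.asarray(metagene_cell_values, dtype=float))
    weights = profile**a
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError(
            "all associations are zero; the metagene has no direction"
        )
    weights = weights / total
    return Metagene(cell_values=weights @ matrix.values, weights=weights)


def _seed_neighborhood(
    matrix: ExpressionMatrix,
    seed_gene: str,
    cfg: AttractorConfig,
    workspace: AssociationWorkspace,
) -> np.ndarray:
    """Initial metagene: mean expression of the seed's ``min_support``
    most associated genes (the seed itself ranks first with J = 1).

    Starting from the raw seed vector instead traps the iteration at a
    one-gene fixed point: the seed's self-association is exactly 1, so at
    any exponent its weight dominates and the metagene never blends. The
    neighborhood mean starts the iteration at an actual co-expression
    candidate while using the same association measure.
    """
    profile = workspace.profile(matrix.expression(seed_gene))
    order = _rank_order(profile, matrix.gene_ids)[: cfg.min_support]
    return matrix.values[order].mean(axis=0)


def _run_fixed_exponent(
    matrix: ExpressionMatrix,
    seed_gene: str,
    m0: np.ndarray,
    a: float,
    cfg: AttractorConfig,
    workspace: AssociationWorkspace,
) -> AttractorResult:
    gene_ids = matrix.gene_ids
    m = m0.astype(float)
    prev_top: frozenset[str] | None = None
    history: list[frozenset[str]] = []

    def result(status: str, profile: np.ndarray, iterations: int) -> AttractorResult:
        order = _rank_order(profile, gene_ids)
        ranked = [(gene_ids[i], float(profile[i])) for i in order]
        return AttractorResult(
            seed_gene=seed_gene,
            final_exponent=a,
            ranked_genes=ranked,
            iterations=iterations,
            status=status,
            metagene_cell_values=m.copy(),
        )

    for it in range(1, cfg.max_iter + 1):
        profile = workspace.profile(m)
        if int((profile > 0).sum()) < cfg.min_support:
            return result("degenerate", profile, it)
        weights = profile**a
        total = weights.sum()
        if total <= 0:
            return result("degenerate", profile, it)
        weights = weights / total
        if weights.max() > cfg.dominance_threshold:
            return result("degenerate", profile, it)
        top = frozenset(gene_ids[i] for i in _rank_order(profile, gene_ids)[: cfg.top_k])
        if top == prev_top:
            return result("converged", profile, it)
        if top in history:
            return result("oscillating", profile, it)
        history.append(top)
        if len(history) > cfg.cycle_window:
            history.pop(0)
        prev_top = top
        m = weights @ matrix.values
    profile = workspace.profile(m)
    return result("max_iter", profile, cfg.max_iter)


def run_attractor(
    matrix: ExpressionMatrix,
    seed_gene: str,
    cfg: AttractorConfig | None = None,
    workspace: AssociationWorkspace | None = None,
) -> AttractorResult:
    """Run the attractor from ``seed_gene`` with adaptive exponent selection.

    The metagene starts at the seed's neighborhood mean (see
    :func:`_seed_neighborhood`). The exponent grid is swept from its
    smallest value upward; among runs
    that converge (and are not degenerate) the one maximizing signature
    strength is returned, with its exponent recorded. If no grid value
    converges, the strongest non-converged run is returned rather than
    raising.
    """
    cfg = cfg or AttractorConfig()
    if matrix.layer != "lognorm":
        raise ValueError("run_attractor requires a log-normalized matrix")
    if seed_gene not in matrix.gene_ids:
        raise KeyError(f"seed gene {seed_gene!r} not in matrix")
    if workspace is None:
        workspace = AssociationWorkspace(matrix, cfg.assoc)

    m0 = _seed_neighborhood(matrix, seed_gene, cfg, workspace)
    best: AttractorResult | None = None
    fallback: AttractorResult | None = None
    for a in cfg.exponent_grid:
        res = _run_fixed_exponent(matrix, seed_gene, m0, a, cfg, workspace)
        strength = signature_strength(res, cfg.min_support)
        logger.debug(
            "seed=%s a=%g status=%s iter=%d strength=%.4f",
            seed_gene, a, res.status, res.iterations, strength,
        )
        if res.status == "converged":
            if best is None or strength > signature_strength(best, cfg.min_support):
                best = res
        else:
            if fallback is None or strength > signature_strength(
                fallback, cfg.min_support
            ):
                fallback = res
    return best if best is not None else fallback  # type: ignore[return-value]


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def scan_attractors(
    matrix: ExpressionMatrix,
    cfg: AttractorConfig | None = None,
    seed_set: GeneList | None = None,
) -> list[AttractorResult]:
    """Run the attractor from many seeds and deduplicate converged results.

    Seeds default to the ``n_variance_seeds`` most variable genes. Two
    converged results merge when the Jaccard similarity of their top-K
    gene sets reaches ``dedup_jaccard``; the stronger one is kept. The
    returned list is sorted by signature strength, descending.
    """
    cfg = cfg or AttractorConfig()
    if matrix.layer != "lognorm":
        raise ValueError("scan_attractors requires a log-normalized matrix")
    if seed_set is not None:
        seeds = [g for g in seed_set.genes if g in set(matrix.gene_ids)]
        missing = len(seed_set) - len(seeds)
        if missing:
            logger.warning("%d seed gene(s) not in matrix, skipped", missing)
    else:
        variances = matrix.values.var(axis=1)
        nonconstant = variances > 0
        order = np.argsort(-variances, kind="stable")
        order = [i for i in order if nonconstant[i]][: cfg.n_variance_seeds]
        seeds = [matrix.gene_ids[i] for i in order]
    if not seeds:
        import warnings

        warnings.warn("empty seed set; nothing to scan")
        return []

    workspace = AssociationWorkspace(matrix, cfg.assoc)
    converged: list[AttractorResult] = []
    for seed in seeds:
        try:
            res = run_attractor(matrix, seed, cfg, workspace)
        except Exception as exc:  # per-seed failures logged, never fatal
            logger.warning("seed %s failed: %s", seed, exc)
            continue
        if res is not None and res.status == "converged":
            converged.append(res)
        else:
            logger.debug(
                "seed %s: status=%s", seed, res.status if res else "none"
            )

    converged.sort(
        key=lambda r: (-signature_strength(r, cfg.min_support), r.seed_gene)
    )
    kept: list[AttractorResult] = []
    kept_sets: list[frozenset[str]] = []
    for res in converged:
        top = frozenset(res.top_genes(cfg.top_k))
        if any(_jaccard(top, s) >= cfg.dedup_jaccard for s in kept_sets):
            continue
        kept.append(res)
        kept_sets.append(top)
    return kept
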