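import dataclasses

import numpy as np
import pytest

from scattractor import (
    AttractorConfig,
    ExpressionMatrix,
    GeneList,
    default_benchmark_spec,
    filter_genes,
    normalize_log,
    simulate,
)
from scattractor.attractor import (
    DegenerateInputError,
    iterate_once,
    run_attractor,
    scan_attractors,
    signature_strength,
)


class StubWorkspace:
    """Injects a fixed association profile into one iteration step."""

    def __init__(self, profile):
        self._profile = np.asarray(profile, dtype=float)

    def profile(self, metagene):
        return self._profile


def lognorm_matrix(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        gene_ids, [f"c{i}" for i in range(values.shape[1])], values, layer="lognorm"
    )


class TestIterateOnce:
    def test_equal_associations_share_weight(self):
        m = lognorm_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = iterate_once(m, m.values[0], 1.0, workspace=StubWorkspace([1, 1, 0]))
        np.testing.assert_allclose(out.weights, [0.5, 0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            out.cell_values, 0.5 * m.values[0] + 0.5 * m.values[1], atol=1e-12
        )

    def test_hand_computed_exponent_weighting(self):
        m = lognorm_matrix([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = iterate_once(
            m, m.values[0], 2.0, workspace=StubWorkspace([0.8, 0.4, 0.2])
        )
        np.testing.assert_allclose(
            out.weights, np.array([0.64, 0.16, 0.04]) / 0.84, atol=1e-12
        )

    def test_large_exponent_concentrates_on_top_gene(self):
        m = lognorm_matrix(np.arange(6, dtype=float).reshape(3, 2))
        out = iterate_once(
            m, m.values[0], 50.0, workspace=StubWorkspace([0.9, 0.3, 0.3])
        )
        assert out.weights[0] > 1 - 1e-10
        np.testing.assert_allclose(out.cell_values, m.values[0], atol=1e-8)

    def test_all_zero_profile_is_degenerate_input(self):
        m = lognorm_matrix([[1.0, 2.0]])
        with pytest.raises(DegenerateInputError):
            iterate_once(m, m.values[0], 2.0, workspace=StubWorkspace([0.0]))

    def test_weight_conservation(self, benchmark_prepared, benchmark_workspace):
        metagene = benchmark_prepared.values[:25].mean(axis=0)
        out = iterate_once(
            benchmark_prepared, metagene, 3.0, workspace=benchmark_workspace
        )
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out.weights >= 0)


class TestRunAttractor:
    def test_unknown_seed_gene_rejected(self, small_planted):
        prepared, _ = small_planted
        with pytest.raises(KeyError, match="NOT_THERE"):
            run_attractor(prepared, "NOT_THERE")

    def test_counts_matrix_rejected(self):
        m = ExpressionMatrix(["g"], ["c1", "c2"], [[1, 2]], layer="counts")
        with pytest.raises(ValueError, match="log-normalized"):
            run_attractor(m, "g")

    def test_recovers_planted_module_on_small_instance(self, small_planted):
        prepared, truth = small_planted
        module = set(truth.module_gene_ids[0])
        res = run_attractor(prepared, truth.module_gene_ids[0][0])
        assert res.status == "converged"
        assert len(set(res.top_genes(20)) & module) >= 18

    def test_ranked_genes_sorted_and_bounded(self, benchmark_result):
        js = [j for _, j in benchmark_result.ranked_genes]
        assert all(0.0 <= j <= 1.0 for j in js)
        assert all(a >= b for a, b in zip(js, js[1:]))

    def test_deterministic_across_repeat_runs(self, small_planted):
        prepared, truth = small_planted
        seed = truth.module_gene_ids[0][0]
        r1 = run_attractor(prepared, seed)
        r2 = run_attractor(prepared, seed)
        assert r1.ranked_genes == r2.ranked_genes
        assert (r1.status, r1.final_exponent, r1.iterations) == (
            r2.status, r2.final_exponent, r2.iterations,
        )

    def test_fixed_point_of_converged_result(
        self, benchmark_prepared, benchmark_workspace, benchmark_result
    ):
        """One extra iteration must leave the converged top-K set unchanged."""
        res = benchmark_result
        assert res.status == "converged"
        cfg = AttractorConfig()
        before = set(res.top_genes(cfg.top_k))
        profile = benchmark_workspace.profile(res.metagene_cell_values)
        order = sorted(
            range(benchmark_prepared.n_genes),
            key=lambda i: (-profile[i], benchmark_prepared.gene_ids[i]),
        )
        after = {benchmark_prepared.gene_ids[i] for i in order[: cfg.top_k]}
        assert after == before

    def test_seed_robustness_across_top_ranked_genes(
        self, benchmark_prepared, benchmark_workspace, benchmark_result
    ):
        cfg = AttractorConfig()
        base = set(benchmark_result.top_genes(cfg.top_k))
        for gene in benchmark_result.top_genes(5):
            res = run_attractor(benchmark_prepared, gene, cfg, benchmark_workspace)
            top = set(res.top_genes(cfg.top_k))
            assert len(base & top) / len(base | top) >= 0.9

    def test_cell_permutation_leaves_ranking_invariant(self):
        spec = dataclasses.replace(default_benchmark_spec(), n_cells=200)
        matrix, truth = simulate(spec)
        prepared = filter_genes(normalize_log(matrix), 0.02)
        seed = truth.module_gene_ids[0][0]
        r1 = run_attractor(prepared, seed)
        perm = np.random.default_rng(3).permutation(prepared.n_cells)
        shuffled = ExpressionMatrix(
            prepared.gene_ids,
            [prepared.cell_ids[i] for i in perm],
            prepared.values[:, perm],
            layer="lognorm",
        )
        r2 = run_attractor(shuffled, seed)
        assert [g for g, _ in r1.ranked_genes] == [g for g, _ in r2.ranked_genes]
        np.testing.assert_allclose(
            [j for _, j in r1.ranked_genes],
            [j for _, j in r2.ranked_genes],
            atol=1e-9,
        )

    def test_noise_matrix_never_yields_a_strong_converged_signature(self):
        spec = dataclasses.replace(
            default_benchmark_spec(),
            module_sizes=(),
            population_fractions=(),
            rng_seed=2,
        )
        matrix, _ = simulate(spec)
        prepared = filter_genes(normalize_log(matrix), 0.02)
        from scattractor.association import AssociationWorkspace

        ws = AssociationWorkspace(prepared)
        for seed in prepared.gene_ids[:3]:
            res = run_attractor(prepared, seed, workspace=ws)
            strong = signature_strength(res) > 0.5
            assert not (res.status == "converged" and strong)
            assert res.status in {"degenerate", "oscillating", "max_iter", "converged"}


class TestScanAttractors:
    def test_two_disjoint_modules_give_two_attractors(self, two_module_scan):
        results, truth, _ = two_module_scan
        assert len(results) == 2
        recovered = [set(r.top_genes(30)) for r in results]
        modules = [set(m) for m in truth.module_gene_ids]
        hits = {
            i: max(range(2), key=lambda m: len(recovered[i] & modules[m]))
            for i in range(2)
        }
        assert set(hits.values()) == {0, 1}
        for i, m in hits.items():
            assert len(recovered[i] & modules[m]) >= 27

    def test_seeds_within_one_module_deduplicate_to_one(
        self, benchmark_prepared, benchmark_truth
    ):
        seeds = GeneList("module", benchmark_truth.module_gene_ids[0][:8])
        results = scan_attractors(benchmark_prepared, seed_set=seeds)
        assert len(results) == 1

    def test_results_sorted_by_strength(self, two_module_scan):
        results, _, cfg = two_module_scan
        strengths = [signature_strength(r, cfg.min_support) for r in results]
        assert strengths == sorted(strengths, reverse=True)

    def test_empty_seed_set_warns_and_returns_empty(self, small_planted):
        prepared, _ = small_planted
        with pytest.warns(UserWarning, match="empty seed set"):
            out = scan_attractors(
                prepared, seed_set=GeneList("none", ("ABSENT_GENE",))
            )
        assert out == []
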