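# scattractor

Attractor metagene co-expression signatures for single-cell RNA-seq.

Dissociated-tissue scRNA-seq routinely contains stromal progenitor
populations — such as the APOD+DCN+LUM+ adipose stromal cell /
fibro-adipogenic progenitor (ASC/FAP) population of the stromal vascular
fraction — whose identity is better captured by a *co-expression
signature* than by cluster boundaries. `scattractor` finds such
signatures without clustering: starting from a seed gene, it converges to
the ranked gene list at the core of a co-expression pattern, compares
independently derived per-sample lists, tests gene-list overlaps, and
scores cells to estimate how abundant the signature-positive population
is.

## The algorithm

For genes *i* with expression vectors *x<sub>i</sub>* (log-normalized,
over cells) and a metagene *m*, define the association

> J(x, m) = I(x, m) / min(I(x, x), I(m, m)),

where I is plug-in mutual information under B-spline soft binning
(B = 6 bins, order 3), so J(x, x) = 1, and J is set to 0 for negatively
correlated pairs. The attractor iteration is

> w<sub>i</sub> ∝ J(x<sub>i</sub>, m)<sup>a</sup>,  Σ w<sub>i</sub> = 1  →  m′ = Σ<sub>i</sub> w<sub>i</sub> x<sub>i</sub>

starting from the mean expression of the seed's most-associated genes.
The exponent *a* is chosen adaptively from a grid (2–10): among exponents
whose iteration converges (the top-K gene set is identical between
successive iterations) without collapsing onto a single gene, the one
maximizing the J of the rank-10 gene — the strength of the signature's
core — is kept. The converged ranked gene list is the signature.

Supporting computations:

- **Consensus ranking** of per-sample signatures: genes ordered by the
  number of samples placing them in the top k, then by median rank
  (absence penalized as k + 1).
- **Hypergeometric overlap test** of two gene lists against a background
  universe, computed in log space so p-values of order 10⁻³⁰ are exact.
- **Signature scoring**: per-cell mean z-score of the signature genes; the
  signature-positive fraction is estimated with a two-component Gaussian
  mixture thresholded at equal posterior probability.
- **Synthetic data**: a negative-binomial simulator with planted
  co-expressed modules carried by latent cell sub-populations, providing
  ground truth for every step.

## Worked example

Recover a planted 30-gene module from the built-in benchmark simulation
(2000 genes × 1000 cells, one module up-regulated 4-fold in 20% of
cells):

```python
from scattractor import (
    default_benchmark_spec, simulate, normalize_log, filter_genes,
    run_attractor, signature_strength, GeneList, score_cells,
    estimate_abundance,
)

matrix, truth = simulate(default_benchmark_spec())
prepared = filter_genes(normalize_log(matrix), min_cell_fraction=0.02)
result = run_attractor(prepared, seed_gene=truth.module_gene_ids[0][0])
print(f"status={result.status}  a*={result.final_exponent}  "
      f"iterations={result.iterations}  strength={signature_strength(result):.3f}")
print("module genes in top 30:",
      len(set(result.top_genes(30)) & set(truth.module_gene_ids[0])), "/ 30")

scored = score_cells(normalize_log(matrix),
                     GeneList("module", truth.module_gene_ids[0]))
abundance = estimate_abundance(scored, method="gmm2")
print(f"threshold={abundance.threshold:.3f}  "
      f"positive_fraction={abundance.positive_fraction:.3f}  (true 0.2)")
```

prints

```
status=converged  a*=2.0  iterations=4  strength=0.274
module genes in top 30: 30 / 30
threshold=0.338  positive_fraction=0.199  (true 0.2)
```

The attractor converged at exponent 2 in four iterations; all 30 planted
module genes occupy the top 30 ranks, and the mixture threshold on the
signature scores recovers the planted 20% sub-population as 19.9% of
cells.

The same pipeline is available from the shell:

```sh
attractor simulate --out sim/
attractor run --matrix sim/ --seed G0000 --out run/
attractor score --matrix sim/ --signature module.txt --out score/
attractor overlap-test --list1 a.txt --list2 b.txt --universe 20000
```

Every output directory contains a `manifest.json` with the resolved
configuration, input checksums and RNG seeds, so any run can be repeated
to byte-identical outputs.

Packaged gene lists (`scattractor.data.load_gene_list`) carry the
ASC/FAP core signature and related published fibroblast marker sets used
in the worked examples; lists suffixed `_synthetic` are reconstructions
that satisfy the documented relationships between the published lists
rather than verbatim figure transcriptions.

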