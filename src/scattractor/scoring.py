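"""Per-cell signature scoring and signature-positive abundance estimation.

A cell's score against a gene signature is the mean of the signature
genes' z-scored log-normalized expression (zero-variance genes contribute
0, so scores stay comparable across matrices). The signature-positive
fraction is estimated either from a fixed threshold or by fitting a
two-component Gaussian mixture to the score distribution and thresholding
at the point of equal posterior probability between the components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .matrix_io import ExpressionMatrix, GeneList

__all__ = ["SignatureScoreResult", "score_cells", "estimate_abundance"]


@dataclass(frozen=True)
class SignatureScoreResult:
    """Per-cell signature scores, optionally with a positivity threshold."""

    cell_ids: tuple[str, ...]
    scores: np.ndarray
    threshold: float | None = None
    positive_fraction: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if len(self.cell_ids) != self.scores.shape[0]:
            raise ValueError("one score per cell required")


def score_cells(matrix: ExpressionMatrix, signature: GeneList) -> SignatureScoreResult:
    """Mean z-score of the signature genes, per cell.

    Signature genes missing from the matrix are dropped with a warning;
    if none is present this is an error. The population mean of the
    scores is ~0 by construction.
    """
    if matrix.layer != "lognorm":
        raise ValueError("score_cells requires a log-normalized matrix")
    gene_set = set(matrix.gene_ids)
    present = [g for g in signature.genes if g in gene_set]
    missing = [g for g in signature.genes if g not in gene_set]
    if not present:
        raise ValueError(
            f"no signature gene present in matrix; missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) not in matrix, dropped: {missing}"
        )
    rows = matrix.values[[matrix.gene_index(g) for g in present]]
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    z = np.divide(rows - mu, sd, out=np.zeros_like(rows), where=sd > 0)
    return SignatureScoreResult(
        cell_ids=tuple(matrix.cell_ids), scores=z.mean(axis=0)
    )


def _equal_posterior_threshold(gmm: GaussianMixture) -> float:
    """Score at which the two fitted components are equally probable,
    searched between the component means."""
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    logw = np.log(gmm.weights_.ravel())
    lo_i, hi_i = np.argsort(means)

    def log_odds(x: float) -> float:
        return (
            logw[hi_i]
            + norm.logpdf(x, means[hi_i], sds[hi_i])
            - logw[lo_i]
            - norm.logpdf(x, means[lo_i], sds[lo_i])
        )

    lo, hi = float(means[lo_i]), float(means[hi_i])
    if lo == hi:
        return lo
    if log_odds(lo) * log_odds(hi) > 0:
        # posteriors never cross between the means (near-degenerate fit)
        return 0.5 * (lo + hi)
    return float(brentq(log_odds, lo, hi))


def estimate_abundance(
    result: SignatureScoreResult,
    method: str = "gmm2",
    fixed_threshold: float | None = None,
    random_state: int = 0,
) -> SignatureScoreResult:
    """Set the positivity threshold and the signature-positive fraction.

    ``gmm2`` fits a two-component 1-D Gaussian mixture (k-means
    initialization, fixed ``random_state``) and thresholds at equal
    posterior between the components; ``fixed`` uses the supplied
    threshold. Cells strictly above the threshold count as positive.
    """
    scores = result.scores
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    elif method == "gmm2":
        if scores.shape[0] < 10:
            raise ValueError(
                "gmm2 needs at least 10 cells; use method='fixed'"
            )
        gmm = GaussianMixture(
            n_components=2, init_params="kmeans", random_state=random_state,
            n_init=3,
        ).fit(scores.reshape(-1, 1))
        threshold = _equal_posterior_threshold(gmm)
    else:
        raise ValueError(f"unknown method {method!r}")
    positive = float(np.mean(scores > threshold))
    return replace(result, threshold=threshold, positive_fraction=positive)
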