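"""Normalized mutual-information association between expression vectors.

The attractor iteration weighs genes by J, a mutual information (MI)
between each gene's expression and the current metagene, normalized so
that self-association equals 1 and (optionally) rectified to zero for
negatively correlated pairs.

Two plug-in estimators are provided:

``bspline``
    Soft binning after Daub et al.: each observation is spread over
    ``num_bins`` B-spline basis functions of order ``spline_order``
    (a partition of unity over the value range), and MI is computed from
    the resulting fractional joint histogram. Default, suited to sparse
    continuous log-normalized data.
``hard_bin``
    Equal-frequency hard binning; for integer vectors with at most
    ``num_bins`` distinct values this reduces to the exact discrete
    plug-in MI, which makes it the testing oracle.

Normalization divides I(x, y) by min(I(x, x), I(y, y)) under the same
estimator, so J(x, x) = 1 by construction for any non-constant vector.
For hard binning the self-information I(x, x) is exactly the plug-in
entropy H(x), recovering the familiar I/min(H(x), H(y)) form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .matrix_io import ExpressionMatrix

__all__ = [
    "AssociationConfig",
    "mutual_information",
    "self_information",
    "normalized_association",
    "association_profile",
    "AssociationWorkspace",
]


@dataclass(frozen=True)
class AssociationConfig:
    """Settings of the association estimator.

    num_bins
        Number of bins B (>= 2). Vectors with fewer distinct values than
        B use one bin per distinct value instead.
    spline_order
        B-spline order k (1 <= k <= B); order 1 degenerates to hard
        binning of the value range. Only used by the ``bspline`` estimator.
    rectify
        Zero out J for pairs with negative Pearson correlation.
    estimator
        ``"bspline"`` or ``"hard_bin"``.
    """

    num_bins: int = 6
    spline_order: int = 3
    rectify: bool = True
    estimator: str = "bspline"

    def __post_init__(self) -> None:
        if self.num_bins < 2:
            raise ValueError("num_bins must be >= 2")
        if self.spline_order < 1 or (
            self.estimator == "bspline" and self.spline_order > self.num_bins
        ):
            raise ValueError("spline_order must be in [1, num_bins]")
        if self.estimator not in ("bspline", "hard_bin"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def _hard_weights(x: np.ndarray, num_bins: int) -> np.ndarray | None:
    """One-hot bin membership under equal-frequency binning.

    Ties at a quantile boundary go to the lower bin. Vectors with at most
    ``num_bins`` distinct values get one bin per distinct value (the
    degenerate-bin rule), which makes the estimator exact for discrete data.
    Returns None for constant vectors.
    """
    uniq, inverse = np.unique(x, return_inverse=True)
    if len(uniq) < 2:
        return None
    if len(uniq) <= num_bins:
        bins = inverse
        n_bins = len(uniq)
    else:
        edges = np.quantile(x, np.arange(1, num_bins) / num_bins)
        bins = np.searchsorted(edges, x, side="left")
        n_bins = num_bins
    w = np.zeros((len(x), n_bins))
    w[np.arange(len(x)), bins] = 1.0
    return w


def _spline_weights(x: np.ndarray, num_bins: int, order: int) -> np.ndarray | None:
    """Fractional bin memberships from a clamped uniform B-spline basis.

    Values are scaled linearly onto the spline domain; the basis is a
    partition of unity, so each row sums to 1. Returns None for constant
    vectors; vectors with fewer distinct values than ``num_bins`` reduce
    the effective bin count to the number of distinct values.
    """
    n_distinct = len(np.unique(x))
    if n_distinct < 2:
        return None
    m = min(num_bins, n_distinct)
    k = min(order, m)
    degree = k - 1
    span = m - degree  # number of knot intervals
    knots = np.concatenate(
        [np.zeros(degree + 1), np.arange(1, span), np.full(degree + 1, span)]
    ).astype(float)
    lo, hi = float(np.min(x)), float(np.max(x))
    z = (np.asarray(x, dtype=float) - lo) / (hi - lo) * span
    z = np.clip(z, 0.0, span)
    return BSpline.design_matrix(z, knots, degree, extrapolate=False).toarray()


def _weights(x: np.ndarray, cfg: AssociationConfig) -> np.ndarray | None:
    if cfg.estimator == "hard_bin":
        return _hard_weights(x, cfg.num_bins)
    return _spline_weights(x, cfg.num_bins, cfg.spline_order)


def _info_from_weights(wx: np.ndarray, wy: np.ndarray) -> float:
    """Plug-in MI (nats) of the fractional joint histogram wx' wy / n."""
    n = wx.shape[0]
    joint = wx.T @ wy / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * (
            np.log(joint) - np.log(px)[:, None] - np.log(py)[None, :]
        )
    return max(float(terms[mask].sum()), 0.0)


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return x, y


def mutual_information(
    x: np.ndarray, y: np.ndarray, cfg: AssociationConfig | None = None
) -> float:
    """Plug-in mutual information I(x, y) in nats, clamped at 0.

    Constant vectors carry no information: I = 0.
    """
    cfg = cfg or AssociationConfig()
    x, y = _check_pair(x, y)
    wx, wy = _weights(x, cfg), _weights(y, cfg)
    if wx is None or wy is None:
        return 0.0
    return _info_from_weights(wx, wy)


def self_information(x: np.ndarray, cfg: AssociationConfig | None = None) -> float:
    """I(x, x); equals the plug-in entropy H(x) under hard binning."""
    cfg = cfg or AssociationConfig()
    x = np.asarray(x, dtype=float).ravel()
    w = _weights(x, cfg)
    if w is None:
        return 0.0
    return _info_from_weights(w, w)


def _pearson_nonneg(x: np.ndarray, y: np.ndarray) -> bool:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc) >= 0.0


def normalized_association(
    x: np.ndarray, y: np.ndarray, cfg: AssociationConfig | None = None
) -> float:
    """Normalized, optionally rectified association J(x, y) in [0, 1]."""
    cfg = cfg or AssociationConfig()
    x, y = _check_pair(x, y)
    if cfg.rectify and not _pearson_nonneg(x, y):
        return 0.0
    wx, wy = _weights(x, cfg), _weights(y, cfg)
    if wx is None or wy is None:
        return 0.0
    denom = min(_info_from_weights(wx, wx), _info_from_weights(wy, wy))
    if denom <= 0.0:
        return 0.0
    return float(np.clip(_info_from_weights(wx, wy) / denom, 0.0, 1.0))


class AssociationWorkspace:
    """Precomputed per-gene binning for repeated profile evaluation.

    The attractor loop evaluates J between every gene and a changing
    metagene many times; the genes' bin-membership weights, marginal
    self-information and centered expression (for the rectification sign)
    depend only on the matrix and are computed once here.
    """

    def __init__(self, matrix: ExpressionMatrix, cfg: AssociationConfig | None = None):
        self.cfg = cfg or AssociationConfig()
        self.matrix = matrix
        g, n = matrix.n_genes, matrix.n_cells
        b = self.cfg.num_bins
        # (g, b, n) layout so the per-iteration joint histogram is one GEMM
        self._gene_weights = np.zeros((g, b, n))
        self.self_info = np.zeros(g)
        for i in range(g):
            w = _weights(matrix.values[i], self.cfg)
            if w is None:
                continue  # constant gene: zero weights force J = 0
            self._gene_weights[i, : w.shape[1], :] = w.T
            self.self_info[i] = _info_from_weights(w, w)
        self._centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
        self._marginals = self._gene_weights.sum(axis=2) / n  # (g, b)

    def profile(self, metagene: np.ndarray) -> np.ndarray:
        """J between every gene and ``metagene`` (length n_cells)."""
        metagene = np.asarray(metagene, dtype=float).ravel()
        n = self.matrix.n_cells
        if metagene.shape[0] != n:
            raise ValueError(
                f"metagene length {metagene.shape[0]} != {n} cells"
            )
        wm = _weights(metagene, self.cfg)
        if wm is None:
            return np.zeros(self.matrix.n_genes)
        self_m = _info_from_weights(wm, wm)
        g, b, _ = self._gene_weights.shape
        joint = (self._gene_weights.reshape(g * b, n) @ wm).reshape(
            g, b, wm.shape[1]
        ) / n
        px = self._marginals[:, :, None]
        py = (wm.sum(axis=0) / n)[None, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * (np.log(joint) - np.log(px) - np.log(py))
        info = np.where(joint > 0, terms, 0.0).sum(axis=(1, 2))
        np.maximum(info, 0.0, out=info)
        denom = np.minimum(self.self_info, self_m)
        j = np.divide(info, denom, out=np.zeros_like(info), where=denom > 0)
        if self.cfg.rectify:
            j[self._centered @ (metagene - metagene.mean()) < 0] = 0.0
        return np.clip(j, 0.0, 1.0)


def association_profile(
    matrix: ExpressionMatrix,
    metagene: np.ndarray,
    cfg: AssociationConfig | None = None,
    workspace: AssociationWorkspace | None = None,
) -> np.ndarray:
    """J between every gene of ``matrix`` and ``metagene``, in gene order.

    Equivalent to calling :func:`normalized_association` per gene; pass a
    prebuilt :class:`AssociationWorkspace` to amortize the per-gene binning
    across repeated calls.
    """
    if workspace is None:
        workspace = AssociationWorkspace(matrix, cfg)
    elif cfg is not None and workspace.cfg != cfg:
        raise ValueError("workspace was built with a different AssociationConfig")
    return workspace.profile(metagene)
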