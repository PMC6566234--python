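"""Histogram-based mutual information between images.

The public :func:`mutual_information` follows the plain joint-histogram
definition: MI = sum p(a,b) ln[ p(a,b) / (p(a) p(b)) ] over a bins x bins
joint histogram of the voxel values inside a mask, with 0*ln(0) = 0.  Values
are binned linearly between the masked 1st and 99th percentiles (values
outside that range fall into the end bins), which makes the metric robust to
a handful of extreme voxels.

Hard binning is the right contract for *evaluating* MI, but it is piecewise
constant under continuous transform parameters, so the registration
optimizers use the same definition with linear partial-volume binning
(:class:`LinearBinner`), which distributes each sample between its two
nearest bin centers and is differentiable almost everywhere.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["mutual_information", "entropy", "histogram_edges", "LinearBinner", "mi_from_joint"]


def histogram_edges(values: np.ndarray, bins: int, plo: float = 1.0, phi: float = 99.0):
    lo, hi = np.percentile(values, [plo, phi])
    if hi <= lo:
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi <= lo:
            hi = lo + 1.0
    return np.linspace(lo, hi, bins + 1)


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def mi_from_joint(p: np.ndarray) -> float:
    """MI in nats from a normalized joint distribution, with 0*ln(0)=0."""
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (pa * pb), 1.0)
        return float(np.sum(np.where(p > 0, p * np.log(ratio), 0.0)))


def _masked_pair(image_a, image_b, mask):
    a = np.asarray(getattr(image_a, "values", image_a), dtype=float).ravel()
    b = np.asarray(getattr(image_b, "values", image_b), dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a common grid")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    return a[keep], b[keep]


def mutual_information(image_a, image_b, bins: int = 32, mask=None) -> float:
    """Mutual information (nats) of two images over a shared sample mask."""
    a, b = _masked_pair(image_a, image_b, mask)
    if a.size < bins:
        raise ValueError(f"only {a.size} defined voxels for {bins} histogram bins")
    ia = _bin_indices(a, histogram_edges(a, bins))
    ib = _bin_indices(b, histogram_edges(b, bins))
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ia, ib), 1.0)
    return mi_from_joint(joint / a.size)


def entropy(image, bins: int = 32, mask=None) -> float:
    """Histogram entropy (nats) under the same binning as mutual_information."""
    a, _ = _masked_pair(image, image, mask)
    if a.size < bins:
        raise ValueError(f"only {a.size} defined voxels for {bins} histogram bins")
    idx = _bin_indices(a, histogram_edges(a, bins))
    counts = np.bincount(idx, minlength=bins).astype(float)
    p = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))


class LinearBinner:
    """Partial-volume (linear) binning onto fixed bin centers.

    Each value contributes linearly to the two bin centers bracketing it;
    values beyond the outermost centers are clipped (zero derivative there).
    """

    def __init__(self, values: np.ndarray, bins: int):
        edges = histogram_edges(np.asarray(values, dtype=float), bins)
        self.bins = bins
        self.lo = float(edges[0])
        self.delta = float(edges[1] - edges[0])

    def weights(self, values: np.ndarray):
        """Return (k0, k1, w0, w1, dw) for each value.

        ``dw`` is d(w1)/d(value) = -d(w0)/d(value); it is zero where the
        value is clipped outside the center range.
        """
        t = (np.asarray(values, dtype=float) - self.lo) / self.delta - 0.5
        inside = (t > 0) & (t < self.bins - 1)
        t = np.clip(t, 0.0, self.bins - 1.0)
        k0 = np.minimum(np.floor(t).astype(int), self.bins - 2)
        f = t - k0
        dw = np.where(inside, 1.0 / self.delta, 0.0)
        return k0, k0 + 1, 1.0 - f, f, dw

    def sparse_weights(self, values: np.ndarray) -> sparse.csr_matrix:
        k0, k1, w0, w1, _ = self.weights(values)
        n = len(k0)
        rows = np.repeat(np.arange(n), 2)
        cols = np.stack([k0, k1], axis=1).ravel()
        vals = np.stack([w0, w1], axis=1).ravel()
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, self.bins))


def soft_mutual_information(a_weights: sparse.csr_matrix, b_weights: sparse.csr_matrix):
    """MI of two soft-binned samples; returns (mi, L) with L the pointwise
    log-ratio table ln(p_jk / (p_j q_k)) used by gradient computations."""
    n = a_weights.shape[0]
    joint = np.asarray((a_weights.T @ b_weights).todense()) / n
    pa = joint.sum(axis=1, keepdims=True)
    qb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(joint > 0, np.log(joint) - np.log(pa * qb + 1e-300), 0.0)
    mi = float(np.sum(joint * L))
    return mi, L
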