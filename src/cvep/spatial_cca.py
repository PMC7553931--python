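"""Canonical correlation analysis and spatial-filter training.

CCA finds weight vectors ``a`` and ``b`` maximizing the Pearson
correlation between the canonical variates ``a'X`` and ``b'Y``;
successive weight pairs maximize the same objective subject to being
uncorrelated with all previous pairs, yielding ``min(m1, m2)``
correlations sorted in descending order.

Spatial filters for c-VEP decoding are the leading left weight vectors
of a CCA between the horizontally concatenated aligned training trials
``[Z_1 ... Z_N]`` and the equally long repetition of their grand average
``[Zbar ... Zbar]``: directions in channel space along which single
trials correlate best with the average evoked response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["CcaResult", "cca", "train_spatial_filters"]

#: relative ridge added to each auto-covariance (guards short buffers)
DEFAULT_REG = 1e-9


@dataclass
class CcaResult:
    """All canonical correlations and the corresponding weight pairs."""

    correlations: np.ndarray      # (d,) descending, in [0, 1]
    x_weights: np.ndarray         # (m1, d), column i pairs with correlations[i]
    y_weights: np.ndarray         # (m2, d)

    @property
    def rho(self) -> float:
        """Maximal (first) canonical correlation."""
        return float(self.correlations[0])


def _whitener(C: np.ndarray, reg: float) -> np.ndarray:
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("zero-variance input: cannot whiten a null covariance")
    Cr = C + (reg * tr / C.shape[0]) * np.eye(C.shape[0])
    vals, vecs = linalg.eigh(Cr)
    vals = np.maximum(vals, np.finfo(float).tiny)
    return (vecs / np.sqrt(vals)) @ vecs.T


def cca(X: np.ndarray, Y: np.ndarray, reg: float = DEFAULT_REG) -> CcaResult:
    """Full CCA between two variables shaped (channels, samples).

    Rows are centred over samples; covariances receive a small relative
    ridge before whitening, and the whitened cross-covariance is
    factored by SVD.  Raises on zero-variance input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    Wx = _whitener(Cxx, reg)
    Wy = _whitener(Cyy, reg)
    U, svals, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    d = min(X.shape[0], Y.shape[0])
    return CcaResult(
        correlations=np.clip(svals[:d], 0.0, 1.0),
        x_weights=Wx @ U[:, :d],
        y_weights=Wy @ Vt.T[:, :d],
    )


def train_spatial_filters(
    aligned: np.ndarray,
    grand_avg: np.ndarray,
    s: int,
) -> "tuple[np.ndarray, CcaResult]":
    """CCA spatial-filter ensemble from aligned trials and their average.

    Concatenates the N aligned trials into ``[Z_1 ... Z_N]`` and matches
    them against N repetitions of the grand average; the first *s* left
    weight vectors are the spatial filters (returned as an (m, s)
    matrix, together with the full CCA result whose leading correlation
    feeds the filter-bank weighting).
    """
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3:
        raise ValueError("aligned trials must be an (N, m, n) array")
    N, m, n = aligned.shape
    if not 1 <= s <= m:
        raise ValueError(f"s={s} must be between 1 and the channel count {m}")
    X_tilde = aligned.transpose(1, 0, 2).reshape(m, N * n)
    Y_tilde = np.tile(grand_avg, (1, N))
    res = cca(X_tilde, Y_tilde)
    if s > res.correlations.size:
        raise ValueError(f"only {res.correlations.size} canonical variates available")
    return res.x_weights[:, :s].copy(), res
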