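"""Sub-band decomposition and individualized band weighting.

Ongoing EEG rhythms — most prominently occipital alpha (8–12 Hz) — overlap
spectrally with the code-locked evoked response and can dominate broadband
correlation scores.  Decomposing the signal into nested sub-bands
(alpha+beta+gamma, beta+gamma, gamma) and weighting each band by how well
the evoked response is expressed in it lets the classifier down-weight
bands that a given subject's background activity contaminates.

The per-band weight is ``a_j = rho_j / sum_j rho_j`` where ``rho_j`` is the
maximal canonical correlation obtained from the training data filtered to
band *j*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "DEFAULT_BANDS",
    "FilterBank",
    "design_filter_bank",
    "apply_subband",
    "compute_band_weights",
]

#: (low, high) cut-off frequencies in Hz of the three default sub-bands.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((8.0, 60.0), (12.0, 60.0), (30.0, 60.0))

#: Band-pass order of the Butterworth designs (overall order, i.e. 8 poles).
DEFAULT_ORDER = 8


@dataclass
class FilterBank:
    """Butterworth band-pass bank with optional fitted band weights."""

    bands: tuple[tuple[float, float], ...]
    order: int
    sampling_rate: float
    sos: list[np.ndarray] = field(repr=False)
    #: per-band maximal canonical correlation from training (set by fitting)
    rhos: np.ndarray | None = None
    #: per-band combination weights, non-negative, summing to 1
    weights: np.ndarray | None = None

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def set_rhos(self, rhos: np.ndarray) -> None:
        rhos = np.asarray(rhos, dtype=float)
        if rhos.shape != (self.n_bands,):
            raise ValueError(f"expected {self.n_bands} band correlations, got {rhos.shape}")
        self.rhos = rhos
        self.weights = compute_band_weights(rhos)


def design_filter_bank(
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    order: int = DEFAULT_ORDER,
    sampling_rate: float = 600.0,
) -> FilterBank:
    """Design one stable Butterworth band-pass per band.

    *order* is the order of the resulting band-pass filter (an order-8
    band-pass has 8 poles, i.e. 4 second-order sections).
    """
    if order < 2 or order % 2:
        raise ValueError("band-pass order must be an even integer >= 2")
    nyq = sampling_rate / 2.0
    sos_list: list[np.ndarray] = []
    for low, high in bands:
        if not (0.0 < low < high < nyq):
            raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
        sos = sps.butter(order // 2, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
        if not np.all(np.abs(np.linalg.eigvals(_sos_to_state(sos))) < 1.0):
            raise ValueError(f"unstable filter design for band ({low}, {high}) Hz")
        sos_list.append(sos)
    return FilterBank(bands=tuple(tuple(b) for b in bands), order=order,
                      sampling_rate=sampling_rate, sos=sos_list)


def _sos_to_state(sos: np.ndarray) -> np.ndarray:
    b, a = sps.sos2tf(sos)
    # companion matrix of the denominator; eigenvalues are the poles
    a = a / a[0]
    n = len(a) - 1
    m = np.zeros((n, n))
    m[0, :] = -a[1:]
    m[1:, :-1] = np.eye(n - 1)
    return m


def apply_subband(x: np.ndarray, bank: FilterBank, j: int, zero_phase: bool = True) -> np.ndarray:
    """Filter a channels x samples array with sub-band *j* of the bank.

    Zero-phase (forward-backward) filtering is the default so that
    templates and decoding buffers stay phase-aligned; a causal variant is
    available for strictly online processing.
    """
    if not 0 <= j < bank.n_bands:
        raise IndexError(f"band index {j} outside 0..{bank.n_bands - 1}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sos = bank.sos[j]
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[1] <= padlen:
        raise ValueError(
            f"signal of {x.shape[1]} samples is too short for the filter warm-up ({padlen})"
        )
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=1)
    return sps.sosfilt(sos, x, axis=1)


def compute_band_weights(rhos: np.ndarray) -> np.ndarray:
    """Normalize per-band canonical correlations into combination weights.

    ``a_j = rho_j / sum(rho)``; scale-invariant and permutation-equivariant.
    """
    rhos = np.asarray(rhos, dtype=float)
    if np.any(rhos < 0):
        raise ValueError("band correlations must be non-negative")
    total = rhos.sum()
    if total <= 0:
        raise ValueError("all band correlations are zero; weights are degenerate")
    return rhos / total
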