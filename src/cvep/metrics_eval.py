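"""Performance metrics and the offline cross-validation harness.

Accuracy is the fraction of correct selections.  The information
transfer rate (Wolpaw ITR) in bit/min is

    B_m = [log2 K + p log2 p + (1 - p) log2((1 - p)/(K - 1))] / (t / 60)

with K classes, accuracy p and mean selection time t seconds (the
selection time includes the 1 s gaze shift).  Output characters per
minute (OCM) divides the length of the final correct text by the total
spelling time, assuming all errors are corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .codebook import CodeBook
from .decoder import MIN_WINDOW_S
from .model import CvepDecoder, DEFAULT_S
from .synth_eeg import GAZE_SHIFT_S, TrialSet

__all__ = ["SessionMetrics", "CvReport", "accuracy", "itr", "ocm",
           "session_metrics", "crossvalidate_offline"]


@dataclass
class SessionMetrics:
    """Headline numbers of one decoded spelling session."""

    p: float            # selection accuracy
    t: float            # mean selection time, s (incl. gaze shift)
    itr: float          # bit/min
    ocm: float          # output characters per minute
    K: int
    n_selections: int
    n_chars: int


def accuracy(selection_log: "list") -> float:
    """Fraction of correct selections in a log.

    Accepts booleans or objects with a truthy ``correct`` attribute.
    """
    if len(selection_log) == 0:
        raise ValueError("empty selection log")
    flags = [bool(getattr(e, "correct", e)) for e in selection_log]
    return float(np.mean(flags))


def itr(p: float, K: int, t: float) -> float:
    """Wolpaw information transfer rate in bit/min.

    The ``0 * log2(0)`` terms are taken as 0.  The formula's bracket is
    convex with its minimum of 0 exactly at chance level, so accuracies
    below 1/K would yield spuriously positive rates; they are reported
    as 0 with a warning instead.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if K < 2:
        raise ValueError("ITR needs at least 2 classes")
    if t <= 0:
        raise ValueError("selection time must be positive")
    if p < 1.0 / K:
        warnings.warn("accuracy below chance level; ITR clamped to 0", stacklevel=2)
        return 0.0
    bits = np.log2(K)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (K - 1))
    return float(max(bits, 0.0) / (t / 60.0))


def ocm(n_chars: int, total_time_min: float) -> float:
    """Output characters per minute of the final correct text."""
    if total_time_min <= 0:
        raise ValueError("spelling time must be positive")
    return n_chars / total_time_min


def session_metrics(
    selection_log: "list",
    selection_times: "list[float]",
    K: int,
    n_chars: int,
) -> SessionMetrics:
    """Bundle accuracy, mean selection time, ITR and OCM for a session."""
    p = accuracy(selection_log)
    t = float(np.mean(selection_times))
    total_min = float(np.sum(selection_times)) / 60.0
    return SessionMetrics(p=p, t=t, itr=itr(p, K, t), ocm=ocm(n_chars, total_min),
                          K=K, n_selections=len(selection_log), n_chars=n_chars)


@dataclass
class CvReport:
    """Cross-validated window sweep for one method / channel subset."""

    windows: np.ndarray           # seconds
    accuracy: np.ndarray          # mean over folds, per window
    itr: np.ndarray               # bit/min, t = window + gaze shift
    fold_accuracy: np.ndarray     # (folds, windows)
    folds: int
    method: str
    channel_subset: "list[int] | None"
    seed: int


def crossvalidate_offline(
    trials: TrialSet,
    codebook: CodeBook,
    windows: "list[float]",
    folds: int = 4,
    channel_subset: "list[int] | None" = None,
    method: str = "filterbank",
    seed: int = 0,
    s: int = DEFAULT_S,
) -> CvReport:
    """Stratified k-fold window sweep with synchronous (beta = 0) scoring.

    Per fold a decoder is trained on the training split (rows restricted
    to *channel_subset* first, if given) and the held-out trials are
    classified truncated to each window; accuracies are averaged across
    folds and converted to ITR with t = window + 1 s gaze shift.
    ``method`` selects the filter-bank decoder or the standard
    single-band one.
    """
    if method not in ("standard", "filterbank"):
        raise ValueError("method must be 'standard' or 'filterbank'")
    data = trials if channel_subset is None else trials.select_channels(channel_subset)
    fs = data.sampling_rate
    windows = np.asarray(sorted(windows), dtype=float)
    n = data.n
    for w in windows:
        n_w = int(round(w * fs))
        if n_w > n:
            raise ValueError(f"window {w} s exceeds the trial length {n / fs} s")
        if n_w < int(round(MIN_WINDOW_S * fs)):
            raise ValueError(f"window {w} s is below the minimum window {MIN_WINDOW_S} s")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = np.zeros((folds, windows.size))
    for f, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(data.N), data.labels)):
        train = TrialSet(data.trials[tr_idx], data.labels[tr_idx], fs)
        res = CvepDecoder(train, codebook, s=min(s, data.m),
                          filterbank=(method == "filterbank")).fit()
        for wi, w in enumerate(windows):
            pred = res.predict(TrialSet(data.trials[te_idx], data.labels[te_idx], fs),
                               window=float(w))
            fold_acc[f, wi] = np.mean(pred == data.labels[te_idx])
    mean_acc = fold_acc.mean(axis=0)
    itrs = np.array([itr(p, codebook.K, w + GAZE_SHIFT_S)
                     for p, w in zip(mean_acc, windows)])
    return CvReport(windows=windows, accuracy=mean_acc, itr=itrs,
                    fold_accuracy=fold_acc, folds=folds, method=method,
                    channel_subset=list(channel_subset) if channel_subset is not None else None,
                    seed=seed)
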