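"""Synchronous and asynchronous target identification.

Correlation scores between the accumulating data buffer and per-target
references (the first ``n_y`` columns of each template) are computed per
sub-band on the spatially filtered signals and combined with the
individualized band weights.  The classification candidate is the
argmax of the combined scores; in asynchronous mode a selection is only
emitted once the margin between the highest and second-highest score
strictly exceeds the threshold ``beta``, which supports a non-control
state on data that matches no template.

The dynamic-window mechanics follow the reference protocol: data arrive
in 0.05 s blocks (30 samples at 600 Hz), classification starts at
0.25 s (150 samples), the window extends until the template length
(1260 samples) and then shuffles out the first half (630 samples, one
stimulation cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filterbank import apply_subband
from .model import CvepDecoderResults
from .spatial_cca import cca
from .synth_eeg import GAZE_SHIFT_S, OnlineStream

__all__ = [
    "Decision",
    "DecoderState",
    "SelectionEvent",
    "SessionResult",
    "correlation_scores",
    "classify_window",
    "run_session",
    "BLOCK_S",
    "MIN_WINDOW_S",
]

#: classification thread period, seconds (one data block)
BLOCK_S = 0.05
#: shortest classified window, seconds
MIN_WINDOW_S = 0.25
#: give-up dwell per intent, seconds
MAX_DWELL_S = 10.0


@dataclass
class Decision:
    """One classification outcome."""

    target: int                 # 1-based candidate index C
    scores: np.ndarray          # combined lambda_1..lambda_K
    margin: float               # lambda_(1) - lambda_(2)
    window_used: float          # classified window length, seconds
    elapsed: float = 0.0        # stimulation time consumed before the decision


def _score_pair(P: np.ndarray, R: np.ndarray, method: str) -> float:
    if method == "pearson":
        p = (P - P.mean(axis=1, keepdims=True)).ravel()
        r = (R - R.mean(axis=1, keepdims=True)).ravel()
        denom = np.linalg.norm(p) * np.linalg.norm(r)
        if denom == 0:
            raise ValueError("zero-variance input in correlation score")
        return float(abs(p @ r) / denom)
    return cca(P, R).rho


def correlation_scores(buffer: np.ndarray, model: CvepDecoderResults) -> np.ndarray:
    """Combined per-target correlation scores for a channels x n_y buffer.

    Per sub-band j the buffer is band-pass filtered, projected through
    the s spatial filters, and correlated with the equally projected
    first ``n_y`` columns of each template; the per-band scores are
    combined as ``lambda_k = sum_j a_j * lambda_k^(j)``.  Scores are
    invariant to the sign of any spatial filter.
    """
    buffer = np.atleast_2d(np.asarray(buffer, dtype=float))
    n_y = buffer.shape[1]
    min_window = int(round(MIN_WINDOW_S * model.sampling_rate))
    if n_y < min_window:
        raise ValueError(f"buffer of {n_y} samples is below the minimum window {min_window}")
    if n_y > model.n:
        raise ValueError(f"buffer of {n_y} samples exceeds the template length {model.n}")
    if not np.any(buffer):
        raise ValueError("all-zero buffer has no variance to correlate")
    scores = np.zeros(model.K)
    for j, (bm, a_j) in enumerate(zip(model.band_models, model.bank.weights)):
        if a_j == 0.0:
            continue
        filtered = apply_subband(buffer, model.bank, j)
        P = bm.filters.T @ filtered
        for k in range(model.K):
            R = bm.projected[k][:, :n_y]
            scores[k] += a_j * _score_pair(P, R, model.score_method)
    return scores


def classify_window(buffer: np.ndarray, model: CvepDecoderResults) -> Decision:
    """Synchronous classification of a fixed window (no threshold, beta = 0).

    Ties resolve to the lowest class index (argmax convention).
    """
    scores = correlation_scores(buffer, model)
    order = np.sort(scores)[::-1]
    margin = float(order[0] - order[1]) if scores.size > 1 else float(order[0])
    return Decision(
        target=int(np.argmax(scores)) + 1,
        scores=scores,
        margin=margin,
        window_used=buffer.shape[1] / model.sampling_rate,
    )


@dataclass
class DecoderState:
    """Accumulating buffer implementing the dynamic-window mechanics."""

    model: CvepDecoderResults
    beta: float | None = None
    buffer: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    blocks_consumed: int = 0

    def __post_init__(self) -> None:
        if self.beta is None:
            self.beta = self.model.beta
        fs = self.model.sampling_rate
        self.n_a = int(round(BLOCK_S * fs))
        self.min_window = int(round(MIN_WINDOW_S * fs))
        self.n_max = self.model.n
        if (self.n_max // 2) % self.n_a:
            raise ValueError(
                f"block size {self.n_a} must divide half the template length {self.n_max // 2}"
            )
        self.clear()

    @property
    def n_y(self) -> int:
        return self.buffer.shape[1]

    def clear(self) -> None:
        self.buffer = np.empty((self.model.band_models[0].filters.shape[0], 0))
        self.blocks_consumed = 0

    def push_block(self, block: np.ndarray) -> Decision | None:
        """Append one 0.05 s block; classify; emit on margin > beta.

        The window extends while ``n_y < n``; at ``n_y = n`` the first
        n/2 columns are shuffled out before the new block is appended.
        On an emitted decision the buffer is cleared.
        """
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape != (self.buffer.shape[0], self.n_a):
            raise ValueError(
                f"block must be {self.buffer.shape[0]} x {self.n_a}, got {block.shape}"
            )
        if self.n_y == self.n_max:
            self.buffer = self.buffer[:, self.n_max // 2:]
        self.buffer = np.hstack([self.buffer, block])
        self.blocks_consumed += 1
        if self.n_y < self.min_window:
            return None
        decision = classify_window(self.buffer, self.model)
        decision.elapsed = self.blocks_consumed * self.n_a / self.model.sampling_rate
        if decision.margin > self.beta:
            self.clear()
            return decision
        return None


@dataclass
class SelectionEvent:
    """One intent period of an online session."""

    intended: int
    decision: Decision | None      # None if the dwell cap expired (timeout)
    correct: bool | None
    selection_time: float | None   # stimulation time + gaze shift, seconds


@dataclass
class SessionResult:
    events: "list[SelectionEvent]"

    @property
    def decisions(self) -> "list[Decision]":
        return [e.decision for e in self.events if e.decision is not None]

    @property
    def n_timeouts(self) -> int:
        return sum(1 for e in self.events if e.decision is None)


def run_session(
    stream: OnlineStream,
    model: CvepDecoderResults,
    beta: float | None = None,
    gaze_shift: float = GAZE_SHIFT_S,
    max_dwell: float = MAX_DWELL_S,
) -> SessionResult:
    """Asynchronously decode an online stream intent by intent.

    For every logged intent segment, 0.05 s blocks are fed to a fresh
    buffer until a selection is emitted or the dwell cap expires; the
    flicker-free pause after each segment is skipped, and the selection
    time is the consumed stimulation time plus the gaze shift.
    """
    if abs(stream.sampling_rate - model.sampling_rate) > 1e-9:
        raise ValueError("stream and model sampling rates differ")
    state = DecoderState(model, beta=beta)
    events: list[SelectionEvent] = []
    for seg in stream.intent_log:
        state.clear()
        data = stream.samples[:, seg.onset: seg.onset + seg.n_samples]
        n_blocks = min(data.shape[1], int(round(max_dwell * model.sampling_rate))) // state.n_a
        decision = None
        for b in range(n_blocks):
            block = data[:, b * state.n_a: (b + 1) * state.n_a]
            decision = state.push_block(block)
            if decision is not None:
                break
        if decision is None:
            events.append(SelectionEvent(intended=seg.target, decision=None,
                                         correct=None, selection_time=None))
        else:
            events.append(SelectionEvent(
                intended=seg.target, decision=decision,
                correct=decision.target == seg.target,
                selection_time=decision.elapsed + gaze_shift,
            ))
    return SessionResult(events=events)
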