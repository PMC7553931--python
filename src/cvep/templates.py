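"""Phase alignment of training trials and class-template construction.

All targets flicker with circular shifts of one base code, so their
evoked responses are circular sample-shifts of a single underlying
response.  Training trials are therefore rotated back to bit-shift 0,
averaged into a grand-average response, and per-class templates are
recovered by rotating the average forward by each target's bit-shift.
Shifts are applied within each stimulation cycle so cycle boundaries
stay aligned for multi-cycle trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codebook import CodeBook
from .synth_eeg import TrialSet

__all__ = ["TemplateSet", "cyclic_shift", "align_trials", "grand_average", "make_class_templates"]


def cyclic_shift(x: np.ndarray, samples: int, cycle_samples: int) -> np.ndarray:
    """Roll the columns of each cycle-length block of *x* by *samples*.

    Positive *samples* delays the pattern (right shift).  The trial
    length must be a whole number of cycles.
    """
    x = np.asarray(x)
    m, n = x.shape
    if n % cycle_samples:
        raise ValueError(f"trial length {n} is not a multiple of the cycle length {cycle_samples}")
    cycles = n // cycle_samples
    blocks = x.reshape(m, cycles, cycle_samples)
    return np.roll(blocks, samples, axis=2).reshape(m, n)


def align_trials(trials: TrialSet, codebook: CodeBook) -> np.ndarray:
    """Rotate every trial back to the phase of target 1 (bit-shift 0).

    A trial of target k, whose code is the base left-shifted by
    ``shifts[k]`` bits (pattern advanced), is delayed by
    ``shifts[k] * samples_per_bit`` samples within each cycle.
    Returns an (N, m, n) array of aligned trials.
    """
    spb = codebook.samples_per_bit(trials.sampling_rate)
    n_cyc = codebook.cycle_samples(trials.sampling_rate)
    aligned = np.empty_like(trials.trials)
    for i, (z, k) in enumerate(zip(trials.trials, trials.labels)):
        if not 1 <= k <= codebook.K:
            raise ValueError(f"label {k} outside 1..{codebook.K}")
        aligned[i] = cyclic_shift(z, codebook.shifts[k - 1] * spb, n_cyc)
    return aligned


def grand_average(aligned: "np.ndarray | list[np.ndarray]") -> np.ndarray:
    """Element-wise mean of phase-aligned trials."""
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3 or aligned.shape[0] == 0:
        raise ValueError("need a non-empty list of equally shaped trials")
    return aligned.mean(axis=0)


@dataclass
class TemplateSet:
    """Grand-average response and its per-class circular shifts."""

    grand_avg: np.ndarray
    class_templates: "list[np.ndarray]"
    samples_per_bit: int
    codebook: CodeBook

    @property
    def n(self) -> int:
        return self.grand_avg.shape[1]

    def template(self, k: int) -> np.ndarray:
        """Template of 1-based target k."""
        return self.class_templates[k - 1]


def make_class_templates(
    grand_avg: np.ndarray,
    codebook: CodeBook,
    samples_per_bit: int,
) -> TemplateSet:
    """Rotate the grand average into one template per target.

    Target k's code is the base advanced by ``shifts[k]`` bits, so its
    template is the grand average advanced (left-rotated) by
    ``shifts[k] * samples_per_bit`` samples within each cycle; target 1
    keeps the grand average unchanged.
    """
    n_cyc = codebook.code_length * samples_per_bit
    templates = [
        cyclic_shift(grand_avg, -shift * samples_per_bit, n_cyc)
        for shift in codebook.shifts
    ]
    return TemplateSet(grand_avg=np.asarray(grand_avg, dtype=float),
                       class_templates=templates,
                       samples_per_bit=samples_per_bit, codebook=codebook)
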