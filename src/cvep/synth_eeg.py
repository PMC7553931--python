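"""Synthetic multichannel EEG with code-locked evoked responses.

The generator emulates the statistical structure the c-VEP decoder relies
on, at the reference recording conditions: 32 channels sampled at 600 Hz,
a 63-bit code updated at 60 Hz (10 samples per bit, 630 samples per
1.05 s cycle), 2.1 s training trials and continuous online streams with
1 s flicker-free pauses.

Model
-----
Each '1' bit of the flicker code elicits a stereotyped evoked transient
(a damped ~100 ms oscillation), circularly wrapped within the stimulation
cycle and spatially projected through a fixed occipitally-weighted
topography.  Because the per-target codes are circular shifts of one
base sequence, the noise-free responses of different targets are exact
circular sample-shifts of each other — the property the template-shifting
classifier exploits.  Background activity is spatially mixed pink (1/f)
noise band-limited to 2–100 Hz, plus an amplitude-modulated 10 Hz alpha
contaminant on occipitally-weighted channels.  The signal-to-noise ratio
is defined as evoked RMS over noise RMS on the channel where the evoked
response is strongest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .codebook import CodeBook, upsample_code

__all__ = [
    "ForwardModel",
    "TrialSet",
    "OnlineStream",
    "make_forward_model",
    "simulate_trial",
    "simulate_noise",
    "simulate_training_set",
    "simulate_online_stream",
]

#: default duration of the evoked kernel, seconds
KERNEL_DURATION = 0.1
#: gaze-shift / inter-trial pause of the reference protocol, seconds
GAZE_SHIFT_S = 1.0


@dataclass(frozen=True)
class ForwardModel:
    """Fixed generative model mapping a flicker code to multichannel EEG."""

    m: int
    sampling_rate: float
    snr: float
    alpha_amp: float
    seed: int
    kernel: np.ndarray = field(repr=False)
    mixing: np.ndarray = field(repr=False)
    noise_mixing: np.ndarray = field(repr=False)
    alpha_mixing: np.ndarray = field(repr=False)


@dataclass
class TrialSet:
    """Labelled training trials, shaped (N, channels, samples)."""

    trials: np.ndarray
    labels: np.ndarray  # 1-based target indices
    sampling_rate: float

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be a (N, channels, samples) array")
        if self.labels.shape != (self.trials.shape[0],):
            raise ValueError("one label per trial required")

    @property
    def N(self) -> int:
        return self.trials.shape[0]

    @property
    def m(self) -> int:
        return self.trials.shape[1]

    @property
    def n(self) -> int:
        return self.trials.shape[2]

    def select_channels(self, channels: "list[int] | np.ndarray") -> "TrialSet":
        return TrialSet(self.trials[:, np.asarray(channels, dtype=int), :],
                        self.labels.copy(), self.sampling_rate)


@dataclass(frozen=True)
class IntentSegment:
    onset: int          # sample index of stimulation onset
    target: int         # 1-based intended target
    n_samples: int      # stimulation samples available for this intent
    pause_samples: int  # flicker-free samples following the segment


@dataclass
class OnlineStream:
    """Continuous recording with a log of intent segments and pauses."""

    samples: np.ndarray  # channels x time
    intent_log: list[IntentSegment]
    sampling_rate: float


def make_forward_model(
    m: int = 32,
    sampling_rate: float = 600.0,
    snr: float = 1.0,
    alpha_amp: float = 0.5,
    seed: int = 0,
) -> ForwardModel:
    """Build a deterministic forward model.

    Parameters mirror the reference recording setup (32 channels at
    600 Hz).  ``snr`` is the evoked/noise RMS ratio on the strongest
    evoked channel; ``alpha_amp`` scales the 8–12 Hz contaminant relative
    to the broadband noise; ``snr = numpy.inf`` yields noise-free data.
    """
    if m < 1 or sampling_rate <= 0 or snr <= 0 or alpha_amp < 0:
        raise ValueError("model parameters must be positive (alpha_amp >= 0)")
    rng = np.random.default_rng(seed)

    t = np.arange(int(round(KERNEL_DURATION * sampling_rate))) / sampling_rate
    kernel = np.exp(-t / 0.02) * np.sin(2 * np.pi * 20.0 * t)
    peak = np.max(np.abs(kernel))
    kernel = kernel / peak if peak > 0 else kernel

    def occipital_profile() -> np.ndarray:
        # later channel indices play the occipital electrodes
        base = np.exp(-np.arange(m)[::-1] / max(m / 4.0, 1.0))
        jitter = 1.0 + 0.1 * rng.standard_normal(m)
        w = np.abs(base * jitter)
        return w / np.linalg.norm(w)

    mixing = occipital_profile()
    alpha_mixing = occipital_profile()
    noise_mixing = np.eye(m) + 0.5 * rng.standard_normal((m, m)) / np.sqrt(m)

    return ForwardModel(
        m=m, sampling_rate=sampling_rate, snr=float(snr), alpha_amp=float(alpha_amp),
        seed=seed, kernel=kernel, mixing=mixing, noise_mixing=noise_mixing,
        alpha_mixing=alpha_mixing,
    )


def _cycle_response(model: ForwardModel, codebook: CodeBook) -> np.ndarray:
    """Single-cycle evoked time course for the unshifted base code."""
    spb = codebook.samples_per_bit(model.sampling_rate)
    up = np.asarray(upsample_code(codebook.base, model.sampling_rate, codebook.update_rate))
    n_cycle = up.size
    impulses = np.zeros(n_cycle)
    onsets = np.flatnonzero(np.array(list(codebook.base), dtype=int)) * spb
    impulses[onsets] = 1.0
    k = np.zeros(n_cycle)
    k[: model.kernel.size] = model.kernel
    # circular convolution keeps targets as exact circular shifts
    return np.real(np.fft.ifft(np.fft.fft(impulses) * np.fft.fft(k)))


def _evoked(model: ForwardModel, codebook: CodeBook, target: int, cycles: int) -> np.ndarray:
    if not 1 <= target <= codebook.K:
        raise IndexError(f"target {target} outside 1..{codebook.K}")
    spb = codebook.samples_per_bit(model.sampling_rate)
    cyc = _cycle_response(model, codebook)
    shifted = np.roll(cyc, -codebook.shifts[target - 1] * spb)
    course = np.tile(shifted, cycles)
    return np.outer(model.mixing, course)


def _pink_noise(rng: np.random.Generator, m: int, n: int, sampling_rate: float) -> np.ndarray:
    """Spatially mixed 1/f noise band-limited to 2–100 Hz, unit mean RMS."""
    white = rng.standard_normal((m, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n, axis=1)
    high = min(100.0, 0.45 * sampling_rate)
    sos = sps.butter(4, [2.0, high], btype="bandpass", fs=sampling_rate, output="sos")
    pink = sps.sosfiltfilt(sos, pink, axis=1)
    rms = np.sqrt(np.mean(pink**2))
    return pink / rms if rms > 0 else pink


def _noise_segment(model: ForwardModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Background EEG (pink noise + alpha contaminant), unscaled."""
    noise = model.noise_mixing @ _pink_noise(rng, model.m, n, model.sampling_rate)
    if model.alpha_amp > 0:
        t = np.arange(n) / model.sampling_rate
        phase = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
        wave = envelope * np.sin(2 * np.pi * 10.0 * t + phase)
        wave = wave / np.sqrt(np.mean(wave**2))
        noise = noise + model.alpha_amp * np.outer(model.alpha_mixing, wave)
    return noise


def _noise_scale(model: ForwardModel, codebook: CodeBook) -> float:
    """Noise scaling that realises the requested SNR on the strongest channel."""
    if np.isinf(model.snr):
        return 0.0
    ch = int(np.argmax(np.abs(model.mixing)))
    evoked_rms = np.sqrt(np.mean(_cycle_response(model, codebook) ** 2)) * abs(model.mixing[ch])
    # expected noise RMS on that channel from the mixing geometry
    probe = np.random.default_rng(model.seed)
    seg = _noise_segment(model, 4 * codebook.cycle_samples(model.sampling_rate), probe)
    noise_rms = np.sqrt(np.mean(seg[ch] ** 2))
    return evoked_rms / (model.snr * noise_rms) if noise_rms > 0 else 0.0


def simulate_noise(model: ForwardModel, n_samples: int, seed: int = 0) -> np.ndarray:
    """Noise-only EEG segment (what the decoder sees in non-control periods)."""
    rng = np.random.default_rng(seed)
    return _noise_segment(model, n_samples, rng)


def simulate_trial(
    model: ForwardModel,
    codebook: CodeBook,
    target: int,
    cycles: int = 2,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One code-locked trial: evoked response + scaled background noise.

    With the reference protocol (2 cycles, 600 Hz) the output has 1260
    columns.  Trials of different targets at infinite SNR are exact
    circular sample-shifts of one another.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    evoked = _evoked(model, codebook, target, cycles)
    scale = _noise_scale(model, codebook)
    if scale == 0.0:
        return evoked
    if rng is None:
        rng = np.random.default_rng(seed)
    return evoked + scale * _noise_segment(model, evoked.shape[1], rng)


def simulate_training_set(
    model: ForwardModel,
    codebook: CodeBook,
    n_b: int,
    seed: int = 0,
    cycles: int = 2,
) -> TrialSet:
    """Simulate the block-structured training protocol.

    Each of ``n_b`` blocks records one trial per target in target order,
    giving ``N = n_b * K`` labelled trials (128 for the 32-target
    protocol with 4 blocks, 24 for the 4-target protocol with 6 blocks).
    """
    if n_b < 1:
        raise ValueError("n_b must be >= 1")
    rng = np.random.default_rng(seed)
    trials, labels = [], []
    for _ in range(n_b):
        for k in range(1, codebook.K + 1):
            trials.append(simulate_trial(model, codebook, k, cycles=cycles, rng=rng))
            labels.append(k)
    return TrialSet(np.stack(trials), np.array(labels), model.sampling_rate)


def simulate_online_stream(
    model: ForwardModel,
    codebook: CodeBook,
    intents: "list[int]",
    seed: int = 0,
    max_duration: float = 6.3,
    pause: float = GAZE_SHIFT_S,
) -> OnlineStream:
    """Continuous stream: per intent, code-locked stimulation followed by a pause.

    Each intent segment carries up to ``max_duration`` seconds of
    stimulation (the decoder stops consuming it once it emits a
    selection) and is followed by ``pause`` seconds of noise-only data,
    emulating the flicker-free gaze-shifting phase.
    """
    if not intents:
        raise ValueError("at least one intent required")
    rng = np.random.default_rng(seed)
    fs = model.sampling_rate
    scale = _noise_scale(model, codebook)
    pieces: list[np.ndarray] = []
    log: list[IntentSegment] = []
    cursor = 0
    n_pause = int(round(pause * fs))
    for target in intents:
        n_cyc = codebook.cycle_samples(fs)
        cycles = max(1, int(np.ceil(max_duration * fs / n_cyc)))
        evoked = _evoked(model, codebook, target, cycles)[:, : int(round(max_duration * fs))]
        seg = evoked + (scale * _noise_segment(model, evoked.shape[1], rng) if scale else 0.0)
        log.append(IntentSegment(onset=cursor, target=target,
                                 n_samples=seg.shape[1], pause_samples=n_pause))
        pieces.append(seg)
        cursor += seg.shape[1]
        if n_pause:
            pieces.append(scale * _noise_segment(model, n_pause, rng)
                          if scale else np.zeros((model.m, n_pause)))
            cursor += n_pause
    return OnlineStream(samples=np.hstack(pieces), intent_log=log, sampling_rate=fs)
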