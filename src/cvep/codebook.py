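"""Circular-shift m-sequence codebooks for c-VEP stimulation.

A c-VEP speller drives every target with the same pseudorandom binary
flicker sequence, offset by a target-specific circular bit-shift.  The
near-ideal two-valued circular autocorrelation of an m-sequence makes the
shifted copies maximally distinguishable, so a single evoked-response
template, rotated by the known shift, serves as the matched reference for
every target.

The bundled 63-bit m-sequence (:data:`DEFAULT_MSEQUENCE`) is updated at
60 Hz, giving a stimulus cycle of 63/60 = 1.05 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DEFAULT_MSEQUENCE",
    "CodeBook",
    "rotate_left",
    "build_codebook",
    "code_cycle_duration",
    "upsample_code",
]

#: 63-bit maximal-length sequence used as the base flicker code
#: (balanced: 32 ones, 31 zeros).
DEFAULT_MSEQUENCE = "101011001101110110100100111000101111001010001100001000001111110"

#: Stimulus update rate of the reference protocol, in Hz.
DEFAULT_UPDATE_RATE = 60.0


def _check_binary(seq: str) -> None:
    if not seq:
        raise ValueError("code sequence must be non-empty")
    if set(seq) - {"0", "1"}:
        raise ValueError(
            f"code sequence contains non-binary characters: {sorted(set(seq) - {'0', '1'})}"
        )


def rotate_left(seq: str, bits: int) -> str:
    """Circularly rotate a bit string *seq* left by *bits* positions.

    Rotation is modulo the sequence length, so ``rotate_left(s, len(s))``
    is the identity.
    """
    _check_binary(seq)
    if bits < 0:
        raise ValueError("rotation must be non-negative")
    k = bits % len(seq)
    return seq[k:] + seq[:k]


@dataclass(frozen=True)
class CodeBook:
    """A set of circularly shifted flicker codes, one per target.

    Target ``k`` (1-based) flickers with ``base`` rotated left by
    ``(k - 1) * shift_step`` bits; target 1 always uses the unshifted base.
    """

    base: str
    K: int
    shift_step: int
    update_rate: float = DEFAULT_UPDATE_RATE
    codes: tuple[str, ...] = field(init=False)
    shifts: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        _check_binary(self.base)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.shift_step < 0:
            raise ValueError("shift_step must be >= 0")
        if self.update_rate <= 0:
            raise ValueError("update_rate must be positive")
        shifts = tuple((k * self.shift_step) % len(self.base) for k in range(self.K))
        codes = tuple(rotate_left(self.base, s) for s in shifts)
        if len(set(codes)) != self.K:
            raise ValueError(
                f"shift collision: {self.K} targets with step {self.shift_step} "
                f"do not yield pairwise distinct codes of length {len(self.base)}"
            )
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "shifts", shifts)

    @property
    def code_length(self) -> int:
        """Number of bits per stimulation cycle."""
        return len(self.base)

    def samples_per_bit(self, sampling_rate: float) -> int:
        """EEG samples covering one stimulus bit at *sampling_rate*."""
        ratio = sampling_rate / self.update_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"sampling rate {sampling_rate} not divisible by update rate {self.update_rate}"
            )
        return int(round(ratio))

    def cycle_samples(self, sampling_rate: float) -> int:
        """EEG samples covering one full stimulation cycle."""
        return self.code_length * self.samples_per_bit(sampling_rate)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "base": self.base,
                "K": self.K,
                "shift_step": self.shift_step,
                "update_rate": self.update_rate,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "CodeBook":
        d = json.loads(doc)
        return cls(
            base=d["base"],
            K=int(d["K"]),
            shift_step=int(d["shift_step"]),
            update_rate=float(d["update_rate"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "CodeBook":
        return cls.from_json(Path(path).read_text())


def build_codebook(
    base: str,
    K: int,
    shift_step: int,
    update_rate: float = DEFAULT_UPDATE_RATE,
) -> CodeBook:
    """Construct the codebook: target k uses ``rotate_left(base, (k-1)*shift_step)``."""
    if shift_step * (K - 1) >= len(base) and K > 1:
        raise ValueError(
            f"shift_step*(K-1) = {shift_step * (K - 1)} must stay below the "
            f"code length {len(base)} for distinct codes"
        )
    return CodeBook(base=base, K=K, shift_step=shift_step, update_rate=update_rate)


def default_codebook(K: int) -> CodeBook:
    """Reference-protocol codebook: 2-bit steps for 32 targets, 4-bit for 4."""
    if K == 32:
        return build_codebook(DEFAULT_MSEQUENCE, 32, 2)
    if K == 4:
        return build_codebook(DEFAULT_MSEQUENCE, 4, 4)
    raise ValueError("default codebooks exist for K=4 and K=32 only")


def code_cycle_duration(codebook: CodeBook) -> float:
    """Duration of one stimulation cycle in seconds (L / update rate)."""
    return codebook.code_length / codebook.update_rate


def upsample_code(code: str, sampling_rate: float, update_rate: float) -> "list[int]":
    """Replicate each bit ``sampling_rate / update_rate`` times.

    Maps a bit sequence onto the EEG sampling grid; with the reference
    rates (600 Hz / 60 Hz) each bit covers 10 samples, so the 63-bit code
    spans 630 samples per cycle.
    """
    _check_binary(code)
    ratio = sampling_rate / update_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sampling rate {sampling_rate} not divisible by update rate {update_rate}"
        )
    r = int(round(ratio))
    out: list[int] = []
    for ch in code:
        out.extend([int(ch)] * r)
    return out
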