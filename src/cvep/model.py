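"""Trained c-VEP decoder: model object, fitting, and results container.

The estimation follows a matched-template scheme.  Per frequency
sub-band, training trials are band-pass filtered, circularly aligned to
bit-shift 0, and averaged; per-class templates are circular shifts of
the average; an ensemble of ``s`` CCA spatial filters maps the channel
space onto directions where single trials best match the average.  The
leading canonical correlation of each sub-band, measured on the training
data itself, sets the band combination weights
``a_j = rho_j / sum(rho)`` — bands in which the evoked response is
poorly expressed (e.g. because of strong intrinsic alpha activity)
contribute less to the classification score.

Usage::

    model = CvepDecoder(trials, codebook)      # filter-bank method
    res = model.fit()                          # -> CvepDecoderResults
    print(res.summary())
    labels = res.predict(test_trials)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codebook import CodeBook
from .filterbank import DEFAULT_BANDS, DEFAULT_ORDER, FilterBank, apply_subband, design_filter_bank
from .spatial_cca import train_spatial_filters
from .synth_eeg import TrialSet
from .templates import TemplateSet, align_trials, grand_average, make_class_templates

__all__ = ["CvepDecoder", "CvepDecoderResults", "BandModel", "train_decoder_model",
           "DEFAULT_S", "default_beta"]

#: number of canonical variates kept as spatial filters
DEFAULT_S = 4

#: single band used by the standard (no filter-bank) method
STANDARD_BANDS: tuple[tuple[float, float], ...] = ((8.0, 60.0),)


def default_beta(K: int) -> float:
    """Reference-protocol decision thresholds: 0.15 for 4 targets, 0.1 for 32."""
    return 0.15 if K <= 4 else 0.1


@dataclass
class BandModel:
    """Spatial filters and templates for one sub-band."""

    filters: np.ndarray              # (m, s)
    templates: TemplateSet
    rho: float                       # leading canonical correlation on training data
    projected: np.ndarray = field(repr=False)  # (K, s, n) filtered-projected templates


class CvepDecoder:
    """c-VEP decoder model specification bound to training data.

    Parameters
    ----------
    trials : TrialSet
        Labelled training trials, every target represented.
    codebook : CodeBook
        Circular-shift code set driving the stimulation.
    bands, order :
        Filter-bank design; pass ``filterbank=False`` for the standard
        single-band method.
    s : int
        Number of CCA spatial filters in the ensemble.
    beta : float, optional
        Asynchronous decision threshold; defaults to the reference
        protocol value for the codebook's target count.
    score_method : {"cca", "pearson"}
        Correlation operator comparing the filtered buffer with a
        reference: leading canonical correlation of the two stacked
        s-variate signals (default), or Pearson correlation of the
        flattened projections.
    """

    def __init__(
        self,
        trials: TrialSet,
        codebook: CodeBook,
        bands: "tuple[tuple[float, float], ...]" = DEFAULT_BANDS,
        order: int = DEFAULT_ORDER,
        s: int = DEFAULT_S,
        beta: float | None = None,
        score_method: str = "cca",
        filterbank: bool = True,
    ) -> None:
        missing = set(range(1, codebook.K + 1)) - set(int(k) for k in trials.labels)
        if missing:
            raise ValueError(f"training data misses target classes {sorted(missing)}")
        if score_method not in ("cca", "pearson"):
            raise ValueError("score_method must be 'cca' or 'pearson'")
        self.trials = trials
        self.codebook = codebook
        self.bands = tuple(bands) if filterbank else STANDARD_BANDS
        self.order = order
        self.s = s
        self.beta = default_beta(codebook.K) if beta is None else float(beta)
        self.score_method = score_method

    def fit(self) -> "CvepDecoderResults":
        """Estimate per-band templates, spatial filters, and band weights."""
        fs = self.trials.sampling_rate
        bank = design_filter_bank(self.bands, self.order, fs)
        spb = self.codebook.samples_per_bit(fs)
        band_models: list[BandModel] = []
        rhos = []
        for j in range(bank.n_bands):
            filtered = TrialSet(
                np.stack([apply_subband(z, bank, j) for z in self.trials.trials]),
                self.trials.labels, fs,
            )
            aligned = align_trials(filtered, self.codebook)
            zbar = grand_average(aligned)
            tset = make_class_templates(zbar, self.codebook, spb)
            W, cres = train_spatial_filters(aligned, zbar, self.s)
            projected = np.stack([W.T @ X for X in tset.class_templates])
            band_models.append(BandModel(filters=W, templates=tset,
                                         rho=cres.rho, projected=projected))
            rhos.append(cres.rho)
        bank.set_rhos(np.array(rhos))
        return CvepDecoderResults(
            codebook=self.codebook, bank=bank, band_models=band_models,
            s=self.s, beta=self.beta, sampling_rate=fs,
            score_method=self.score_method, n_trials=self.trials.N,
            n_channels=self.trials.m,
        )


@dataclass
class CvepDecoderResults:
    """Fitted c-VEP decoder: everything needed to classify new data."""

    codebook: CodeBook
    bank: FilterBank
    band_models: "list[BandModel]"
    s: int
    beta: float
    sampling_rate: float
    score_method: str = "cca"
    n_trials: int = 0
    n_channels: int = 0

    @property
    def K(self) -> int:
        return self.codebook.K

    @property
    def n(self) -> int:
        """Template length in samples."""
        return self.band_models[0].templates.n

    # -- classification (delegates to the decoder module) --------------

    def correlation_scores(self, buffer: np.ndarray) -> np.ndarray:
        from .decoder import correlation_scores
        return correlation_scores(buffer, self)

    def classify(self, buffer: np.ndarray):
        from .decoder import classify_window
        return classify_window(buffer, self)

    def predict(self, trials: "TrialSet | np.ndarray", window: float | None = None) -> np.ndarray:
        """Synchronously classify trials, optionally truncated to *window* seconds."""
        arrs = trials.trials if isinstance(trials, TrialSet) else np.asarray(trials)
        if window is not None:
            n_w = int(round(window * self.sampling_rate))
            arrs = arrs[..., :n_w]
        return np.array([self.classify(z).target for z in arrs])

    # -- persistence ----------------------------------------------------

    def save(self, path: "str | Path") -> None:
        from .io import save_model
        save_model(self, path)

    @classmethod
    def load(cls, path: "str | Path") -> "CvepDecoderResults":
        from .io import load_model
        return load_model(path)

    def summary(self) -> str:
        """Human-readable account of the fitted decoder."""
        lines = [
            "c-VEP decoder (CCA spatial-filter ensemble)",
            "=" * 46,
            f"targets (K):            {self.K}",
            f"code length / step:     {self.codebook.code_length} bits / "
            f"{self.codebook.shift_step} bits",
            f"sampling rate:          {self.sampling_rate:g} Hz",
            f"template length:        {self.n} samples",
            f"training trials:        {self.n_trials}",
            f"channels:               {self.n_channels}",
            f"spatial filters (s):    {self.s}",
            f"threshold (beta):       {self.beta:g}",
            f"score method:           {self.score_method}",
            "",
            f"{'band (Hz)':>12} {'rho':>8} {'weight':>8}",
        ]
        for (low, high), bm, w in zip(self.bank.bands, self.band_models, self.bank.weights):
            lines.append(f"{f'{low:g}-{high:g}':>12} {bm.rho:8.4f} {w:8.4f}")
        return "\n".join(lines)


def train_decoder_model(
    trials: TrialSet,
    codebook: CodeBook,
    bank: FilterBank | None = None,
    s: int = DEFAULT_S,
    beta: float | None = None,
    **kwargs,
) -> CvepDecoderResults:
    """Functional wrapper: build and fit a :class:`CvepDecoder`."""
    if bank is not None:
        kwargs.setdefault("bands", bank.bands)
        kwargs.setdefault("order", bank.order)
    return CvepDecoder(trials, codebook, s=s, beta=beta, **kwargs).fit()
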