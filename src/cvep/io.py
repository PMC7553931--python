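"""Containers and readers: HDF5 trial sets, trained models, streams, EDF.

HDF5 schemas
------------
Trial set:  datasets ``/trials`` (N x channels x samples) and
``/labels`` (N, 1-based), attribute ``sampling_rate``.

Trained model: attributes (sampling_rate, s, beta, score_method, order,
codebook JSON, score bookkeeping), datasets ``/bands``, ``/rhos``,
``/weights``, and per sub-band groups ``/band{j}`` holding ``filters``
and ``grand_average``; class templates are deterministic circular
shifts of the grand average and are rebuilt on load.

Stream: dataset ``/samples`` plus the intent log as parallel arrays.

EDF recordings are ingested read-only through mne.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .codebook import CodeBook
from .filterbank import design_filter_bank
from .model import BandModel, CvepDecoderResults
from .synth_eeg import IntentSegment, OnlineStream, TrialSet
from .templates import make_class_templates

__all__ = [
    "write_trialset", "read_trialset", "write_trialset_csv", "read_trialset_csv",
    "save_model", "load_model", "write_stream", "read_stream", "read_edf",
]


def write_trialset(trials: TrialSet, path: "str | Path") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=trials.trials)
        f.create_dataset("labels", data=trials.labels)
        f.attrs["sampling_rate"] = trials.sampling_rate


def read_trialset(path: "str | Path") -> TrialSet:
    with h5py.File(path, "r") as f:
        for name in ("trials", "labels"):
            if name not in f:
                raise ValueError(f"malformed trial container: missing dataset '{name}'")
        if "sampling_rate" not in f.attrs:
            raise ValueError("malformed trial container: missing attribute 'sampling_rate'")
        return TrialSet(f["trials"][()], f["labels"][()], float(f.attrs["sampling_rate"]))


def write_trialset_csv(trials: TrialSet, path: "str | Path") -> None:
    """Delimited-text export: one row per (trial, channel) with full precision."""
    N, m, n = trials.trials.shape
    df = pd.DataFrame(trials.trials.reshape(N * m, n))
    df.insert(0, "channel", np.tile(np.arange(m), N))
    df.insert(0, "label", np.repeat(trials.labels, m))
    df.insert(0, "trial", np.repeat(np.arange(N), m))
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={trials.sampling_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trialset_csv(path: "str | Path") -> TrialSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sampling_rate="):
            raise ValueError("malformed CSV export: missing sampling_rate header")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    n_trials = df["trial"].nunique()
    m = df["channel"].nunique()
    samples = df.drop(columns=["trial", "label", "channel"]).to_numpy()
    labels = df.groupby("trial", sort=True)["label"].first().to_numpy()
    return TrialSet(samples.reshape(n_trials, m, -1), labels, fs)


def save_model(res: CvepDecoderResults, path: "str | Path") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = res.sampling_rate
        f.attrs["s"] = res.s
        f.attrs["beta"] = res.beta
        f.attrs["order"] = res.bank.order
        f.attrs["score_method"] = res.score_method
        f.attrs["codebook"] = res.codebook.to_json()
        f.attrs["n_trials"] = res.n_trials
        f.attrs["n_channels"] = res.n_channels
        f.create_dataset("bands", data=np.asarray(res.bank.bands, dtype=float))
        f.create_dataset("rhos", data=res.bank.rhos)
        f.create_dataset("weights", data=res.bank.weights)
        for j, bm in enumerate(res.band_models):
            g = f.create_group(f"band{j}")
            g.create_dataset("filters", data=bm.filters)
            g.create_dataset("grand_average", data=bm.templates.grand_avg)


def load_model(path: "str | Path") -> CvepDecoderResults:
    with h5py.File(path, "r") as f:
        codebook = CodeBook.from_json(f.attrs["codebook"])
        fs = float(f.attrs["sampling_rate"])
        bands = tuple(tuple(b) for b in f["bands"][()])
        bank = design_filter_bank(bands, int(f.attrs["order"]), fs)
        bank.set_rhos(f["rhos"][()])
        spb = codebook.samples_per_bit(fs)
        band_models = []
        for j in range(len(bands)):
            g = f[f"band{j}"]
            W = g["filters"][()]
            tset = make_class_templates(g["grand_average"][()], codebook, spb)
            projected = np.stack([W.T @ X for X in tset.class_templates])
            band_models.append(BandModel(filters=W, templates=tset,
                                         rho=float(f["rhos"][j]), projected=projected))
        return CvepDecoderResults(
            codebook=codebook, bank=bank, band_models=band_models,
            s=int(f.attrs["s"]), beta=float(f.attrs["beta"]), sampling_rate=fs,
            score_method=str(f.attrs["score_method"]),
            n_trials=int(f.attrs["n_trials"]), n_channels=int(f.attrs["n_channels"]),
        )


def write_stream(stream: OnlineStream, path: "str | Path") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=stream.samples)
        f.attrs["sampling_rate"] = stream.sampling_rate
        f.create_dataset("intent_onsets", data=[s.onset for s in stream.intent_log])
        f.create_dataset("intent_targets", data=[s.target for s in stream.intent_log])
        f.create_dataset("intent_nsamples", data=[s.n_samples for s in stream.intent_log])
        f.create_dataset("intent_pauses", data=[s.pause_samples for s in stream.intent_log])


def read_stream(path: "str | Path") -> OnlineStream:
    with h5py.File(path, "r") as f:
        log = [
            IntentSegment(onset=int(o), target=int(t), n_samples=int(ns), pause_samples=int(p))
            for o, t, ns, p in zip(f["intent_onsets"][()], f["intent_targets"][()],
                                   f["intent_nsamples"][()], f["intent_pauses"][()])
        ]
        return OnlineStream(samples=f["samples"][()], intent_log=log,
                            sampling_rate=float(f.attrs["sampling_rate"]))


def _edf_header_rates(path: "str | Path") -> "dict[str, int]":
    """Per-signal samples-per-record from the ASCII EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode().strip())
        sig = fh.read(ns * 256)
    labels = [sig[16 * i: 16 * (i + 1)].decode().strip() for i in range(ns)]
    off = ns * 216  # label/transducer/dim/phys+dig ranges/prefilter precede n_samps
    n_samps = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode().strip()) for i in range(ns)]
    return dict(zip(labels, n_samps))


def read_edf(path: "str | Path", channels: "list[str] | None" = None):
    """Read a continuous EDF recording; returns (channels x samples, rate).

    Raises if a requested channel is absent or if the requested channels
    are stored at different sampling rates (resample before ingestion).
    """
    import mne

    rates = _edf_header_rates(path)
    rates.pop("EDF Annotations", None)
    wanted = channels if channels is not None else list(rates)
    missing = set(wanted) - set(rates)
    if missing:
        raise ValueError(f"channels not present in EDF file: {sorted(missing)}")
    if len({rates[ch] for ch in wanted}) > 1:
        raise ValueError("requested EDF channels have multiple sampling rates; "
                         "resample the recording first")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    raw.pick(wanted)
    return raw.get_data(), float(raw.info["sfreq"])
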