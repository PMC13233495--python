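"""Internal array store and EDF reading.

The native on-disk format is a directory with ``.npy`` arrays plus a
``meta.json`` sidecar (rate, labels, annotations, axes).  EDF recordings can
be imported through MNE when it is installed; the store is the format the
pipeline itself writes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .multiway import NPLSModel
from .preprocess import EpochSet
from .spectral import FeatureTensor
from .synth import ContinuousEEG, Segment

__all__ = [
    "save_continuous", "load_continuous",
    "save_epochs", "load_epochs",
    "save_tensor", "load_tensor",
    "save_model", "load_model",
    "save_segments", "load_segments",
    "read_edf",
]


def _write_meta(path: Path, meta: dict) -> None:
    path.mkdir(parents=True, exist_ok=True)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _read_meta(path: Path) -> dict:
    return json.loads((Path(path) / "meta.json").read_text())


def save_continuous(eeg: ContinuousEEG, path) -> None:
    path = Path(path)
    _write_meta(path, {
        "kind": "continuous",
        "rate": eeg.rate,
        "channel_labels": list(eeg.channel_labels),
        "annotations": [[o, d, lb] for o, d, lb in eeg.annotations],
    })
    np.save(path / "signal.npy", eeg.signal)


def load_continuous(path) -> ContinuousEEG:
    path = Path(path)
    meta = _read_meta(path)
    sig = np.load(path / "signal.npy")
    anns = [(float(o), float(d), str(lb)) for o, d, lb in meta["annotations"]]
    return ContinuousEEG(sig, meta["rate"], tuple(meta["channel_labels"]), anns)


def save_segments(segments: list[Segment], path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "segments.json").write_text(json.dumps(
        [[s.kind, s.onset, s.duration] for s in segments]))


def load_segments(path) -> list[Segment]:
    raw = json.loads((Path(path) / "segments.json").read_text())
    return [Segment(kind, float(onset), float(dur)) for kind, onset, dur in raw]


def save_epochs(epochs: EpochSet, path) -> None:
    path = Path(path)
    _write_meta(path, {
        "kind": "epochs",
        "rate": epochs.rate,
        "epoch_length": epochs.epoch_length,
        "step": epochs.step,
        "channel_labels": list(epochs.channel_labels),
    })
    np.save(path / "data.npy", epochs.data)
    np.save(path / "onsets.npy", epochs.epoch_onsets)
    np.save(path / "labels.npy", epochs.labels.astype(str))
    np.save(path / "flags.npy", epochs.channel_flags)


def load_epochs(path) -> EpochSet:
    path = Path(path)
    meta = _read_meta(path)
    return EpochSet(np.load(path / "data.npy"), meta["rate"],
                    np.load(path / "onsets.npy"), meta["epoch_length"],
                    meta["step"],
                    np.load(path / "labels.npy").astype(object),
                    tuple(meta["channel_labels"]),
                    np.load(path / "flags.npy"))


def save_tensor(tensor: FeatureTensor, path) -> None:
    path = Path(path)
    _write_meta(path, {
        "kind": "feature_tensor",
        "component": tensor.component,
        "channel_labels": list(tensor.channel_labels),
    })
    np.save(path / "values.npy", tensor.values)
    np.save(path / "freqs.npy", tensor.freqs)
    np.save(path / "epoch_labels.npy", tensor.epoch_labels.astype(str))


def load_tensor(path) -> FeatureTensor:
    path = Path(path)
    meta = _read_meta(path)
    return FeatureTensor(np.load(path / "values.npy"), np.load(path / "freqs.npy"),
                         tuple(meta["channel_labels"]),
                         np.load(path / "epoch_labels.npy").astype(object),
                         meta["component"])


def save_model(model: NPLSModel, path, provenance: dict | None = None) -> None:
    """Serialize an N-PLS model: array bundle plus JSON metadata.

    The bulky training residuals ``E`` and ``C`` are diagnostics and are not
    persisted; ``H`` is kept because factor-subset prediction needs it.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "model.npz",
             freq_weights=model.freq_weights, spatial_weights=model.spatial_weights,
             T=model.T, U=model.U, q=model.q, B=model.B,
             x_mean=model.x_mean, H=model.H, freqs=model.freqs)
    meta = {"kind": "npls_model", "n_factors": model.n_factors,
            "y_mean": model.y_mean,
            "channel_labels": list(model.channel_labels or ()),
            "provenance": provenance or {}}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> NPLSModel:
    path = Path(path)
    meta = _read_meta(path)
    z = np.load(path / "model.npz")
    return NPLSModel(n_factors=meta["n_factors"], freq_weights=z["freq_weights"],
                     spatial_weights=z["spatial_weights"], T=z["T"], U=z["U"],
                     q=z["q"], B=z["B"], x_mean=z["x_mean"],
                     y_mean=meta["y_mean"], H=z["H"], freqs=z["freqs"],
                     channel_labels=tuple(meta["channel_labels"]))


def read_edf(path) -> ContinuousEEG:
    """Load an EDF recording (microvolts) via MNE."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sig = raw.get_data() * 1e6  # volts -> microvolts
    anns = [(float(a["onset"]), float(a["duration"]), str(a["description"]))
            for a in raw.annotations]
    return ContinuousEEG(sig, float(raw.info["sfreq"]),
                         tuple(raw.ch_names), anns)
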