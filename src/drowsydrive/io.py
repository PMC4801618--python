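"""File formats: delimited recordings with key-value sidecars, dictionaries, tables.

Recordings are written as tab-separated text (a time column in seconds plus
one amplitude column per channel) with a ``<name>.meta`` sidecar holding
``key = value`` lines for the rate, device mode, channel list and optional
per-second labels.  Learned dictionaries go to NumPy ``.npz`` with a JSON
text header alongside.  Feature and prediction tables are plain TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sparse import ClassDictionary
from .synthetic import EEGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_dictionary",
    "read_dictionary",
    "write_predictions",
    "read_labels",
    "write_manifest",
]


def write_recording(rec: EEGRecording, path) -> Path:
    """Write a recording as TSV plus a ``.meta`` sidecar; returns the data path."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    t = np.arange(rec.n_samples) / rec.fs
    table = pd.DataFrame({"time_s": t})
    for name, row in zip(rec.channels, rec.data):
        table[name] = row
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "fs": rec.fs,
        "device": rec.device,
        "channels": ",".join(rec.channels),
    }
    if rec.labels is not None:
        meta["labels"] = ",".join(rec.labels)
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text("".join(f"{k} = {v}\n" for k, v in meta.items()))
    return path


def read_recording(path) -> EEGRecording:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    meta = {}
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    channels = tuple(meta["channels"].split(","))
    data = table[list(channels)].to_numpy().T
    labels = np.array(meta["labels"].split(","), dtype="U6") if "labels" in meta else None
    return EEGRecording(data, float(meta["fs"]), channels, meta["device"], labels)


def write_dictionary(dic: ClassDictionary, path) -> Path:
    """Binary atom matrices plus a JSON text header next to them."""
    path = Path(path)
    np.savez(path, atoms_alert=dic.atoms_alert, atoms_drowsy=dic.atoms_drowsy)
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    header = {"p": dic.p, "w": dic.w, "trained": dic.trained,
              "train_meta": _jsonable(dic.train_meta)}
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def read_dictionary(path) -> ClassDictionary:
    path = Path(path)
    arrays = np.load(path)
    header = json.loads(path.with_suffix(".json").read_text())
    return ClassDictionary(arrays["atoms_alert"], arrays["atoms_drowsy"],
                           trained=header.get("trained", False),
                           train_meta=header.get("train_meta", {}))


def write_predictions(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_labels(path) -> np.ndarray:
    """Per-second label stream: one 'alert'/'drowsy' (or 0/1) token per line."""
    path = Path(path)
    labels = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        if tok in ("0", "alert"):
            labels.append("alert")
        elif tok in ("1", "drowsy"):
            labels.append("drowsy")
        else:
            raise ValueError(f"{path}:{lineno}: unrecognized label {tok!r}")
    return np.asarray(labels, dtype="U6")


#: extension point: map a file suffix to a reader returning an EEGRecording,
#: so real-EEG formats (e.g. EDF) can be plugged in without touching the CLI
READERS = {".tsv": read_recording, ".txt": read_recording}


def read_any(path) -> EEGRecording:
    """Dispatch to the reader registered for the file's suffix."""
    path = Path(path)
    try:
        return READERS[path.suffix](path)
    except KeyError:
        raise ValueError(
            f"no reader registered for {path.suffix!r}; known: {sorted(READERS)}"
        ) from None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_manifest(config: dict, path) -> Path:
    """Reproducibility manifest: canonical config, its hash, library versions."""
    import scipy
    import sklearn

    from . import __version__

    payload = _jsonable(config)
    blob = json.dumps(payload, sort_keys=True).encode()
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "drowsydrive": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1))
    return path
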