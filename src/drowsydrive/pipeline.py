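"""End-to-end glue: raw recording -> denoise -> downsample -> features -> SRC.

One function pair covers the whole detection path: `train_detector` learns a
per-channel sparse classifier from a labeled session, `detect` replays a
recording through the same preprocessing and returns per-second vigilance
labels and residuals.  The train/test split is by contiguous blocks within
each class — history-averaged features are temporally correlated, so a
random shuffle would leak across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import extract_features
from .preprocessing import denoise_recording, downsample
from .sparse import SparseRepresentationClassifier, accuracy
from .synthetic import EEGRecording

__all__ = [
    "TARGET_FS",
    "preprocess",
    "split_by_class_blocks",
    "train_detector",
    "detect",
    "evaluate_session",
]

#: downsampling target per device mode
TARGET_FS = {"HBS": 128.0, "BP": 100.0}


def preprocess(rec: EEGRecording) -> EEGRecording:
    """Wavelet-denoise at the native rate, then downsample per device mode."""
    return downsample(denoise_recording(rec), TARGET_FS[rec.device])


def split_by_class_blocks(X: np.ndarray, y: np.ndarray, train_fraction: float = 2.0 / 3.0):
    """Per-class contiguous split: leading fraction trains, trailing third tests."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        cut = int(round(train_fraction * idx.size))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    return (X[train_idx], y[train_idx]), (X[test_idx], y[test_idx])


def train_detector(rec: EEGRecording, channel: str, b: int = 8,
                   n_atoms: int = 50, sparsity: int = 5, n_iter: int = 30,
                   method: str = "ksvd", random_state: int | None = 0,
                   train_fraction: float = 2.0 / 3.0):
    """Train an SRC detector on the leading two-thirds of a labeled session.

    Returns ``(clf, held_out_accuracy_percent)``.
    """
    if rec.labels is None:
        raise ValueError("training requires a labeled recording")
    proc = preprocess(rec)
    times, X = extract_features(proc, channel, b)
    y = proc.labels[times]
    (X_tr, y_tr), (X_te, y_te) = split_by_class_blocks(X, y, train_fraction)
    clf = SparseRepresentationClassifier(
        n_atoms=n_atoms, sparsity=sparsity, n_iter=n_iter,
        method=method, random_state=random_state,
    ).fit(X_tr, y_tr)
    held_out = accuracy(clf.predict(X_te), y_te) if len(y_te) else float("nan")
    return clf, held_out


def detect(rec: EEGRecording, clf, channel: str, b: int = 8) -> pd.DataFrame:
    """Per-second vigilance labels + residuals for one channel of a recording."""
    proc = preprocess(rec)
    times, X = extract_features(proc, channel, b)
    res = clf.predict_residuals(X)
    pred = clf.predict(X)
    frame = pd.DataFrame({
        "t": times, "channel": channel,
        "residual_alert": res[:, 0], "residual_drowsy": res[:, 1],
        "state": pred,
    })
    if rec.labels is not None:
        frame["true_state"] = proc.labels[times]
    return frame


def evaluate_session(rec: EEGRecording, channels=("O1", "O2"), b: int = 8,
                     **train_kwargs) -> dict:
    """Held-out accuracy per channel on one labeled session."""
    return {ch: train_detector(rec, ch, b=b, **train_kwargs)[1] for ch in channels}
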