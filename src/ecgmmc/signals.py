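"""Core signal containers and plain-text I/O.

An :class:`ECGSignal` is a uniformly sampled single-lead voltage trace in
millivolts.  :class:`GroundTruth` carries per-beat landmark indices and AAMI
class labels, and exists so that detectors and feature extractors can be
scored against exactly known fiducial points on synthetic records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ECGSignal", "GroundTruth", "read_signal_csv", "write_signal_csv"]

#: canonical landmark order within one beat
LANDMARKS = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class ECGSignal:
    """Uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    fs : float
        Sampling frequency in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "ECGSignal":
        """Copy of this signal with new sample values (fs, t0 kept)."""
        return ECGSignal(samples=samples, fs=self.fs, t0=self.t0)


@dataclass
class GroundTruth:
    """Exact beat landmarks and class labels for a synthetic record.

    ``landmarks`` is an (n_beats, 5) integer array of sample indices in
    P, Q, R, S, T order; ``labels`` holds one AAMI class symbol
    (N/S/V/F/Q) per beat.
    """

    landmarks: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=int)
        if lm.ndim != 2 or lm.shape[1] != 5:
            raise ValueError("landmarks must be (n_beats, 5)")
        if not np.all(np.diff(lm, axis=1) > 0):
            raise ValueError("landmark order P < Q < R < S < T violated")
        self.landmarks = lm
        if self.labels and len(self.labels) != lm.shape[0]:
            raise ValueError("one label per beat required")

    @property
    def n_beats(self) -> int:
        return self.landmarks.shape[0]

    def landmark(self, name: str) -> np.ndarray:
        """All indices of one landmark type, e.g. ``landmark('R')``."""
        return self.landmarks[:, LANDMARKS.index(name)]


def write_signal_csv(signal: ECGSignal, path: str | Path,
                     truth: GroundTruth | None = None) -> None:
    """Write a 2-column (sample_index, mV) CSV plus a JSON sidecar.

    The sidecar ``<path>.json`` records fs, t0 and, when available, the
    ground-truth landmarks and labels.
    """
    path = Path(path)
    pd.DataFrame({"sample_index": np.arange(len(signal)),
                  "mV": signal.samples}).to_csv(path, index=False)
    meta: dict = {"fs": signal.fs, "t0": signal.t0}
    if truth is not None:
        meta["landmarks"] = {name: truth.landmark(name).tolist()
                             for name in LANDMARKS}
        meta["labels"] = list(truth.labels)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_signal_csv(path: str | Path, fs: float | None = None) -> ECGSignal:
    """Read a (sample_index, mV) CSV; fs from the JSON sidecar unless given."""
    path = Path(path)
    frame = pd.read_csv(path)
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"no sampling frequency: pass fs= or provide {sidecar}")
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
    col = "mV" if "mV" in frame.columns else frame.columns[-1]
    return ECGSignal(samples=frame[col].to_numpy(float), fs=float(fs))
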