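"""Nine time-domain beat features over two succeeding cardiac cycles.

Per beat: the preceding and following RR intervals (RRn, RRn'), the QRS,
PR, QT and ST intervals, and the R, P and T amplitudes above the isoelectric
baseline.  Intervals are in seconds, amplitudes in mV.  The QT interval is
measured Q peak to T peak (consistent with ST = T peak - S); the baseline is
the median of the PR segment (samples between P and Q) of each beat.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import ECGSignal
from .waveform import BeatAnnotation

__all__ = ["FEATURE_COLUMNS", "extract_features", "normalize_features",
           "read_feature_csv", "write_feature_csv"]

log = logging.getLogger(__name__)

#: normative column order for feature tables
FEATURE_COLUMNS = ["RRn", "RRn_prime", "QRSn", "PRn", "QTn", "STn",
                   "Rn", "Pn", "Tn"]


def extract_features(signal: ECGSignal, beats: list[BeatAnnotation],
                     labels: list[str] | None = None) -> pd.DataFrame:
    """Build the n x 9 feature matrix from annotated beats.

    ``beats`` must be ordered by R index (as produced by
    :func:`ecgmmc.waveform.annotate_beats`); consecutive entries supply the
    neighbouring R peaks for the RR intervals, so the first and last beats
    of the list contribute rows only as neighbours.  Beats with missing
    landmarks or non-positive intervals are dropped with a log message.

    Returns a DataFrame with :data:`FEATURE_COLUMNS`, a ``beat_id`` index
    (position of the beat in ``beats``), and a ``label`` column when
    per-beat labels are given.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 annotated beats")
    fs = signal.fs
    x = signal.samples
    rows = []
    ids = []
    kept_labels = []
    for b in range(1, len(beats) - 1):
        prev_r, ann, next_r = beats[b - 1].R, beats[b], beats[b + 1].R
        if not ann.valid or not ann.complete:
            log.info("beat %d skipped: incomplete annotation", b)
            continue
        baseline = float(np.median(x[ann.P: ann.Q + 1]))
        vec = {
            "RRn": (ann.R - prev_r) / fs,
            "RRn_prime": (next_r - ann.R) / fs,
            "QRSn": (ann.S - ann.Q) / fs,
            "PRn": (ann.R - ann.P) / fs,
            "QTn": (ann.T - ann.Q) / fs,
            "STn": (ann.T - ann.S) / fs,
            "Rn": x[ann.R] - baseline,
            "Pn": x[ann.P] - baseline,
            "Tn": x[ann.T] - baseline,
        }
        intervals = [vec[c] for c in FEATURE_COLUMNS[:6]]
        if min(intervals) <= 0 or vec["QRSn"] >= vec["RRn"]:
            log.warning("beat %d dropped: disordered intervals %s", b, vec)
            continue
        rows.append(vec)
        ids.append(b)
        if labels is not None:
            kept_labels.append(labels[b])
    frame = pd.DataFrame(rows, columns=FEATURE_COLUMNS,
                         index=pd.Index(ids, name="beat_id"))
    if labels is not None:
        frame["label"] = kept_labels
    return frame


def normalize_features(matrix: pd.DataFrame,
                       method: str = "none") -> pd.DataFrame:
    """Column-wise normalization of the feature block.

    ``none`` returns the input unchanged; ``zscore`` maps every feature
    column to mean 0 / sd 1 (population sd).  A constant column cannot be
    scaled and is mapped to zeros with a warning instead of NaN.  A
    ``label`` column, if present, passes through untouched.
    """
    if method == "none":
        return matrix
    if method != "zscore":
        raise ValueError(f"unknown normalization method {method!r}")
    if len(matrix) < 2:
        raise ValueError("zscore needs at least 2 rows")
    out = matrix.copy()
    cols = [c for c in matrix.columns if c != "label"]
    for c in cols:
        col = out[c].to_numpy(float)
        sd = col.std()
        if sd == 0:
            log.warning("constant feature column %r mapped to zeros", c)
            out[c] = 0.0
        else:
            out[c] = (col - col.mean()) / sd
    return out


def write_feature_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write features (and any label column) in the normative column order."""
    cols = FEATURE_COLUMNS + (["label"] if "label" in matrix.columns else [])
    matrix[cols].to_csv(path, index=True)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV; accepts files with or without a beat_id index."""
    frame = pd.read_csv(path)
    if "beat_id" in frame.columns:
        frame = frame.set_index("beat_id")
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature CSV lacks columns {missing}")
    return frame
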