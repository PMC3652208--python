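"""Rule-based ECG waveform delineation.

R peaks are found on the rectified first difference of the signal (the R
wave has the steepest slope of the cardiac cycle), with an adaptive lower
limit, a 200 ms relative refractory period to sidestep tall T waves, and an
RR-interval search-back that rescans suspiciously long gaps at a reduced
threshold.  Q and S are the turning points flanking each R within 0.1 s;
P is the voltage maximum within 0.16 s before Q, and T the voltage maximum
between S and the next beat's P.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signals import ECGSignal

__all__ = [
    "DetectorConfig", "BeatAnnotation", "detect_r_peaks", "detect_qs",
    "detect_pt", "annotate_beats",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the three delineation stages (times in seconds)."""

    threshold_factor: float = 0.4    # fraction of running peak level
    refractory: float = 0.200        # relative refractory period after R
    searchback_factor: float = 1.66  # RR gap factor triggering re-scan
    smooth_window: float = 0.025     # envelope moving-average span (s)
    qs_window: float = 0.1           # Q/S search span around R
    p_window: float = 0.16           # P search span before Q
    t_fallback: float = 0.4          # T span after S for the final beat
    slope_flat_frac: float = 0.1     # "flat" slope fraction for turning point
    low_confidence_amp: float = 0.05 # mV; P/T below this flagged

    def __post_init__(self) -> None:
        if not 0 < self.threshold_factor < 1:
            raise ValueError("threshold_factor must be in (0, 1)")
        if min(self.refractory, self.qs_window, self.p_window,
               self.t_fallback) <= 0:
            raise ValueError("refractory and search windows must be > 0")


@dataclass
class BeatAnnotation:
    """Landmark sample indices of one beat; ``R`` is mandatory.

    Flags: ``valid`` — all five landmarks present and ordered;
    ``low_confidence`` — a P/T amplitude near the noise floor or a T found
    in the end-of-record fallback window.
    """

    R: int
    P: int | None = None
    Q: int | None = None
    S: int | None = None
    T: int | None = None
    valid: bool = True
    low_confidence: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return None not in (self.P, self.Q, self.R, self.S, self.T)

    def ordered(self) -> bool:
        if not self.complete:
            return False
        return self.P < self.Q < self.R < self.S < self.T


def _local_max_peaks(d: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of d (plateau-left convention)."""
    idx = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    return idx


def detect_r_peaks(signal: ECGSignal,
                   cfg: DetectorConfig | None = None) -> np.ndarray:
    """Locate R peaks; returns strictly increasing sample indices.

    The rectified first difference amplifies the QRS upstroke; a short
    moving average (``smooth_window``) turns it into a slope envelope so
    that isolated broadband-noise spikes do not form candidates.  Candidate
    envelope peaks must exceed an adaptive lower limit —
    ``threshold_factor`` times the running mean of the last 8 accepted peak
    heights — and fall outside the refractory period of the previous
    detection.  After the first pass, any RR interval longer than
    ``searchback_factor`` x median RR is re-scanned at half the threshold
    (escaped-beat recovery).  Each accepted candidate is snapped to the
    local maximum of the raw signal within +-60 ms.

    Emits a warning and returns an empty array when nothing crosses the
    threshold.
    """
    cfg = cfg or DetectorConfig()
    x = signal.samples
    fs = signal.fs
    d = np.abs(np.diff(x))
    win = max(1, int(round(cfg.smooth_window * fs)))
    if win > 1:
        d = np.convolve(d, np.ones(win) / win, mode="same")
    refr = int(round(cfg.refractory * fs))
    snap = int(round(0.06 * fs))

    cand = _local_max_peaks(d)
    if cand.size == 0:
        warnings.warn("no difference peaks found; empty R set")
        return np.array([], dtype=int)

    # bootstrap the running level from the first two seconds
    boot = d[: max(int(2 * fs), 10)]
    level = float(boot.max())
    recent: list[float] = [level]

    def snap_to_r(c: int) -> int:
        lo, hi = max(0, c - snap), min(x.size, c + snap + 1)
        return lo + int(np.argmax(x[lo:hi]))

    accepted: list[int] = []
    heights: dict[int, float] = {}
    for c in cand:
        thr = cfg.threshold_factor * float(np.mean(recent[-8:]))
        if d[c] < thr:
            continue
        r = snap_to_r(c)
        if accepted and r - accepted[-1] <= refr:
            continue
        if accepted and r == accepted[-1]:
            continue
        accepted.append(r)
        heights[r] = float(d[c])
        recent.append(float(d[c]))

    if not accepted:
        warnings.warn("no difference peak exceeded the adaptive threshold")
        return np.array([], dtype=int)

    # search-back over long RR gaps at half threshold
    if len(accepted) >= 3:
        final_thr = cfg.threshold_factor * float(np.mean(recent[-8:]))
        changed = True
        while changed:
            changed = False
            rr = np.diff(accepted)
            med = float(np.median(rr))
            for g in np.flatnonzero(rr > cfg.searchback_factor * med):
                lo = accepted[g] + refr
                hi = accepted[g + 1] - refr
                if hi <= lo:
                    continue
                seg = cand[(cand >= lo) & (cand < hi)]
                seg = seg[d[seg] >= 0.5 * final_thr]
                if seg.size:
                    best = seg[np.argmax(d[seg])]
                    r = snap_to_r(int(best))
                    if all(abs(r - a) > refr for a in accepted):
                        accepted.append(r)
                        accepted.sort()
                        changed = True
                        log.info("search-back recovered beat at %d", r)
                        break
    return np.asarray(sorted(set(accepted)), dtype=int)


def _turning_point(x: np.ndarray, r: int, step: int, span: int,
                   flat_frac: float) -> int | None:
    """First sample moving outward from R where the signal stops falling
    (derivative sign change) or the slope flattens below ``flat_frac`` of
    the steepest slope seen; None when the window is truncated."""
    last = r + step * span
    if last < 0 or last >= x.size:
        return None
    prev_val = x[r]
    max_drop = 0.0
    best = None
    for k in range(1, span + 1):
        i = r + step * k
        drop = prev_val - x[i]          # positive while descending outward
        max_drop = max(max_drop, drop)
        if drop < 0:                    # started rising: passed the trough
            return r + step * (k - 1)
        if max_drop > 0 and drop < flat_frac * max_drop:
            return i
        prev_val = x[i]
        best = i
    return best                         # monotone within window: its edge


def detect_qs(signal: ECGSignal, r_peaks: np.ndarray,
              cfg: DetectorConfig | None = None
              ) -> list[tuple[int | None, int | None]]:
    """Q and S turning points within ``qs_window`` seconds around each R.

    Beats whose window is truncated by the record edge yield ``None`` for
    the affected landmark (flagged invalid downstream), never an exception.
    """
    cfg = cfg or DetectorConfig()
    x = signal.samples
    span = int(round(cfg.qs_window * signal.fs))
    out: list[tuple[int | None, int | None]] = []
    for r in np.asarray(r_peaks, dtype=int):
        q = _turning_point(x, r, -1, span, cfg.slope_flat_frac)
        s = _turning_point(x, r, +1, span, cfg.slope_flat_frac)
        out.append((q, s))
    return out


def detect_pt(signal: ECGSignal, r_peaks: np.ndarray,
              qs: list[tuple[int | None, int | None]],
              cfg: DetectorConfig | None = None
              ) -> list[tuple[int | None, int | None, bool]]:
    """P and T peaks per beat; returns (P, T, low_confidence) triples.

    P is the voltage maximum within ``p_window`` seconds before Q; T is the
    voltage maximum between S and the next beat's P.  The final beat has no
    following P, so its T is searched in a ``t_fallback`` window after S
    and flagged.  An amplitude below ``low_confidence_amp`` relative to the
    local median (e.g. the absent P of a ventricular beat) is flagged, not
    rejected.
    """
    cfg = cfg or DetectorConfig()
    x = signal.samples
    fs = signal.fs
    p_span = int(round(cfg.p_window * fs))
    t_span = int(round(cfg.t_fallback * fs))

    p_idx: list[int | None] = []
    low_p: list[bool] = []
    for (q, _s) in qs:
        if q is None or q - p_span < 0:
            p_idx.append(None)
            low_p.append(False)
            continue
        lo = q - p_span
        p = lo + int(np.argmax(x[lo:q]))
        amp = x[p] - float(np.median(x[lo:q]))
        p_idx.append(int(p))
        low_p.append(bool(amp < cfg.low_confidence_amp))

    out: list[tuple[int | None, int | None, bool]] = []
    for b, (q, s) in enumerate(qs):
        p = p_idx[b]
        low = low_p[b]
        if s is None:
            out.append((p, None, low))
            continue
        nxt = p_idx[b + 1] if b + 1 < len(qs) else None
        if nxt is not None and nxt > s + 1:
            hi = nxt
        else:
            hi = min(x.size, s + 1 + t_span)
            low = True                  # fallback window
        if hi <= s + 1:
            out.append((p, None, low))
            continue
        t = s + 1 + int(np.argmax(x[s + 1: hi]))
        t_amp = x[t] - float(np.median(x[s + 1: hi]))
        out.append((p, int(t), low or t_amp < cfg.low_confidence_amp))
    return out


def annotate_beats(signal: ECGSignal,
                   cfg: DetectorConfig | None = None) -> list[BeatAnnotation]:
    """Full delineation: R, then Q/S, then P/T.

    Beats lacking a preceding or a following R peak (the first and last
    detections) are dropped because they cannot yield both RR intervals,
    as are beats with missing or disordered landmarks.  Requires at least
    three R peaks.
    """
    cfg = cfg or DetectorConfig()
    r = detect_r_peaks(signal, cfg)
    if r.size < 3:
        raise ValueError(
            f"only {r.size} R peaks detected; feature extraction needs at "
            "least 3 (two succeeding RR intervals per beat)")
    qs = detect_qs(signal, r, cfg)
    pt = detect_pt(signal, r, qs, cfg)

    beats: list[BeatAnnotation] = []
    for b in range(1, r.size - 1):      # interior beats only
        q, s = qs[b]
        p, t, low = pt[b]
        ann = BeatAnnotation(R=int(r[b]), P=p, Q=q, S=s, T=t,
                             low_confidence=low)
        ann.valid = ann.ordered()
        if not ann.valid:
            ann.notes.append("missing or disordered landmarks")
            log.info("beat at R=%d dropped: %s", ann.R, ann.notes[-1])
        beats.append(ann)
    return beats
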