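"""Seeded synthetic data: ECG records with exact landmarks, noise, clusters.

The ECG generator builds each beat as a sum of five Gaussian bumps (P, Q, R,
S, T) placed at scheduled beat times, so every landmark index is known in
closed form and detectors can be scored exactly.  AAMI beat classes are
emulated as parameter shifts of the normal morphology:

* ``S`` — supraventricular premature: shortened preceding RR interval;
* ``V`` — ventricular ectopic: widened QRS, absent P wave, premature;
* ``F`` — fusion: intermediate QRS widening;
* ``Q`` — paced/unknown: aberrant wave amplitudes.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .signals import ECGSignal, GroundTruth, LANDMARKS

__all__ = [
    "NoiseSpec", "BEAT_TYPES", "gen_synthetic_ecg", "add_noise",
    "gen_cluster_data",
]

# Per-wave (amplitude mV, offset from R in s, Gaussian width sigma in s) for a
# normal beat; chosen to give physiologic interval/amplitude scales
# (QRS ~ 0.07 s, PR ~ 0.17 s, ST ~ 0.22 s, R ~ 1.5 mV).
_NORMAL_WAVES: dict[str, dict[str, float]] = {
    "P": {"amp": 0.12, "offset": -0.170, "width": 0.022},
    "Q": {"amp": -0.12, "offset": -0.035, "width": 0.010},
    "R": {"amp": 1.50, "offset": 0.000, "width": 0.012},
    "S": {"amp": -0.25, "offset": 0.035, "width": 0.010},
    "T": {"amp": 0.35, "offset": 0.260, "width": 0.055},
}


def _shift(base: dict, wave: str, **changes: float) -> None:
    base[wave] = {**base[wave], **changes}


def _make_beat_types() -> dict[str, dict]:
    normal = {"waves": copy.deepcopy(_NORMAL_WAVES), "rr_factor": 1.0}

    prem = copy.deepcopy(normal)
    prem["rr_factor"] = 0.60          # premature: short preceding RR

    vent = copy.deepcopy(normal)
    vent["rr_factor"] = 0.75
    _shift(vent["waves"], "P", amp=0.0)               # absent P
    _shift(vent["waves"], "Q", offset=-0.090, width=0.030)
    _shift(vent["waves"], "R", width=0.036, amp=1.25)  # wide QRS
    _shift(vent["waves"], "S", offset=0.090, width=0.030)
    _shift(vent["waves"], "T", amp=0.45)

    fusion = copy.deepcopy(normal)
    _shift(fusion["waves"], "Q", offset=-0.060, width=0.018)
    _shift(fusion["waves"], "R", width=0.022)          # intermediate QRS
    _shift(fusion["waves"], "S", offset=0.060, width=0.018)

    paced = copy.deepcopy(normal)
    _shift(paced["waves"], "R", amp=0.90)
    _shift(paced["waves"], "P", amp=0.04)
    _shift(paced["waves"], "T", amp=0.55)

    return {"N": normal, "S": prem, "V": vent, "F": fusion, "Q": paced}


#: per-class morphology/rate parameters (amplitudes mV, times s)
BEAT_TYPES = _make_beat_types()


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise description.

    Baseline wander and powerline interference are deterministic sinusoids
    (zero phase); the EMG-like broadband component is white Gaussian noise
    drawn from ``seed``.
    """

    bw_amp: float = 0.0      # baseline-wander amplitude, mV
    bw_freq: float = 0.3     # baseline-wander frequency, Hz (< 7)
    pl_amp: float = 0.0      # powerline amplitude, mV
    pl_freq: float = 50.0    # powerline frequency, Hz
    emg_sd: float = 0.0      # broadband (EMG-band) noise sd, mV
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.bw_amp, self.pl_amp, self.emg_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not self.bw_freq < 7.0:
            raise ValueError("baseline wander is a sub-7 Hz phenomenon; "
                             f"got bw_freq={self.bw_freq}")


def gen_synthetic_ecg(
    fs: float,
    duration: float,
    heart_rate: float = 60.0,
    beat_classes: str | list[str] = "N",
    rr_jitter: float = 0.0,
    beat_amplitude: np.ndarray | None = None,
    overrides: dict | None = None,
    seed: int = 0,
) -> tuple[ECGSignal, GroundTruth]:
    """Generate a multi-beat ECG with exact ground-truth landmarks.

    Parameters
    ----------
    fs : float
        Sampling frequency, >= 100 Hz.
    duration : float
        Record length in seconds; must accommodate at least three beats.
    heart_rate : float
        Base rate in beats/min; class ``rr_factor`` shortens individual
        preceding RR intervals.
    beat_classes : str or sequence of str
        A single AAMI class used for all beats, or one class per beat
        (cycled if shorter than the number of beats that fit).
    rr_jitter : float
        Fractional s.d. of multiplicative RR jitter.
    beat_amplitude : array-like, optional
        Per-beat global amplitude scale (cycled); e.g. ``[1, 1, 0.3]``
        produces every third beat at 30 % amplitude.
    overrides : dict, optional
        ``{class: {wave: {field: value}}}`` morphology overrides merged over
        :data:`BEAT_TYPES` defaults (e.g. a tall-T fixture).
    seed : int
        Master seed; identical arguments give bit-identical output.

    Returns
    -------
    (ECGSignal, GroundTruth)
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    types = copy.deepcopy(BEAT_TYPES)
    for cls, waves in (overrides or {}).items():
        for wave, changes in waves.items():
            _shift(types[cls]["waves"], wave, **changes)

    base_rr = 60.0 / heart_rate
    classes = [beat_classes] if isinstance(beat_classes, str) \
        else list(beat_classes)

    # schedule R times; leave margins so every P and T lies inside the record
    lead_in, lead_out = 0.30, 0.45
    r_times: list[float] = []
    labels: list[str] = []
    t = lead_in
    k = 0
    while True:
        cls = classes[k % len(classes)]
        if k > 0:
            rr = base_rr * types[cls]["rr_factor"]
            if rr_jitter > 0:
                rr *= max(0.2, 1.0 + rr_jitter * rng.standard_normal())
            t = r_times[-1] + rr
        if t + lead_out > duration:
            break
        r_times.append(t)
        labels.append(cls)
        k += 1
    if len(r_times) < 3:
        raise ValueError(
            f"duration {duration} s too short: fewer than 3 beats fit at "
            f"{heart_rate} bpm")

    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    x = np.zeros(n)
    landmarks = np.empty((len(r_times), 5), dtype=int)
    amp_cycle = None if beat_amplitude is None else np.asarray(
        beat_amplitude, dtype=float)
    for b, (t_r, cls) in enumerate(zip(r_times, labels)):
        scale = 1.0 if amp_cycle is None else amp_cycle[b % amp_cycle.size]
        for w, name in enumerate(LANDMARKS):
            p = types[cls]["waves"][name]
            center = t_r + p["offset"]
            x += scale * p["amp"] * np.exp(
                -0.5 * ((tt - center) / p["width"]) ** 2)
            landmarks[b, w] = int(round(center * fs))
    return ECGSignal(samples=x, fs=fs), GroundTruth(landmarks=landmarks,
                                                    labels=labels)


def add_noise(signal: ECGSignal, spec: NoiseSpec) -> ECGSignal:
    """Add baseline wander, powerline interference and broadband noise.

    The sinusoidal components are deterministic (zero phase), so composing
    two specs is exactly additive for them; only the broadband term depends
    on ``spec.seed``.  A zero spec returns the input unchanged.
    """
    t = signal.times
    out = signal.samples.copy()
    if spec.bw_amp > 0:
        out = out + spec.bw_amp * np.sin(2 * np.pi * spec.bw_freq * t)
    if spec.pl_amp > 0:
        out = out + spec.pl_amp * np.sin(2 * np.pi * spec.pl_freq * t)
    if spec.emg_sd > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + spec.emg_sd * rng.standard_normal(out.size)
    return signal.with_samples(out)


def _simplex_centers(k: int, dims: int, separation: float) -> np.ndarray:
    """k centroids in `dims` dimensions with all pairwise distances equal
    to `separation` (regular-simplex construction)."""
    if dims < k - 1:
        raise ValueError(f"dims={dims} too small for {k} equidistant centers")
    v = np.eye(k) - 1.0 / k          # centered simplex, pairwise dist sqrt(2)
    # orthonormal basis of the (k-1)-dim span
    u, s, _ = np.linalg.svd(v, full_matrices=False)
    coords = (u[:, : k - 1] * s[: k - 1]) * (separation / np.sqrt(2.0))
    centers = np.zeros((k, dims))
    centers[:, : k - 1] = coords
    return centers


def gen_cluster_data(
    n: int,
    k: int = 2,
    separation: float = 6.0,
    dims: int = 2,
    balance: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled Gaussian blobs with controlled separation and class balance.

    Centroids are pairwise ``separation`` x within-cluster s.d. (= 1) apart.
    Cluster sizes are as equal as possible.  For ``k = 2`` the returned
    labels are in {-1, +1} and their sum is guaranteed to satisfy
    ``|sum| <= balance`` (default: the parity minimum); for ``k > 2`` labels
    are 0..k-1.
    """
    if not (n >= k >= 2):
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    if k == 2:
        imbalance = abs(sizes[0] - sizes[1])
        if balance is not None and imbalance > balance:
            raise ValueError(
                f"balance bound {balance} infeasible for n={n}, k=2 "
                f"(minimum imbalance {imbalance})")
    rng = np.random.default_rng(seed)
    centers = _simplex_centers(k, dims, separation)
    X = np.vstack([centers[i] + rng.standard_normal((sizes[i], dims))
                   for i in range(k)])
    if k == 2:
        y = np.concatenate([-np.ones(sizes[0]), np.ones(sizes[1])])
    else:
        y = np.concatenate([np.full(sizes[i], i) for i in range(k)])
    perm = rng.permutation(n)
    return X[perm], y[perm].astype(int)
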