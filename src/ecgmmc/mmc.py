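"""Square-loss maximum-margin clustering primitives.

For a *fixed* labeling ``y`` in {-1,+1}^n the square-loss SVM problem

    min_{w,b,eta}  J = 1/2 ||w||^2 + C/2 sum_i eta_i^2
    s.t.           y_i (w.phi(x_i) + b) = 1 - eta_i

is the least-squares SVM: its KKT conditions form one symmetric linear
system per labeling, so candidate labelings can be scored cheaply.
Clustering then searches over balanced labelings (|sum y_i| <= l) for the
one admitting the largest margin, i.e. the smallest optimal J; the affinity
F(y) = exp(-J) turns that into a fitness in (0, 1].

:func:`refine_bias_labels` performs the inner coordinate refinement: with
``w`` fixed, the optimal balanced labeling is a threshold labeling in
sorted-score order, so scanning the balanced split positions (the gaps
between consecutive sorted scores, i.e. the midpoint candidates) with the
closed-form optimal bias per split attains the exact constrained optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "MMCModel", "kernel_matrix", "inner_solve",
           "objective", "affinity", "refine_bias_labels"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice.

    ``rbf`` is exp(-||x - x'|| / sigma^2) — note the *unsquared* Euclidean
    norm, an exponential (Laplacian-type) kernel with an unusual bandwidth
    exponent; it is the form this package treats as canonical.
    ``rbf_squared`` is the conventional Gaussian exp(-||x - x'||^2 / sigma^2).
    ``linear`` is the plain dot product.
    """

    kind: str = "rbf"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "rbf_squared", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind != "linear" and not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def kernel_matrix(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Symmetric n x n Gram matrix; unit diagonal for the rbf kinds."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with n >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if spec.kind == "linear":
        return X @ X.T
    d = cdist(X, X, metric="euclidean")
    if spec.kind == "rbf":
        K = np.exp(-d / spec.sigma ** 2)
    else:
        K = np.exp(-(d ** 2) / spec.sigma ** 2)
    np.fill_diagonal(K, 1.0)
    return K


@dataclass
class MMCModel:
    """Solution of the square-loss problem for one fixed labeling.

    ``alpha`` are the dual coefficients (one per sample); the raw score of
    sample i is ``scores[i] = w.phi(x_i) = sum_j alpha_j y_j K_ij`` (bias
    excluded); ``eta`` the per-sample slacks 1 - y_i (scores_i + b).
    """

    y: np.ndarray
    alpha: np.ndarray
    bias: float
    C: float
    kernel: KernelSpec | None
    scores: np.ndarray
    eta: np.ndarray
    J: float
    F: float = field(init=False)

    def __post_init__(self) -> None:
        self.F = affinity(self.J)


def inner_solve(K: np.ndarray, y: np.ndarray, C: float,
                kernel: KernelSpec | None = None) -> MMCModel:
    """Least-squares SVM fit for fixed labels via the KKT linear system.

    Solves ``[[0, y^T], [y, Omega + I/C]] [b; alpha] = [0; 1]`` with
    ``Omega_ij = y_i y_j K_ij``; then ``w.phi(x_i) = sum_j alpha_j y_j K_ij``,
    ``eta_i = alpha_i / C`` and ``J = 1/2 alpha^T Omega alpha +
    1/(2C) sum alpha_i^2``.  A singular system (duplicate points, degenerate
    Gram matrix) is regularized with a 1e-10 ridge and logged.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("K must be n x n matching y")
    if not np.all(np.abs(y) == 1):
        raise ValueError("y must be a vector of +-1")
    if not C > 0:
        raise ValueError("C must be positive")

    omega = (y[:, None] * y[None, :]) * K
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = omega + np.eye(n) / C
    rhs = np.concatenate(([0.0], np.ones(n)))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        log.warning("singular KKT system; adding 1e-10 ridge")
        sol = np.linalg.solve(A + 1e-10 * np.eye(n + 1), rhs)
    b = float(sol[0])
    alpha = sol[1:]
    scores = omega @ alpha * y          # sum_j alpha_j y_j K_ij
    eta = alpha / C
    J = 0.5 * float(alpha @ omega @ alpha) + 0.5 / C * float(alpha @ alpha)
    return MMCModel(y=y.astype(int), alpha=alpha, bias=b, C=C, kernel=kernel,
                    scores=scores, eta=eta, J=max(J, 0.0))


def objective(model: MMCModel) -> float:
    """The optimal square-loss objective J of the model's labeling."""
    return model.J


def affinity(J: float) -> float:
    """Affinity F = exp(-J); strictly decreasing in J, in (0, 1].

    Underflows to 0.0 for very poor labelings; comparisons inside the
    evolutionary loop therefore rank by J, never by F alone.
    """
    if not np.isfinite(J):
        raise ValueError(f"objective must be finite, got {J}")
    return float(np.exp(-J))


def _split_positions(n: int, balance: int) -> np.ndarray:
    """Feasible split positions p (count of -1 labels) for |sum y| <= l.

    |n - 2p| <= l gives ceil((n-l)/2) <= p <= floor((n+l)/2); when that
    range is empty (parity: n odd with l = 0) it is rounded outward to the
    splits of minimal imbalance.  p = 0 and p = n (one empty cluster) are
    never feasible.
    """
    lo = int(np.ceil((n - balance) / 2))
    hi = int(np.floor((n + balance) / 2))
    lo, hi = max(lo, 1), min(hi, n - 1)
    if lo > hi:                         # parity round-out
        lo = hi = n // 2 if n // 2 >= 1 else 1
    return np.arange(lo, hi + 1)


def refine_bias_labels(scores: np.ndarray, balance: int
                       ) -> tuple[float, np.ndarray, float]:
    """Optimal (bias, labels) for fixed w under the balance constraint.

    Minimizes ``sum_i (scores_i + b - y_i)^2`` over b and balanced
    y in {-1,+1}^n.  The sorted-score midpoints enumerate every distinct
    threshold labeling; splits violating ``|sum y| <= balance`` are
    discarded, and for each surviving split the bias takes its closed-form
    optimum ``mean(y - scores)``, which renders the scan exact (the
    constrained optimum is always a threshold labeling).

    Returns ``(bias, y, objective)``; ties in ``sign(0)`` map to +1.

    Raises
    ------
    ValueError
        If all scores are identical (no split separates anything).
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 scores")
    if np.ptp(s) == 0:
        raise ValueError(
            "all raw scores identical: no bias candidate can separate the "
            "samples (degenerate w)")
    order = np.argsort(s, kind="stable")
    best: tuple[float, np.ndarray, float] | None = None
    for p in _split_positions(n, balance):
        y_sorted = np.ones(n, dtype=int)
        y_sorted[:p] = -1
        y = np.empty(n, dtype=int)
        y[order] = y_sorted
        b = float(np.mean(y - s))
        obj = float(np.sum((s + b - y) ** 2))
        if best is None or obj < best[2]:
            best = (b, y, obj)
    assert best is not None
    return best
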