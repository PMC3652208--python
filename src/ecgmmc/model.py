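"""Model/Results interface for maximum-margin clustering.

:class:`MaximumMarginClustering` is constructed from a data matrix (or a
feature DataFrame), holds the search configuration, and :meth:`fit` runs
the immune evolutionary optimization, returning :class:`MMCResults` with
the estimated labeling, the fitted least-squares SVM (dual coefficients,
bias), the objective/affinity, per-generation convergence history, and a
``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from . import evaluate as ev
from .features import FEATURE_COLUMNS
from .immune import IEMMCConfig, recursive_multiclass, run_iemmc
from .mmc import MMCModel

__all__ = ["MaximumMarginClustering", "MMCResults"]


class MaximumMarginClustering:
    """Maximum-margin clustering of a sample matrix.

    Searches over balanced labelings ``y`` in {-1,+1}^n for the one whose
    square-loss SVM fit has the smallest optimal objective
    ``J = 1/2 ||w||^2 + C/2 sum eta_i^2`` (largest margin).  The search is
    the clonal-selection immune algorithm of :mod:`ecgmmc.immune`; for
    ``n_clusters > 2`` the binary problem is applied by recursive
    bipartition of the largest cluster.

    Parameters
    ----------
    X : array-like, (n, d)
        Samples (e.g. the nine time-domain beat features, z-scored).
    n_clusters : int
        Number of clusters; 2 is the native problem.
    true_labels : array-like, optional
        Held-out class labels; never used in fitting, only by
        ``MMCResults.score()``.
    **config
        :class:`ecgmmc.immune.IEMMCConfig` fields (C, kernel, sigma,
        balance, pop_size, ...).
    """

    def __init__(self, X, n_clusters: int = 2, true_labels=None, **config):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n_clusters = int(n_clusters)
        self.true_labels = None if true_labels is None \
            else np.asarray(true_labels)
        self.config = IEMMCConfig(**config)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, columns=None,
                       label_column: str | None = None, **config
                       ) -> "MaximumMarginClustering":
        """Build from a feature DataFrame.

        ``columns`` defaults to the nine canonical feature columns when
        present, else every numeric column; ``label_column`` (or a column
        named ``label``) supplies held-out truth for scoring.
        """
        if label_column is None and "label" in frame.columns:
            label_column = "label"
        if columns is None:
            if all(c in frame.columns for c in FEATURE_COLUMNS):
                columns = FEATURE_COLUMNS
            else:
                columns = [c for c in frame.columns
                           if c != label_column
                           and pd.api.types.is_numeric_dtype(frame[c])]
        labels = frame[label_column].to_numpy() if label_column else None
        return cls(frame[columns].to_numpy(float),
                   true_labels=labels, **config)

    def fit(self, seed: int = 0,
            seed_labelings: list[np.ndarray] | None = None) -> "MMCResults":
        """Run the immune search; deterministic for a fixed seed."""
        if self.n_clusters == 2:
            res = run_iemmc(self.X, self.config, seed=seed,
                            seed_labelings=seed_labelings)
            labels = np.where(res.y > 0, 2, 1)
            return MMCResults(self, labels=labels, y=res.y, model=res.model,
                              history=res.history,
                              generations=res.generations)
        labels = recursive_multiclass(self.X, self.n_clusters, self.config,
                                      seed=seed)
        return MMCResults(self, labels=labels)


class MMCResults:
    """Fitted clustering: estimates, diagnostics, summary.

    Attributes
    ----------
    labels : ndarray of int
        Cluster assignment per sample, 1..k.
    y : ndarray or None
        The sign labeling (+-1, sign-canonical) for the binary problem.
    model : MMCModel or None
        The least-squares SVM of the best labeling: dual coefficients
        ``model.alpha``, bias ``model.bias``, slacks ``model.eta``,
        objective ``model.J``, affinity ``model.F``.
    history : list of dict
        Per-generation best/mean objective and affinity.
    """

    def __init__(self, parent: MaximumMarginClustering, labels: np.ndarray,
                 y: np.ndarray | None = None, model: MMCModel | None = None,
                 history: list | None = None, generations: int = 0):
        self.parent = parent
        self.labels = np.asarray(labels, dtype=int)
        self.y = y
        self.model = model
        self.history = history or []
        self.generations = generations

    @property
    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def score(self, true_labels=None) -> pd.DataFrame:
        """Matched-permutation metric table against held-out labels."""
        truth = true_labels if true_labels is not None \
            else self.parent.true_labels
        if truth is None:
            raise ValueError("no true labels available to score against")
        truth = np.asarray(truth)
        mapping = ev.match_clusters(self.labels, truth)
        matched = np.array([mapping[c] for c in self.labels])
        return ev.metrics_report(ev.confusion(truth, matched))

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        p = self.parent
        cfg = p.config
        buf = io.StringIO()
        w = buf.write
        w("Maximum Margin Clustering (immune evolutionary search)\n")
        w("=" * 58 + "\n")
        rows = [
            ("No. samples", p.X.shape[0]),
            ("No. features", p.X.shape[1]),
            ("Clusters", self.parent.n_clusters),
            ("Kernel", f"{cfg.kernel}"
             + (f" (sigma={cfg.sigma:g})" if cfg.sigma else " (median sigma)")
             if cfg.kernel != "linear" else "linear"),
            ("C (regularization)", cfg.C),
            ("Balance bound l", cfg.resolve_balance(p.X.shape[0])),
            ("Population / clones / memory",
             f"{cfg.pop_size} / {cfg.n_clone} / {cfg.n_memory}"),
            ("Generations run", self.generations),
        ]
        if self.model is not None:
            rows += [
                ("Objective J", f"{self.model.J:.6g}"),
                ("Affinity F = exp(-J)", f"{self.model.F:.6g}"),
                ("Bias b", f"{self.model.bias:.6g}"),
                ("Max |slack|", f"{np.max(np.abs(self.model.eta)):.4g}"),
            ]
        rows.append(("Cluster sizes", self.cluster_sizes))
        for name, val in rows:
            w(f"{name:<32}{val}\n")
        w("=" * 58 + "\n")
        return buf.getvalue()

    def plot_convergence(self, ax=None):
        """Best/mean affinity per generation (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history_frame()
        if h.empty:
            raise ValueError("no history to plot (multiclass fit?)")
        ax.plot(h["generation"], h["best_F"], label="best affinity")
        ax.plot(h["generation"], h["mean_F"], label="mean affinity",
                linestyle="--")
        ax.set_xlabel("generation")
        ax.set_ylabel("affinity F = exp(-J)")
        ax.legend()
        return ax
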