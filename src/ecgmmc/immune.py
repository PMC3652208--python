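"""Clonal-selection immune search over balanced labelings.

The clustering objective — the optimal square-loss SVM value J(y) over
labelings y — is non-convex and combinatorial, so it is optimized by an
artificial immune system: a population of candidate labelings (antibodies)
is scored by affinity F = exp(-J), the best are cloned and hypermutated
(mutation pressure inversely proportional to affinity), improved mutants
re-enter the population, and the worst antibodies are periodically replaced
by fresh random ones (receptor editing) to keep diversity.  Every antibody
additionally undergoes a Lamarckian local refinement: the fitted model's
raw scores induce an optimal balanced re-thresholding of the labels, which
replaces the antibody's labeling whenever it lowers J.

All moves preserve the class-balance constraint |sum y_i| <= l exactly, and
elitism makes the best affinity non-decreasing across generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

from .mmc import (KernelSpec, MMCModel, inner_solve, kernel_matrix,
                  refine_bias_labels)

__all__ = [
    "Antibody", "Population", "IEMMCConfig", "IEMMCResult",
    "evaluate_antibody", "init_population", "clone_select", "hypermutate",
    "reselect", "receptor_edit", "run_iemmc", "recursive_multiclass",
]

log = logging.getLogger(__name__)


@dataclass
class Antibody:
    """A candidate labeling with its (lazily computed) score.

    ``J``/``F`` are None until evaluated; ``model`` caches the fitted
    least-squares SVM so re-evaluation is free (idempotent).
    """

    y: np.ndarray
    J: float | None = None
    F: float | None = None
    model: MMCModel | None = None
    age: int = 0

    def canonical(self) -> np.ndarray:
        """Sign-canonical labeling (first component forced +1); J(y)=J(-y)."""
        return self.y if self.y[0] > 0 else -self.y

    def key(self) -> bytes:
        return self.canonical().astype(np.int8).tobytes()


def _distance(a: Antibody, b: Antibody) -> int:
    """Hamming distance between canonical labelings."""
    return int(np.sum(a.canonical() != b.canonical()))


@dataclass
class Population:
    """Antibody pool: elite memory set plus the working remainder."""

    memory: list[Antibody]
    remainder: list[Antibody]

    @property
    def members(self) -> list[Antibody]:
        return self.memory + self.remainder

    @property
    def size(self) -> int:
        return len(self.memory) + len(self.remainder)

    def best(self) -> Antibody:
        scored = [a for a in self.members if a.J is not None]
        return min(scored, key=lambda a: a.J)


@dataclass(frozen=True)
class IEMMCConfig:
    """Search configuration.

    ``balance`` is the bound l on |sum y_i| (default 0.2 n, the fraction
    via ``balance_frac``); ``C`` the square-loss regularization weight;
    ``sigma=None`` selects the median pairwise distance heuristic.
    ``suppression`` is the minimum pairwise Hamming distance enforced at
    initialization (default n/10).  ``n_clone``/``n_memory`` are the clone
    pool and memory-set sizes, ``f_max`` the mutation strength (pair flips)
    assigned to the lowest-affinity antibody.
    """

    C: float = 10.0
    kernel: str = "rbf"
    sigma: float | None = None
    balance: int | None = None
    balance_frac: float = 0.2
    pop_size: int = 20
    n_clone: int = 5
    n_memory: int = 5
    edit_fraction: float = 0.2
    suppression: int | None = None
    f_max: int | None = None
    max_generations: int = 50
    stall: int = 10
    refine_rounds: int = 10
    init: str = "random"        # "random" or "kmeans" (one seeded antibody)

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0 <= self.edit_fraction < 1:
            raise ValueError("edit_fraction must be in [0, 1)")
        if self.n_clone > self.pop_size:
            raise ValueError("n_clone cannot exceed pop_size")
        if self.init not in ("random", "kmeans"):
            raise ValueError(f"unknown init scheme {self.init!r}")

    def resolve_balance(self, n: int) -> int:
        b = self.balance if self.balance is not None \
            else int(np.floor(self.balance_frac * n))
        if not 0 <= b <= n:
            raise ValueError(f"balance bound {b} outside [0, {n}]")
        return b

    def resolve_suppression(self, n: int) -> int:
        return self.suppression if self.suppression is not None \
            else max(1, n // 10)

    def resolve_f_max(self, n: int) -> int:
        return self.f_max if self.f_max is not None else max(2, n // 10)


@dataclass
class IEMMCResult:
    """Best labeling found, its fitted model, and the search history."""

    y: np.ndarray
    model: MMCModel
    history: list[dict] = field(default_factory=list)
    generations: int = 0


def _random_balanced(n: int, balance: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Uniform-ish random labeling with |sum y| <= balance (parity-aware)."""
    lo = int(np.ceil((n - balance) / 2))
    hi = int(np.floor((n + balance) / 2))
    lo, hi = max(lo, 1), min(hi, n - 1)
    if lo > hi:
        lo = hi = n // 2
    n_neg = int(rng.integers(lo, hi + 1))
    y = np.ones(n, dtype=int)
    y[rng.choice(n, size=n_neg, replace=False)] = -1
    return y


def check_balance(y: np.ndarray, balance: int) -> bool:
    """Balance constraint with parity round-out for odd n - balance."""
    return abs(int(np.sum(y))) <= max(balance, (y.size - balance) % 2)


def evaluate_antibody(K: np.ndarray, antibody: Antibody,
                      config: IEMMCConfig, balance: int) -> Antibody:
    """Score an antibody: inner solve, then Lamarckian label refinement.

    The refinement loop alternates the KKT solve with the optimal balanced
    re-thresholding of the raw scores and keeps the labeling only while J
    strictly decreases; the result is cached on the antibody, so repeated
    evaluation is a no-op.
    """
    if antibody.J is not None:
        return antibody
    y = antibody.y
    model = inner_solve(K, y, config.C)
    for _ in range(config.refine_rounds):
        if np.ptp(model.scores) == 0:
            break
        _, y_ref, _ = refine_bias_labels(model.scores, balance)
        if np.array_equal(y_ref, y) or np.array_equal(y_ref, -y):
            break
        cand = inner_solve(K, y_ref, config.C)
        if cand.J < model.J - 1e-12:
            y, model = y_ref, cand
        else:
            break
    antibody.y = y
    antibody.J = model.J
    antibody.F = model.F
    antibody.model = model
    return antibody


def init_population(n: int, config: IEMMCConfig,
                    rng: np.random.Generator,
                    seed_labelings: list[np.ndarray] | None = None
                    ) -> Population:
    """Random balanced antibodies, pairwise suppression-distance apart.

    ``seed_labelings`` lets callers inject non-random starting points (e.g.
    a centroid-based baseline partition); they count toward the population
    size and are exempt from the distance check against each other.
    """
    balance = config.resolve_balance(n)
    t_s = config.resolve_suppression(n)
    members: list[Antibody] = [
        Antibody(y=np.asarray(y, dtype=int).copy())
        for y in (seed_labelings or [])]
    attempts = 0
    while len(members) < config.pop_size:
        cand = Antibody(y=_random_balanced(n, balance, rng))
        if all(_distance(cand, m) > t_s for m in members):
            members.append(cand)
        attempts += 1
        if attempts > 500 * config.pop_size:
            raise RuntimeError(
                f"could not place {config.pop_size} antibodies at pairwise "
                f"distance > {t_s}; lower the suppression threshold")
    return Population(memory=[], remainder=members)


def clone_select(population: Population, n_clone: int) -> list[Antibody]:
    """Clone the n_clone highest-affinity antibodies of the remainder.

    The rank-r best individual receives ``n_clone - r`` exact copies, so
    clone counts decrease with affinity rank.
    """
    scored = sorted((a for a in population.remainder if a.J is not None),
                    key=lambda a: a.J)
    if n_clone > len(scored):
        raise ValueError("n_clone exceeds the evaluated remainder size")
    clones: list[Antibody] = []
    for rank, parent in enumerate(scored[:n_clone]):
        for _ in range(n_clone - rank):
            clones.append(Antibody(y=parent.y.copy()))
    return clones


def hypermutate(antibody: Antibody, rank_frac: float, f_max: int,
                rng: np.random.Generator,
                evaluator) -> Antibody:
    """Affinity-proportional mutation with a keep-if-better guarantee.

    Flips ``f`` opposite-signed label pairs (one +1 -> -1 and one
    -1 -> +1 per flip), which conserves sum(y) exactly; ``f`` grows
    linearly from 1 for the best-ranked antibody (``rank_frac = 0``) to
    ``f_max`` for the worst (``rank_frac = 1``).  The mutant is evaluated
    with ``evaluator`` and returned only if its affinity improves on the
    parent's; otherwise the parent is kept.
    """
    y = antibody.y
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("labeling has no opposite-signed pair to flip")
    f = 1 + int(round(rank_frac * (f_max - 1)))
    f = min(f, pos.size, neg.size)
    mut = y.copy()
    mut[rng.choice(pos, size=f, replace=False)] = -1
    mut[rng.choice(neg, size=f, replace=False)] = 1
    child = evaluator(Antibody(y=mut))
    parent = evaluator(antibody)
    return child if child.J < parent.J else parent


def reselect(population: Population, candidates: list[Antibody],
             config: IEMMCConfig) -> Population:
    """Merge candidates into the pool, keeping the best as the memory set.

    Deduplicates by sign-canonical labeling, ranks everything by J, puts
    the top ``n_memory`` into the memory set and refills the remainder to
    restore the population size (fresh antibodies are left unevaluated).
    The incumbent best is always retained (elitism).
    """
    pool: dict[bytes, Antibody] = {}
    for a in population.members + candidates:
        if a.J is None:
            continue
        k = a.key()
        if k not in pool or a.J < pool[k].J:
            pool[k] = a
    ranked = sorted(pool.values(), key=lambda a: a.J)
    memory = ranked[: config.n_memory]
    remainder = ranked[config.n_memory: config.pop_size]
    return Population(memory=memory, remainder=remainder)


def receptor_edit(population: Population, fraction: float,
                  rng: np.random.Generator, n: int, balance: int
                  ) -> Population:
    """Replace the lowest-affinity remainder antibodies with random ones.

    ``floor(fraction * |remainder|)`` antibodies are replaced; the memory
    set is untouched; fraction 0 is the identity.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rem = sorted(population.remainder,
                 key=lambda a: np.inf if a.J is None else a.J)
    n_replace = int(np.floor(fraction * len(rem)))
    kept = rem[: len(rem) - n_replace] if n_replace else rem
    fresh = [Antibody(y=_random_balanced(n, balance, rng))
             for _ in range(n_replace)]
    return Population(memory=population.memory, remainder=kept + fresh)


def _kmeans_seed(X: np.ndarray, balance: int, seed: int) -> np.ndarray:
    """Centroid-based starting labeling, repaired to satisfy the balance
    bound by flipping the excess side's samples closest to the opposite
    centroid."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, init="random", n_init=1,
                random_state=int(seed) % (2 ** 31))
    lab = km.fit_predict(X)
    y = np.where(lab == 0, -1, 1)
    centers = km.cluster_centers_
    margin = (np.linalg.norm(X - centers[0], axis=1)
              - np.linalg.norm(X - centers[1], axis=1))   # >0 nearer c1
    while abs(int(y.sum())) > max(balance, (y.size - balance) % 2):
        sign = 1 if y.sum() > 0 else -1
        side = np.flatnonzero(y == sign)
        flip = side[np.argmin(sign * margin[side])]
        y[flip] = -sign
    return y


def _resolve_kernel(X: np.ndarray, config: IEMMCConfig) -> KernelSpec:
    """Kernel with the median pairwise distance as default bandwidth."""
    if config.kernel == "linear":
        return KernelSpec("linear")
    sigma = config.sigma
    if sigma is None:
        d = pdist(np.asarray(X, dtype=float))
        sigma = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return KernelSpec(config.kernel, sigma)


def run_iemmc(X: np.ndarray, config: IEMMCConfig | None = None,
              seed: int = 0,
              seed_labelings: list[np.ndarray] | None = None) -> IEMMCResult:
    """Full immune search for the maximum-margin bipartition of X.

    Per generation: evaluate the population, clone-select and hypermutate
    the affinity elite, hypermutate the best of the remaining pool,
    reselect survivors into memory/remainder, then receptor-edit the tail.
    Stops at ``max_generations`` or after ``stall`` generations without
    best-J improvement.  Deterministic for fixed arguments; the master
    seed drives named substreams for initialization, mutation and editing.
    """
    cfg = config or IEMMCConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    balance = cfg.resolve_balance(n)
    f_max = cfg.resolve_f_max(n)
    kernel = _resolve_kernel(X, cfg)
    K = kernel_matrix(X, kernel)

    rng_init, rng_mut, rng_edit = np.random.default_rng(seed).spawn(3)

    def ev(a: Antibody) -> Antibody:
        return evaluate_antibody(K, a, cfg, balance)

    if cfg.init == "kmeans":
        seed_labelings = list(seed_labelings or [])
        seed_labelings.append(_kmeans_seed(X, balance, seed))
    pop = init_population(n, cfg, rng_init, seed_labelings)
    history: list[dict] = []
    best_J = np.inf
    stall = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        for a in pop.members:
            ev(a)

        clones = clone_select(pop, min(cfg.n_clone, len(pop.remainder)))
        matured: list[Antibody] = []
        for i, c in enumerate(clones):
            rank_frac = i / max(len(clones) - 1, 1)
            matured.append(hypermutate(c, rank_frac, f_max, rng_mut, ev))

        elite_keys = {c.key() for c in clones}
        rest = sorted((a for a in pop.remainder
                       if a.key() not in elite_keys), key=lambda a: a.J)
        for i, a in enumerate(rest[: cfg.n_memory]):
            rank_frac = i / max(cfg.n_memory - 1, 1)
            matured.append(hypermutate(a, rank_frac, f_max, rng_mut, ev))

        pop = reselect(pop, matured, cfg)
        pop = receptor_edit(pop, cfg.edit_fraction, rng_edit, n, balance)
        while pop.size < cfg.pop_size:   # restore size after deduplication
            pop.remainder.append(
                Antibody(y=_random_balanced(n, balance, rng_edit)))
        for a in pop.members:
            ev(a)
            a.age += 1

        cur = pop.best()
        scored = [a.J for a in pop.members if a.J is not None]
        history.append({"generation": gen, "best_J": cur.J, "best_F": cur.F,
                        "mean_J": float(np.mean(scored)),
                        "mean_F": float(np.mean([a.F for a in pop.members
                                                 if a.F is not None]))})
        if cur.J < best_J - 1e-12:
            best_J = cur.J
            stall = 0
        else:
            stall += 1
        if stall >= cfg.stall:
            break

    best = pop.best()
    log.info("IEMMC finished after %d generations: J=%.6g F=%.6g",
             gen, best.J, best.F)
    return IEMMCResult(y=best.canonical(), model=best.model,
                       history=history, generations=gen)


def recursive_multiclass(X: np.ndarray, k: int,
                         config: IEMMCConfig | None = None,
                         seed: int = 0) -> np.ndarray:
    """k-way clustering by recursive balanced bipartition.

    The binary objective is applied repeatedly, always splitting the
    currently largest cluster, until k clusters exist; returns integer
    labels 1..k.  Deterministic for a fixed seed (each split draws its own
    substream).

    Intermediate splits relax the balance bound to 0.6 x subset size
    (each side still >= 20 % of the subset): a subset holding m > 2 of the
    final clusters is correctly divided 1 : (m-1), which a tight
    symmetric-balance bound would forbid.  ``k = 2`` is exactly
    :func:`run_iemmc` under the caller's own balance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2*k} samples for k={k} clusters")
    cfg = config or IEMMCConfig()
    if k == 2:
        res = run_iemmc(X, cfg, seed=seed)
        return np.where(res.y < 0, 2, 1)
    split_cfg = replace(cfg, balance=None,
                        balance_frac=max(cfg.balance_frac, 0.6))
    labels = np.ones(n, dtype=int)
    streams = iter(np.random.default_rng(seed).integers(0, 2**31, size=k))
    while labels.max() < k:
        sizes = {c: int(np.sum(labels == c)) for c in range(1, labels.max() + 1)}
        target = max(sizes, key=lambda c: (sizes[c], -c))
        idx = np.flatnonzero(labels == target)
        if idx.size < 4:
            raise ValueError(
                f"cluster {target} too small to split ({idx.size} samples)")
        res = run_iemmc(X[idx], split_cfg, seed=int(next(streams)))
        new = labels.max() + 1
        labels[idx[res.y < 0]] = new
    return labels
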