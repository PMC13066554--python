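"""The three cross-validation partitions compared by the pipeline.

* ``random_kfold`` — plain uniform k-fold, the baseline.
* ``spatial_block_cv`` — rows binned into square lon/lat tiles; whole tiles
  assigned to folds, so training and held-out data are geographically
  disjoint at the tile scale.
* ``env_stratified_cv`` — k-means climate classes (on z-scored mean ANPP +
  five climatic baselines) dealt proportionally across folds, preserving
  environmental representativeness in every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_K = 10
DEFAULT_N_CLASSES = 10


@dataclass(frozen=True)
class FoldAssignment:
    """One CV partition: per-row fold indices in 1..k plus strategy metadata."""

    strategy: str
    k: int
    folds: np.ndarray  # shape (n,), values 1..k
    seed: int
    groups: np.ndarray | None = None  # tile or class label per row
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.folds)
        if f.ndim != 1:
            raise ValueError("folds must be a 1-D index array")
        if f.size and (f.min() < 1 or f.max() > self.k):
            raise ValueError("fold indices must lie in 1..k")

    @property
    def n(self) -> int:
        return self.folds.size

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def to_frame(self) -> pd.DataFrame:
        d = {"row_id": np.arange(self.n), "fold": self.folds}
        if self.groups is not None:
            d["class_or_tile"] = self.groups
        return pd.DataFrame(d)


def random_kfold(n_rows: int, k: int = DEFAULT_K, seed: int = 0) -> FoldAssignment:
    """Uniformly random k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_rows:
        raise ValueError(f"k={k} exceeds the number of rows ({n_rows})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    folds = np.empty(n_rows, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k), start=1):
        folds[chunk] = f
    return FoldAssignment(strategy="random", k=k, folds=folds, seed=seed)


def spatial_block_cv(
    lon: np.ndarray,
    lat: np.ndarray,
    block_size: float,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> FoldAssignment:
    """Tile-based spatial blocking: no tile is ever split across folds.

    Tiles (square lon/lat bins of ``block_size`` degrees) are ordered by
    descending occupancy — ties shuffled by seed — and each is handed to the
    currently smallest fold, which keeps fold sizes as even as whole tiles
    allow.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if block_size <= 0:
        raise ValueError("block size must be > 0")
    tx = np.floor(lon / block_size).astype(int)
    ty = np.floor(lat / block_size).astype(int)
    tiles = tx * 1_000_003 + ty  # collision-free composite key for int tiles
    uniq, inverse, counts = np.unique(tiles, return_inverse=True, return_counts=True)
    if uniq.size < k:
        raise ValueError(
            f"only {uniq.size} occupied tiles for k={k} folds; "
            f"use a smaller block size than {block_size} degrees"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    order = order[np.argsort(-counts[order], kind="stable")]
    fold_of_tile = np.empty(uniq.size, dtype=int)
    load = np.zeros(k, dtype=int)
    for t in order:
        f = int(np.argmin(load))  # smallest current fold, lowest index on ties
        fold_of_tile[t] = f + 1
        load[f] += counts[t]
    folds = fold_of_tile[inverse]
    return FoldAssignment(
        strategy="spatial_block",
        k=k,
        folds=folds,
        seed=seed,
        groups=inverse,
        meta={"block_size": block_size, "n_tiles": int(uniq.size)},
    )


def suggest_block_size(lon: np.ndarray, lat: np.ndarray, k: int = DEFAULT_K) -> float:
    """Block size aiming at roughly 5*k occupied tiles over the point extent."""
    span = max(np.ptp(lon), np.ptp(lat), 1e-9)
    return float(span / max(np.sqrt(5 * k), 1.0))


def env_stratified_cv(
    strat_features: np.ndarray,
    n_classes: int = DEFAULT_N_CLASSES,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> FoldAssignment:
    """Environmentally-stratified k-fold via k-means climate classes.

    Features are z-scored, clustered into ``n_classes`` (k-means++, 10
    restarts), and each class's rows are dealt round-robin to folds after a
    seeded shuffle, so per-class fold counts differ by at most one.
    Degenerate all-identical features fall back to ``random_kfold``.
    """
    X = np.asarray(strat_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("stratification features must be 2-D (rows x features)")
    n = X.shape[0]
    if n_classes > n:
        raise ValueError(f"n_classes={n_classes} exceeds the number of rows ({n})")
    if not np.isfinite(X).all():
        raise ValueError("stratification features must be finite")
    sd = X.std(axis=0)
    informative = sd > 0
    if not informative.any():
        logger.warning("all stratification features constant; falling back to random k-fold")
        rk = random_kfold(n, k, seed)
        return FoldAssignment(
            strategy="env_stratified", k=k, folds=rk.folds, seed=seed,
            groups=np.zeros(n, dtype=int), meta={"fallback": "random_kfold"},
        )
    Z = (X[:, informative] - X[:, informative].mean(axis=0)) / sd[informative]
    km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(Z)

    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    cursor = 0  # global round-robin pointer keeps overall fold sizes balanced
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = members[rng.permutation(members.size)]
        for m in members:
            folds[m] = cursor % k + 1
            cursor += 1
    return FoldAssignment(
        strategy="env_stratified", k=k, folds=folds, seed=seed, groups=labels,
        meta={"n_classes": int(n_classes)},
    )
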