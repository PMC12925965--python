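"""Topological lenses: per-block 2D embeddings and the composite filtered space.

Each omics block is projected to two dimensions with a neighbor-graph
manifold embedding (UMAP) computed on the correlation distance between
sample Z-score profiles. The per-block projections are horizontally
concatenated into a composite filtered space (6 columns for 3 blocks) that
the cubical cover of the Mapper stage is built on.

A deterministic classical-MDS embedder operating on the same distance
matrix is available as a drop-in alternative (``method="mds"``); it makes
the whole pipeline a pure function of its inputs, which is convenient for
testing and exact reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import OmicsBlock

__all__ = [
    "LensEmbedding",
    "CompositeLens",
    "BlockEmbedder",
    "correlation_distance_matrix",
    "pairwise_distances",
    "embed_block",
    "concatenate_lenses",
    "rescale_unit",
]

METRICS = ("correlation", "euclidean", "cosine")


def correlation_distance_matrix(
    X: np.ndarray, sample_ids: Sequence[str] | None = None
) -> np.ndarray:
    """1 - Pearson correlation between sample rows, nan-aware.

    Missing cells are excluded pairwise (complete-pairs correlation). A
    zero-variance sample row cannot be placed in correlation space and is a
    hard error naming the sample.
    """
    X = np.asarray(X, dtype=float)
    ids = list(sample_ids) if sample_ids is not None else list(range(X.shape[0]))
    sd = np.nanstd(X, axis=1)
    bad = [ids[i] for i in range(X.shape[0]) if not np.isfinite(sd[i]) or sd[i] == 0]
    if bad:
        raise ValueError(
            f"zero-variance sample rows under correlation metric: {bad}"
        )
    # pandas corr is pairwise-complete and tolerates NaN
    corr = pd.DataFrame(X.T).corr(method="pearson").to_numpy()
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def pairwise_distances(
    X: np.ndarray, metric: str, sample_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Square pairwise distance matrix for one of the supported metrics."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if metric == "correlation":
        return correlation_distance_matrix(X, sample_ids)
    if np.isnan(X).any():
        raise ValueError(f"{metric} metric does not support missing values")
    return squareform(pdist(X, metric=metric))


@dataclass
class LensEmbedding:
    """A 2D lens (filter-function output) for one block."""

    block_id: str
    coords: np.ndarray  # (n_samples, 2), dataset sample order
    sample_ids: list[str]
    metric: str
    seed: int
    params: dict

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("lens coords must be (n_samples, 2)")
        if self.coords.shape[0] != len(self.sample_ids):
            raise ValueError("one coordinate row per sample required")
        if not np.isfinite(self.coords).all():
            raise ValueError("lens coords must be finite")


@dataclass
class CompositeLens:
    """Horizontal concatenation of per-block lenses (the filtered space)."""

    coords: np.ndarray  # (n_samples, 2 * n_blocks)
    sample_ids: list[str]
    column_origin: list[tuple[str, int]]  # column -> (block_id, axis)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[1] != len(self.column_origin):
            raise ValueError("column_origin must describe every column")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{b}_{'xy'[a]}" for b, a in self.column_origin]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


def _classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix (deterministic)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[idx], 0.0, None)
    Y = V[:, idx] * np.sqrt(w)
    # fix reflection: make the largest-magnitude loading positive per axis
    for k in range(Y.shape[1]):
        j = np.argmax(np.abs(Y[:, k]))
        if Y[j, k] < 0:
            Y[:, k] = -Y[:, k]
    return Y


class BlockEmbedder(BaseEstimator, TransformerMixin):
    """2D lens embedder for one block's Z-score matrix.

    Parameters
    ----------
    method:
        ``"umap"`` (neighbor-graph manifold embedding; default) or ``"mds"``
        (classical metric MDS on the same distance matrix, deterministic).
    metric:
        ``"correlation"`` (1 - Pearson between sample rows; default),
        ``"euclidean"`` or ``"cosine"``. The distance matrix is always
        precomputed here so missing values are handled uniformly.
    n_neighbors:
        UMAP neighborhood size. ``None`` (default) means 15 clamped to
        ``n_samples - 1``; an explicit value >= n_samples is an error.
    min_dist:
        UMAP minimum embedding distance.
    random_state:
        Seed; identical inputs and seed give identical coordinates.
    """

    def __init__(
        self,
        method: str = "umap",
        metric: str = "correlation",
        n_neighbors: int | None = None,
        min_dist: float = 0.1,
        random_state: int = 0,
    ):
        self.method = method
        self.metric = metric
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.random_state = random_state

    def fit_transform(self, X, y=None, sample_ids: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 4:
            raise ValueError("embedding requires at least 4 samples")
        if self.n_neighbors is None:
            k = min(15, n - 1)
        else:
            k = int(self.n_neighbors)
            if k >= n:
                raise ValueError(
                    f"n_neighbors={k} must be < n_samples={n}; "
                    f"use a smaller value (e.g. {n - 1})"
                )
        D = pairwise_distances(X, self.metric, sample_ids)
        if self.method == "mds":
            coords = _classical_mds(D, 2)
        elif self.method == "umap":
            import umap

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reducer = umap.UMAP(
                    n_components=2,
                    n_neighbors=k,
                    min_dist=self.min_dist,
                    metric="precomputed",
                    random_state=self.random_state,
                )
                coords = reducer.fit_transform(D)
        else:
            raise ValueError(f"unknown embedding method {self.method!r}")
        self.embedding_ = np.asarray(coords, dtype=float)
        return self.embedding_

    def fit(self, X, y=None, **kw):
        self.fit_transform(X, y, **kw)
        return self


def embed_block(
    block: OmicsBlock,
    metric: str = "correlation",
    seed: int = 0,
    method: str = "umap",
    n_neighbors: int | None = None,
    min_dist: float = 0.1,
) -> LensEmbedding:
    """Embed one Z-scored block to a 2D lens in dataset sample order."""
    if block.stage != "zscored":
        raise ValueError(f"embed_block expects a zscored block, got {block.stage}")
    est = BlockEmbedder(
        method=method,
        metric=metric,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = est.fit_transform(block.values, sample_ids=block.sample_ids)
    return LensEmbedding(
        block_id=block.block_id,
        coords=coords,
        sample_ids=block.sample_ids,
        metric=metric,
        seed=seed,
        params={"method": method, "n_neighbors": n_neighbors, "min_dist": min_dist},
    )


def concatenate_lenses(lenses: Sequence[LensEmbedding]) -> CompositeLens:
    """Concatenate per-block lenses into the composite filtered space."""
    if not lenses:
        raise ValueError("need at least one lens")
    ids = lenses[0].sample_ids
    for l in lenses[1:]:
        if l.coords.shape[0] != len(ids) or l.sample_ids != ids:
            raise ValueError(
                "lenses must share row count and sample order "
                f"(block {l.block_id!r} differs)"
            )
    coords = np.hstack([l.coords for l in lenses])
    origin = [(l.block_id, a) for l in lenses for a in (0, 1)]
    return CompositeLens(coords=coords, sample_ids=list(ids), column_origin=origin)


def rescale_unit(composite: CompositeLens) -> CompositeLens:
    """Min-max rescale each composite column to [0, 1].

    Makes the cover geometry comparable across lens axes; a constant column
    maps to 0. Membership in the uniform cubical cover is invariant under
    this per-axis affine map, so this is a presentation choice.
    """
    C = composite.coords.copy()
    lo = C.min(axis=0)
    span = C.max(axis=0) - lo
    for j in range(C.shape[1]):
        C[:, j] = (C[:, j] - lo[j]) / span[j] if span[j] > 0 else 0.0
    return CompositeLens(
        coords=C,
        sample_ids=list(composite.sample_ids),
        column_origin=list(composite.column_origin),
    )


def write_lenses_csv(lenses: Sequence[LensEmbedding], path: str | Path) -> None:
    """Export lens coordinates as tidy CSV (sample_id, block, x, y)."""
    rows = []
    for l in lenses:
        for s, (x, y) in zip(l.sample_ids, l.coords):
            rows.append({"sample_id": s, "block": l.block_id, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)
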