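"""Background-region selection.

For every region the k background-modeling regions are chosen by one of
four modes: highest Pearson correlation of coverage profiles across
samples (primary), uniform random, or smallest absolute difference in a
scalar metric (GC, length, or mean depth). Ties always break by
ascending region index so assignments are bit-reproducible.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_coverage import CoverageMatrix

logger = logging.getLogger(__name__)

MODES = ("pearson", "random", "gc", "length", "mean_depth")


@dataclass(frozen=True)
class NeighborConfig:
    k: int
    mode: str = "pearson"
    seed: int = 0
    log1p: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class NeighborAssignment:
    """Per-region ordered neighbor indices and their selection scores."""

    indices: np.ndarray  # (n, k) int
    scores: np.ndarray  # (n, k) float: correlation or -|delta metric|
    region_ids: list[str]

    def __post_init__(self) -> None:
        n, k = self.indices.shape
        if k > n - 1:
            raise ValueError("k cannot exceed n - 1")
        rows = np.arange(n)[:, None]
        if np.any(self.indices == rows):
            raise ValueError("region assigned to its own background set")
        if self.indices.min() < 0 or self.indices.max() >= n:
            raise ValueError("neighbor index out of range")

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def _clip_k(k: int, n: int) -> int:
    if k > n - 1:
        logger.warning("k=%d exceeds n-1=%d; clipped", k, n - 1)
        return n - 1
    return k


def _rank_rows(score: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k per row of a score matrix (higher is better, diag excluded),
    ties by ascending column index."""
    score = score.copy()
    np.fill_diagonal(score, -np.inf)
    order = np.argsort(-score, axis=1, kind="stable")[:, :k]
    picked = np.take_along_axis(score, order, axis=1)
    return order, picked


def pearson_neighbors(matrix: CoverageMatrix, k: int, log1p: bool = False) -> NeighborAssignment:
    """k most-correlated regions per region (Pearson across samples)."""
    n, m = matrix.counts.shape
    if m < 3:
        raise ValueError("too few samples for correlation (need >= 3)")
    if n < 2:
        raise ValueError("need at least 2 regions")
    k = _clip_k(k, n)
    x = matrix.counts.astype(float)
    if log1p:
        x = np.log1p(x)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))
    zero_var = norms == 0
    norms[zero_var] = 1.0
    x /= norms[:, None]
    corr = x @ x.T
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    indices, scores = _rank_rows(corr, k)
    return NeighborAssignment(indices, scores, list(matrix.region_ids))


def scalar_neighbors(
    values: np.ndarray, k: int, region_ids: Sequence[str] | None = None
) -> NeighborAssignment:
    """k regions with the smallest |metric difference| per region."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if np.any(~np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        name = region_ids[bad] if region_ids is not None else str(bad)
        raise ValueError(f"non-finite metric for region {name}")
    if n < 2:
        raise ValueError("need at least 2 regions")
    k = _clip_k(k, n)
    score = -np.abs(values[:, None] - values[None, :])
    indices, scores = _rank_rows(score, k)
    ids = list(region_ids) if region_ids is not None else [str(i) for i in range(n)]
    return NeighborAssignment(indices, scores, ids)


def random_neighbors(
    n: int, k: int, seed: int, region_ids: Sequence[str] | None = None
) -> NeighborAssignment:
    """k uniform random background regions per region, reproducible from seed.

    Each region draws independently (generator keyed by (seed, region))."""
    if n < 2:
        raise ValueError("need at least 2 regions")
    k = _clip_k(k, n)
    indices = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        indices[i] = rng.choice(others, size=k, replace=False)
    ids = list(region_ids) if region_ids is not None else [str(i) for i in range(n)]
    return NeighborAssignment(indices, np.zeros((n, k)), ids)


def select_neighbors(
    matrix: CoverageMatrix,
    config: NeighborConfig,
    annotations: pd.DataFrame | None = None,
) -> NeighborAssignment:
    """Dispatch on mode; gc/length modes need the annotation table."""
    if config.mode == "pearson":
        return pearson_neighbors(matrix, config.k, log1p=config.log1p)
    if config.mode == "random":
        return random_neighbors(
            matrix.n_regions, config.k, config.seed, matrix.region_ids
        )
    if config.mode == "mean_depth":
        values = matrix.counts.mean(axis=1)
    else:
        if annotations is None:
            raise ValueError(f"mode {config.mode!r} requires region annotations")
        values = annotations[config.mode].to_numpy(dtype=float)
    return scalar_neighbors(values, config.k, matrix.region_ids)


def write_neighbors_tsv(assignment: NeighborAssignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tneighbors\n")
        for rid, row in zip(assignment.region_ids, assignment.indices):
            ids = ",".join(assignment.region_ids[j] for j in row)
            fh.write(f"{rid}\t{ids}\n")


def read_neighbors_tsv(path: str | os.PathLike) -> NeighborAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    region_ids = list(df["region_id"])
    pos = {rid: i for i, rid in enumerate(region_ids)}
    rows = [
        [pos[rid] for rid in cell.split(",")] for cell in df["neighbors"]
    ]
    k = len(rows[0])
    if any(len(r) != k for r in rows):
        raise ValueError(f"{path}: ragged neighbor lists")
    indices = np.array(rows, dtype=np.int64)
    return NeighborAssignment(indices, np.zeros_like(indices, dtype=float), region_ids)
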