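"""Isolation forest for anomalous-superpixel scoring, implemented from scratch.

An ensemble of random binary trees recursively splits subsamples of the
feature matrix on a uniformly random attribute at a uniformly random value
between that attribute's min and max within the node.  Points that isolate
after few splits (short average path length) are anomalous.  The anomaly
score is

    s(x) = 2 ** ( -E[h(x)] / c(psi) )

where E[h(x)] is the mean path length over trees, and c(n) is the average
path length of an unsuccessful BST search,

    c(n) = 2 * H(n - 1) - 2 * (n - 1) / n,   H(i) = ln(i) + Euler-Mascheroni,

with c(node size) added at truncated leaves and c(1) = 0.  Scores near 1 mean
quick isolation (anomalous); scores well below 0.5 mean normal.

Flagging is by contamination fraction: the top ceil(contamination * n)
scores are flagged, ties broken by patch id for determinism.  The workflow
deliberately runs with a high contamination (default 0.4) so that subtle,
camouflaged organisms are flagged too, and relies on downstream filtering to
remove the false positives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .vae import FeatureMatrix

EULER_GAMMA = 0.5772156649


@dataclass
class ForestConfig:
    n_trees: int = 100
    subsample_size: int = 256
    contamination: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ArgumentError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.subsample_size < 2:
            raise ArgumentError(f"subsample_size must be >= 2, got {self.subsample_size}")
        if not (0 < self.contamination <= 0.5):
            raise ArgumentError(
                f"contamination must be in (0, 0.5], got {self.contamination}")


@dataclass
class AnomalyResult:
    patch_id: str
    score: float
    flagged: bool = False


def average_path_length(n: int | np.ndarray) -> float | np.ndarray:
    """c(n): expected path length of an unsuccessful BST search; c(1) = 0."""
    n_arr = np.asarray(n, dtype=float)
    out = np.zeros_like(n_arr)
    big = n_arr > 1
    nb = n_arr[big]
    out[big] = 2.0 * (np.log(nb - 1.0) + EULER_GAMMA) - 2.0 * (nb - 1.0) / nb
    if np.isscalar(n) or n_arr.ndim == 0:
        return float(out)
    return out


class _Node:
    __slots__ = ("attr", "threshold", "left", "right", "size", "depth")

    def __init__(self, size: int, depth: int):
        self.attr = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.size = size
        self.depth = depth


def _build_tree(x: np.ndarray, idx: np.ndarray, depth: int, height_limit: int,
                rng: np.random.Generator) -> _Node:
    node = _Node(size=len(idx), depth=depth)
    if depth >= height_limit or len(idx) <= 1:
        return node
    d = x.shape[1]
    # Constant attributes at a node are resampled up to d times, then the
    # node becomes a leaf.
    for _ in range(d):
        attr = int(rng.integers(d))
        col = x[idx, attr]
        lo, hi = col.min(), col.max()
        if hi > lo:
            node.attr = attr
            node.threshold = float(rng.uniform(lo, hi))
            mask = col < node.threshold
            node.left = _build_tree(x, idx[mask], depth + 1, height_limit, rng)
            node.right = _build_tree(x, idx[~mask], depth + 1, height_limit, rng)
            return node
    return node


@dataclass
class IsolationForestModel:
    trees: list[_Node]
    psi: int  # effective subsample size
    n_features: int
    config: ForestConfig = field(repr=False, default_factory=ForestConfig)


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, FeatureMatrix):
        return np.asarray(features.values, dtype=float), list(features.ids)
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, [str(i) for i in range(x.shape[0])]


def fit_forest(features, config: ForestConfig | None = None) -> IsolationForestModel:
    """Build ``n_trees`` isolation trees on uniform subsamples of the rows.

    If fewer rows than ``subsample_size`` are available, the subsample size
    is lowered to the row count with a warning.  Growth stops at the height
    limit ceil(log2(psi)) or at singleton nodes.
    """
    config = config or ForestConfig()
    config.validate()
    x, _ = _as_matrix(features)
    n = x.shape[0]
    if n < 2:
        raise ArgumentError(f"need >= 2 rows to fit a forest, got {n}")
    psi = config.subsample_size
    if n < psi:
        warnings.warn(f"subsample_size lowered from {psi} to row count {n}")
        psi = n
    height_limit = math.ceil(math.log2(psi))
    rng = np.random.default_rng(config.seed)
    trees = []
    for _ in range(config.n_trees):
        idx = rng.choice(n, size=psi, replace=False)
        trees.append(_build_tree(x, idx, 0, height_limit, rng))
    return IsolationForestModel(trees=trees, psi=psi, n_features=x.shape[1],
                                config=config)


def _path_length(node: _Node, row: np.ndarray) -> float:
    while node.attr >= 0:
        node = node.left if row[node.attr] < node.threshold else node.right
    return node.depth + average_path_length(node.size)


def score(forest: IsolationForestModel, features) -> list[AnomalyResult]:
    """Anomaly score per row: s = 2^(-E[h]/c(psi)), strictly in (0, 1)."""
    x, ids = _as_matrix(features)
    if x.shape[1] != forest.n_features:
        raise ArgumentError(
            f"feature dimension {x.shape[1]} does not match fitted {forest.n_features}")
    denom = average_path_length(forest.psi)
    results = []
    for i, pid in enumerate(ids):
        e_h = np.mean([_path_length(t, x[i]) for t in forest.trees])
        results.append(AnomalyResult(patch_id=pid,
                                     score=float(2.0 ** (-e_h / denom))))
    return results


def flag_by_contamination(results: Sequence[AnomalyResult],
                          contamination: float) -> list[AnomalyResult]:
    """Flag exactly ceil(contamination * n) highest-scoring results.

    Ties are broken toward the smaller patch id so flagging is deterministic.
    Returns new results in the input order.
    """
    if not results:
        raise ArgumentError("results must be non-empty")
    if not (0 < contamination <= 0.5):
        raise ArgumentError(f"contamination must be in (0, 0.5], got {contamination}")
    k = math.ceil(contamination * len(results))
    ranked = sorted(results, key=lambda r: (-r.score, r.patch_id))
    flagged_ids = {r.patch_id for r in ranked[:k]}
    return [AnomalyResult(r.patch_id, r.score, r.patch_id in flagged_ids)
            for r in results]
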