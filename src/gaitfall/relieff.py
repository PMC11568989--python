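"""ReliefF feature weighting and the two-dimensional selection sweep.

ReliefF scores each feature by how well it separates nearest neighbors of
different classes. For every instance R the K nearest same-class neighbors
(hits) and K nearest other-class neighbors (misses) are found by Manhattan
distance over all features; a feature is penalized for differing across
hits and rewarded, weighted by the miss class prior, for differing across
misses. On features scaled to [0, 1] every weight lies in [-1, 1].

This implementation iterates over all instances (no sampling), uses the
two-class prior-weighted miss term, and breaks neighbor-distance ties by
ascending subject index so results are permutation-invariant.

The selection sweep reproduces the study design: one weighting per neighbor
count K (default 1..40), and for each K an evaluation of the top-N feature
subset for every N (default 5..40), yielding a K x N grid of evaluation
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidKError
from .feature_table import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class ReliefFResult:
    """Per-feature weights and the descending-weight ranking for one K."""

    K: int
    weights: pd.Series
    ranking: list[str]


@dataclass
class SelectionSweepConfig:
    """The (K, N) sweep grid; defaults match the study design."""

    k_range: Sequence[int] = tuple(range(1, 41))
    n_range: Sequence[int] = tuple(range(5, 41))

    def validate(self, n_features: int) -> None:
        if not self.k_range or any(k < 1 for k in self.k_range):
            raise InvalidInputError("k_range must be nonempty with all K >= 1")
        if any(not (1 <= n <= n_features) for n in self.n_range):
            raise InvalidInputError(
                f"n_range must lie in [1, {n_features}]"
            )


def relieff_weights(matrix: FeatureMatrix, K: int) -> ReliefFResult:
    """ReliefF weights on a [0, 1]-scaled feature matrix.

    Update for each instance R (m = number of instances)::

        W[f] -= sum_hits   |R_f - H_f| / (m * K)
        W[f] += P(miss) / (1 - P(class(R))) * sum_misses |R_f - M_f| / (m * K)

    Requires both classes to have more than K members (each instance needs
    K hits besides itself and K misses).
    """
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y()
    m, p = X.shape
    counts = np.bincount(y, minlength=2)
    if min(counts) <= K:
        raise InvalidKError(
            f"K={K} requires more than K members in each class, got {counts.tolist()}"
        )
    priors = counts / m
    weights = np.zeros(p)
    # Manhattan distances over all features; n is small so the full matrix is fine.
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    dist = diffs.sum(axis=2)
    idx = np.arange(m)
    for i in range(m):
        for cls in (0, 1):
            members = idx[(y == cls) & (idx != i)]
            # stable tie-break: ascending distance, then ascending index
            order = members[np.lexsort((members, dist[i, members]))]
            neighbors = order[:K]
            contrib = diffs[i, neighbors, :].sum(axis=0) / (m * K)
            if cls == y[i]:
                weights -= contrib
            else:
                weights += priors[cls] / (1.0 - priors[y[i]]) * contrib
    w = pd.Series(weights, index=matrix.X.columns)
    # descending weight, ties broken by registry (column) order
    order = np.argsort(-w.to_numpy(), kind="stable")
    ranking = [matrix.X.columns[j] for j in order]
    return ReliefFResult(K=K, weights=w, ranking=ranking)


def top_n(result: ReliefFResult, N: int) -> list[str]:
    """First N names of the ranking (prefix property holds by construction)."""
    if not (1 <= N <= len(result.ranking)):
        raise InvalidInputError(f"N={N} outside [1, {len(result.ranking)}]")
    return result.ranking[:N]


@dataclass
class SweepResult:
    """Grid of evaluation reports keyed by (K, N); skipped cells are None."""

    grid: dict[tuple[int, int], object]
    weightings: dict[int, ReliefFResult]
    skipped: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_weightings(self) -> int:
        return len(self.weightings)

    @property
    def n_cells(self) -> int:
        return len(self.grid)

    def reports(self) -> list[object]:
        return [r for r in self.grid.values() if r is not None]


def selection_sweep(
    matrix: FeatureMatrix,
    cfg: SelectionSweepConfig,
    eval_fn: Callable[[list[str], int, int], object],
) -> SweepResult:
    """One ReliefF weighting per K; evaluate every top-N subset per (K, N).

    ``eval_fn(feature_names, K, N)`` is supplied by the evaluation module and
    returns an evaluation report for the given subset. A K that is invalid
    for the cohort marks its row as skipped rather than failing the sweep.
    ReliefF runs on a min-max scaled copy of the matrix; ``eval_fn`` receives
    only feature names and is responsible for its own fold-aware scaling.
    """
    from .feature_table import minmax_scale

    cfg.validate(matrix.X.shape[1])
    scaled, _ = minmax_scale(matrix)
    grid: dict[tuple[int, int], object] = {}
    weightings: dict[int, ReliefFResult] = {}
    skipped: list[tuple[int, int]] = []
    for K in cfg.k_range:
        try:
            result = relieff_weights(scaled, K)
        except InvalidKError as exc:
            log.warning("skipping K=%d: %s", K, exc)
            for N in cfg.n_range:
                grid[(K, N)] = None
                skipped.append((K, N))
            continue
        weightings[K] = result
        for N in cfg.n_range:
            grid[(K, N)] = eval_fn(top_n(result, N), K, N)
    return SweepResult(grid=grid, weightings=weightings, skipped=skipped)
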