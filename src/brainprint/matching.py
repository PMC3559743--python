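"""Voxel-level matching of aligned GM maps and min-max score normalization.

Because all volumes live in one normalized template space, two brains can be
compared voxel by voxel without any feature extraction.  The dissimilarity
between two GM maps G_a, G_b is the sum over all voxel coordinates x of the
absolute probability difference,

    d(a, b) = sum_x | G_a(x) - G_b(x) |        (L1; optional L2 variant)

so a smaller d means a higher chance the two scans show the same brain.
Distances of one experiment are then min-max normalized to matching scores
on [0, 100],

    s = 100 * (d_max - d) / (d_max - d_min)

with d_max, d_min the extremes over all distances of the pooled experiment:
the best match in the pool scores 100, the worst 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .volumes import DatasetIndex, GMVolume, GridMismatchError, ScanKey

Metric = Literal["l1", "l2"]

PairLabel = Literal["genuine", "imposter"]


@dataclass(frozen=True)
class MatchResult:
    """One comparison: the pair's identity, raw distance and (once the pool
    is normalized) the matching score on [0, 100]."""

    id_a: ScanKey
    id_b: ScanKey
    distance_d: float
    score_s: float | None = None
    label: PairLabel = "imposter"


@dataclass
class ScorePool:
    """An experiment's collection of comparisons with its distance extremes.

    d_min and d_max are always the extremes over exactly this pool; score
    normalization is relative to them, so scores from different pools are
    not comparable.
    """

    results: list[MatchResult]
    metric: Metric = "l1"

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("a score pool must contain at least one comparison")

    def __len__(self) -> int:
        return len(self.results)

    @property
    def d_min(self) -> float:
        return min(r.distance_d for r in self.results)

    @property
    def d_max(self) -> float:
        return max(r.distance_d for r in self.results)

    def scores(self, label: PairLabel | None = None) -> np.ndarray:
        """Normalized scores, optionally restricted to one label."""
        vals = [
            r.score_s
            for r in self.results
            if label is None or r.label == label
        ]
        if any(v is None for v in vals):
            raise ValueError("pool has unnormalized results; call normalize_scores")
        return np.asarray(vals, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Score table, deterministically ordered (lexicographic by ids)."""
        rows = sorted(self.results, key=lambda r: (r.id_a, r.id_b))
        return pd.DataFrame(
            {
                "id_a": ["/".join(map(str, r.id_a)) for r in rows],
                "id_b": ["/".join(map(str, r.id_b)) for r in rows],
                "label": [r.label for r in rows],
                "distance": [r.distance_d for r in rows],
                "score": [r.score_s for r in rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the float64 roundtrip exact: the JSON summary stays
        # recomputable from the score CSV alone
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def gm_distance(a: GMVolume, b: GMVolume, metric: Metric = "l1") -> float:
    """Distance between two aligned GM maps over all voxel coordinates.

    ``l1`` (default) is the sum of absolute voxelwise differences; ``l2``
    the sum of squared differences.  Both are symmetric, nonnegative and
    zero iff the maps are voxelwise identical.  Volumes must share grid
    shape and voxel size (same template space).
    """
    if not a.same_grid(b):
        raise GridMismatchError(
            f"cannot match {a.key} {a.shape}/{a.voxel_size_mm} against "
            f"{b.key} {b.shape}/{b.voxel_size_mm}"
        )
    diff = a.data.astype(np.float64) - b.data.astype(np.float64)
    if metric == "l1":
        return float(np.abs(diff).sum())
    if metric == "l2":
        return float(np.square(diff).sum())
    raise ValueError(f"unknown metric {metric!r}; expected 'l1' or 'l2'")


def pair_label(id_a: ScanKey, id_b: ScanKey) -> PairLabel:
    return "genuine" if id_a[0] == id_b[0] else "imposter"


def pairwise_distances(
    pairs: Sequence[tuple[ScanKey, ScanKey]],
    index: DatasetIndex,
    metric: Metric = "l1",
) -> ScorePool:
    """Compute one :class:`MatchResult` per id pair; labels by shared subject."""
    if not pairs:
        raise ValueError("empty pair list: nothing to match")
    results = [
        MatchResult(
            id_a=ka,
            id_b=kb,
            distance_d=gm_distance(index.resolve(ka), index.resolve(kb), metric),
            label=pair_label(ka, kb),
        )
        for ka, kb in pairs
    ]
    return ScorePool(results=results, metric=metric)


def normalize_scores(pool: ScorePool) -> ScorePool:
    """Min-max normalize the pool's distances to matching scores on [0, 100].

    d_min maps to 100 and d_max to 0 (smaller distance, higher score).  In
    the degenerate pool where every distance is equal, all scores are 100:
    every pair is then the pool's best match.
    """
    d_min, d_max = pool.d_min, pool.d_max
    span = d_max - d_min
    if span == 0:
        scored = [replace(r, score_s=100.0) for r in pool.results]
    else:
        # divide before scaling so d_min maps to exactly 100.0
        scored = [
            replace(r, score_s=(d_max - r.distance_d) / span * 100.0)
            for r in pool.results
        ]
    return ScorePool(results=scored, metric=pool.metric)
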