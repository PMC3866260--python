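"""Developmental-stage segmentation of the time axis.

The time course is split into stages either by a shipped preset mirroring the
published early (t1-3) / late (t4-6) partition with the final maturation
point excluded, or by two-way hierarchical clustering of the expression
columns followed by a majority vote of replicates per time point. A derived
"whole" stage -- the union of every non-excluded time point -- is always
available alongside the named stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .data_io import ExpressionMatrix

WHOLE = "whole"

#: minimum time points per stage; below this a permutation test over
#: replicate-averaged points cannot reach conventional significance levels.
MIN_STAGE_POINTS = 3


@dataclass
class StagePartition:
    """Named, disjoint, time-ordered groups of time-point indices.

    ``stages`` never contains the derived "whole" stage; iterate with
    :meth:`iter_stages` to get it appended exactly once.
    """

    stages: dict[str, list[int]]
    excluded: list[int] = field(default_factory=list)
    #: total number of time points, if known; lets "whole" pick up time
    #: points that belong to no named stage but are not excluded either.
    n_timepoints: int | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, idx in self.stages.items():
            if len(idx) < MIN_STAGE_POINTS:
                raise ValueError(
                    f"stage {label!r} has {len(idx)} time points; "
                    f"at least {MIN_STAGE_POINTS} are required"
                )
            overlap = seen & set(idx)
            if overlap:
                raise ValueError(f"stage {label!r} overlaps earlier stages at {sorted(overlap)}")
            if set(idx) & set(self.excluded):
                raise ValueError(f"stage {label!r} contains excluded time points")
            seen |= set(idx)

    @property
    def whole(self) -> list[int]:
        points = {i for idx in self.stages.values() for i in idx}
        if self.n_timepoints is not None:
            points |= set(range(self.n_timepoints)) - set(self.excluded)
        return sorted(points)

    def iter_stages(self, include_whole: bool = True) -> Iterator[tuple[str, list[int]]]:
        yield from self.stages.items()
        if include_whole:
            yield WHOLE, self.whole

    def stage_indices(self, label: str) -> list[int]:
        if label == WHOLE:
            return self.whole
        try:
            return self.stages[label]
        except KeyError:
            raise KeyError(f"unknown stage label {label!r}") from None

    @property
    def labels(self) -> list[str]:
        return list(self.stages) + [WHOLE]

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {k: list(v) for k, v in self.stages.items()}
        doc["excluded"] = list(self.excluded)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "StagePartition":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        excluded = [int(i) for i in doc.pop("excluded", [])]
        stages = {str(k): [int(i) for i in v] for k, v in doc.items()}
        return cls(stages=stages, excluded=excluded)


def preset_early_late() -> StagePartition:
    """The published partition: early = t1-3, late = t4-6, final point excluded."""
    return StagePartition(
        stages={"early": [0, 1, 2], "late": [3, 4, 5]}, excluded=[6], n_timepoints=7
    )


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each row to mean 0, unit (n-1) variance across all columns."""
    mu = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    flat = sd.ravel()
    if np.any(flat == 0):
        bad = expr.entity_ids[int(np.argmax(flat == 0))]
        raise ValueError(f"zero-variance row cannot be standardized: {bad!r}")
    return ExpressionMatrix(
        kind=expr.kind,
        entity_ids=list(expr.entity_ids),
        time_points=list(expr.time_points),
        columns=list(expr.columns),
        values=(expr.values - mu) / sd,
    )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over expression columns.

    Leaves are numbered 0..n-1 in column order; merge step i creates cluster
    ``n + i``. ``merges`` rows are (cluster_a, cluster_b, height) with
    cluster_a < cluster_b.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]
    columns: list[tuple[int, str]]

    def cut(self, k: int) -> list[list[int]]:
        """Leaf groups after cutting into k clusters, ordered by smallest leaf."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"cannot cut {self.n_leaves} leaves into {k} clusters")
        members: dict[int, list[int]] = {i: [i] for i in range(self.n_leaves)}
        for step, (a, b, _) in enumerate(self.merges[: self.n_leaves - k]):
            members[self.n_leaves + step] = sorted(members.pop(a) + members.pop(b))
        return sorted(members.values(), key=min)


def _column_distance(values: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        c = np.corrcoef(values.T)
        return 1.0 - c
    if metric == "euclidean":
        diff = values.T[:, None, :] - values.T[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown distance metric {metric!r}")


def cluster_columns(
    expr: ExpressionMatrix,
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Deterministic agglomerative clustering of expression columns.

    Distances are 1 - Pearson (``correlation``) or Euclidean between column
    vectors; linkage is Lance-Williams ``average`` or ``complete``. Ties in
    the minimum inter-cluster distance are broken toward the pair with the
    lowest cluster indices, so the merge order is fully reproducible.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(expr.columns)
    if n < 2:
        raise ValueError("clustering requires at least 2 columns")
    dist = _column_distance(expr.values, distance)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (a, b), height = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = active.pop(a), active.pop(b)
        new_d: dict[tuple[int, int], float] = {}
        for c in active:
            dac = d[(min(a, c), max(a, c))]
            dbc = d[(min(b, c), max(b, c))]
            if linkage == "average":
                val = (na * dac + nb * dbc) / (na + nb)
            else:
                val = max(dac, dbc)
            new_d[(c, next_id)] = val
        d = {
            (i, j): v
            for (i, j), v in d.items()
            if a not in (i, j) and b not in (i, j)
        }
        d.update(new_d)
        merges.append((a, b, height))
        active[next_id] = na + nb
        next_id += 1
    return Dendrogram(n_leaves=n, merges=merges, columns=list(expr.columns))


def suggest_stage_partition(
    dendrogram: Dendrogram,
    k: int,
    exclude: Sequence[int] = (),
    replicate_collapse: str = "majority",
) -> StagePartition:
    """Cut the column dendrogram into k groups and derive a stage partition.

    Replicate columns of the same time point vote by majority for a group
    (ties go to the lower group index). Excluded time points are removed
    after grouping; the surviving groups become stages labeled ``stage1``,
    ``stage2``, ... in time order, and the derived "whole" stage is the union
    of all non-excluded points.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if replicate_collapse != "majority":
        raise ValueError(f"unknown replicate_collapse {replicate_collapse!r}")
    groups = dendrogram.cut(k)
    # votes[time_index][group] = number of replicate columns in that group
    votes: dict[int, dict[int, int]] = {}
    for gi, leaves in enumerate(groups):
        for leaf in leaves:
            t, _ = dendrogram.columns[leaf]
            votes.setdefault(t, {})[gi] = votes.setdefault(t, {}).get(gi, 0) + 1
    assignment: dict[int, int] = {}
    for t, counts in votes.items():
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        assignment[t] = best[0]

    by_group: dict[int, list[int]] = {}
    for t in sorted(assignment):
        if t in exclude:
            continue
        by_group.setdefault(assignment[t], []).append(t)
    ordered = sorted(by_group.values(), key=min)
    for idx in ordered:
        if len(idx) < MIN_STAGE_POINTS:
            raise ValueError(
                f"a stage would keep only {len(idx)} time points "
                f"({idx}); choose a different k or exclusion set"
            )
    stages = {f"stage{i + 1}": idx for i, idx in enumerate(ordered)}
    return StagePartition(stages=stages, excluded=sorted(int(e) for e in exclude))
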