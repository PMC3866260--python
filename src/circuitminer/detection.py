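"""Permutation-tested Pearson correlation and the circuit significance call.

A circuit candidate (miRNA, TF, gene) is called a circuit within a stage when
all three of its pairwise expression relationships -- miRNA-gene, TF-gene and
miRNA-TF (the TF represented by its coding gene's mRNA profile) -- are
significant at level alpha. Significance of each edge is assessed by a
permutation test on the Pearson correlation R computed over the stage's
columns: one vector is held fixed and the other permuted, exhaustively when
n! is small enough and by seeded Monte-Carlo draws otherwise. Monte-Carlo
p-values use the add-one correction (p = (1 + #extreme) / (B + 1)) so they
are valid and never zero; exhaustive p-values count the identity permutation.

p-values are discrete, so the significance rule is p <= alpha. A useful
counting consequence: over a stage of 3 collapsed points only 6 orderings
exist, so no edge can reach p <= 0.05 there -- which is why replicates are
concatenated (not averaged) by default, doubling the effective n.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_io import CircuitCandidate, EdgeKind, ExpressionMatrix, TFMap
from .stages import StagePartition

log = logging.getLogger(__name__)

TWO_SIDED = "two_sided"
SIGN_CONSTRAINED = "sign_constrained"


@dataclass
class DetectionConfig:
    """Knobs of the per-edge permutation test and the circuit call.

    alpha: significance level for each edge (the published threshold is 0.05).
    n_permutations: Monte-Carlo draws B when exhaustive enumeration is off.
    exhaustive_cap: enumerate all n! permutations whenever n! <= cap.
    tail: ``two_sided`` tests |R|; ``sign_constrained`` tests R against the
        direction required per edge kind in ``sign_constraints``.
    replicate_handling: ``concatenate`` uses every stage column in (time,
        replicate) order; ``average`` collapses replicates to per-time means.
    seed: master seed; each (edge, stage) derives a stable sub-seed from it.
    tie_tolerance: slack when comparing permuted statistics against the
        observed one, so exact ties count as at-least-as-extreme.
    """

    alpha: float = 0.05
    n_permutations: int = 10_000
    exhaustive_cap: int = 10_000
    tail: str = TWO_SIDED
    sign_constraints: dict[EdgeKind, int] | None = None
    replicate_handling: str = "concatenate"
    seed: int = 0
    tie_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.tail not in (TWO_SIDED, SIGN_CONSTRAINED):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.replicate_handling not in ("concatenate", "average"):
            raise ValueError(f"unknown replicate_handling {self.replicate_handling!r}")


@dataclass(frozen=True)
class EdgeTest:
    """Result of testing one regulator-target edge within one stage."""

    edge_kind: EdgeKind
    source_id: str
    target_id: str
    stage: str
    n: int
    r: float  # NaN when undefined (zero-variance vector)
    p: float  # NaN when undefined
    method: str  # "exhaustive" | "monte_carlo" | "undefined"
    permutations_used: int

    @property
    def defined(self) -> bool:
        return self.method != "undefined"

    def significant(self, alpha: float) -> bool:
        return self.defined and self.p <= alpha


@dataclass(frozen=True)
class CircuitResult:
    """The three edge tests of one candidate within one stage and the verdict."""

    candidate: CircuitCandidate
    stage: str
    mirna_gene: EdgeTest
    tf_gene: EdgeTest
    mirna_tf: EdgeTest
    is_circuit: bool

    @property
    def edge_tests(self) -> tuple[EdgeTest, EdgeTest, EdgeTest]:
        return (self.mirna_gene, self.tf_gene, self.mirna_tf)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation R(i,j): centered cross-moment over centered norms.

    Returns NaN (an undefined correlation, not an error) when either vector
    has zero variance. Raises on length mismatch or fewer than 2 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-d vectors")
    if x.size < 2:
        raise ValueError("pearson requires at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


class PermutationResult(NamedTuple):
    p: float
    method: str
    permutations_used: int
    r: float


def _required_sign(config: DetectionConfig, edge_kind: EdgeKind | None) -> int:
    if config.tail == TWO_SIDED:
        return 0
    constraints = config.sign_constraints or {}
    if edge_kind is None or EdgeKind(edge_kind) not in constraints:
        return 0
    return int(np.sign(constraints[EdgeKind(edge_kind)]))


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    config: DetectionConfig,
    rng: np.random.Generator | None = None,
    edge_kind: EdgeKind | None = None,
) -> PermutationResult:
    """Permutation p-value for the correlation of x and y.

    x is held fixed; y is permuted. The test statistic is |R| (two-sided) or
    sign * R when a sign constraint applies to ``edge_kind``. With n! <=
    ``exhaustive_cap`` all n! permutations are enumerated (identity included)
    and p = #{stat_perm >= stat_obs - tol} / n!; otherwise B seeded
    Monte-Carlo permutations give p = (1 + #extreme) / (B + 1). An undefined
    correlation yields the undefined-edge marker rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson(x, y)
    if math.isnan(r_obs):
        return PermutationResult(float("nan"), "undefined", 0, float("nan"))

    sign = _required_sign(config, edge_kind)

    def stat(r: np.ndarray | float) -> np.ndarray | float:
        return np.abs(r) if sign == 0 else sign * np.asarray(r)

    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    stat_obs = float(stat(r_obs))
    tol = config.tie_tolerance

    if math.factorial(n) <= config.exhaustive_cap:
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        r_perm = (yc[perms] @ xc) / denom
        count = int(np.sum(stat(r_perm) >= stat_obs - tol))
        return PermutationResult(count / len(perms), "exhaustive", len(perms), r_obs)

    if rng is None:
        rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    perm_y = rng.permuted(np.broadcast_to(yc, (B, n)).copy(), axis=1)
    r_perm = (perm_y @ xc) / denom
    count = int(np.sum(stat(r_perm) >= stat_obs - tol))
    return PermutationResult((1 + count) / (B + 1), "monte_carlo", B, r_obs)


def _edge_subseed(seed: int, edge_kind: EdgeKind, source: str, target: str, stage: str) -> int:
    token = f"{seed}|{EdgeKind(edge_kind).value}|{source}|{target}|{stage}".encode()
    return int.from_bytes(hashlib.blake2b(token, digest_size=4).digest(), "big") % (2**31)


def stage_vector(
    expr: ExpressionMatrix,
    entity_id: str,
    time_indices: Sequence[int],
    replicate_handling: str = "concatenate",
) -> np.ndarray:
    """Expression vector of an entity over a stage's columns.

    ``concatenate`` keeps every (time, replicate) column in order;
    ``average`` collapses replicates into one mean value per time point.
    """
    row = expr.row(entity_id)
    if replicate_handling == "concatenate":
        return row[expr.column_indices(time_indices)]
    if replicate_handling == "average":
        return np.array(
            [row[expr.column_indices([t])].mean() for t in time_indices], dtype=float
        )
    raise ValueError(f"unknown replicate_handling {replicate_handling!r}")


def _edge_vectors(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    tf_map: TFMap,
    pair: tuple[str, str],
    edge_kind: EdgeKind,
    time_indices: Sequence[int],
    replicate_handling: str,
) -> tuple[np.ndarray, np.ndarray]:
    source, target = pair
    edge_kind = EdgeKind(edge_kind)
    if edge_kind is EdgeKind.MIRNA_GENE:
        return (
            stage_vector(mirna_expr, source, time_indices, replicate_handling),
            stage_vector(gene_expr, target, time_indices, replicate_handling),
        )
    if edge_kind is EdgeKind.TF_GENE:
        coding = tf_map.coding_gene(source)
        return (
            stage_vector(gene_expr, coding, time_indices, replicate_handling),
            stage_vector(gene_expr, target, time_indices, replicate_handling),
        )
    # miRNA -> TF: the TF side is its coding gene's profile
    coding = tf_map.coding_gene(target)
    return (
        stage_vector(mirna_expr, source, time_indices, replicate_handling),
        stage_vector(gene_expr, coding, time_indices, replicate_handling),
    )


def test_edge(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    tf_map: TFMap,
    pair: tuple[str, str],
    edge_kind: EdgeKind,
    stage: tuple[str, Sequence[int]],
    config: DetectionConfig,
) -> EdgeTest:
    """Test one edge within one stage; ``stage`` is a (label, time indices) pair."""
    label, time_indices = stage
    x, y = _edge_vectors(
        mirna_expr, gene_expr, tf_map, pair, edge_kind, time_indices,
        config.replicate_handling,
    )
    sub = _edge_subseed(config.seed, edge_kind, pair[0], pair[1], label)
    res = permutation_pvalue(
        x, y, config, rng=np.random.default_rng(sub), edge_kind=edge_kind
    )
    return EdgeTest(
        edge_kind=EdgeKind(edge_kind),
        source_id=pair[0],
        target_id=pair[1],
        stage=label,
        n=int(x.size),
        r=res.r,
        p=res.p,
        method=res.method,
        permutations_used=res.permutations_used,
    )


def _sign_ok(config: DetectionConfig, test: EdgeTest) -> bool:
    sign = _required_sign(config, test.edge_kind)
    if sign == 0 or not test.defined:
        return True
    return np.sign(test.r) == sign


def detect_circuits(
    candidates: Iterable[CircuitCandidate],
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    tf_map: TFMap,
    partition: StagePartition,
    config: DetectionConfig | None = None,
    use_cache: bool = True,
) -> list[CircuitResult]:
    """Test every candidate in every stage (including "whole").

    Each distinct (pair, stage) edge is tested once and reused across
    candidates sharing it; caching is semantically invisible because per-edge
    sub-seeds depend only on (seed, edge, stage). The output is one
    CircuitResult per (candidate, stage), in candidate order then stage order.
    """
    config = config or DetectionConfig()
    candidates = list(candidates)
    if not candidates:
        log.warning("detect_circuits called with no candidates")
        return []
    cache: dict[tuple, EdgeTest] = {}

    def cached_test(pair: tuple[str, str], edge_kind: EdgeKind, label: str, idx) -> EdgeTest:
        key = (EdgeKind(edge_kind), pair[0], pair[1], label)
        if use_cache and key in cache:
            return cache[key]
        res = test_edge(mirna_expr, gene_expr, tf_map, pair, edge_kind, (label, idx), config)
        if use_cache:
            cache[key] = res
        return res

    results: list[CircuitResult] = []
    for cand in candidates:
        for label, idx in partition.iter_stages():
            mg = cached_test((cand.mirna_id, cand.gene_id), EdgeKind.MIRNA_GENE, label, idx)
            tg = cached_test((cand.tf_id, cand.gene_id), EdgeKind.TF_GENE, label, idx)
            mt = cached_test((cand.mirna_id, cand.tf_id), EdgeKind.MIRNA_TF, label, idx)
            tests = (mg, tg, mt)
            verdict = all(t.significant(config.alpha) for t in tests) and all(
                _sign_ok(config, t) for t in tests
            )
            results.append(
                CircuitResult(
                    candidate=cand,
                    stage=label,
                    mirna_gene=mg,
                    tf_gene=tg,
                    mirna_tf=mt,
                    is_circuit=verdict,
                )
            )
    return results


def results_to_frame(results: Iterable[CircuitResult]) -> pd.DataFrame:
    """Flatten circuit results into the tabular export layout."""
    rows = []
    for res in results:
        rows.append(
            {
                "mirna": res.candidate.mirna_id,
                "tf": res.candidate.tf_id,
                "gene": res.candidate.gene_id,
                "stage": res.stage,
                "r_mg": res.mirna_gene.r,
                "p_mg": res.mirna_gene.p,
                "r_tg": res.tf_gene.r,
                "p_tg": res.tf_gene.p,
                "r_mt": res.mirna_tf.r,
                "p_mt": res.mirna_tf.p,
                "n": res.mirna_gene.n,
                "method_mg": res.mirna_gene.method,
                "method_tg": res.tf_gene.method,
                "method_mt": res.mirna_tf.method,
                "is_circuit": res.is_circuit,
            }
        )
    return pd.DataFrame(rows)
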