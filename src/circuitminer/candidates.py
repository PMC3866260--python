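"""Variance filtering of the expression universe and candidate assembly.

A circuit candidate (m, t, g) exists when the miRNA-gene, TF-gene and
miRNA-TF pair sets each contain the corresponding edge and all three
entities survive their expression universes -- the TF through its coding
gene. Genes with little variation across the whole time course are removed
first, since a near-constant profile cannot carry correlation evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .data_io import (
    CircuitCandidate,
    EntityKind,
    ExpressionMatrix,
    InteractionSet,
    TFMap,
    id_key,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariancePolicy:
    """How to drop low-variance rows.

    ``absolute_threshold``: keep rows with variance strictly greater than
    ``value``. ``quantile``: drop the lowest floor(value * n) rows by
    variance (stable order; value in [0, 1)), so value=0 keeps everything
    and value=0.25 drops exactly the bottom quartile.
    """

    mode: str = "quantile"
    value: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("absolute_threshold", "quantile"):
            raise ValueError(f"unknown variance policy mode {self.mode!r}")
        if self.mode == "quantile" and not 0 <= self.value < 1:
            raise ValueError("quantile value must be in [0, 1)")
        if self.mode == "absolute_threshold" and self.value < 0:
            raise ValueError("absolute threshold must be >= 0")


def variance_filter(
    expr: ExpressionMatrix, policy: VariancePolicy
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Split entities into retained and dropped by row variance.

    Variance is the unbiased (n-1) sample variance across all columns (every
    time point, every replicate). Returns the filtered matrix plus retained
    and dropped id lists in input order. A policy removing every entity is an
    error.
    """
    if expr.n_entities == 0:
        raise ValueError("variance_filter requires a non-empty matrix")
    variances = expr.values.var(axis=1, ddof=1)
    n = expr.n_entities
    if policy.mode == "absolute_threshold":
        keep = variances > policy.value
    else:
        k = int(np.floor(policy.value * n))
        order = np.argsort(variances, kind="stable")
        keep = np.ones(n, dtype=bool)
        keep[order[:k]] = False
    retained = [e for e, m in zip(expr.entity_ids, keep) if m]
    dropped = [e for e, m in zip(expr.entity_ids, keep) if not m]
    if not retained:
        raise ValueError("variance policy removed every entity")
    log.info(
        "variance filter (%s=%g): %d retained, %d dropped",
        policy.mode, policy.value, len(retained), len(dropped),
    )
    return expr.subset(retained), retained, dropped


def assemble_candidates(
    mg: InteractionSet,
    tg: InteractionSet,
    mt: InteractionSet,
    tf_map: TFMap,
    gene_universe: Iterable[str],
    mirna_universe: Iterable[str],
    allow_tf_self_target: bool = False,
) -> list[CircuitCandidate]:
    """Combine the three pair sets into deduplicated candidate triples.

    (m, t, g) is emitted iff (m,g) in mg, (t,g) in tg, (m,t) in mt, m and g
    are in their universes, the TF's coding gene is in the gene universe, and
    g is not the TF's own coding gene (unless ``allow_tf_self_target``). TFs
    without a coding-gene mapping are excluded with a logged count. Output in
    lexicographic order.
    """
    gene_keys = {id_key(g, EntityKind.GENE) for g in gene_universe}
    mirna_keys = {id_key(m, EntityKind.MIRNA) for m in mirna_universe}

    def gkey(x: str) -> str:
        return id_key(x, EntityKind.GENE)

    def mkey(x: str) -> str:
        return id_key(x, EntityKind.MIRNA)

    # index mg by gene and mt by tf for the join over tg
    mg_by_gene: dict[str, set[str]] = {}
    for m, g in mg.pairs:
        if mkey(m) in mirna_keys and gkey(g) in gene_keys:
            mg_by_gene.setdefault(gkey(g), set()).add(m)
    mt_by_tf: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for m, t in mt.pairs:
        if mkey(m) not in mirna_keys:
            continue
        if t not in tf_map:
            unmapped.add(t)
            continue
        mt_by_tf.setdefault(gkey(t), set()).add(m)

    out: set[CircuitCandidate] = set()
    seen_keys: set[tuple[str, str, str]] = set()
    for t, g in tg.pairs:
        if t not in tf_map:
            unmapped.add(t)
            continue
        coding = tf_map.coding_gene(t)
        if gkey(coding) not in gene_keys or gkey(g) not in gene_keys:
            continue
        if not allow_tf_self_target and gkey(g) == gkey(coding):
            continue
        mirnas = mg_by_gene.get(gkey(g), set()) & mt_by_tf.get(gkey(t), set())
        for m in mirnas:
            key = (mkey(m), gkey(t), gkey(g))
            if key not in seen_keys:
                seen_keys.add(key)
                out.add(CircuitCandidate(m, t, g))
    if unmapped:
        log.info("%d TFs without a coding-gene mapping were excluded", len(unmapped))
    return sorted(out)


def write_candidates(candidates: Iterable[CircuitCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttf\tgene\n")
        for c in candidates:
            fh.write(f"{c.mirna_id}\t{c.tf_id}\t{c.gene_id}\n")
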