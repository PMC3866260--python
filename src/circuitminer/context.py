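"""Downstream set analyses over detected circuits.

Everything here is pure set algebra over circuit results: Venn-style
overlaps of circuits and their member node classes across stages,
restriction of circuits to a context gene set (tissue-specific or cancer
genes), regulators exclusive to out-of-context circuits, and the merged
network of cross-stage common nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .data_io import CircuitCandidate, EntityKind, GeneSet, id_key
from .detection import CircuitResult

log = logging.getLogger(__name__)

NODE_CLASSES = ("circuit", "tf", "mirna", "gene")


def circuits_by_stage(results: Iterable[CircuitResult]) -> dict[str, set[CircuitCandidate]]:
    """Stage label -> set of candidate triples with is_circuit true."""
    out: dict[str, set[CircuitCandidate]] = {}
    for res in results:
        out.setdefault(res.stage, set())
        if res.is_circuit:
            out[res.stage].add(res.candidate)
    return out


@dataclass
class OverlapReport:
    """Venn decomposition per node class over a list of stages.

    ``regions[cls]`` maps each non-empty stage-membership pattern (a
    frozenset of stage labels) to the sorted ids landing exactly there.
    """

    stages: list[str]
    regions: dict[str, dict[frozenset[str], list]]

    def counts(self, cls: str) -> dict[frozenset[str], int]:
        return {pat: len(ids) for pat, ids in self.regions[cls].items()}

    def union_size(self, cls: str) -> int:
        return sum(len(ids) for ids in self.regions[cls].values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in NODE_CLASSES:
            for pat, ids in sorted(
                self.regions[cls].items(), key=lambda kv: sorted(kv[0])
            ):
                rows.append(
                    {
                        "class": cls,
                        "stages": "&".join(sorted(pat)),
                        "count": len(ids),
                    }
                )
        return pd.DataFrame(rows, columns=["class", "stages", "count"])


def _members(circuits: set[CircuitCandidate], cls: str) -> set:
    if cls == "circuit":
        return set(circuits)
    field = {"mirna": "mirna_id", "tf": "tf_id", "gene": "gene_id"}[cls]
    return {getattr(c, field) for c in circuits}


def overlap_analysis(
    results: Iterable[CircuitResult], stages: Sequence[str]
) -> OverlapReport:
    """Venn region sizes and id lists for circuits, TFs, miRNAs and genes."""
    results = list(results)
    known = {res.stage for res in results}
    for s in stages:
        if s not in known:
            raise ValueError(f"unknown stage label {s!r}")
    by_stage = circuits_by_stage(results)
    regions: dict[str, dict[frozenset[str], list]] = {}
    for cls in NODE_CLASSES:
        membership: dict = {}
        for s in stages:
            for item in _members(by_stage.get(s, set()), cls):
                membership.setdefault(item, set()).add(s)
        cls_regions: dict[frozenset[str], list] = {}
        for item, pat in membership.items():
            cls_regions.setdefault(frozenset(pat), []).append(item)
        regions[cls] = {pat: sorted(ids) for pat, ids in cls_regions.items()}
    return OverlapReport(stages=list(stages), regions=regions)


def subset_by_gene_set(
    results: Iterable[CircuitResult], gene_set: GeneSet, mode: str = "within"
) -> list[CircuitResult]:
    """Circuit results whose target gene lies within (or outside) a gene set.

    Edge tests are carried through untouched; ``within`` and ``outside``
    partition the input disjointly.
    """
    if mode not in ("within", "outside"):
        raise ValueError(f"unknown mode {mode!r}")
    keys = gene_set.keys
    out = [
        res
        for res in results
        if (id_key(res.candidate.gene_id, EntityKind.GENE) in keys) == (mode == "within")
    ]
    if not out:
        log.info("subset_by_gene_set(%s, %s) is empty", gene_set.name, mode)
    return out


def exclusive_regulators(
    results: Iterable[CircuitResult], gene_set: GeneSet
) -> dict[str, tuple[set[str], set[str]]]:
    """Per stage: (TFs, miRNAs) regulating only genes outside the gene set.

    A regulator is exclusive when it occurs in at least one out-of-context
    circuit and in no within-context circuit of that stage.
    """
    results = list(results)
    within = circuits_by_stage(subset_by_gene_set(results, gene_set, "within"))
    outside = circuits_by_stage(subset_by_gene_set(results, gene_set, "outside"))
    out: dict[str, tuple[set[str], set[str]]] = {}
    for stage in {res.stage for res in results}:
        w, o = within.get(stage, set()), outside.get(stage, set())
        out[stage] = (
            _members(o, "tf") - _members(w, "tf"),
            _members(o, "mirna") - _members(w, "mirna"),
        )
    return out


def circuit_network(
    circuits: Iterable[CircuitCandidate], stage: str | None = None
) -> nx.DiGraph:
    """Typed regulatory network of the given circuits (3 edges per circuit)."""
    g = nx.DiGraph()
    for c in circuits:
        g.add_node(c.mirna_id, type="mirna")
        g.add_node(c.tf_id, type="tf")
        g.add_node(c.gene_id, type="gene")
        for s, t, rel in (
            (c.mirna_id, c.gene_id, "mirna_gene"),
            (c.tf_id, c.gene_id, "tf_gene"),
            (c.mirna_id, c.tf_id, "mirna_tf"),
        ):
            if g.has_edge(s, t):
                stages = set(g[s][t].get("stages", ()))
            else:
                stages = set()
            if stage is not None:
                stages.add(stage)
            g.add_edge(s, t, relation=rel, stages=tuple(sorted(stages)))
    return g


def common_node_network(
    results: Iterable[CircuitResult],
    stage_a: str,
    stage_b: str,
    context_set: GeneSet | None = None,
) -> nx.DiGraph:
    """Merged network of circuits touching a cross-stage common node.

    Optionally restricted to circuits whose gene is in ``context_set``; a
    circuit is kept when at least one of its three members (same class) is
    present in both stages' circuits. Edges carry stage tags.
    """
    results = list(results)
    known = {res.stage for res in results}
    for s in (stage_a, stage_b):
        if s not in known:
            raise ValueError(f"unknown stage label {s!r}")
    if context_set is not None:
        results = subset_by_gene_set(results, context_set, "within")
    by_stage = circuits_by_stage(results)
    ca, cb = by_stage.get(stage_a, set()), by_stage.get(stage_b, set())
    common = {
        cls: _members(ca, cls) & _members(cb, cls)
        for cls in ("tf", "mirna", "gene")
    }

    def touches_common(c: CircuitCandidate) -> bool:
        return (
            c.tf_id in common["tf"]
            or c.mirna_id in common["mirna"]
            or c.gene_id in common["gene"]
        )

    g = nx.DiGraph()
    for stage, circuits in ((stage_a, ca), (stage_b, cb)):
        kept = {c for c in circuits if touches_common(c)}
        sub = circuit_network(kept, stage=stage)
        for node, data in sub.nodes(data=True):
            g.add_node(node, **data)
        for s, t, data in sub.edges(data=True):
            if g.has_edge(s, t):
                stages = tuple(sorted(set(g[s][t]["stages"]) | set(data["stages"])))
                g[s][t]["stages"] = stages
            else:
                g.add_edge(s, t, **data)
    return g


@dataclass
class CancerContext:
    """Cancer-gene circuits per stage and their tissue-specific core."""

    cancer_circuits: dict[str, set[CircuitCandidate]]
    tissue_cancer_circuits: dict[str, set[CircuitCandidate]]
    summary: pd.DataFrame


def cancer_context(
    results: Iterable[CircuitResult],
    cancer_set: GeneSet,
    tissue_set: GeneSet,
) -> CancerContext:
    """Circuits targeting cancer genes, then the tissue-specific subset.

    Composes two within-set restrictions and summarizes distinct TF/miRNA/
    gene counts per stage at both levels.
    """
    if len(cancer_set) == 0 or len(tissue_set) == 0:
        raise ValueError("context gene sets must be non-empty")
    results = list(results)
    cancer = subset_by_gene_set(results, cancer_set, "within")
    tissue_cancer = subset_by_gene_set(cancer, tissue_set, "within")
    c_by = circuits_by_stage(cancer)
    tc_by = circuits_by_stage(tissue_cancer)
    rows = []
    for level, by in (("cancer", c_by), ("tissue_cancer", tc_by)):
        for stage in sorted(by):
            circuits = by[stage]
            rows.append(
                {
                    "level": level,
                    "stage": stage,
                    "n_circuits": len(circuits),
                    "n_tfs": len(_members(circuits, "tf")),
                    "n_mirnas": len(_members(circuits, "mirna")),
                    "n_genes": len(_members(circuits, "gene")),
                }
            )
    summary = pd.DataFrame(
        rows, columns=["level", "stage", "n_circuits", "n_tfs", "n_mirnas", "n_genes"]
    )
    return CancerContext(
        cancer_circuits=c_by, tissue_cancer_circuits=tc_by, summary=summary
    )
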