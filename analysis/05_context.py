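#!/usr/bin/env python
"""Stage overlaps and gene-set contexts over the detected circuits.

Computes the Venn decomposition of circuits/TFs/miRNAs/genes across the
early, late and whole stages, then re-reads the detected circuits in the
context of two synthetic gene lists standing in for tissue-specific and
cancer gene sets: which circuits target in-context genes, which regulators
act exclusively outside the context, and the merged network of cross-stage
common nodes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import circuitminer as cm
from circuitminer.detection import EdgeTest

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def load_results() -> list[cm.CircuitResult]:
    frame = pd.read_csv(OUT / "results.tsv", sep="\t")
    results = []
    for r in frame.itertuples():
        cand = cm.CircuitCandidate(r.mirna, r.tf, r.gene)
        def edge(kind, s, t, rr, p):
            return EdgeTest(edge_kind=kind, source_id=s, target_id=t, stage=r.stage,
                            n=int(r.n), r=rr, p=p, method="exhaustive",
                            permutations_used=0)
        results.append(
            cm.CircuitResult(
                candidate=cand, stage=r.stage,
                mirna_gene=edge(cm.EdgeKind.MIRNA_GENE, r.mirna, r.gene, r.r_mg, r.p_mg),
                tf_gene=edge(cm.EdgeKind.TF_GENE, r.tf, r.gene, r.r_tg, r.p_tg),
                mirna_tf=edge(cm.EdgeKind.MIRNA_TF, r.mirna, r.tf, r.r_mt, r.p_mt),
                is_circuit=bool(r.is_circuit),
            )
        )
    return results


def main() -> None:
    if not (OUT / "results.tsv").exists():
        raise SystemExit("run analysis/04_detect.py first")
    results = load_results()
    rep = cm.overlap_analysis(results, ["early", "late", "whole"])
    rep.to_frame().to_csv(OUT / "overlap.tsv", sep="\t", index=False)
    print("overlap regions (circuits):")
    for pat, count in sorted(rep.counts("circuit").items(), key=lambda kv: sorted(kv[0])):
        print(f"  {'&'.join(sorted(pat))}: {count}")

    # synthetic context sets: a 'tissue' list covering part of the circuit
    # genes and a 'cancer' list overlapping it, mirroring how the real lists
    # arrive as opaque files
    genes = sorted({r.candidate.gene_id for r in results if r.is_circuit})
    rng = np.random.default_rng(0)
    tissue = cm.GeneSet(name="tissue_specific_synthetic",
                        ids=frozenset(rng.choice(genes, size=len(genes) // 2,
                                                 replace=False)))
    cancer_pool = sorted(set(genes))
    cancer = cm.GeneSet(name="cancer_synthetic",
                        ids=frozenset(rng.choice(cancer_pool,
                                                 size=len(cancer_pool) // 3,
                                                 replace=False)))
    within = cm.subset_by_gene_set(results, tissue, "within")
    outside = cm.subset_by_gene_set(results, tissue, "outside")
    print(f"tissue context: {sum(r.is_circuit for r in within)} in-context vs "
          f"{sum(r.is_circuit for r in outside)} out-of-context circuit calls")
    excl = cm.exclusive_regulators(results, tissue)
    for stage in ("early", "late"):
        tfs, mirnas = excl[stage]
        print(f"  {stage}: {len(tfs)} exclusive TFs, {len(mirnas)} exclusive miRNAs")

    net = cm.common_node_network(results, "early", "late", context_set=tissue)
    cm.export_network(net, "graphml", OUT / "common_node_network.graphml")
    print(f"common-node network: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges -> common_node_network.graphml")

    cc = cm.cancer_context(results, cancer, tissue)
    cc.summary.to_csv(OUT / "cancer_context.tsv", sep="\t", index=False)
    print("cancer-gene circuit summary:")
    print(cc.summary.to_string(index=False))


if __name__ == "__main__":
    main()
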