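#!/usr/bin/env python
"""Variance-filter the gene universe and assemble circuit candidates.

Reads the simulated dataset from results/data/, drops the lowest-variance
quartile of gene rows (the near-constant profiles that cannot carry
correlation evidence), and joins the three interaction pair sets into
(miRNA, TF, gene) candidate triples. In the emulated data the planted genes
carry stage-confined signal and survive the filter; candidates are written
to results/analysis/candidates.tsv.
"""

from pathlib import Path

import circuitminer as cm
from circuitminer.candidates import write_candidates

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    if not (DATA / "gene_expression.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    gene_expr = cm.read_expression(DATA / "gene_expression.tsv", cm.EntityKind.GENE)
    mirna_expr = cm.read_expression(DATA / "mirna_expression.tsv", cm.EntityKind.MIRNA)
    _, retained, dropped = cm.variance_filter(
        gene_expr, cm.VariancePolicy("quantile", 0.25)
    )
    print(f"variance filter: {len(gene_expr.entity_ids)} gene rows -> "
          f"{len(retained)} retained, {len(dropped)} dropped")
    cands = cm.assemble_candidates(
        cm.read_pairs(DATA / "mirna_gene_pairs.tsv", cm.EdgeKind.MIRNA_GENE),
        cm.read_pairs(DATA / "tf_gene_pairs.tsv", cm.EdgeKind.TF_GENE),
        cm.read_pairs(DATA / "mirna_tf_pairs.tsv", cm.EdgeKind.MIRNA_TF),
        cm.read_tf_map(DATA / "tf_map.tsv"),
        gene_universe=retained,
        mirna_universe=mirna_expr.entity_ids,
    )
    write_candidates(cands, OUT / "candidates.tsv")
    n_m = len({c.mirna_id for c in cands})
    n_t = len({c.tf_id for c in cands})
    n_g = len({c.gene_id for c in cands})
    print(f"{len(cands)} circuit candidates "
          f"({n_m} miRNAs, {n_t} TFs, {n_g} genes) -> {OUT / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
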