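#!/usr/bin/env python
"""Over-representation of per-stage circuit genes against a GMT collection.

Builds a synthetic annotation collection in which one term is enriched for
early-stage circuit genes and one for late-stage genes (plus random terms),
then scores each stage's circuit gene list with the exact hypergeometric
tail against the variance-filtered analysis universe, BH-adjusted within
the collection. Stands in for a biological-process/pathway analysis whose
annotation database arrives as a file.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import circuitminer as cm
from circuitminer.data_io import GeneSet, write_gmt
from circuitminer.enrichment import enrichment_to_frame

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    if not (OUT / "results.tsv").exists():
        raise SystemExit("run analysis/04_detect.py first")
    frame = pd.read_csv(OUT / "results.tsv", sep="\t")
    gene_expr = cm.read_expression(DATA / "gene_expression.tsv", cm.EntityKind.GENE)
    _, retained, _ = cm.variance_filter(gene_expr, cm.VariancePolicy("quantile", 0.25))
    universe = GeneSet(name="analysis_universe", ids=frozenset(retained))

    circuits = frame[frame["is_circuit"]]
    stage_genes = {
        stage: sorted(set(sub["gene"]) & universe.ids)
        for stage, sub in circuits.groupby("stage")
    }
    rng = np.random.default_rng(1)
    uni_list = sorted(universe.ids)
    collection = []
    for stage in ("early", "late"):
        core = stage_genes.get(stage, [])
        pad = rng.choice(uni_list, size=10, replace=False).tolist()
        collection.append(
            GeneSet(name=f"term_{stage}_biased", ids=frozenset(core[:15] + pad))
        )
    for i in range(4):
        collection.append(
            GeneSet(name=f"term_random_{i}",
                    ids=frozenset(rng.choice(uni_list, size=25, replace=False)))
        )
    write_gmt(collection, OUT / "collection.gmt")

    frames = []
    for stage, genes in stage_genes.items():
        if not genes:
            continue
        rows = cm.enrich(
            GeneSet(name=f"{stage}_circuit_genes", ids=frozenset(genes)),
            collection, universe,
        )
        f = enrichment_to_frame(rows)
        f.insert(0, "stage", stage)
        frames.append(f)
        top = rows[0]
        print(f"{stage}: top term {top.term} (k={top.k}/{top.K}, p={top.p:.3g}, "
              f"BH={top.p_adjusted:.3g})")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    print(f"enrichment table -> {OUT / 'enrichment.tsv'}")


if __name__ == "__main__":
    main()
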