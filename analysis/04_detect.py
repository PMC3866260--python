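#!/usr/bin/env python
"""Detect significant circuits per stage and score recovery of the truth.

For every candidate and every stage (early, late, whole) the three edges are
tested by exhaustive or Monte-Carlo permutation of the Pearson correlation;
a candidate is a circuit where all three p-values are <= 0.05. The detected
set is compared against the generator's planted ledger.
"""

from pathlib import Path

import pandas as pd

import circuitminer as cm
from circuitminer.detection import results_to_frame

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    cand_path = OUT / "candidates.tsv"
    if not cand_path.exists():
        raise SystemExit("run analysis/02_candidates.py first")
    cands = [
        cm.CircuitCandidate(r.mirna, r.tf, r.gene)
        for r in pd.read_csv(cand_path, sep="\t").itertuples()
    ]
    mirna_expr = cm.read_expression(DATA / "mirna_expression.tsv", cm.EntityKind.MIRNA)
    gene_expr = cm.read_expression(DATA / "gene_expression.tsv", cm.EntityKind.GENE)
    tf_map = cm.read_tf_map(DATA / "tf_map.tsv")
    part = cm.preset_early_late()
    results = cm.detect_circuits(
        cands, mirna_expr, gene_expr, tf_map, part, cm.DetectionConfig(seed=2)
    )
    frame = results_to_frame(results)
    frame.to_csv(OUT / "results.tsv", sep="\t", index=False)

    truth = pd.read_csv(DATA / "truth.tsv", sep="\t")
    planted = {
        (cm.CircuitCandidate(r.mirna, r.tf, r.gene), r.stage)
        for r in truth.itertuples()
    }
    detected = {(r.candidate, r.stage) for r in results if r.is_circuit}
    for stage in part.labels:
        n = len({c for c, s in detected if s == stage})
        print(f"stage {stage}: {n} circuits detected")
    for stage in ("early", "late"):
        p = {c for c, s in planted if s == stage}
        hit = sum((c, stage) in detected for c in p)
        print(f"  recall in {stage}: {hit}/{len(p)} = {hit / len(p):.2f}")
    print(f"results table -> {OUT / 'results.tsv'}")


if __name__ == "__main__":
    main()
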