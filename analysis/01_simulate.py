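#!/usr/bin/env python
"""Generate the synthetic developmental time course used by all later steps.

Emulates a 7-time-point, two-replicate miRNA + gene expression study with an
early (t1-t3) and late (t4-t6) stage, 50 planted circuits per stage whose
three edges correlate at |R| ~ 0.95 within their stage only, and decoy
interaction pairs that are listed but expression-independent. Outputs land
in results/data/ in the exact TSV/YAML formats the readers consume.
"""

import sys
from pathlib import Path

import circuitminer as cm

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 1) -> None:
    cfg = cm.SimConfig(seed=seed)
    ds = cm.generate_dataset(cfg)
    paths = cm.write_dataset(ds, OUT)
    truth = ds.truth
    print(f"wrote {len(paths)} files under {OUT}")
    print(f"  miRNAs: {ds.mirna_expr.n_entities}, gene rows: {ds.gene_expr.n_entities} "
          f"(incl. {len(ds.tf_map.mapping)} TF coding genes)")
    for kind, iset in ds.interactions.items():
        print(f"  {kind.value} pairs: {len(iset)}")
    per_stage = {}
    for pc in truth.planted_circuits:
        per_stage[pc.stage] = per_stage.get(pc.stage, 0) + 1
    print(f"  planted circuits: {per_stage}; "
          f"decoys per edge kind: { {k.value: len(v) for k, v in truth.decoy_pairs.items()} }")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
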