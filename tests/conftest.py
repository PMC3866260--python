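import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import circuitminer as cm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> cm.SimConfig:
    return cm.SimConfig(
        n_mirnas=30,
        n_tfs=25,
        n_genes=40,
        n_planted_per_stage=10,
        n_decoy_pairs=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> cm.SyntheticDataset:
    return cm.generate_dataset(small_config)


@pytest.fixture(scope="session")
def planted_dataset() -> cm.SyntheticDataset:
    """Full-size planted dataset at the emulated study design defaults."""
    return cm.generate_dataset(cm.SimConfig(seed=11))


@pytest.fixture(scope="session")
def planted_results(planted_dataset):
    """Detection run over the candidates assembled from the planted dataset."""
    ds = planted_dataset
    cands = cm.assemble_candidates(
        ds.interactions[cm.EdgeKind.MIRNA_GENE],
        ds.interactions[cm.EdgeKind.TF_GENE],
        ds.interactions[cm.EdgeKind.MIRNA_TF],
        ds.tf_map,
        gene_universe=ds.gene_expr.entity_ids,
        mirna_universe=ds.mirna_expr.entity_ids,
    )
    results = cm.detect_circuits(
        cands,
        ds.mirna_expr,
        ds.gene_expr,
        ds.tf_map,
        ds.config.stage_design,
        cm.DetectionConfig(seed=101),
    )
    return cands, results


def make_fake_results(
    rng: np.random.Generator,
    n_mirnas: int = 6,
    n_tfs: int = 4,
    n_genes: int = 10,
    stages: tuple[str, ...] = ("early", "late", "whole"),
    p_circuit: float = 0.4,
) -> list[cm.CircuitResult]:
    """Random CircuitResults for set-algebra tests (no expression involved)."""
    from circuitminer.detection import EdgeTest

    results = []
    for mi in range(n_mirnas):
        for ti in range(n_tfs):
            for gi in range(n_genes):
                if rng.random() > 0.15:
                    continue
                cand = cm.CircuitCandidate(f"mir-{mi}", f"TF{ti}", f"G{gi}")
                for stage in stages:
                    hit = bool(rng.random() < p_circuit)
                    p = 0.01 if hit else 0.5
                    tests = {}
                    for kind, s, t in (
                        (cm.EdgeKind.MIRNA_GENE, cand.mirna_id, cand.gene_id),
                        (cm.EdgeKind.TF_GENE, cand.tf_id, cand.gene_id),
                        (cm.EdgeKind.MIRNA_TF, cand.mirna_id, cand.tf_id),
                    ):
                        tests[kind] = EdgeTest(
                            edge_kind=kind, source_id=s, target_id=t, stage=stage,
                            n=6, r=0.9 if hit else 0.1, p=p, method="exhaustive",
                            permutations_used=720,
                        )
                    results.append(
                        cm.CircuitResult(
                            candidate=cand,
                            stage=stage,
                            mirna_gene=tests[cm.EdgeKind.MIRNA_GENE],
                            tf_gene=tests[cm.EdgeKind.TF_GENE],
                            mirna_tf=tests[cm.EdgeKind.MIRNA_TF],
                            is_circuit=hit,
                        )
                    )
    return results
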