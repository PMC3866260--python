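"""Synthetic time-course datasets with planted, stage-confined circuits.

The generator emulates a two-class developmental time course: miRNAs and
genes measured over an ordered time axis (default 7 points, two replicates
per point, mirroring a two-animal design), a TF-to-coding-gene map, and three
typed interaction pair sets. Every entity's value at (time, replicate) is a
per-time mean plus independent Gaussian replicate noise. Background entities
and planted entities outside their stage have mean 0 everywhere, so their
columns are exchangeable and form an exact permutation null. Each planted
circuit owns a latent driver s(t) -- i.i.d. standard-normal draws over its
stage's time points -- and its three member entities load on the driver with
coefficient +/- a, where

    a = noise_sd * sqrt(r / (1 - r)),   r = edge_target_abs_r,

so the expected within-stage correlation between any two members is r (each
observed profile correlates sqrt(r) with the latent driver, and the pairwise
correlation is the product). Decoy pairs are listed in the interaction sets
but drawn among background entities, independent of all expression. The
whole run is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    CircuitCandidate,
    EdgeKind,
    EntityKind,
    ExpressionMatrix,
    InteractionSet,
    TFMap,
)
from .detection import pearson, stage_vector
from .stages import StagePartition, preset_early_late


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study design.

    ``max_alias_correlation`` keeps planted drivers permutation-identifiable:
    a short stage (3 time points, replicates duplicated) admits rearrangements
    of any profile that correlate strongly with the original -- for a
    two-replicate three-point stage the best achievable profile still has a
    rearrangement at |corr| ~ 0.91 -- and a driver whose best rearrangement
    nearly ties the identity cannot be distinguished from it by an exact
    permutation test. Drivers are redrawn until no rearrangement of their
    replicated stage profile exceeds this absolute correlation with the
    original, so "planted" always means "recoverable in principle". The
    default sits just above the geometric floor, keeping aliases well below
    the planted alignment relative to the correlation noise scale.
    """

    n_timepoints: int = 7
    n_replicates: int = 2
    stage_design: StagePartition = field(default_factory=preset_early_late)
    n_mirnas: int = 120
    n_tfs: int = 110
    n_genes: int = 300
    n_planted_per_stage: int = 50
    edge_target_abs_r: float = 0.95
    mirna_sign: str = "negative"  # or "unconstrained"
    noise_sd: float = 0.05
    n_decoy_pairs: int = 50
    n_extra_pairs: int = 0
    max_alias_correlation: float = 0.93
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_timepoints", "n_replicates", "n_mirnas", "n_tfs", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.edge_target_abs_r < 1:
            raise ValueError("edge_target_abs_r must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mirna_sign not in ("negative", "unconstrained"):
            raise ValueError(f"unknown mirna_sign {self.mirna_sign!r}")
        if self.n_planted_per_stage < 0 or self.n_decoy_pairs < 0:
            raise ValueError("counts must be non-negative")
        if not 0.9 < self.max_alias_correlation < 1:
            # below ~0.91 no replicated 3-point driver can satisfy the bound
            raise ValueError("max_alias_correlation must be in (0.9, 1)")

    @property
    def signal_coefficient(self) -> float:
        r = self.edge_target_abs_r
        return self.noise_sd * float(np.sqrt(r / (1.0 - r)))

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            k: getattr(self, k)
            for k in (
                "n_timepoints", "n_replicates", "n_mirnas", "n_tfs", "n_genes",
                "n_planted_per_stage", "edge_target_abs_r", "mirna_sign",
                "noise_sd", "n_decoy_pairs", "n_extra_pairs", "seed",
            )
        }
        doc["stage_design"] = {
            **{k: list(v) for k, v in self.stage_design.stages.items()},
            "excluded": list(self.stage_design.excluded),
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        sd = doc.pop("stage_design", None)
        if sd is not None:
            excluded = [int(i) for i in sd.pop("excluded", [])]
            doc["stage_design"] = StagePartition(
                stages={k: [int(i) for i in v] for k, v in sd.items()},
                excluded=excluded,
                n_timepoints=int(doc.get("n_timepoints", 7)),
            )
        return cls(**doc)


def _max_alias_abs_corr(pattern: np.ndarray, rng: np.random.Generator) -> float:
    """Largest |corr| between a profile and any non-trivial rearrangement.

    Rearrangements that reproduce the pattern exactly (replicate swaps within
    a time point) are not aliases and are skipped. Exhaustive for n <= 8,
    Monte-Carlo (2000 draws) beyond that, where aliasing is negligible anyway.
    """
    import itertools
    import math

    p = np.asarray(pattern, dtype=float)
    n = p.size
    pc = p - p.mean()
    norm = float(pc @ pc)
    if norm == 0:
        return 1.0
    if math.factorial(n) <= 40_320:
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    else:
        perms = rng.permuted(np.broadcast_to(np.arange(n), (2000, n)).copy(), axis=1)
    rearranged = pc[perms]
    keep = ~np.all(rearranged == pc, axis=1)
    if not np.any(keep):
        return 0.0
    corrs = (rearranged[keep] @ pc) / norm
    return float(np.max(np.abs(corrs)))


def _draw_driver(
    rng: np.random.Generator,
    n_points: int,
    n_replicates: int,
    max_alias: float,
    max_tries: int = 1000,
) -> np.ndarray:
    """Standardized stage driver whose replicated profile has no strong alias.

    The alias bound is enforced only for short stages (replicated length
    <= 6): there a handful of aliasing rearrangements is a sizeable share of
    the n! permutation budget and can mask a planted edge, whereas for longer
    stages aliases are a vanishing fraction of n! (and close duplicated
    values make an absolute bound unattainable anyway).
    """
    check_alias = n_points * n_replicates <= 6
    for _ in range(max_tries):
        s = rng.standard_normal(n_points)
        sd = s.std(ddof=1)
        if sd == 0:
            continue
        s = (s - s.mean()) / sd
        if not check_alias:
            return s
        if _max_alias_abs_corr(np.repeat(s, n_replicates), rng) <= max_alias:
            return s
    raise RuntimeError(
        f"could not draw an identifiable {n_points}-point driver in {max_tries} tries; "
        f"raise max_alias_correlation"
    )


@dataclass(frozen=True)
class PlantedCircuit:
    candidate: CircuitCandidate
    stage: str
    edge_signs: dict[EdgeKind, int]  # designed sign of each edge's correlation


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of what the generator planted."""

    planted_circuits: list[PlantedCircuit]
    decoy_pairs: dict[EdgeKind, set[tuple[str, str]]]
    latent_profiles: dict[tuple[str, int], np.ndarray]

    def planted_edges(self) -> dict[EdgeKind, set[tuple[str, str]]]:
        out: dict[EdgeKind, set[tuple[str, str]]] = {k: set() for k in EdgeKind}
        for pc in self.planted_circuits:
            m, t, g = pc.candidate
            out[EdgeKind.MIRNA_GENE].add((m, g))
            out[EdgeKind.TF_GENE].add((t, g))
            out[EdgeKind.MIRNA_TF].add((m, t))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": pc.candidate.mirna_id,
                "tf": pc.candidate.tf_id,
                "gene": pc.candidate.gene_id,
                "stage": pc.stage,
                "sign_mg": pc.edge_signs[EdgeKind.MIRNA_GENE],
                "sign_tg": pc.edge_signs[EdgeKind.TF_GENE],
                "sign_mt": pc.edge_signs[EdgeKind.MIRNA_TF],
            }
            for pc in self.planted_circuits
        ]
        return pd.DataFrame(
            rows, columns=["mirna", "tf", "gene", "stage", "sign_mg", "sign_tg", "sign_mt"]
        )


@dataclass
class SyntheticDataset:
    mirna_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    tf_map: TFMap
    interactions: dict[EdgeKind, InteractionSet]
    truth: SyntheticTruth
    config: SimConfig


def _expression(
    kind: EntityKind,
    ids: list[str],
    means: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Expand per-time means to replicate columns and add Gaussian noise."""
    n_t, n_r = config.n_timepoints, config.n_replicates
    cols = [(t, f"r{r + 1}") for t in range(n_t) for r in range(n_r)]
    values = np.repeat(means, n_r, axis=1) + rng.normal(
        0.0, config.noise_sd, size=(len(ids), n_t * n_r)
    )
    return ExpressionMatrix(
        kind=kind,
        entity_ids=ids,
        time_points=[f"t{i + 1}" for i in range(n_t)],
        columns=cols,
        values=values,
    )


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate expression, interaction sets and the truth ledger from a seed."""
    n_stages = len(config.stage_design.stages)
    needed = n_stages * config.n_planted_per_stage
    if needed > min(config.n_mirnas, config.n_tfs, config.n_genes):
        raise ValueError(
            f"{needed} planted circuits need {needed} distinct entities per class; "
            f"only {config.n_mirnas} miRNAs / {config.n_tfs} TFs / "
            f"{config.n_genes} genes configured"
        )
    rng = np.random.default_rng(config.seed)

    mirna_ids = [f"mmu-mir-s{i + 1:04d}" for i in range(config.n_mirnas)]
    tf_ids = [f"TFS{i + 1:04d}" for i in range(config.n_tfs)]
    tf_coding = {tf: f"Tfcg{i + 1:04d}" for i, tf in enumerate(tf_ids)}
    gene_ids = [f"Gs{i + 1:04d}" for i in range(config.n_genes)]

    n_t = config.n_timepoints
    mirna_means = np.zeros((config.n_mirnas, n_t))
    gene_rows = gene_ids + [tf_coding[t] for t in tf_ids]
    gene_means = np.zeros((len(gene_rows), n_t))
    gene_row_pos = {g: i for i, g in enumerate(gene_rows)}

    a = config.signal_coefficient
    planted: list[PlantedCircuit] = []
    latents: dict[tuple[str, int], np.ndarray] = {}
    counter = 0
    for label, idx in config.stage_design.stages.items():
        for c in range(config.n_planted_per_stage):
            m, t, g = mirna_ids[counter], tf_ids[counter], gene_ids[counter]
            # i.i.d. draws standardized within the stage (so the realized
            # driver spread is fixed and the analytic |R| target holds),
            # redrawn until permutation-identifiable
            s = _draw_driver(
                rng, len(idx), config.n_replicates, config.max_alias_correlation
            )
            latents[(label, c)] = s
            sign_m = -1 if config.mirna_sign == "negative" else int(rng.choice([-1, 1]))
            sign_t, sign_g = 1, 1
            mirna_means[counter, idx] = sign_m * a * s
            gene_means[gene_row_pos[g], idx] = sign_g * a * s
            gene_means[gene_row_pos[tf_coding[t]], idx] = sign_t * a * s
            planted.append(
                PlantedCircuit(
                    candidate=CircuitCandidate(m, t, g),
                    stage=label,
                    edge_signs={
                        EdgeKind.MIRNA_GENE: sign_m * sign_g,
                        EdgeKind.TF_GENE: sign_t * sign_g,
                        EdgeKind.MIRNA_TF: sign_m * sign_t,
                    },
                )
            )
            counter += 1

    mirna_expr = _expression(EntityKind.MIRNA, mirna_ids, mirna_means, config, rng)
    gene_expr = _expression(EntityKind.GENE, gene_rows, gene_means, config, rng)
    tf_map = TFMap(mapping=dict(tf_coding))

    interactions = {k: InteractionSet(edge_kind=k) for k in EdgeKind}
    for pc in planted:
        m, t, g = pc.candidate
        interactions[EdgeKind.MIRNA_GENE].add(m, g, ["planted"])
        interactions[EdgeKind.TF_GENE].add(t, g, ["planted"])
        interactions[EdgeKind.MIRNA_TF].add(m, t, ["planted"])

    # decoys and extras live among the never-planted background entities
    bg_m = mirna_ids[needed:]
    bg_t = tf_ids[needed:]
    bg_g = gene_ids[needed:]
    decoys: dict[EdgeKind, set[tuple[str, str]]] = {k: set() for k in EdgeKind}

    def draw_pairs(sources: list[str], targets: list[str], count: int) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        if not sources or not targets:
            return out
        guard = 0
        while len(out) < count and guard < 50 * max(count, 1):
            guard += 1
            s = sources[int(rng.integers(len(sources)))]
            t = targets[int(rng.integers(len(targets)))]
            out.add((s, t))
        return out

    pools = {
        EdgeKind.MIRNA_GENE: (bg_m, bg_g),
        EdgeKind.TF_GENE: (bg_t, bg_g),
        EdgeKind.MIRNA_TF: (bg_m, bg_t),
    }
    for kind, (src, tgt) in pools.items():
        decoys[kind] = draw_pairs(src, tgt, config.n_decoy_pairs)
        for s, t in sorted(decoys[kind]):
            interactions[kind].add(s, t, ["decoy"])
        for s, t in sorted(draw_pairs(src, tgt, config.n_extra_pairs) - decoys[kind]):
            interactions[kind].add(s, t, ["extra"])

    truth = SyntheticTruth(
        planted_circuits=planted, decoy_pairs=decoys, latent_profiles=latents
    )
    return SyntheticDataset(
        mirna_expr=mirna_expr,
        gene_expr=gene_expr,
        tf_map=tf_map,
        interactions=interactions,
        truth=truth,
        config=config,
    )


def generate_stage_profile_matrix(
    n_genes: int = 40,
    blocks: dict[str, list[int]] | None = None,
    n_replicates: int = 2,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Gene matrix with block-wise stage profiles for clustering tests.

    Emulates the structure a two-way clustered heatmap reveals in real
    developmental data: two gene groups with opposite stage-level profiles
    (up in one block of time points and down in the other), plus replicate
    noise. Columns within a block are strongly positively correlated and
    anti-correlated across blocks, so cutting the column dendrogram at k=2
    recovers the blocks.
    """
    blocks = blocks or {"A": [0, 1, 2], "B": [3, 4, 5, 6]}
    rng = np.random.default_rng(seed)
    n_t = max(i for idx in blocks.values() for i in idx) + 1
    block_sign = np.zeros(n_t)
    for bi, idx in enumerate(blocks.values()):
        block_sign[idx] = 1.0 if bi % 2 == 0 else -1.0
    gene_sign = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    means = amplitude * np.outer(gene_sign, block_sign)
    cols = [(t, f"r{r + 1}") for t in range(n_t) for r in range(n_replicates)]
    values = np.repeat(means, n_replicates, axis=1) + rng.normal(
        0.0, noise_sd, size=(n_genes, n_t * n_replicates)
    )
    return ExpressionMatrix(
        kind=EntityKind.GENE,
        entity_ids=[f"Gb{i + 1:03d}" for i in range(n_genes)],
        time_points=[f"t{i + 1}" for i in range(n_t)],
        columns=cols,
        values=values,
    )


def realized_edge_correlations(
    dataset: SyntheticDataset,
    truth: SyntheticTruth | None = None,
    partition: StagePartition | None = None,
) -> pd.DataFrame:
    """Within-stage Pearson R of every planted edge, one row per edge x stage.

    Uses the detection module's correlation on concatenated replicate columns,
    so the table reflects exactly what the detector would see.
    """
    truth = truth if truth is not None else dataset.truth
    partition = partition if partition is not None else dataset.config.stage_design
    rows = []
    for ci, pc in enumerate(truth.planted_circuits):
        m, t, g = pc.candidate
        coding = dataset.tf_map.coding_gene(t)
        edges = [
            (EdgeKind.MIRNA_GENE, m, g, dataset.mirna_expr, dataset.gene_expr, g),
            (EdgeKind.TF_GENE, t, g, dataset.gene_expr, dataset.gene_expr, g),
            (EdgeKind.MIRNA_TF, m, t, dataset.mirna_expr, dataset.gene_expr, coding),
        ]
        for kind, src, tgt, src_expr, tgt_expr, tgt_row in edges:
            src_row = coding if (kind is EdgeKind.TF_GENE) else src
            for label, idx in partition.iter_stages():
                x = stage_vector(src_expr, src_row, idx)
                y = stage_vector(tgt_expr, tgt_row, idx)
                rows.append(
                    {
                        "circuit": ci,
                        "edge_kind": kind.value,
                        "source": src,
                        "target": tgt,
                        "planted_stage": pc.stage,
                        "stage": label,
                        "r": pearson(x, y),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["circuit", "edge_kind", "source", "target", "planted_stage", "stage", "r"],
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit the dataset in exactly the on-disk formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_expression": out / "mirna_expression.tsv",
        "gene_expression": out / "gene_expression.tsv",
        "mirna_gene_pairs": out / "mirna_gene_pairs.tsv",
        "tf_gene_pairs": out / "tf_gene_pairs.tsv",
        "mirna_tf_pairs": out / "mirna_tf_pairs.tsv",
        "tf_map": out / "tf_map.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    dataset.mirna_expr.write_tsv(paths["mirna_expression"])
    dataset.gene_expr.write_tsv(paths["gene_expression"])
    dataset.interactions[EdgeKind.MIRNA_GENE].write_tsv(paths["mirna_gene_pairs"])
    dataset.interactions[EdgeKind.TF_GENE].write_tsv(paths["tf_gene_pairs"])
    dataset.interactions[EdgeKind.MIRNA_TF].write_tsv(paths["mirna_tf_pairs"])
    dataset.tf_map.write_tsv(paths["tf_map"])
    dataset.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    dataset.config.to_yaml(paths["config"])
    return paths
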