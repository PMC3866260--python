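"""End-to-end pipeline driver: read -> filter -> assemble -> stage -> detect
-> context -> enrich -> export, from a single YAML run configuration.

Every artifact is written under the configured output directory together
with a manifest (file -> SHA-256) and the resolved configuration, so a rerun
with the same config and seed reproduces byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import candidates as cand_mod
from . import context as ctx_mod
from . import enrichment as enr_mod
from .candidates import VariancePolicy
from .data_io import (
    EdgeKind,
    EntityKind,
    GeneSet,
    read_expression,
    read_gene_set,
    read_pairs,
    read_tf_map,
)
from .detection import CircuitResult, DetectionConfig, detect_circuits, results_to_frame
from .stages import (
    StagePartition,
    cluster_columns,
    preset_early_late,
    suggest_stage_partition,
    zscore_rows,
)

log = logging.getLogger(__name__)

_DETECTION_KEYS = {
    "alpha", "n_permutations", "exhaustive_cap", "tail",
    "replicate_handling", "seed", "tie_tolerance",
}
_STAGE_KEYS = {"source", "file", "k", "distance", "linkage", "exclude"}


@dataclass
class RunConfig:
    """One-document YAML configuration of a full pipeline run."""

    mirna_expression: str
    gene_expression: str
    mirna_gene_pairs: str
    tf_gene_pairs: str
    mirna_tf_pairs: str
    tf_map: str
    out_dir: str
    variance: VariancePolicy = field(default_factory=VariancePolicy)
    stage_source: str = "preset"  # preset | file | auto
    stage_file: str | None = None
    stage_k: int = 2
    stage_distance: str = "correlation"
    stage_linkage: str = "average"
    stage_exclude: list[int] = field(default_factory=list)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tissue_genes: str | None = None
    cancer_genes: str | None = None
    enrichment_gmt: str | None = None
    enrichment_method: str = "hypergeometric"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(str(source)).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        known = {
            "mirna_expression", "gene_expression", "mirna_gene_pairs",
            "tf_gene_pairs", "mirna_tf_pairs", "tf_map", "out_dir",
            "variance", "stages", "detection", "context", "enrichment",
            "log_level",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs: dict = {
            k: doc[k]
            for k in (
                "mirna_expression", "gene_expression", "mirna_gene_pairs",
                "tf_gene_pairs", "mirna_tf_pairs", "tf_map", "out_dir",
            )
        }
        if "log_level" in doc:
            kwargs["log_level"] = doc["log_level"]
        if "variance" in doc:
            v = dict(doc["variance"])
            if set(v) - {"mode", "value"}:
                raise ValueError(f"unknown variance keys: {sorted(set(v) - {'mode', 'value'})}")
            kwargs["variance"] = VariancePolicy(**v)
        if "stages" in doc:
            s = dict(doc["stages"])
            if set(s) - _STAGE_KEYS:
                raise ValueError(f"unknown stages keys: {sorted(set(s) - _STAGE_KEYS)}")
            kwargs["stage_source"] = s.get("source", "preset")
            kwargs["stage_file"] = s.get("file")
            kwargs["stage_k"] = int(s.get("k", 2))
            kwargs["stage_distance"] = s.get("distance", "correlation")
            kwargs["stage_linkage"] = s.get("linkage", "average")
            kwargs["stage_exclude"] = [int(i) for i in s.get("exclude", [])]
        if "detection" in doc:
            d = dict(doc["detection"])
            if set(d) - _DETECTION_KEYS:
                raise ValueError(f"unknown detection keys: {sorted(set(d) - _DETECTION_KEYS)}")
            kwargs["detection"] = DetectionConfig(**d)
        if "context" in doc:
            c = dict(doc["context"])
            if set(c) - {"tissue_genes", "cancer_genes"}:
                raise ValueError("unknown context keys")
            kwargs["tissue_genes"] = c.get("tissue_genes")
            kwargs["cancer_genes"] = c.get("cancer_genes")
        if "enrichment" in doc:
            e = dict(doc["enrichment"])
            if set(e) - {"collection_gmt", "method"}:
                raise ValueError("unknown enrichment keys")
            kwargs["enrichment_gmt"] = e.get("collection_gmt")
            kwargs["enrichment_method"] = e.get("method", "hypergeometric")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "mirna_expression": self.mirna_expression,
            "gene_expression": self.gene_expression,
            "mirna_gene_pairs": self.mirna_gene_pairs,
            "tf_gene_pairs": self.tf_gene_pairs,
            "mirna_tf_pairs": self.mirna_tf_pairs,
            "tf_map": self.tf_map,
            "out_dir": self.out_dir,
            "variance": {"mode": self.variance.mode, "value": self.variance.value},
            "stages": {
                "source": self.stage_source,
                "file": self.stage_file,
                "k": self.stage_k,
                "distance": self.stage_distance,
                "linkage": self.stage_linkage,
                "exclude": list(self.stage_exclude),
            },
            "detection": {
                "alpha": self.detection.alpha,
                "n_permutations": self.detection.n_permutations,
                "exhaustive_cap": self.detection.exhaustive_cap,
                "tail": self.detection.tail,
                "replicate_handling": self.detection.replicate_handling,
                "seed": self.detection.seed,
                "tie_tolerance": self.detection.tie_tolerance,
            },
            "context": {"tissue_genes": self.tissue_genes, "cancer_genes": self.cancer_genes},
            "enrichment": {
                "collection_gmt": self.enrichment_gmt,
                "method": self.enrichment_method,
            },
            "log_level": self.log_level,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class RunReport:
    """Counts per stage plus the manifest of files written."""

    n_candidates: int
    n_genes_retained: int
    n_genes_dropped: int
    per_stage: pd.DataFrame  # stage, n_circuits, n_tfs, n_mirnas, n_genes
    manifest: dict[str, str]  # relative path -> sha256
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_summary(results: list[CircuitResult]) -> pd.DataFrame:
    by_stage = ctx_mod.circuits_by_stage(results)
    rows = []
    for stage in by_stage:
        circuits = by_stage[stage]
        rows.append(
            {
                "stage": stage,
                "n_circuits": len(circuits),
                "n_tfs": len({c.tf_id for c in circuits}),
                "n_mirnas": len({c.mirna_id for c in circuits}),
                "n_genes": len({c.gene_id for c in circuits}),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "n_circuits", "n_tfs", "n_mirnas", "n_genes"])


def resolve_partition(config: RunConfig, gene_expr) -> StagePartition:
    if config.stage_source == "preset":
        preset = preset_early_late()
        if len(gene_expr.time_points) != 7:
            raise ValueError(
                "the preset partition expects a 7-time-point design; "
                f"got {len(gene_expr.time_points)} time points"
            )
        return preset
    if config.stage_source == "file":
        if not config.stage_file:
            raise ValueError("stage_source=file requires stages.file")
        part = StagePartition.from_yaml(config.stage_file)
        part.n_timepoints = len(gene_expr.time_points)
        return part
    if config.stage_source == "auto":
        dend = cluster_columns(
            zscore_rows(gene_expr), config.stage_distance, config.stage_linkage
        )
        return suggest_stage_partition(dend, config.stage_k, config.stage_exclude)
    raise ValueError(f"unknown stage source {config.stage_source!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full circuit-mining pipeline described by ``config``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mirna_expr = read_expression(config.mirna_expression, EntityKind.MIRNA)
    gene_expr = read_expression(config.gene_expression, EntityKind.GENE)
    mg = read_pairs(config.mirna_gene_pairs, EdgeKind.MIRNA_GENE)
    tg = read_pairs(config.tf_gene_pairs, EdgeKind.TF_GENE)
    mt = read_pairs(config.mirna_tf_pairs, EdgeKind.MIRNA_TF)
    tf_map = read_tf_map(config.tf_map)
    log.info(
        "loaded %d miRNAs, %d genes, %d/%d/%d pairs",
        mirna_expr.n_entities, gene_expr.n_entities, len(mg), len(tg), len(mt),
    )

    filtered_genes, retained, dropped = cand_mod.variance_filter(gene_expr, config.variance)
    cands = cand_mod.assemble_candidates(
        mg, tg, mt, tf_map,
        gene_universe=retained,
        mirna_universe=mirna_expr.entity_ids,
    )
    log.info("%d circuit candidates after variance filtering", len(cands))

    partition = resolve_partition(config, gene_expr)
    results = detect_circuits(
        cands, mirna_expr, gene_expr, tf_map, partition, config.detection
    )
    per_stage = _stage_summary(results)
    for row in per_stage.itertuples():
        log.info("stage %s: %d circuits", row.stage, row.n_circuits)

    files: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        files[name] = path

    emit("candidates.tsv", lambda p: cand_mod.write_candidates(cands, p))
    emit("results.tsv", lambda p: results_to_frame(results).to_csv(p, sep="\t", index=False))
    emit("stage_partition.yaml", lambda p: partition.to_yaml(p))
    emit("stage_summary.tsv", lambda p: per_stage.to_csv(p, sep="\t", index=False))

    stage_labels = partition.labels
    if len(stage_labels) >= 2:
        report = ctx_mod.overlap_analysis(results, stage_labels)
        emit("overlap.tsv", lambda p: report.to_frame().to_csv(p, sep="\t", index=False))

    tissue = cancer = None
    if config.tissue_genes:
        tissue = read_gene_set(config.tissue_genes, format="plain_list")
        within = ctx_mod.subset_by_gene_set(results, tissue, "within")
        excl = ctx_mod.exclusive_regulators(results, tissue)
        emit(
            "tissue_within_circuits.tsv",
            lambda p: results_to_frame([r for r in within if r.is_circuit]).to_csv(
                p, sep="\t", index=False
            ),
        )
        excl_rows = [
            {"stage": s, "exclusive_tfs": ";".join(sorted(t)), "exclusive_mirnas": ";".join(sorted(m))}
            for s, (t, m) in sorted(excl.items())
        ]
        emit(
            "exclusive_regulators.tsv",
            lambda p: pd.DataFrame(
                excl_rows, columns=["stage", "exclusive_tfs", "exclusive_mirnas"]
            ).to_csv(p, sep="\t", index=False),
        )
    if config.cancer_genes:
        cancer = read_gene_set(config.cancer_genes, format="plain_list")
        if tissue is not None:
            cc = ctx_mod.cancer_context(results, cancer, tissue)
            emit("cancer_context.tsv", lambda p: cc.summary.to_csv(p, sep="\t", index=False))
        else:
            cancer_within = ctx_mod.subset_by_gene_set(results, cancer, "within")
            emit(
                "cancer_circuits.tsv",
                lambda p: results_to_frame(
                    [r for r in cancer_within if r.is_circuit]
                ).to_csv(p, sep="\t", index=False),
            )

    if config.enrichment_gmt:
        collection = read_gene_set(config.enrichment_gmt, format="gmt")
        universe = GeneSet(name="analysis_universe", ids=frozenset(retained))
        by_stage = ctx_mod.circuits_by_stage(results)
        enr_frames = []
        for stage in sorted(by_stage):
            genes = {c.gene_id for c in by_stage[stage]}
            genes &= universe.ids  # drop TF coding genes outside the universe
            if not genes:
                continue
            rows = enr_mod.enrich(
                GeneSet(name=f"{stage}_circuit_genes", ids=frozenset(genes)),
                collection,
                universe,
                method=config.enrichment_method,
            )
            frame = enr_mod.enrichment_to_frame(rows)
            frame.insert(0, "stage", stage)
            enr_frames.append(frame)
        if enr_frames:
            emit(
                "enrichment.tsv",
                lambda p: pd.concat(enr_frames, ignore_index=True).to_csv(
                    p, sep="\t", index=False
                ),
            )

    emit("circuit_network.sif", lambda p: export_network(results, "sif", p))
    emit("circuit_network.graphml", lambda p: export_network(results, "graphml", p))

    emit("resolved_config.yaml", lambda p: config.to_yaml(p))
    manifest = {name: _sha256(path) for name, path in sorted(files.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RunReport(
        n_candidates=len(cands),
        n_genes_retained=len(retained),
        n_genes_dropped=len(dropped),
        per_stage=per_stage,
        manifest=manifest,
        out_dir=out,
    )


def _as_network(obj) -> nx.DiGraph:
    if isinstance(obj, nx.DiGraph):
        return obj
    results = list(obj)
    g = nx.DiGraph()
    for res in results:
        if not isinstance(res, CircuitResult):
            raise TypeError("export_network expects a DiGraph or CircuitResults")
        if not res.is_circuit:
            continue
        sub = ctx_mod.circuit_network([res.candidate], stage=res.stage)
        for node, data in sub.nodes(data=True):
            g.add_node(node, **data)
        for s, t, data in sub.edges(data=True):
            if g.has_edge(s, t):
                data = dict(data)
                data["stages"] = tuple(
                    sorted(set(g[s][t].get("stages", ())) | set(data.get("stages", ())))
                )
            g.add_edge(s, t, **data)
    # attach correlation/p of each tested edge where available
    for res in results:
        if not res.is_circuit:
            continue
        for test in res.edge_tests:
            s, t = test.source_id, test.target_id
            if g.has_edge(s, t):
                g[s][t][f"r_{test.stage}"] = float(test.r)
                g[s][t][f"p_{test.stage}"] = float(test.p)
    return g


def export_network(obj, format: str, path: str | Path) -> None:
    """Write a circuit network as SIF, GraphML or an edge-list TSV.

    ``obj`` is either a typed networkx DiGraph or an iterable of
    CircuitResults (only rows with is_circuit contribute). Empty networks
    produce valid empty documents with a logged warning.
    """
    g = _as_network(obj)
    path = Path(path)
    if g.number_of_edges() == 0:
        log.warning("exporting an empty network to %s", path)
    if format == "sif":
        with open(path, "w") as fh:
            for s, t, data in sorted(g.edges(data=True)):
                fh.write(f"{s}\t{data.get('relation', 'edge')}\t{t}\n")
        return
    if format == "graphml":
        h = nx.DiGraph()
        for node, data in g.nodes(data=True):
            h.add_node(node, **{k: str(v) for k, v in data.items()})
        for s, t, data in g.edges(data=True):
            attrs = {}
            for k, v in data.items():
                attrs[k] = ";".join(v) if isinstance(v, (tuple, list, set)) else v
            h.add_edge(s, t, **attrs)
        nx.write_graphml(h, path)
        return
    if format == "tsv":
        rows = [
            {
                "source": s,
                "target": t,
                "relation": data.get("relation", ""),
                "stages": ";".join(data.get("stages", ())),
            }
            for s, t, data in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "relation", "stages"]).to_csv(
            path, sep="\t", index=False
        )
        return
    raise ValueError(f"unknown network format {format!r}")
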