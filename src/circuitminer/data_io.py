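"""Domain types and file I/O for expression matrices, interaction pairs and gene sets.

All on-disk formats are plain text: expression matrices are TSV with an
entity-id first column and ``<time>_<replicate>`` headers, interaction pairs
are 2-3 column TSV (source, target[, provenance]), gene sets are one-id-per-line
lists or standard GMT. Identifiers are normalized on the way in: miRNA names
are lower-cased (unifying ``miR``/``mir`` spellings, keeping a species prefix
such as ``mmu-`` when present); gene and TF symbols keep their spelling but
compare case-insensitively everywhere downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class EntityKind(str, Enum):
    MIRNA = "mirna"
    GENE = "gene"


class EdgeKind(str, Enum):
    MIRNA_GENE = "mirna_gene"
    TF_GENE = "tf_gene"
    MIRNA_TF = "mirna_tf"


#: id namespace of (source, target) for each edge kind; TF ids follow the
#: gene convention (case-preserving, case-insensitive comparison).
EDGE_NAMESPACES: dict[EdgeKind, tuple[EntityKind, EntityKind]] = {
    EdgeKind.MIRNA_GENE: (EntityKind.MIRNA, EntityKind.GENE),
    EdgeKind.TF_GENE: (EntityKind.GENE, EntityKind.GENE),
    EdgeKind.MIRNA_TF: (EntityKind.MIRNA, EntityKind.GENE),
}


def normalize_id(raw: str, kind: EntityKind) -> str:
    """Return the canonical form of an entity identifier.

    miRNAs: trimmed and lower-cased, which unifies ``miR-200a``/``mir-200a``
    and retains any species prefix (``mmu-miR-200a`` -> ``mmu-mir-200a``).
    Genes/TFs: trimmed, case preserved (comparison is case-insensitive via
    :func:`id_key`). Raises ``ValueError`` on empty/whitespace-only input.
    Idempotent by construction.
    """
    s = raw.strip()
    if not s:
        raise ValueError("empty identifier")
    if EntityKind(kind) is EntityKind.MIRNA:
        return s.lower()
    return s


def id_key(canonical: str, kind: EntityKind) -> str:
    """Fold a canonical id to the key used for equality comparison."""
    if EntityKind(kind) is EntityKind.MIRNA:
        return canonical.lower()
    return canonical.casefold()


@dataclass
class ExpressionMatrix:
    """Entities x (time point, replicate) log-scale expression values.

    ``columns`` holds one ``(time_index, replicate_label)`` tuple per value
    column, sorted by time index then replicate label; ``time_points`` maps
    time index -> time label.
    """

    kind: EntityKind
    entity_ids: list[str]
    time_points: list[str]
    columns: list[tuple[int, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.kind = EntityKind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.columns)} columns"
            )
        seen: set[str] = set()
        for eid in self.entity_ids:
            k = id_key(eid, self.kind)
            if k in seen:
                raise ValueError(f"duplicate entity id: {eid!r}")
            seen.add(k)
        if sorted(self.columns) != list(self.columns):
            raise ValueError("columns must be sorted by (time index, replicate)")
        for t, _ in self.columns:
            if not 0 <= t < len(self.time_points):
                raise ValueError(f"column time index {t} out of range")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self._row_index = {id_key(e, self.kind): i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def replicate_labels(self) -> list[str]:
        return [r for _, r in self.columns]

    def has(self, entity_id: str) -> bool:
        return id_key(entity_id, self.kind) in self._row_index

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[id_key(entity_id, self.kind)]]
        except KeyError:
            raise KeyError(
                f"entity {entity_id!r} not found in {self.kind.value} expression matrix"
            ) from None

    def column_indices(self, time_indices: Iterable[int]) -> np.ndarray:
        """Value-column positions for the given time points, in (time, replicate) order."""
        wanted = list(time_indices)
        out = [
            j
            for t in wanted
            for j, (tj, _) in enumerate(self.columns)
            if tj == t
        ]
        return np.asarray(out, dtype=int)

    def subset(self, entity_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = [self._row_index[id_key(e, self.kind)] for e in entity_ids]
        return ExpressionMatrix(
            kind=self.kind,
            entity_ids=[self.entity_ids[i] for i in idx],
            time_points=list(self.time_points),
            columns=list(self.columns),
            values=self.values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.time_points[t]}_{r}" for t, r in self.columns]
        return pd.DataFrame(self.values, index=self.entity_ids, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.10g")


DEFAULT_COLUMN_DIALECT = r"^(?P<time>.+)_(?P<rep>[^_]+)$"


def read_expression(
    path: str | Path,
    kind: EntityKind,
    dialect: str = DEFAULT_COLUMN_DIALECT,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (rows = entities, header = time x replicate).

    Column headers are parsed with the ``dialect`` regular expression, which
    must expose ``time`` and ``rep`` groups. Time points are ordered by first
    appearance in the header; columns are then sorted by (time index,
    replicate label). Rows containing unparseable or missing values are
    rejected with a logged count; a duplicated entity id is a hard error.
    """
    kind = EntityKind(kind)
    pat = re.compile(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    time_points: list[str] = []
    parsed: list[tuple[int, str, str]] = []  # (time_index, rep, original column)
    for col in raw.columns:
        m = pat.match(str(col))
        if m is None:
            log.warning("column %r does not match dialect; ignored", col)
            continue
        t, r = m.group("time"), m.group("rep")
        if t not in time_points:
            time_points.append(t)
        parsed.append((time_points.index(t), r, col))
    if not parsed:
        raise ValueError(f"no parsable time columns in {path}")
    parsed.sort(key=lambda x: (x[0], x[1]))

    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_rejected = 0
    seen: set[str] = set()
    for raw_id, row in raw.iterrows():
        eid = normalize_id(str(raw_id), kind)
        k = id_key(eid, kind)
        if k in seen:
            raise ValueError(f"duplicate entity id in {path}: {eid!r}")
        vals = pd.to_numeric(
            pd.Series([row[c] for _, _, c in parsed]), errors="coerce"
        ).to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            n_rejected += 1
            continue
        seen.add(k)
        ids.append(eid)
        rows.append(vals)
    if n_rejected:
        log.info("rejected %d rows with missing/unparseable values in %s", n_rejected, path)
    return ExpressionMatrix(
        kind=kind,
        entity_ids=ids,
        time_points=time_points,
        columns=[(t, r) for t, r, _ in parsed],
        values=np.array(rows, dtype=float) if rows else np.empty((0, len(parsed))),
    )


@dataclass
class InteractionSet:
    """Directed regulator->target pairs of one edge kind, with provenance."""

    edge_kind: EdgeKind
    pairs: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edge_kind = EdgeKind(self.edge_kind)
        self._fold_index = {self._fold(p): p for p in self.pairs}

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._fold(pair) in self._fold_index

    def _fold(self, pair: tuple[str, str]) -> tuple[str, str]:
        ks, kt = EDGE_NAMESPACES[self.edge_kind]
        return (id_key(pair[0], ks), id_key(pair[1], kt))

    def add(self, source: str, target: str, provenance: Iterable[str] = ()) -> None:
        ks, kt = EDGE_NAMESPACES[self.edge_kind]
        pair = (normalize_id(source, ks), normalize_id(target, kt))
        fold = self._fold(pair)
        existing = self._fold_index.get(fold)
        if existing is not None:
            merged = sorted(set(self.pairs[existing]) | set(provenance))
            self.pairs[existing] = tuple(merged)
            return
        self.pairs[pair] = tuple(sorted(set(provenance)))
        self._fold_index[fold] = pair

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (s, t), prov in sorted(self.pairs.items()):
                if prov:
                    fh.write(f"{s}\t{t}\t{';'.join(prov)}\n")
                else:
                    fh.write(f"{s}\t{t}\n")


def read_pairs(path: str | Path, edge_kind: EdgeKind) -> InteractionSet:
    """Read a 2-3 column TSV of interaction pairs; duplicates merge provenance.

    Malformed lines are skipped with a logged line number. An empty result is
    a warning, not an error.
    """
    iset = InteractionSet(edge_kind=EdgeKind(edge_kind))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-separated exports
                fields = line.split()
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                log.warning("%s:%d: malformed pair line skipped", path, lineno)
                continue
            prov = [p for p in fields[2].split(";")] if len(fields) > 2 and fields[2] else []
            iset.add(fields[0], fields[1], prov)
    if len(iset) == 0:
        log.warning("no pairs loaded from %s", path)
    return iset


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. lung-specific or cancer genes)."""

    name: str
    ids: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet requires a non-empty name")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(id_key(g, EntityKind.GENE) for g in self.ids)

    def __contains__(self, gene_id: str) -> bool:
        return id_key(gene_id, EntityKind.GENE) in self.keys


def _dedupe_genes(raw_ids: Iterable[str]) -> frozenset[str]:
    out: dict[str, str] = {}
    for r in raw_ids:
        r = r.strip()
        if not r:
            continue
        g = normalize_id(r, EntityKind.GENE)
        out.setdefault(id_key(g, EntityKind.GENE), g)
    return frozenset(out.values())


def read_gene_set(
    path: str | Path,
    name: str | None = None,
    format: str = "plain_list",
) -> GeneSet | list[GeneSet]:
    """Read a gene set from a plain list (one id/line) or a GMT file.

    ``plain_list`` returns one :class:`GeneSet` (named after ``name`` or the
    file stem); ``gmt`` returns one per line. A named set that is empty after
    normalization is an error.
    """
    path = Path(path)
    if format == "plain_list":
        ids = _dedupe_genes(path.read_text().splitlines())
        setname = name or path.stem
        if not ids:
            raise ValueError(f"gene set {setname!r} is empty after normalization")
        return GeneSet(name=setname, ids=ids, provenance=str(path))
    if format == "gmt":
        sets: list[GeneSet] = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("%s:%d: malformed GMT line skipped", path, lineno)
                continue
            ids = _dedupe_genes(fields[2:])
            if not ids:
                raise ValueError(f"GMT set {fields[0]!r} is empty after normalization")
            sets.append(GeneSet(name=fields[0], ids=ids, provenance=fields[1]))
        return sets
    raise ValueError(f"unknown gene set format: {format!r}")


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gs.ids)))


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.ids))
            fh.write(f"{gs.name}\t{gs.provenance}\t{members}\n")


@dataclass
class TFMap:
    """TF identifier -> coding-gene identifier (the mRNA proxy for the TF)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for tf, gene in self.mapping.items():
            norm[normalize_id(tf, EntityKind.GENE)] = normalize_id(gene, EntityKind.GENE)
        self.mapping = norm
        self._index = {id_key(t, EntityKind.GENE): g for t, g in self.mapping.items()}

    def __contains__(self, tf_id: str) -> bool:
        return id_key(tf_id, EntityKind.GENE) in self._index

    def coding_gene(self, tf_id: str) -> str:
        try:
            return self._index[id_key(tf_id, EntityKind.GENE)]
        except KeyError:
            raise KeyError(f"TF {tf_id!r} has no coding-gene mapping") from None

    def unmapped_against(self, gene_expr: ExpressionMatrix) -> list[str]:
        """TFs whose coding gene is absent from the gene expression matrix."""
        return [tf for tf, g in self.mapping.items() if not gene_expr.has(g)]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tf, g in sorted(self.mapping.items()):
                fh.write(f"{tf}\t{g}\n")


def read_tf_map(path: str | Path) -> TFMap:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                log.warning("%s:%d: malformed TF map line skipped", path, lineno)
                continue
            mapping[fields[0].strip()] = fields[1].strip()
    return TFMap(mapping=mapping)


class CircuitCandidate(NamedTuple):
    """A (miRNA, TF, gene) triple supported by all three interaction pair sets."""

    mirna_id: str
    tf_id: str
    gene_id: str
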