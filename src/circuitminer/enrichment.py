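"""Hypergeometric over-representation testing of circuit gene lists.

Given a query gene list (e.g. the genes of all early-stage circuits), an
annotation collection (GMT gene sets) and a background universe, each term
is scored with the exact upper-tail hypergeometric probability of observing
at least k overlapping genes, or with the more conservative EASE variant
(k replaced by k-1). Benjamini-Hochberg adjustment is applied across the
collection's tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int  # overlap
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        """Raw p below the conventional 0.05 reporting threshold."""
        return self.p < 0.05


def _tail_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); probability 1 when k <= 0."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: GeneSet,
    collection: Iterable[GeneSet],
    universe: GeneSet,
    method: str = "hypergeometric",
) -> list[EnrichmentRow]:
    """Over-representation p-values of the query against each collection term.

    Query ids outside the universe are dropped with a logged count; each term
    is intersected with the universe before testing. ``hypergeometric`` is
    the exact upper tail; ``ease`` recomputes it with the overlap reduced by
    one. Rows are sorted by (p, term name) with BH adjustment across the
    collection.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown enrichment method {method!r}")
    uni = universe.keys
    if not uni:
        raise ValueError("empty universe")
    q = query.keys & uni
    dropped = len(query.keys) - len(q)
    if dropped:
        log.info("%d query ids outside the universe dropped", dropped)
    if not q:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(uni), len(q)
    rows = []
    for term in collection:
        members = term.keys & uni
        K = len(members)
        k = len(members & q)
        k_eff = k if method == "hypergeometric" else max(k - 1, 0)
        rows.append((term.name, k, K, _tail_p(k_eff, K, n, N)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    out = [
        EnrichmentRow(term=name, k=k, K=K, n=n, N=N, p=p, p_adjusted=float(adj))
        for (name, k, K, p), adj in zip(rows, adjusted)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def enrichment_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "overlap": r.k,
                "term_size": r.K,
                "query_size": r.n,
                "universe_size": r.N,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "significant_p05": r.significant,
            }
            for r in rows
        ],
        columns=[
            "term", "overlap", "term_size", "query_size",
            "universe_size", "p", "p_adjusted", "significant_p05",
        ],
    )
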