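"""Hypergeometric over-representation analysis (ORA) of effector gene sets.

Given the target genes of a CB network's regulator and secondary effector
miRNAs, pathway over-representation asks whether those genes hit an annotated
set more often than chance, drawing without replacement from a background
universe of N genes of which K belong to the set.  The reported P value is
the upper tail P(X >= k) of the hypergeometric distribution, with
Benjamini-Hochberg adjustment across tested sets.

The background universe is always an explicit input: whether it is an
annotation universe or an expressed-gene universe changes every ratio, so no
default is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background universe must be non-empty")
        restricted = {}
        for set_id, (desc, members) in self.sets.items():
            kept = frozenset(members) & self.background
            if not kept:
                continue
            restricted[set_id] = (desc, kept)
        self.sets = restricted


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    k: int  # query hits in the set
    n: int  # query size after background restriction
    K: int  # set size within background
    N: int  # background size
    pvalue: float
    padj: float
    hit_genes: tuple[str, ...] = field(default=())

    @property
    def gene_ratio(self) -> str:
        return f"{self.k}/{self.n}"

    @property
    def bg_ratio(self) -> str:
        return f"{self.K}/{self.N}"


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Accumulated in log space (log-pmf + logsumexp) so that deep tails of
    large universes do not underflow.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k} n={n} K={K} N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(n, K) + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(ks, N, K, n))))


def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    padj_method: str = "BH",
) -> list[EnrichmentResult]:
    """Test a query gene list against every set in the collection.

    Query genes outside the background are dropped (and logged) before the
    query size n is fixed, so the gene-ratio denominator reflects only
    mappable genes.  One result is emitted per set with at least one hit,
    BH-adjusted across all tested sets and sorted by ascending P value.
    """
    if padj_method != "BH":
        raise ValueError("only Benjamini-Hochberg ('BH') adjustment is supported")
    query = set(query_genes)
    mappable = query & collection.background
    n_dropped = len(query) - len(mappable)
    if n_dropped:
        logger.info("dropped %d query gene(s) absent from background", n_dropped)
    n = len(mappable)
    N = len(collection.background)

    raw: list[tuple[str, str, int, int, tuple[str, ...]]] = []
    for set_id, (desc, members) in sorted(collection.sets.items()):
        hits = tuple(sorted(mappable & members))
        if not hits:
            continue
        raw.append((set_id, desc, len(hits), len(members), hits))
    if not raw:
        return []

    pvals = [hypergeom_pvalue(k, n, K, N) for _, _, k, K, _ in raw]
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            set_id=set_id,
            description=desc,
            k=k,
            n=n,
            K=K,
            N=N,
            pvalue=p,
            padj=q,
            hit_genes=hits,
        )
        for (set_id, desc, k, K, hits), p, q in zip(raw, pvals, padj)
    ]
    results.sort(key=lambda r: (r.pvalue, r.set_id))
    return results


def read_gmt(path: str | Path, background: Iterable[str]) -> GeneSetCollection:
    """Read gene sets from a GMT file (set_id <tab> description <tab> genes...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        set_id, desc, members = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
        if not members:
            raise ValueError(f"empty gene set {set_id!r}")
        sets[set_id] = (desc, members)
    return GeneSetCollection(sets=sets, background=frozenset(background))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results in the conventional ORA layout."""
    rows = [
        {
            "ID": r.set_id,
            "Description": r.description,
            "GeneRatio": r.gene_ratio,
            "BgRatio": r.bg_ratio,
            "pvalue": r.pvalue,
            "padj": r.padj,
            "geneID": "/".join(r.hit_genes),
            "Count": r.k,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["ID", "Description", "GeneRatio", "BgRatio", "pvalue", "padj", "geneID", "Count"],
    )
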