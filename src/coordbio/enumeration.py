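"""Enumeration of CB regulator-target triads and pair prevalence.

A CB (coordinated biogenesis) triad ``miRNA-1 : gene A -> miRNA-2 : gene B``
is defined by two site-count conditions on merged 3'UTR binding sites:

1. the regulator miRNA-1 has >= 2 sites on gene A, in tandem with the
   secondary miRNA-2 which has >= 1 but strictly fewer sites on the same
   gene A;
2. gene B, the secondary effector gene, carries >= 2 miRNA-2 sites and no
   miRNA-1 site on its 3'UTR.

Prevalence of a (regulator, secondary) pair is the number of distinct genes A
across which the pair co-occurs; higher prevalence marks the pair as a more
likely coordination partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from coordbio.catalog import InteractionCatalog

logger = logging.getLogger(__name__)

ALL_REGULATORS = "ALL"


@dataclass(frozen=True, order=True)
class CBTriad:
    """One regulator-target relationship with its supporting site counts."""

    regulator: str
    gene_a: str
    secondary: str
    gene_b: str
    n_m1_on_a: int = 2
    n_m2_on_a: int = 1
    n_m2_on_b: int = 2
    n_m1_on_b: int = 0

    def __post_init__(self) -> None:
        if self.regulator == self.secondary:
            raise ValueError("regulator and secondary miRNA must differ")
        if self.gene_a == self.gene_b:
            raise ValueError("gene A and gene B must differ")
        if self.n_m1_on_a < 2:
            raise ValueError("regulator needs >= 2 sites on gene A")
        if not (1 <= self.n_m2_on_a < self.n_m1_on_a):
            raise ValueError("secondary needs 1 <= sites on gene A < regulator's")
        if self.n_m2_on_b < 2:
            raise ValueError("secondary needs >= 2 sites on gene B")
        if self.n_m1_on_b != 0:
            raise ValueError("gene B must carry no regulator site")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.secondary)


@dataclass(frozen=True)
class PrevalenceRecord:
    """Distinct gene-A count supporting one (regulator, secondary) pair."""

    regulator: str
    secondary: str
    prevalence: int

    def __post_init__(self) -> None:
        if self.prevalence < 1:
            raise ValueError("prevalence records are only emitted for observed pairs")


def _within_gap(catalog: InteractionCatalog, m1: str, m2: str, gene: str, max_gap: int) -> bool:
    """True when some m1 site and some m2 site on the gene's 3'UTR lie within max_gap bases."""
    s1 = [s for s in catalog.sites if s.mirna_id == m1 and s.gene_id == gene and s.region == "3UTR"]
    s2 = [s for s in catalog.sites if s.mirna_id == m2 and s.gene_id == gene and s.region == "3UTR"]
    for a in s1:
        for b in s2:
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_gap:
                return True
    return False


def enumerate_triads(
    catalog: InteractionCatalog,
    regulator: str = ALL_REGULATORS,
    max_gap: int | None = None,
) -> list[CBTriad]:
    """Enumerate every CB triad in the catalog, optionally for one regulator.

    Returns triads in lexicographic order by (regulator, gene_a, secondary,
    gene_b).  An absent regulator yields an empty list with a warning rather
    than an error: a miRNA without indexed sites simply has no triads.

    "In tandem" imposes no distance constraint by default — co-occurrence on
    one gene's 3'UTR suffices; pass ``max_gap`` (bases) to additionally
    require a regulator and a secondary site on gene A closer than that gap.

    The search is index-driven: genes are scanned once, candidate
    (regulator, secondary) pairs are read off each gene's per-miRNA counts,
    and gene-B candidates come from a per-miRNA gene list, so cost scales with
    the number of indexed pairs rather than all quadruples.
    """
    index = catalog.site_count_index
    if regulator != ALL_REGULATORS and regulator not in {m for m, _ in index}:
        logger.warning("regulator %r has no indexed 3'UTR sites in catalog", regulator)
        return []

    mirnas_by_gene: dict[str, dict[str, int]] = {}
    genes_by_mirna: dict[str, dict[str, int]] = {}
    for (mirna, gene), count in index.items():
        mirnas_by_gene.setdefault(gene, {})[mirna] = count
        genes_by_mirna.setdefault(mirna, {})[gene] = count

    triads: list[CBTriad] = []
    for gene_a, counts in mirnas_by_gene.items():
        for m1, n1 in counts.items():
            if n1 < 2:
                continue
            if regulator != ALL_REGULATORS and m1 != regulator:
                continue
            for m2, n2 in counts.items():
                if m2 == m1 or not (1 <= n2 < n1):
                    continue
                if max_gap is not None and not _within_gap(catalog, m1, m2, gene_a, max_gap):
                    continue
                for gene_b, nb in genes_by_mirna[m2].items():
                    if gene_b == gene_a or nb < 2:
                        continue
                    if index.get((m1, gene_b), 0) != 0:
                        continue
                    triads.append(
                        CBTriad(
                            regulator=m1,
                            gene_a=gene_a,
                            secondary=m2,
                            gene_b=gene_b,
                            n_m1_on_a=n1,
                            n_m2_on_a=n2,
                            n_m2_on_b=nb,
                            n_m1_on_b=0,
                        )
                    )
    triads.sort(key=lambda t: (t.regulator, t.gene_a, t.secondary, t.gene_b))
    return triads


def pair_prevalence(triads: list[CBTriad]) -> list[PrevalenceRecord]:
    """Count distinct genes A per (regulator, secondary) pair.

    Gene-B multiplicity is ignored: a pair co-occurring on one gene A with
    ten candidate genes B still contributes prevalence 1 for that gene A.
    Records are sorted by descending prevalence, then lexicographically.
    """
    genes_a: dict[tuple[str, str], set[str]] = {}
    for t in triads:
        genes_a.setdefault(t.pair, set()).add(t.gene_a)
    records = [
        PrevalenceRecord(regulator=m1, secondary=m2, prevalence=len(genes))
        for (m1, m2), genes in genes_a.items()
    ]
    records.sort(key=lambda r: (-r.prevalence, r.regulator, r.secondary))
    return records


def triads_to_frame(triads: list[CBTriad]) -> pd.DataFrame:
    cols = [
        "regulator",
        "gene_a",
        "secondary",
        "gene_b",
        "n_m1_on_a",
        "n_m2_on_a",
        "n_m2_on_b",
    ]
    return pd.DataFrame(
        [
            (t.regulator, t.gene_a, t.secondary, t.gene_b, t.n_m1_on_a, t.n_m2_on_a, t.n_m2_on_b)
            for t in triads
        ],
        columns=cols,
    )


def prevalence_to_frame(records: list[PrevalenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.regulator, r.secondary, r.prevalence) for r in records],
        columns=["regulator", "secondary", "prevalence"],
    )
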