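"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from coordbio.catalog import BindingSite, InteractionCatalog
from coordbio.enumeration import CBTriad


def make_catalog(pair_counts: dict[tuple[str, str], int], species: str = "test") -> InteractionCatalog:
    """Catalog realizing exact 3'UTR site counts via disjoint intervals."""
    sites = []
    for (mirna, gene), count in pair_counts.items():
        for i in range(count):
            start = 1000 + 50 * i
            sites.append(
                BindingSite(
                    mirna_id=mirna,
                    gene_id=gene,
                    chrom=f"chr_{gene}",
                    start=start,
                    end=start + 8,
                    strand="+",
                    region="3UTR",
                )
            )
    catalog = InteractionCatalog(sites=sites, species=species)
    catalog.reindex()
    return catalog


def brute_force_triads(catalog: InteractionCatalog) -> list[CBTriad]:
    """Independent oracle: naive quadruple loop applying the CB conditions.

    Deliberately ignorant of the production enumeration's indexing strategy —
    it re-reads every (miRNA, gene, miRNA, gene) combination straight off the
    site-count index.
    """
    count = catalog.site_count_index.get
    mirnas = sorted({m for m, _ in catalog.site_count_index})
    genes = sorted({g for _, g in catalog.site_count_index})
    triads = []
    for m1, gene_a, m2, gene_b in itertools.product(mirnas, genes, mirnas, genes):
        if m1 == m2 or gene_a == gene_b:
            continue
        n1a = count((m1, gene_a), 0)
        n2a = count((m2, gene_a), 0)
        n2b = count((m2, gene_b), 0)
        n1b = count((m1, gene_b), 0)
        if n1a >= 2 and 1 <= n2a < n1a and n2b >= 2 and n1b == 0:
            triads.append(
                CBTriad(
                    regulator=m1, gene_a=gene_a, secondary=m2, gene_b=gene_b,
                    n_m1_on_a=n1a, n_m2_on_a=n2a, n_m2_on_b=n2b,
                )
            )
    triads.sort(key=lambda t: (t.regulator, t.gene_a, t.secondary, t.gene_b))
    return triads


def random_pair_counts(
    rng: np.random.Generator, n_mirnas: int, n_genes: int, density: float = 0.3
) -> dict[tuple[str, str], int]:
    """Sparse random (miRNA, gene) -> count map with counts in 1..4."""
    counts = {}
    for i in range(n_mirnas):
        for j in range(n_genes):
            if rng.random() < density:
                counts[(f"m{i}", f"g{j}")] = int(rng.integers(1, 5))
    return counts


@pytest.fixture
def example_catalog() -> InteractionCatalog:
    """Minimal catalog containing exactly one CB triad (m1, A, m2, B)."""
    return make_catalog({("m1", "A"): 3, ("m2", "A"): 1, ("m2", "B"): 2})
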