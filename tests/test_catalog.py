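"""Catalog parsing, merging, and 3'UTR indexing."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coordbio.catalog import (
    BindingSite,
    CatalogFormatError,
    InteractionCatalog,
    load_catalog,
    merge_catalogs,
    site_count,
    write_catalog,
)

HEADER = "mirna_id\tgene_id\ttranscript_id\tchrom\tstart\tend\tstrand\tregion\tevidence\tsource_db\n"


def write_tsv(tmp_path, name, rows):
    path = tmp_path / name
    path.write_text(HEADER + "".join(rows))
    return path


def row(mirna, gene, chrom, start, end, strand="+", region="3UTR", evidence="strong", tx="", db="dbX"):
    return f"{mirna}\t{gene}\t{tx}\t{chrom}\t{start}\t{end}\t{strand}\t{region}\t{evidence}\t{db}\n"


class TestLoadCatalog:
    def test_counts_distinct_sites_per_pair(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "c.tsv",
            [
                row("miR-X", "geneA", "chr1", 100, 107),
                row("miR-X", "geneA", "chr1", 200, 207),
                row("miR-Y", "geneA", "chr1", 300, 307),
            ],
        )
        catalog = load_catalog(path)
        assert catalog.site_count_index == {("miR-X", "geneA"): 2, ("miR-Y", "geneA"): 1}

    def test_header_only_file_yields_empty_index(self, tmp_path):
        catalog = load_catalog(write_tsv(tmp_path, "empty.tsv", []))
        assert catalog.site_count_index == {}
        assert catalog.sites == []

    def test_cds_sites_retained_but_not_indexed(self, tmp_path):
        path = write_tsv(tmp_path, "cds.tsv", [row("miR-X", "geneA", "chr1", 100, 107, region="CDS")])
        catalog = load_catalog(path)
        assert catalog.site_count_index == {}
        assert len(catalog.sites) == 1
        # brute-force recount over 3'UTR sites agrees with the (empty) index
        assert sum(1 for s in catalog.sites if s.region == "3UTR") == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mirna_id\tgene_id\tchrom\tstart\nmiR-X\tgeneA\tchr1\t100\n")
        with pytest.raises(CatalogFormatError, match="end"):
            load_catalog(path)

    def test_unparseable_coordinates_collected_and_reported(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "coords.tsv",
            [row("miR-X", "geneA", "chr1", 100, 107), row("miR-Y", "geneA", "chr1", "oops", 207)],
        )
        with pytest.raises(CatalogFormatError, match="line 3"):
            load_catalog(path)

    def test_rows_without_positions_dropped_not_fatal(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "nopos.tsv",
            [row("miR-X", "geneA", "chr1", 100, 107), row("miR-Y", "geneA", "chr1", "", "")],
        )
        catalog = load_catalog(path)
        assert catalog.site_count_index == {("miR-X", "geneA"): 1}

    def test_region_defaults_to_3utr(self, tmp_path):
        path = write_tsv(tmp_path, "noregion.tsv", [row("miR-X", "geneA", "chr1", 100, 107, region="")])
        catalog = load_catalog(path)
        assert catalog.sites[0].region == "3UTR"
        assert site_count(catalog, "miR-X", "geneA") == 1

    def test_one_based_dialect_converted(self, tmp_path):
        path = tmp_path / "tb.tsv"
        path.write_text(
            "mirna\tgeneName\ttranscript\tchromosome\tstart\tstop\tstrand\tregion\tmethod_type\n"
            "miR-X\tgeneA\t\tchr1\t101\t107\t+\t3UTR\tdirect\n"
        )
        catalog = load_catalog(path, format_dialect="tarbase_like")
        site = catalog.sites[0]
        assert (site.start, site.end) == (100, 107)  # 1-based inclusive -> 0-based half-open
        assert site.source_db == "TarBase"

    def test_min_evidence_restricts(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "ev.tsv",
            [
                row("miR-X", "geneA", "chr1", 100, 107, evidence="strong"),
                row("miR-X", "geneA", "chr1", 200, 207, evidence="weak"),
            ],
        )
        assert site_count(load_catalog(path), "miR-X", "geneA") == 2
        assert site_count(load_catalog(path, min_evidence="strong"), "miR-X", "geneA") == 1


class TestMergeCatalogs:
    def make(self, tmp_path, name, rows, species="mouse"):
        return load_catalog(write_tsv(tmp_path, name, rows), species=species)

    def test_exact_duplicate_counts_once(self, tmp_path):
        a = self.make(tmp_path, "a.tsv", [row("miR-X", "geneA", "chr1", 100, 107)])
        b = self.make(tmp_path, "b.tsv", [row("miR-X", "geneA", "chr1", 100, 107)])
        assert site_count(merge_catalogs(a, b), "miR-X", "geneA") == 1

    def test_overlapping_sites_merge_to_union_interval(self, tmp_path):
        a = self.make(tmp_path, "a.tsv", [row("miR-X", "geneA", "chr1", 100, 107)])
        b = self.make(tmp_path, "b.tsv", [row("miR-X", "geneA", "chr1", 105, 112)])
        merged = merge_catalogs(a, b)
        assert site_count(merged, "miR-X", "geneA") == 1
        (site,) = merged.sites
        assert (site.start, site.end) == (100, 112)

    def test_disjoint_sites_count_separately(self, tmp_path):
        a = self.make(tmp_path, "a.tsv", [row("miR-X", "geneA", "chr1", 100, 107)])
        b = self.make(tmp_path, "b.tsv", [row("miR-X", "geneA", "chr1", 200, 207)])
        assert site_count(merge_catalogs(a, b), "miR-X", "geneA") == 2

    def test_species_mismatch_refused(self, tmp_path):
        a = self.make(tmp_path, "a.tsv", [row("miR-X", "geneA", "chr1", 100, 107)], species="mouse")
        b = self.make(tmp_path, "b.tsv", [row("miR-X", "geneA", "chr1", 100, 107)], species="human")
        with pytest.raises(ValueError, match="species"):
            merge_catalogs(a, b)

    def test_transcript_level_sites_pool_to_gene(self, tmp_path):
        a = self.make(
            tmp_path,
            "tx.tsv",
            [
                row("miR-X", "geneA", "chr1", 100, 107, tx="tx1"),
                row("miR-X", "geneA", "chr1", 103, 110, tx="tx2"),
            ],
        )
        assert site_count(a, "miR-X", "geneA") == 1


class TestInvariants:
    def test_index_conserves_total_3utr_sites(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "mix.tsv",
            [
                row("miR-X", "geneA", "chr1", 100, 107),
                row("miR-X", "geneA", "chr1", 200, 207),
                row("miR-Y", "geneB", "chr2", 100, 107, region="CDS"),
                row("miR-Z", "geneC", "chr3", 100, 107),
            ],
        )
        catalog = load_catalog(path)
        n_3utr = sum(1 for s in catalog.sites if s.region == "3UTR")
        assert sum(catalog.site_count_index.values()) == n_3utr

    def test_reindex_idempotent(self, example_catalog):
        before = dict(example_catalog.site_count_index)
        example_catalog.reindex()
        example_catalog.reindex()
        assert example_catalog.site_count_index == before

    def test_roundtrip_generic_tsv(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "rt.tsv",
            [row("miR-X", "geneA", "chr1", 100, 107), row("miR-Y", "geneB", "chr2", 50, 60, strand="-")],
        )
        catalog = load_catalog(path)
        out = tmp_path / "out.tsv"
        write_catalog(catalog, out)
        again = load_catalog(out)
        assert again.sites == catalog.sites
        assert again.site_count_index == catalog.site_count_index

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.data())
    def test_merge_commutative_and_associative(self, data):
        """Pooling catalogs is order-insensitive at the site level."""

        def random_catalog(label):
            n = data.draw(st.integers(0, 6), label=label)
            sites = []
            for k in range(n):
                start = data.draw(st.integers(0, 300), label=f"{label}:start{k}")
                length = data.draw(st.integers(1, 30), label=f"{label}:len{k}")
                mirna = data.draw(st.sampled_from(["m1", "m2"]), label=f"{label}:m{k}")
                gene = data.draw(st.sampled_from(["gA", "gB"]), label=f"{label}:g{k}")
                sites.append(
                    BindingSite(
                        mirna_id=mirna, gene_id=gene, chrom="chr1",
                        start=start, end=start + length, strand="+",
                    )
                )
            c = InteractionCatalog(sites=sites, species="x")
            c.reindex()
            return c

        a, b, c = random_catalog("a"), random_catalog("b"), random_catalog("c")

        def key(cat):
            return sorted(
                (s.mirna_id, s.gene_id, s.chrom, s.strand, s.start, s.end) for s in cat.sites
            )

        assert key(merge_catalogs(a, b)) == key(merge_catalogs(b, a))
        assert key(merge_catalogs(merge_catalogs(a, b), c)) == key(
            merge_catalogs(a, merge_catalogs(b, c))
        )


def test_site_count_absent_pair_is_zero(example_catalog):
    assert site_count(example_catalog, "m1", "A") == 3
    assert site_count(example_catalog, "nope", "A") == 0
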