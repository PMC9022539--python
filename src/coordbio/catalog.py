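"""Binding-site catalog I/O, merging, and site-count indexing.

A catalog holds experimentally verified miRNA binding sites on target mRNAs
(miRTarBase/TarBase-style exports pooled into one table).  The quantity every
downstream CB condition consumes is the number of *distinct merged* binding
sites a miRNA has on the 3'UTR of a gene, so the catalog maintains a
``(mirna_id, gene_id) -> count`` index over 3'UTR sites only.  Sites in other
regions (CDS, 5'UTR) are retained for reporting but never indexed.

Coordinates are stored 0-based half-open.  Database-style dialects that export
1-based inclusive coordinates are converted at parse time.  Sites of the same
(miRNA, gene) pair on the same chromosome and strand whose intervals overlap
by at least one base are collapsed into one site spanning their union, so a
site reported by two databases (or on two transcripts of one gene) is counted
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENERIC_COLUMNS = [
    "mirna_id",
    "gene_id",
    "transcript_id",
    "chrom",
    "start",
    "end",
    "strand",
    "region",
    "evidence",
    "source_db",
]

VALID_REGIONS = {"3UTR", "5UTR", "CDS", "unknown"}
VALID_EVIDENCE = {"strong", "weak", "direct", "unknown"}

#: column-name mappings for database-style export dialects; both use 1-based
#: inclusive genomic coordinates, the generic dialect is 0-based half-open.
_DIALECTS = {
    "generic_tsv": {"columns": {}, "one_based": False},
    "mirtarbase_like": {
        "columns": {
            "miRNA": "mirna_id",
            "Target Gene": "gene_id",
            "Transcript": "transcript_id",
            "Chromosome": "chrom",
            "Binding Site Start": "start",
            "Binding Site End": "end",
            "Strand": "strand",
            "Region": "region",
            "Support Type": "evidence",
        },
        "one_based": True,
        "source_db": "miRTarBase",
    },
    "tarbase_like": {
        "columns": {
            "mirna": "mirna_id",
            "geneName": "gene_id",
            "transcript": "transcript_id",
            "chromosome": "chrom",
            "start": "start",
            "stop": "end",
            "strand": "strand",
            "region": "region",
            "method_type": "evidence",
        },
        "one_based": True,
        "source_db": "TarBase",
    },
}


class CatalogFormatError(ValueError):
    """Raised when a catalog file violates its declared dialect."""


@dataclass(frozen=True)
class BindingSite:
    """One miRNA binding site on a target mRNA.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    """

    mirna_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    transcript_id: str | None = None
    strand: str = "unknown"
    region: str = "3UTR"
    evidence: str = "unknown"
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.gene_id:
            raise ValueError("mirna_id and gene_id must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"site interval must be non-empty: start={self.start} end={self.end}"
            )
        if self.region not in VALID_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.evidence not in VALID_EVIDENCE:
            raise ValueError(f"unknown evidence tier {self.evidence!r}")


@dataclass
class InteractionCatalog:
    """Indexed collection of binding sites.

    ``site_count_index`` maps ``(mirna_id, gene_id)`` to the number of merged
    3'UTR sites for that pair; pairs whose only sites lie outside the 3'UTR
    are absent from the index.
    """

    sites: list[BindingSite] = field(default_factory=list)
    site_count_index: dict[tuple[str, str], int] = field(default_factory=dict)
    species: str = "unknown"

    def __post_init__(self) -> None:
        if not self.site_count_index and self.sites:
            self.reindex()

    def reindex(self) -> None:
        """Rebuild the 3'UTR site-count index from ``self.sites``.

        Idempotent: the sites themselves are not modified (merging happens at
        load/merge time), only the counts are re-derived.
        """
        index: dict[tuple[str, str], int] = {}
        for site in self.sites:
            if site.region == "3UTR":
                key = (site.mirna_id, site.gene_id)
                index[key] = index.get(key, 0) + 1
        self.site_count_index = index

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.site_count_index}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.site_count_index}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": s.mirna_id,
                "gene_id": s.gene_id,
                "transcript_id": s.transcript_id or "",
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "region": s.region,
                "evidence": s.evidence,
                "source_db": s.source_db,
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows, columns=GENERIC_COLUMNS)


def _merge_intervals(sites: Sequence[BindingSite]) -> list[BindingSite]:
    """Collapse overlapping sites of one (miRNA, gene, chrom, strand, region) group."""
    ordered = sorted(sites, key=lambda s: (s.start, s.end))
    merged: list[BindingSite] = []
    for site in ordered:
        if merged and site.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                end=max(prev.end, site.end),
                source_db=prev.source_db
                if prev.source_db == site.source_db
                else f"{prev.source_db}+{site.source_db}".strip("+"),
            )
        else:
            merged.append(site)
    return merged


def _dedup_sites(sites: Iterable[BindingSite], merge_overlapping: bool = True) -> list[BindingSite]:
    """Pool sites to the gene level and merge overlapping intervals.

    Transcript identity is deliberately dropped when grouping: sites on
    different transcripts of one gene count once toward the gene if their
    genomic intervals overlap.
    """
    if not merge_overlapping:
        return list(sites)
    groups: dict[tuple[str, str, str, str, str], list[BindingSite]] = {}
    for site in sites:
        key = (site.mirna_id, site.gene_id, site.chrom, site.strand, site.region)
        groups.setdefault(key, []).append(site)
    out: list[BindingSite] = []
    for key in sorted(groups):
        out.extend(_merge_intervals(groups[key]))
    return out


def load_catalog(
    path: str | Path,
    format_dialect: str = "generic_tsv",
    species: str = "unknown",
    min_evidence: str | None = None,
    merge_overlapping: bool = True,
) -> InteractionCatalog:
    """Read a binding-site table into an indexed :class:`InteractionCatalog`.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    format_dialect
        ``generic_tsv`` (native schema, 0-based half-open coordinates) or
        ``mirtarbase_like`` / ``tarbase_like`` (database export columns,
        1-based inclusive coordinates, converted on read).
    species
        Species tag attached to the catalog; merging refuses to cross tags.
    min_evidence
        Optional restriction to one evidence tier ("strong", "weak",
        "direct"); by default all tiers are kept.
    merge_overlapping
        Collapse overlapping duplicate sites (cross-database dedup); can be
        switched off to count raw rows.

    Rows lacking genomic positions are dropped (a count is logged).  Rows
    whose coordinates are present but unparseable are collected and raised
    together in one :class:`CatalogFormatError`.
    """
    path = Path(path)
    if format_dialect not in _DIALECTS:
        raise CatalogFormatError(f"unknown dialect {format_dialect!r}")
    dialect = _DIALECTS[format_dialect]

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect["columns"]:
        missing = [c for c in dialect["columns"] if c not in df.columns]
        df = df.rename(columns=dialect["columns"])
    else:
        missing = [c for c in ("mirna_id", "gene_id", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"{path.name}: dialect {format_dialect!r} requires missing column(s): "
            + ", ".join(missing)
        )

    sites: list[BindingSite] = []
    bad_rows: list[str] = []
    n_dropped_no_position = 0
    offset = 1 if dialect["one_based"] else 0
    default_source = dialect.get("source_db", "")

    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        raw_start, raw_end = rec.get("start", ""), rec.get("end", "")
        if raw_start == "" or raw_end == "" or rec.get("chrom", "") == "":
            n_dropped_no_position += 1
            continue
        try:
            start = int(raw_start) - offset
            end = int(raw_end)  # 1-based inclusive end == 0-based exclusive end
        except ValueError:
            bad_rows.append(f"line {i}: unparseable coordinates ({raw_start!r}, {raw_end!r})")
            continue
        try:
            sites.append(
                BindingSite(
                    mirna_id=rec["mirna_id"],
                    gene_id=rec["gene_id"],
                    transcript_id=rec.get("transcript_id") or None,
                    chrom=rec["chrom"],
                    start=start,
                    end=end,
                    strand=rec.get("strand") or "unknown",
                    region=rec.get("region") or "3UTR",
                    evidence=(rec.get("evidence") or "unknown").lower(),
                    source_db=rec.get("source_db") or default_source,
                )
            )
        except ValueError as exc:
            bad_rows.append(f"line {i}: {exc}")

    if bad_rows:
        raise CatalogFormatError(
            f"{path.name}: {len(bad_rows)} malformed row(s):\n  " + "\n  ".join(bad_rows)
        )
    if n_dropped_no_position:
        logger.info(
            "%s: dropped %d row(s) without genomic positions", path.name, n_dropped_no_position
        )
    if min_evidence is not None:
        sites = [s for s in sites if s.evidence == min_evidence]

    catalog = InteractionCatalog(
        sites=_dedup_sites(sites, merge_overlapping), species=species
    )
    catalog.reindex()
    return catalog


def write_catalog(catalog: InteractionCatalog, path: str | Path) -> None:
    """Write a catalog in the generic TSV dialect (0-based half-open)."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def merge_catalogs(
    a: InteractionCatalog, b: InteractionCatalog, merge_overlapping: bool = True
) -> InteractionCatalog:
    """Pool two catalogs of the same species into one.

    Overlapping sites of the same (miRNA, gene, chrom, strand) across the two
    inputs are merged into single union intervals and counts re-derived.
    """
    if a.species != b.species:
        raise ValueError(
            f"refusing to merge catalogs of different species: {a.species!r} vs {b.species!r}"
        )
    merged = InteractionCatalog(
        sites=_dedup_sites(list(a.sites) + list(b.sites), merge_overlapping),
        species=a.species,
    )
    merged.reindex()
    return merged


def site_count(catalog: InteractionCatalog, mirna_id: str, gene_id: str) -> int:
    """Merged 3'UTR site count for a (miRNA, gene) pair; 0 when absent."""
    return catalog.site_count_index.get((mirna_id, gene_id), 0)
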