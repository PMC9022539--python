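"""End-to-end CB pipeline: catalog -> triads -> context -> prevalence -> ORA.

One configured run mirrors the COORD-BIO query flow: load and pool the
binding-site catalogs, enumerate triads for the requested regulator(s),
contextualize against the supplied expression tables, drop triads confounded
by direct gene A -> gene B regulation, score pair prevalence, and (when gene
sets are supplied) test effector-gene over-representation.  Stage-level row
counts are recorded in the run summary because the scientific result of a
run *is* largely those deltas — how many candidate relationships survive
each layer of evidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
import yaml

from coordbio.catalog import InteractionCatalog, load_catalog, merge_catalogs
from coordbio.enrichment import enrich, read_gmt, results_to_frame
from coordbio.enumeration import (
    ALL_REGULATORS,
    CBTriad,
    enumerate_triads,
    pair_prevalence,
    prevalence_to_frame,
    triads_to_frame,
)
from coordbio.expression import (
    ContextualizedTriad,
    RegulatoryEdge,
    contextualize,
    contextualized_to_frame,
    filter_direct_regulation,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Paths are resolved relative to the config file's directory when loaded
    via :meth:`from_yaml`.
    """

    catalog_paths: list[str]
    output_dir: str
    catalog_dialects: list[str] = field(default_factory=list)
    species: str = "unknown"
    regulator: str = ALL_REGULATORS
    mrna_de_path: str | None = None
    mirna_de_path: str | None = None
    mode: str = "down_down"
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    tf_edges_path: str | None = None
    gmt_path: str | None = None
    background_path: str | None = None
    seed: int = 0
    max_gap: int | None = None

    def __post_init__(self) -> None:
        if not self.catalog_paths:
            raise ValueError("at least one catalog path is required")
        if not self.catalog_dialects:
            self.catalog_dialects = ["generic_tsv"] * len(self.catalog_paths)
        if len(self.catalog_dialects) != len(self.catalog_paths):
            raise ValueError("need one dialect per catalog path")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.mode not in {"down_down", "full_pattern"}:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        cfg = cls(**raw)
        base = path.parent
        cfg.catalog_paths = [str((base / p)) for p in cfg.catalog_paths]
        for attr in ("mrna_de_path", "mirna_de_path", "tf_edges_path", "gmt_path", "background_path"):
            val = getattr(cfg, attr)
            if val is not None:
                setattr(cfg, attr, str(base / val))
        cfg.output_dir = str(base / cfg.output_dir)
        return cfg

    def validate_paths(self) -> None:
        for p in self.catalog_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"catalog file not found: {p}")
        for attr in ("mrna_de_path", "mirna_de_path", "tf_edges_path", "gmt_path", "background_path"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{attr.replace('_path', '')} file not found: {val}")


@dataclass
class RunSummary:
    stage_counts: dict[str, int | None]
    output_paths: dict[str, str]
    config_echo: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "output_paths": self.output_paths,
                "config": self.config_echo,
            },
            indent=2,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_edges(path: str) -> list[RegulatoryEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_gene", "target_gene"}
    if not required <= set(df.columns):
        raise ValueError(f"edge table missing column(s): {', '.join(sorted(required - set(df.columns)))}")
    return [
        RegulatoryEdge(
            source_gene=r.source_gene,
            target_gene=r.target_gene,
            relation=getattr(r, "relation", "TF->target"),
        )
        for r in df.itertuples(index=False)
    ]


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute load/merge -> enumerate -> contextualize -> TF filter ->
    prevalence -> optional enrichment, writing TSV/JSON outputs.

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage; outputs written by completed stages are left in place alongside a
    ``FAILED_<stage>`` marker file.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | None] = {}
    paths: dict[str, str] = {}
    stage = "load_catalogs"
    try:
        catalogs = [
            load_catalog(p, format_dialect=d, species=config.species)
            for p, d in zip(config.catalog_paths, config.catalog_dialects)
        ]
        catalog = catalogs[0]
        for other in catalogs[1:]:
            catalog = merge_catalogs(catalog, other)
        counts["catalog_sites"] = len(catalog.sites)
        counts["catalog_pairs"] = len(catalog.site_count_index)

        stage = "enumerate"
        triads = enumerate_triads(catalog, regulator=config.regulator, max_gap=config.max_gap)
        counts["enumerated"] = len(triads)
        triads_path = outdir / "triads.tsv"
        triads_to_frame(triads).to_csv(triads_path, sep="\t", index=False)
        paths["triads"] = str(triads_path)

        stage = "contextualize"
        kept: list[CBTriad]
        contextualized: list[ContextualizedTriad] = []
        if config.mrna_de_path is not None:
            mrna_de = pd.read_csv(config.mrna_de_path, sep="\t")
            mirna_de = (
                pd.read_csv(config.mirna_de_path, sep="\t")
                if config.mirna_de_path is not None
                else None
            )
            contextualized = contextualize(
                triads,
                mrna_de,
                mirna_de,
                mode=config.mode,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
            )
            if config.mode == "full_pattern":
                kept = [c.triad for c in contextualized if c.tier.value != "unsupported"]
            else:
                kept = [c.triad for c in contextualized]
            counts["contextualized"] = len(kept)
            ctx_path = outdir / "contextualized.tsv"
            contextualized_to_frame(contextualized).to_csv(ctx_path, sep="\t", index=False)
            paths["contextualized"] = str(ctx_path)
        else:
            kept = triads
            counts["contextualized"] = None  # not applicable without DE tables

        stage = "filter_direct_regulation"
        if config.tf_edges_path is not None:
            edges = _read_edges(config.tf_edges_path)
            kept = filter_direct_regulation(kept, edges)
        counts["final_triads"] = len(kept)
        final_path = outdir / "final_triads.tsv"
        triads_to_frame(kept).to_csv(final_path, sep="\t", index=False)
        paths["final_triads"] = str(final_path)

        stage = "prevalence"
        prevalence = pair_prevalence(kept)
        counts["prevalence_pairs"] = len(prevalence)
        prev_path = outdir / "prevalence.tsv"
        prevalence_to_frame(prevalence).to_csv(prev_path, sep="\t", index=False)
        paths["prevalence"] = str(prev_path)

        stage = "export_network"
        net_path = outdir / "network.json"
        export_network(kept, "json", net_path)
        paths["network"] = str(net_path)

        stage = "enrichment"
        if config.gmt_path is not None:
            if config.background_path is None:
                raise ValueError("enrichment requires an explicit background gene list")
            background = [
                line.strip()
                for line in Path(config.background_path).read_text().splitlines()
                if line.strip()
            ]
            collection = read_gmt(config.gmt_path, background)
            effectors = sorted({t.gene_b for t in kept})
            results = enrich(effectors, collection)
            counts["enriched_sets"] = len(results)
            enr_path = outdir / "enrichment.tsv"
            results_to_frame(results).to_csv(enr_path, sep="\t", index=False)
            paths["enrichment"] = str(enr_path)
    except Exception as exc:  # noqa: BLE001 - converted to a stage-tagged error
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(stage, exc) from exc

    summary = RunSummary(
        stage_counts=counts,
        output_paths=paths,
        config_echo={k: v for k, v in vars(config).items()},
    )
    (outdir / "summary.json").write_text(summary.to_json())
    for name, count in counts.items():
        logger.info("stage %s: %s rows", name, count)
    return summary


def _triads_graph(triads: Iterable[CBTriad]) -> nx.DiGraph:
    """Typed network: regulator/secondary miRNA nodes, gene A/B nodes.

    Per triad: repression edges m1->geneA, m2->geneA, m2->geneB and one
    coordination edge m1->m2.
    """
    g = nx.DiGraph()
    for t in triads:
        g.add_node(t.regulator, node_type="regulator_miRNA")
        g.add_node(t.secondary, node_type="secondary_miRNA")
        g.add_node(t.gene_a, node_type="gene_a")
        g.add_node(t.gene_b, node_type="gene_b")
        g.add_edge(t.regulator, t.gene_a, edge_type="represses", n_sites=t.n_m1_on_a)
        g.add_edge(t.secondary, t.gene_a, edge_type="represses", n_sites=t.n_m2_on_a)
        g.add_edge(t.secondary, t.gene_b, edge_type="represses", n_sites=t.n_m2_on_b)
        g.add_edge(t.regulator, t.secondary, edge_type="coordinates_biogenesis", n_sites=0)
    return g


def export_network(
    triads: Sequence[CBTriad],
    fmt: str,
    path: str | Path,
) -> Path:
    """Write the triad network as edge TSV, GraphML-style XML, or JSON.

    The JSON form is lossless for node types and edge attributes and can be
    read back with :func:`load_network_json`.
    """
    path = Path(path)
    g = _triads_graph(triads)
    if fmt == "edge_tsv":
        rows = [
            {"source": u, "target": v, "edge_type": d["edge_type"], "n_sites": d["n_sites"]}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "edge_type", "n_sites"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "graphml_like_xml":
        nx.write_graphml(g, path)
    elif fmt == "json":
        doc = {
            "nodes": [
                {"id": n, "node_type": d["node_type"]} for n, d in sorted(g.nodes(data=True))
            ],
            "edges": [
                {"source": u, "target": v, "edge_type": d["edge_type"], "n_sites": d["n_sites"]}
                for u, v, d in sorted(g.edges(data=True))
            ],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def load_network_json(path: str | Path) -> nx.DiGraph:
    doc = json.loads(Path(path).read_text())
    g = nx.DiGraph()
    for node in doc["nodes"]:
        g.add_node(node["id"], node_type=node["node_type"])
    for edge in doc["edges"]:
        g.add_edge(edge["source"], edge["target"], edge_type=edge["edge_type"], n_sites=edge["n_sites"])
    return g
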