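"""Synthetic catalogs, expression tables, and dose series with planted truth.

Real CB inference runs on pooled TarBase/miRTarBase snapshots and GEO
differential-expression tables.  Those inputs are large, versioned and
external; this module builds structurally faithful stand-ins whose ground
truth is known by construction, so every pipeline stage can be tested for
exact recovery.

The defining contract of the catalog generator is *planted/decoy
separation*: exhaustive enumeration of the generated catalog returns exactly
the planted triads.  Each planted triad gets its own disjoint pair of
miRNAs and pair of genes, which provably prevents cross-triad artifacts (a
planted secondary has at most one site on its gene A and its gene B carries
no other miRNA's sites, so no unintended regulator/secondary role is
possible).  Decoys are negative controls, one construction per CB-condition
violation, likewise built on dedicated identifiers.

Expression tables emulate the study design the method assumes: the stimulus
induces the regulator and, through coordinated biogenesis, the secondary
miRNAs (both upregulated), while their target genes A and B are repressed
(downregulated); all other features sit at a null log fold change.  P values
come from a two-group t-test on simulated replicates (3 vs 3 by default) so
the joint (log2fc, p) structure is realistic; at noise_sigma = 0 the test is
degenerate and planted features are assigned a passing p-value directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coordbio.catalog import BindingSite, InteractionCatalog
from coordbio.dampening import DampeningParams, LayerNetwork, simulate_series
from coordbio.enumeration import CBTriad

#: decoy classes, one per CB-condition violation (plus a region control):
#: tie_on_gene_a     — secondary matches the regulator's gene-A site count
#: single_site_on_b  — gene B carries only one secondary site
#: m1_site_on_b      — gene B carries a regulator site
#: no_m2_on_a        — secondary has no site on gene A ("in tandem" fails)
#: self_pair         — one miRNA with multi-site targets but no partner
#: non_3utr          — qualifying counts located in the CDS, not the 3'UTR
DECOY_CLASSES = (
    "tie_on_gene_a",
    "single_site_on_b",
    "m1_site_on_b",
    "no_m2_on_a",
    "self_pair",
    "non_3utr",
)

_SITE_LEN = 8
_SITE_SPACING = 100


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated catalog."""

    planted_triads: list[CBTriad]
    decoys: dict[str, str] = field(default_factory=dict)  # decoy tag -> violated condition
    de_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_triads": [
                    {
                        "regulator": t.regulator,
                        "gene_a": t.gene_a,
                        "secondary": t.secondary,
                        "gene_b": t.gene_b,
                        "n_m1_on_a": t.n_m1_on_a,
                        "n_m2_on_a": t.n_m2_on_a,
                        "n_m2_on_b": t.n_m2_on_b,
                    }
                    for t in self.planted_triads
                ],
                "decoys": self.decoys,
                "de_effects": {k: list(v) for k, v in self.de_effects.items()},
                "noise_sigma": self.noise_sigma,
                "seed": self.seed,
            },
            indent=2,
        )


def _sites(
    rng: np.random.Generator,
    mirna: str,
    gene: str,
    chrom: str,
    n: int,
    region: str = "3UTR",
    start0: int | None = None,
) -> list[BindingSite]:
    """n disjoint fixed-length sites for one pair on one chromosome."""
    base = int(rng.integers(1000, 5000)) if start0 is None else start0
    out = []
    for i in range(n):
        s = base + i * _SITE_SPACING
        out.append(
            BindingSite(
                mirna_id=mirna,
                gene_id=gene,
                chrom=chrom,
                start=s,
                end=s + _SITE_LEN,
                strand="+",
                region=region,
                evidence="strong",
                source_db="synthetic",
            )
        )
    return out


def generate_catalog(
    n_mirnas: int,
    n_genes: int,
    n_planted: int,
    decoy_profile: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[InteractionCatalog, SyntheticTruth]:
    """Catalog whose exhaustive triad enumeration equals the planted set.

    Each planted triad i consumes two dedicated miRNAs (regulator, secondary)
    and two dedicated genes (A, B); each decoy consumes its own identifiers
    from the remaining pool.  Site counts per planted triad are drawn as
    n_m1_on_a in {2..4}, n_m2_on_a in {1..n_m1_on_a-1}, n_m2_on_b in {2, 3}.
    Every gene lives on its own chromosome, so interval merging across genes
    never interacts.

    Raises if the requested identifiers exceed ``n_mirnas`` x ``n_genes``.
    """
    decoy_profile = list(DECOY_CLASSES) if decoy_profile is None else list(decoy_profile)
    unknown = [d for d in decoy_profile if d not in DECOY_CLASSES]
    if unknown:
        raise ValueError(f"unknown decoy class(es): {', '.join(unknown)}")

    mirnas_needed = 2 * n_planted + sum(1 if d == "self_pair" else 2 for d in decoy_profile)
    genes_needed = 2 * n_planted + 2 * len(decoy_profile)
    if mirnas_needed > n_mirnas or genes_needed > n_genes:
        raise ValueError(
            f"infeasible request: need {mirnas_needed} miRNAs and {genes_needed} genes, "
            f"have {n_mirnas} x {n_genes}"
        )

    rng = np.random.default_rng(seed)
    mirna_pool = iter([f"miR-{i:03d}" for i in range(n_mirnas)])
    gene_pool = iter([f"gene{i:03d}" for i in range(n_genes)])

    sites: list[BindingSite] = []
    planted: list[CBTriad] = []
    for _ in range(n_planted):
        m1, m2 = next(mirna_pool), next(mirna_pool)
        ga, gb = next(gene_pool), next(gene_pool)
        n1 = int(rng.integers(2, 5))
        n2a = int(rng.integers(1, n1))
        n2b = int(rng.integers(2, 4))
        sites += _sites(rng, m1, ga, f"chr_{ga}", n1)
        sites += _sites(rng, m2, ga, f"chr_{ga}", n2a, start0=9000)
        sites += _sites(rng, m2, gb, f"chr_{gb}", n2b)
        planted.append(
            CBTriad(
                regulator=m1, gene_a=ga, secondary=m2, gene_b=gb,
                n_m1_on_a=n1, n_m2_on_a=n2a, n_m2_on_b=n2b,
            )
        )

    decoys: dict[str, str] = {}
    for idx, cls in enumerate(decoy_profile):
        tag = f"decoy{idx}_{cls}"
        if cls == "self_pair":
            m = next(mirna_pool)
            ga, gb = next(gene_pool), next(gene_pool)
            sites += _sites(rng, m, ga, f"chr_{ga}", 3)
            sites += _sites(rng, m, gb, f"chr_{gb}", 2)
            decoys[tag] = "regulator == secondary is excluded"
            continue
        m1, m2 = next(mirna_pool), next(mirna_pool)
        ga, gb = next(gene_pool), next(gene_pool)
        if cls == "tie_on_gene_a":
            sites += _sites(rng, m1, ga, f"chr_{ga}", 2)
            sites += _sites(rng, m2, ga, f"chr_{ga}", 2, start0=9000)
            sites += _sites(rng, m2, gb, f"chr_{gb}", 2)
            decoys[tag] = "n_m2_on_a == n_m1_on_a violates strict 'fewer'"
        elif cls == "single_site_on_b":
            sites += _sites(rng, m1, ga, f"chr_{ga}", 3)
            sites += _sites(rng, m2, ga, f"chr_{ga}", 1, start0=9000)
            sites += _sites(rng, m2, gb, f"chr_{gb}", 1)
            decoys[tag] = "n_m2_on_b == 1 violates gene-B >= 2 sites"
        elif cls == "m1_site_on_b":
            sites += _sites(rng, m1, ga, f"chr_{ga}", 3)
            sites += _sites(rng, m2, ga, f"chr_{ga}", 1, start0=9000)
            sites += _sites(rng, m2, gb, f"chr_{gb}", 2)
            sites += _sites(rng, m1, gb, f"chr_{gb}", 1, start0=9000)
            decoys[tag] = "gene B carries a regulator site"
        elif cls == "no_m2_on_a":
            sites += _sites(rng, m1, ga, f"chr_{ga}", 3)
            sites += _sites(rng, m2, gb, f"chr_{gb}", 2)
            decoys[tag] = "secondary has no site on gene A ('in tandem' fails)"
        elif cls == "non_3utr":
            sites += _sites(rng, m1, ga, f"chr_{ga}", 3, region="CDS")
            sites += _sites(rng, m2, ga, f"chr_{ga}", 1, region="CDS", start0=9000)
            sites += _sites(rng, m2, gb, f"chr_{gb}", 2, region="CDS")
            decoys[tag] = "qualifying counts lie in the CDS, not the 3'UTR"

    catalog = InteractionCatalog(sites=sites, species="synthetic")
    catalog.reindex()
    planted.sort(key=lambda t: (t.regulator, t.gene_a, t.secondary, t.gene_b))
    truth = SyntheticTruth(planted_triads=planted, decoys=decoys, seed=seed)
    return catalog, truth


def generate_expression(
    truth: SyntheticTruth,
    catalog: InteractionCatalog,
    up_lfc: float = 1.0,
    down_lfc: float = 1.0,
    noise_sigma: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """mRNA and miRNA DE tables consistent with coordinated repression.

    Planted regulators and secondaries are centred at +``up_lfc`` (log2),
    planted genes A/B at -``down_lfc``; every other catalog feature at 0.
    With ``noise_sigma`` > 0, per-replicate Gaussian noise feeds a two-group
    Welch t-test whose mean difference is the reported log2fc; at
    ``noise_sigma`` = 0 the effects are exact and planted features receive
    p = 1e-6 while null features receive p = 1.0.
    """
    if up_lfc <= 0 or down_lfc <= 0:
        raise ValueError("effect magnitudes must be positive")
    rng = np.random.default_rng(seed)

    up_features = set()
    down_features = set()
    for t in truth.planted_triads:
        up_features |= {t.regulator, t.secondary}
        down_features |= {t.gene_a, t.gene_b}

    all_mirnas = sorted(catalog.mirnas | up_features)
    all_genes = sorted(catalog.genes | down_features)

    def _row(feature: str, delta: float) -> tuple[str, float, float]:
        if noise_sigma == 0.0:
            pval = 1e-6 if delta != 0.0 else 1.0
            return feature, delta, pval
        ctrl = rng.normal(0.0, noise_sigma, n_replicates)
        treat = rng.normal(delta, noise_sigma, n_replicates)
        t_res = stats.ttest_ind(treat, ctrl, equal_var=False)
        return feature, float(treat.mean() - ctrl.mean()), float(t_res.pvalue)

    effects: dict[str, tuple[str, float]] = {}
    mirna_rows, mrna_rows = [], []
    for m in all_mirnas:
        delta = up_lfc if m in up_features else 0.0
        if delta:
            effects[m] = ("up", delta)
        mirna_rows.append(_row(m, delta))
    for g in all_genes:
        delta = -down_lfc if g in down_features else 0.0
        if delta:
            effects[g] = ("down", -delta)
        mrna_rows.append(_row(g, delta))

    truth.de_effects = effects
    truth.noise_sigma = noise_sigma
    cols = ["feature_id", "log2fc", "pvalue"]
    return (
        pd.DataFrame(mrna_rows, columns=cols),
        pd.DataFrame(mirna_rows, columns=cols),
    )


def generate_tf_edges(
    truth: SyntheticTruth, n_edges: int = 0, seed: int = 0
) -> pd.DataFrame:
    """TF->target edges covering the first ``n_edges`` planted (geneA, geneB) pairs."""
    if n_edges > len(truth.planted_triads):
        raise ValueError("cannot cover more planted pairs than exist")
    rows = [
        {"source_gene": t.gene_a, "target_gene": t.gene_b, "relation": "TF->target"}
        for t in truth.planted_triads[:n_edges]
    ]
    return pd.DataFrame(rows, columns=["source_gene", "target_gene", "relation"])


def generate_gene_sets(
    truth: SyntheticTruth,
    catalog: InteractionCatalog,
    n_background_extra: int = 50,
) -> tuple[dict[str, tuple[str, frozenset[str]]], frozenset[str]]:
    """One 'planted effector' gene set against a padded background universe."""
    effectors = frozenset(t.gene_b for t in truth.planted_triads)
    background = frozenset(catalog.genes) | frozenset(
        f"bg_gene{i:03d}" for i in range(n_background_extra)
    )
    sets = {"PLANTED_EFFECTORS": ("planted secondary effector genes", effectors)}
    return sets, background


def generate_concentration_series(
    params: DampeningParams,
    network: LayerNetwork,
    doses: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-response table from the forward model, plus optional Gaussian noise.

    Noise is additive on the measured target levels only (miRNA levels are
    treated as controlled); deterministic for a fixed seed.
    """
    table = simulate_series(params, network, doses)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        table = table.copy()
        table["target_level"] = table["target_level"] + rng.normal(
            0.0, noise_sigma, len(table)
        )
    return table
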