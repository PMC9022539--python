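"""Differential-expression contextualization of CB triads.

Triads enumerated from binding sites are hypotheses; expression data pick out
the ones consistent with coordinated repression.  Two classification rules
are used, matching how mRNA microarray/RNA-seq tables and small-RNA-seq
tables are conventionally thresholded:

* mRNAs: linear fold change >= 1.5 (or <= 1/1.5) at P <= 0.05;
* miRNAs: sign of the log fold change at P <= 0.05 (any nonzero change).

``down_down`` contextualization keeps triads whose gene A and gene B are both
downregulated — the signature of regulator-driven coordinated repression when
the regulator itself is induced by the stimulus.  ``full_pattern`` assigns
confidence tiers: high confidence requires both miRNAs up with both target
genes down (or the fully mirrored pattern); low confidence requires all four
features significantly changed in any other arrangement.

A directional transcription-factor filter removes triads where gene A could
itself regulate gene B, since there the gene-B change need not reflect
miRNA-2 biogenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from coordbio.enumeration import CBTriad


class ExpressionCall(str, Enum):
    UP = "up"
    DOWN = "down"
    NOT_SIGNIFICANT = "not_significant"
    UNMEASURED = "unmeasured"


class Tier(str, Enum):
    HIGH_CONFIDENCE = "high_confidence"
    LOW_CONFIDENCE = "low_confidence"
    UNSUPPORTED = "unsupported"


@dataclass(frozen=True)
class ExpressionRecord:
    """One row of a differential-expression table (log2 fold change)."""

    feature_id: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"{self.feature_id}: p-value {self.pvalue} outside [0, 1]")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.feature_id}: non-finite log2 fold change")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed gene-gene regulatory relation (e.g. TF -> target)."""

    source_gene: str
    target_gene: str
    relation: str = "TF->target"

    def __post_init__(self) -> None:
        if self.source_gene == self.target_gene:
            raise ValueError("self-regulation edges are not meaningful here")


@dataclass(frozen=True)
class ContextualizedTriad:
    triad: CBTriad
    call_gene_a: ExpressionCall
    call_gene_b: ExpressionCall
    call_regulator: ExpressionCall
    call_secondary: ExpressionCall
    tier: Tier


def classify_mrna(
    record: ExpressionRecord, fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> ExpressionCall:
    """Call an mRNA up/down/not_significant by symmetric linear fold change.

    Up requires ``2**log2fc >= fc_threshold``, down requires
    ``2**log2fc <= 1/fc_threshold``, both at ``pvalue <= p_threshold``.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1 (linear scale)")
    if record.pvalue > p_threshold:
        return ExpressionCall.NOT_SIGNIFICANT
    log2_cut = math.log2(fc_threshold)
    if record.log2fc >= log2_cut:
        return ExpressionCall.UP
    if record.log2fc <= -log2_cut:
        return ExpressionCall.DOWN
    return ExpressionCall.NOT_SIGNIFICANT


def classify_mirna(record: ExpressionRecord, p_threshold: float = 0.05) -> ExpressionCall:
    """Call a miRNA by the sign of its log fold change at P <= threshold."""
    if record.pvalue > p_threshold or record.log2fc == 0.0:
        return ExpressionCall.NOT_SIGNIFICANT
    return ExpressionCall.UP if record.log2fc > 0 else ExpressionCall.DOWN


def _index_table(table: pd.DataFrame, what: str) -> Mapping[str, ExpressionRecord]:
    required = {"feature_id", "log2fc", "pvalue"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{what} table missing column(s): {', '.join(sorted(missing))}")
    dupes = table["feature_id"][table["feature_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(
            f"{what} table has duplicate feature_id(s) (ambiguous): "
            + ", ".join(map(str, dupes[:5]))
        )
    return {
        str(row.feature_id): ExpressionRecord(
            feature_id=str(row.feature_id),
            log2fc=float(row.log2fc),
            pvalue=float(row.pvalue),
        )
        for row in table.itertuples(index=False)
    }


def _call(
    records: Mapping[str, ExpressionRecord] | None,
    feature: str,
    classifier,
    **kwargs,
) -> ExpressionCall:
    if records is None or feature not in records:
        return ExpressionCall.UNMEASURED
    return classifier(records[feature], **kwargs)


def _tier(
    reg: ExpressionCall, sec: ExpressionCall, ga: ExpressionCall, gb: ExpressionCall
) -> Tier:
    up, down = ExpressionCall.UP, ExpressionCall.DOWN
    if (reg, sec, ga, gb) == (up, up, down, down) or (reg, sec, ga, gb) == (down, down, up, up):
        return Tier.HIGH_CONFIDENCE
    if all(c in (up, down) for c in (reg, sec, ga, gb)):
        return Tier.LOW_CONFIDENCE
    return Tier.UNSUPPORTED


def contextualize(
    triads: Iterable[CBTriad],
    mrna_de: pd.DataFrame,
    mirna_de: pd.DataFrame | None = None,
    mode: str = "down_down",
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> list[ContextualizedTriad]:
    """Attach expression calls to triads and filter/tier them.

    Parameters
    ----------
    triads
        Candidate CB triads.
    mrna_de, mirna_de
        DataFrames with columns feature_id, log2fc, pvalue.  The miRNA table
        is optional; without it miRNA calls are ``unmeasured``.
    mode
        ``down_down`` keeps triads whose gene A and gene B are both called
        down (and, when a miRNA table is given, whose secondary miRNA is
        called up); the regulator is assumed induced by the study design and
        is annotated but not required.  Unmeasured target genes drop the
        triad.  ``full_pattern`` keeps every triad and assigns a confidence
        tier instead.
    """
    if mode not in {"down_down", "full_pattern"}:
        raise ValueError(f"unknown contextualization mode {mode!r}")
    mrna = _index_table(mrna_de, "mRNA DE")
    mirna = _index_table(mirna_de, "miRNA DE") if mirna_de is not None else None

    out: list[ContextualizedTriad] = []
    for t in triads:
        ga = _call(mrna, t.gene_a, classify_mrna, fc_threshold=fc_threshold, p_threshold=p_threshold)
        gb = _call(mrna, t.gene_b, classify_mrna, fc_threshold=fc_threshold, p_threshold=p_threshold)
        reg = _call(mirna, t.regulator, classify_mirna, p_threshold=p_threshold)
        sec = _call(mirna, t.secondary, classify_mirna, p_threshold=p_threshold)
        tier = _tier(reg, sec, ga, gb)
        ct = ContextualizedTriad(
            triad=t, call_gene_a=ga, call_gene_b=gb, call_regulator=reg, call_secondary=sec, tier=tier
        )
        if mode == "down_down":
            if ga is not ExpressionCall.DOWN or gb is not ExpressionCall.DOWN:
                continue
            if mirna is not None and sec is not ExpressionCall.UP:
                continue
        out.append(ct)
    return out


def filter_direct_regulation(
    triads: Iterable[CBTriad],
    edges: Iterable[RegulatoryEdge],
    bidirectional: bool = False,
) -> list[CBTriad]:
    """Drop triads whose gene A directly regulates gene B.

    The exclusion is directional (gene A -> gene B) by default: only when
    gene A is the regulator of gene B can the gene-B change be confounded.
    ``bidirectional=True`` removes the reverse orientation too.
    """
    forbidden = {(e.source_gene, e.target_gene) for e in edges}
    if bidirectional:
        forbidden |= {(b, a) for a, b in forbidden}
    return [t for t in triads if (t.gene_a, t.gene_b) not in forbidden]


def contextualized_to_frame(cts: list[ContextualizedTriad]) -> pd.DataFrame:
    rows = [
        {
            "regulator": c.triad.regulator,
            "gene_a": c.triad.gene_a,
            "secondary": c.triad.secondary,
            "gene_b": c.triad.gene_b,
            "call_gene_a": c.call_gene_a.value,
            "call_gene_b": c.call_gene_b.value,
            "call_regulator": c.call_regulator.value,
            "call_secondary": c.call_secondary.value,
            "tier": c.tier.value,
        }
        for c in cts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "regulator",
            "gene_a",
            "secondary",
            "gene_b",
            "call_gene_a",
            "call_gene_b",
            "call_regulator",
            "call_secondary",
            "tier",
        ],
    )
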