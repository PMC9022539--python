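"""Small bundled example tables.

``lps_macrophage_relationships`` is a published worked example of CB
regulator-target relationships in the mmu-miR-146a-5p network of murine
macrophages responding to LPS: eleven triads in which the secondary effector
miRNA (miR-16-5p or miR-23b-3p) is upregulated upon regulator overexpression
and both target genes are downregulated, together with the secondary miRNA's
small-RNA-seq log fold change, its P value, and the (regulator, secondary)
pair prevalence in the pooled murine binding-site catalog.

``salmonella_pathway_example`` is the matching KEGG over-representation
worked example for the network's effector genes: 15 of 170 mappable query
genes fall in the Salmonella infection pathway (mmu05132), which annotates
253 of the 8,900 background genes.
"""

from __future__ import annotations

import io

import pandas as pd

_LPS_TSV = """\
gene_a\tregulator\tgene_b\tsecondary\tlog2fc_secondary\tpvalue_secondary\tprevalence
bach2\tmmu-miR-146a-5p\tmcm5\tmmu-miR-16-5p\t0.611762\t0.000437\t39
mmd\tmmu-miR-146a-5p\tmcm5\tmmu-miR-16-5p\t0.611762\t0.000437\t39
rbl1\tmmu-miR-146a-5p\tmcm5\tmmu-miR-16-5p\t0.611762\t0.000437\t39
irf4\tmmu-miR-146a-5p\tmcm5\tmmu-miR-16-5p\t0.611762\t0.000437\t39
bach2\tmmu-miR-146a-5p\tncapg2\tmmu-miR-16-5p\t0.611762\t0.000437\t39
mmd\tmmu-miR-146a-5p\tncapg2\tmmu-miR-16-5p\t0.611762\t0.000437\t39
rbl1\tmmu-miR-146a-5p\tncapg2\tmmu-miR-16-5p\t0.611762\t0.000437\t39
irf4\tmmu-miR-146a-5p\tncapg2\tmmu-miR-16-5p\t0.611762\t0.000437\t39
irf4\tmmu-miR-146a-5p\tmcm4\tmmu-miR-23b-3p\t0.295528\t0.02836\t21
bach2\tmmu-miR-146a-5p\tmcm4\tmmu-miR-23b-3p\t0.295528\t0.02836\t21
rbl1\tmmu-miR-146a-5p\tmcm4\tmmu-miR-23b-3p\t0.295528\t0.02836\t21
"""

#: ORA worked example: (k, n, K, N) and the published P value.
SALMONELLA_PATHWAY_EXAMPLE = {
    "set_id": "mmu05132",
    "description": "Salmonella infection",
    "k": 15,
    "n": 170,
    "K": 253,
    "N": 8900,
    "published_pvalue": 9.57e-05,
}


def lps_macrophage_relationships() -> pd.DataFrame:
    """The eleven-relationship mmu-miR-146a-5p worked example as a DataFrame."""
    return pd.read_csv(io.StringIO(_LPS_TSV), sep="\t")
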