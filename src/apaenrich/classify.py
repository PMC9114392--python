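"""Four-way classification of multi-UTR genes.

Each filtered multi-UTR gene is placed into exactly one of five buckets
based on its gene-level expression change and the behaviour of its short
3'UTR (SU) isoform:

* gene-up criterion: gene fold change > 2 (log2FC > 1) and gene q < 0.10;
* SU-up criterion: SU TPM fold change > 2 and dPAU > 0.1 and usage p < 0.05
  and usage q < 0.10;
* control (not-SU-up) criterion: SU fold change < 2 and dPAU < 0.1 and
  usage p > 0.05.

Gene-up genes are subdivided into ``GENE_AND_SU_UP`` (SU-up criterion
holds) and ``GENE_UP`` (its complement): a purely transcriptional increase
raises SU and LU proportionally, so SU fold change alone cannot
disqualify a gene-up gene.  Among genes that are not gene-up, ``SU_UP``
requires the SU-up criterion and the control group ``GENE_NOT_UP``
requires the strict control criterion; genes in between — e.g. a slight SU
upregulation that is neither significant nor clearly absent — are
``UNCLASSIFIED`` and excluded from group comparisons.  All inequalities
are strict, so boundary values (FC exactly 2, dPAU exactly 0.1) fall into
``UNCLASSIFIED``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENE_NOT_UP = "GENE_NOT_UP"
GENE_UP = "GENE_UP"
SU_UP = "SU_UP"
GENE_AND_SU_UP = "GENE_AND_SU_UP"
UNCLASSIFIED = "UNCLASSIFIED"

CATEGORIES = (GENE_NOT_UP, GENE_UP, SU_UP, GENE_AND_SU_UP, UNCLASSIFIED)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds; the defaults are the printed analysis values."""

    gene_fc: float = 2.0
    gene_fdr: float = 0.10
    su_fc: float = 2.0
    dpau: float = 0.10
    usage_p: float = 0.05
    usage_fdr: float = 0.10


def classify_genes(
    gene_de: pd.DataFrame,
    usage: pd.DataFrame,
    dpau: pd.Series,
    su_fc: pd.Series,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Assign every gene in ``gene_de``'s index to one category.

    Parameters
    ----------
    gene_de : frame with columns ``log2fc`` and ``q_value`` (gene NB test).
    usage : frame with columns ``p_value`` and ``q_value`` (usage test).
    dpau : per-gene dPAU (condition-B mean PAU minus condition-A mean PAU).
    su_fc : per-gene SU TPM fold change on the normalized scale.

    Returns a frame indexed by gene with ``category`` plus the supporting
    quantities that determined it.
    """
    genes = gene_de.index
    missing = []
    for name, obj in (("usage", usage), ("dpau", dpau), ("su_fc", su_fc)):
        absent = genes.difference(obj.index)
        if len(absent):
            missing.append(f"{name}: {sorted(absent.tolist())}")
    if missing:
        raise KeyError(
            "inputs do not cover the classified gene set; missing from "
            + "; ".join(missing)
        )
    t = thresholds
    lfc = gene_de["log2fc"].to_numpy(float)
    gq = gene_de["q_value"].to_numpy(float)
    up = usage.reindex(genes)
    upv = up["p_value"].to_numpy(float)
    uq = up["q_value"].to_numpy(float)
    d = dpau.reindex(genes).to_numpy(float)
    fc = su_fc.reindex(genes).to_numpy(float)

    gene_up = (lfc > np.log2(t.gene_fc)) & (gq < t.gene_fdr)
    su_up = (fc > t.su_fc) & (d > t.dpau) & (upv < t.usage_p) & (uq < t.usage_fdr)
    control = (fc < t.su_fc) & (d < t.dpau) & (upv > t.usage_p)
    # NaN comparisons are False, so genes with NA usage or PAU fall through
    # to UNCLASSIFIED unless the control rule is decidable

    category = np.full(len(genes), UNCLASSIFIED, dtype=object)
    category[gene_up & su_up] = GENE_AND_SU_UP
    category[gene_up & ~su_up] = GENE_UP
    category[~gene_up & su_up] = SU_UP
    category[~gene_up & ~su_up & control] = GENE_NOT_UP

    return pd.DataFrame(
        {
            "category": category,
            "gene_log2fc": lfc,
            "gene_q": gq,
            "su_fc": fc,
            "dpau": d,
            "usage_p": upv,
            "usage_q": uq,
        },
        index=genes,
    )
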