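"""Isoform-level quantification and normalization.

Houses the central in-memory container (:class:`IsoformTable`) plus the
operations that turn raw isoform counts/TPM into the quantities the rest of
the pipeline consumes: median-of-ratios size factors, rescaled TPM, poly(A)
site usage (PAU, equivalently the short-3'UTR index SUI), dPAU between two
conditions, condition-level expression fold changes, and the multi-UTR gene
filter.

Conventions
-----------
* A multi-UTR gene carries exactly one short-3'UTR (``SU``) and one
  long-3'UTR (``LU``) isoform; a single-UTR gene carries one ``SINGLE``
  isoform.
* PAU is the fraction of a gene's 3'UTR isoform expression attributed to the
  SU isoform, ``SU / (SU + LU)``, on the [0, 1] scale.  dPAU is
  ``PAU(alt) - PAU(ref)`` where by convention the alternative condition is
  the one in which short isoforms may be upregulated (erythroblast-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SU = "SU"
LU = "LU"
SINGLE = "SINGLE"

ISOFORM_CLASSES = (SU, LU, SINGLE)


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclass
class IsoformTable:
    """Per-isoform counts and TPM across replicated samples of two conditions.

    Attributes
    ----------
    isoforms : pd.DataFrame
        Indexed by ``isoform_id`` with columns ``gene_id`` and
        ``isoform_class`` (one of ``SU``/``LU``/``SINGLE``).
    counts : pd.DataFrame
        Non-negative integer counts, index ``isoform_id``, one column per
        sample.
    tpm : pd.DataFrame
        Non-negative TPM values, same shape as ``counts``.
    samples : pd.DataFrame
        Indexed by sample id with columns ``condition`` (``"A"``/``"B"``)
        and ``replicate`` (int).
    """

    isoforms: pd.DataFrame
    counts: pd.DataFrame
    tpm: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "IsoformTable":
        iso = self.isoforms
        for col in ("gene_id", "isoform_class"):
            if col not in iso.columns:
                raise ValidationError(f"isoforms table missing column {col!r}")
        if iso.index.duplicated().any():
            dups = iso.index[iso.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate isoform ids: {dups}")
        bad = set(iso["isoform_class"]) - set(ISOFORM_CLASSES)
        if bad:
            raise ValidationError(f"unknown isoform classes: {sorted(bad)}")
        for name, frame in (("counts", self.counts), ("tpm", self.tpm)):
            if not frame.index.equals(iso.index):
                raise ValidationError(f"{name} index does not match isoforms")
            if (frame.to_numpy() < 0).any():
                raise ValidationError(f"negative values in {name}")
        counts = self.counts.to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers")
        if not self.counts.columns.equals(self.samples.index):
            raise ValidationError("count columns do not match sample metadata")
        conds = set(self.samples["condition"])
        if not conds <= {"A", "B"}:
            raise ValidationError(f"conditions must be A/B, got {sorted(conds)}")
        # one SU + one LU per multi-UTR gene, one isoform per single-UTR gene
        cls = iso.groupby("gene_id")["isoform_class"].apply(tuple)
        for gene, classes in cls.items():
            c = sorted(classes)
            if c not in (["SINGLE"], ["LU", "SU"]):
                raise ValidationError(
                    f"gene {gene!r} has invalid isoform composition {c}"
                )
        return self

    @property
    def multi_utr_genes(self) -> pd.Index:
        iso = self.isoforms
        return pd.Index(
            sorted(iso.loc[iso["isoform_class"] == SU, "gene_id"].unique())
        )

    @property
    def single_utr_genes(self) -> pd.Index:
        iso = self.isoforms
        return pd.Index(
            sorted(iso.loc[iso["isoform_class"] == SINGLE, "gene_id"].unique())
        )

    def gene_counts(self) -> pd.DataFrame:
        """Gene x sample matrix of summed isoform counts."""
        return self.counts.groupby(self.isoforms["gene_id"]).sum()

    def gene_tpm(self) -> pd.DataFrame:
        return self.tpm.groupby(self.isoforms["gene_id"]).sum()

    def class_matrix(self, isoform_class: str, values: str = "tpm") -> pd.DataFrame:
        """Gene x sample matrix for one isoform class (``values``: tpm|counts)."""
        mat = self.tpm if values == "tpm" else self.counts
        mask = self.isoforms["isoform_class"] == isoform_class
        sub = mat.loc[mask]
        sub = sub.set_axis(self.isoforms.loc[mask, "gene_id"], axis=0)
        return sub.sort_index()

    def samples_of(self, condition: str) -> list:
        return self.samples.index[self.samples["condition"] == condition].tolist()


@dataclass
class PauTable:
    """Per-sample and per-condition poly(A) site usage for multi-UTR genes.

    ``per_sample`` is a gene x sample frame of PAU values (NaN where
    SU + LU expression is zero); ``summary`` has columns ``pau_A``,
    ``pau_B`` (condition means) and ``dpau`` (= pau_B - pau_A).
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    basis: str = "tpm_norm"

    @property
    def dpau(self) -> pd.Series:
        return self.summary["dpau"]


def compute_size_factors(gene_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq approach).

    For each sample j, the factor is the median over genes of
    ``count_gj / geomean_g`` where the geometric mean reference is taken over
    genes with strictly positive counts in every sample.
    """
    mat = np.asarray(gene_counts, dtype=float)
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise ValidationError("gene_counts must be a non-empty gene x sample matrix")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; "
            "pseudo-reference fallback is disabled"
        )
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=gene_counts.columns, name="size_factor")


def rescale_tpm(tpm: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's expression column by its size factor."""
    factors = pd.Series(size_factors)
    if not set(tpm.columns) == set(factors.index):
        raise ValidationError("size factors do not match expression columns")
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    return tpm / factors.reindex(tpm.columns)


def condition_mean_fold_change(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    ref: str = "A",
    alt: str = "B",
    pseudocount: float = 0.01,
) -> pd.Series:
    """Fold change of condition-mean expression, alt over ref.

    A small pseudocount (default 0.01 TPM) is added to both condition means
    so the ratio is defined when one condition is unexpressed; it does not
    move FC > 2 decisions for expressed genes.
    """
    cols_ref = samples.index[samples["condition"] == ref]
    cols_alt = samples.index[samples["condition"] == alt]
    mean_ref = expr[cols_ref].mean(axis=1)
    mean_alt = expr[cols_alt].mean(axis=1)
    fc = (mean_alt + pseudocount) / (mean_ref + pseudocount)
    fc.name = "fold_change"
    return fc


def compute_pau(
    table: IsoformTable,
    expression_basis: str = "tpm_norm",
    size_factors: pd.Series | None = None,
    pooled: bool = False,
    ref: str = "A",
    alt: str = "B",
) -> PauTable:
    """PAU = SU / (SU + LU) per sample; condition means; dPAU = mean_B - mean_A.

    ``expression_basis`` is one of ``tpm_norm`` (size-factor-rescaled TPM,
    the default), ``tpm`` or ``counts``.  Because PAU is a within-sample
    ratio it is invariant to the per-sample rescaling; the option exists so
    pooled-count mode and audits can state their basis explicitly.

    With ``pooled=True`` the per-condition PAU is computed from summed
    expression across a condition's replicates instead of the unweighted
    mean of per-replicate PAUs.
    """
    if expression_basis not in ("tpm_norm", "tpm", "counts"):
        raise ValidationError(f"unknown expression basis {expression_basis!r}")
    values = "counts" if expression_basis == "counts" else "tpm"
    su = table.class_matrix(SU, values=values)
    lu = table.class_matrix(LU, values=values)
    if su.empty:
        raise ValidationError("no multi-UTR (SU/LU) rows present")
    if expression_basis == "tpm_norm":
        if size_factors is None:
            size_factors = compute_size_factors(table.gene_counts())
        su = rescale_tpm(su, size_factors)
        lu = rescale_tpm(lu, size_factors)
    total = su + lu
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = su / total
    per_sample = per_sample.where(total > 0)  # NaN exactly when SU + LU == 0

    cols_ref = table.samples_of(ref)
    cols_alt = table.samples_of(alt)
    if pooled:
        pau_ref = su[cols_ref].sum(axis=1) / total[cols_ref].sum(axis=1).where(
            total[cols_ref].sum(axis=1) > 0
        )
        pau_alt = su[cols_alt].sum(axis=1) / total[cols_alt].sum(axis=1).where(
            total[cols_alt].sum(axis=1) > 0
        )
    else:
        pau_ref = per_sample[cols_ref].mean(axis=1)
        pau_alt = per_sample[cols_alt].mean(axis=1)
    summary = pd.DataFrame(
        {"pau_A": pau_ref, "pau_B": pau_alt, "dpau": pau_alt - pau_ref}
    )
    return PauTable(per_sample=per_sample, summary=summary, basis=expression_basis)


# the short-3'UTR index is the same quantity under the name used for
# expression-association analyses
compute_sui = compute_pau


def filter_multi_utr(
    table: IsoformTable, min_tpm: float = 3.0, level: str = "gene"
) -> pd.Index:
    """Multi-UTR genes passing the expression filter.

    Keeps genes with more than one annotated isoform whose total TPM is at
    least ``min_tpm`` in one or more samples.  ``level="isoform"`` instead
    requires a single isoform to reach the cutoff.
    """
    if level not in ("gene", "isoform"):
        raise ValidationError(f"unknown filter level {level!r}")
    multi = table.multi_utr_genes
    if level == "gene":
        expr = table.gene_tpm().reindex(multi)
        keep = (expr >= min_tpm).any(axis=1)
    else:
        iso = table.isoforms
        is_multi = iso["gene_id"].isin(multi) & iso["isoform_class"].isin((SU, LU))
        hits = (table.tpm.loc[is_multi] >= min_tpm).any(axis=1)
        keep = hits.groupby(iso.loc[is_multi, "gene_id"]).any().reindex(multi)
    return pd.Index(sorted(keep.index[keep]))
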