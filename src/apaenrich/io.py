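"""Readers and writers for the pipeline's tab-separated tables and configs.

All tables are UTF-8 TSV with a header row; missing values are encoded as
``NA``; reals are written with 6 significant digits; gene-id matching is
case-sensitive exact string match.

The isoform table is a single wide TSV with columns ``gene_id``,
``isoform_id``, ``isoform_class`` followed by ``count_<sample>`` and
``tpm_<sample>`` columns, with the condition encoded in the sample name
(``A1``, ``A2``, ..., ``B1``, ...).  Quantifier-style inputs that report
PAU in percent are converted to fractions with ``pau_scale="percent"``;
short-isoform rows may be identified either by the ``isoform_class`` column
or by an isoform id ending in ``_P``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quantify import SU, LU, SINGLE, IsoformTable, ValidationError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a DataFrame as TSV with the package-wide formatting rules."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT, index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_isoform_table(table: IsoformTable, path) -> None:
    counts = table.counts.add_prefix("count_")
    tpm = table.tpm.add_prefix("tpm_")
    out = pd.concat([table.isoforms, counts, tpm], axis=1)
    out.index.name = "isoform_id"
    write_table(out.reset_index().set_index("gene_id").reset_index(), path, index=False)


def _sample_metadata(sample_ids) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        m = re.fullmatch(r"([AB])(\d+)", sid)
        if not m:
            raise ValidationError(
                f"sample column {sid!r} does not encode a condition "
                "(expected e.g. A1, B2)"
            )
        rows.append((sid, m.group(1), int(m.group(2))))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")


def read_isoform_table(path, pau_scale: str = "fraction") -> IsoformTable:
    """Read and validate an isoform count/TPM table.

    ``pau_scale`` only affects optional PAU columns carried by quantifier
    exports (``pau_<sample>``), which native tools report in percent; counts
    and TPM are scale-free.  Rows whose ``isoform_class`` is missing are
    classified SU when the isoform id ends in ``_P``, LU otherwise (SINGLE
    when the gene has a single row).
    """
    if pau_scale not in ("fraction", "percent"):
        raise ValidationError(f"unknown pau_scale {pau_scale!r}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("gene_id", "isoform_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["gene_id", "isoform_id"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # 1-based, after the header
        raise ValidationError(f"{path}: duplicate (gene_id, isoform_id) at lines {lines}")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    if not count_cols or not tpm_cols:
        raise ValidationError(f"{path}: need count_<sample> and tpm_<sample> columns")
    sample_ids = [c[len("count_"):] for c in count_cols]
    if sorted(sample_ids) != sorted(c[len("tpm_"):] for c in tpm_cols):
        raise ValidationError(f"{path}: count and tpm sample sets differ")

    counts = df[count_cols].copy()
    for col in count_cols:
        vals = pd.to_numeric(counts[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValidationError(
                f"{path}: non-integer counts in column {col!r} at lines {lines}"
            )
        counts[col] = vals.astype(np.int64)
    counts.columns = sample_ids
    tpm = df[[f"tpm_{s}" for s in sample_ids]].astype(float)
    tpm.columns = sample_ids

    if "isoform_class" in df.columns:
        classes = df["isoform_class"].to_numpy()
    else:
        per_gene = df.groupby("gene_id")["isoform_id"].transform("count")
        classes = np.where(
            per_gene == 1,
            SINGLE,
            np.where(df["isoform_id"].str.endswith("_P"), SU, LU),
        )
    isoforms = pd.DataFrame(
        {"gene_id": df["gene_id"].to_numpy(), "isoform_class": classes},
        index=pd.Index(df["isoform_id"], name="isoform_id"),
    )
    counts.index = isoforms.index
    tpm.index = isoforms.index
    table = IsoformTable(
        isoforms=isoforms,
        counts=counts,
        tpm=tpm,
        samples=_sample_metadata(sample_ids),
    )
    return table.validate()


def write_enhancer_map(enhancers: pd.Series, path) -> None:
    df = pd.DataFrame(
        {"gene_id": enhancers.index, "ery_plus": enhancers.astype(int).to_numpy()}
    )
    write_table(df, path, index=False)


def read_enhancer_map(path) -> pd.Series:
    """Gene -> Ery+ flag map.

    A single-column file lists Ery+ genes (all listed genes flagged True);
    a two-column file carries explicit 0/1 or true/false flags.  Unlisted
    genes default to Ery- at join time (the join logs how many).
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: enhancer map is empty")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        n = int(genes.duplicated().sum())
        logger.warning("%s: %d duplicate gene ids deduplicated", path, n)
    if df.shape[1] == 1:
        flags = pd.Series(True, index=genes.values)
    else:
        raw = df[df.columns[1]].astype(str)
        bad = ~raw.isin(_TRUE | _FALSE)
        if bad.any():
            vals = sorted(raw[bad].unique().tolist())
            raise ValidationError(
                f"{path}: enhancer flags must be 0/1/true/false, got {vals}"
            )
        flags = pd.Series(raw.isin(_TRUE).to_numpy(), index=genes.values)
    flags = flags[~flags.index.duplicated(keep="first")]
    flags.index.name = "gene_id"
    flags.name = "ery_plus"
    return flags


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data


def dump_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
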