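"""End-to-end orchestration: filter -> normalize -> PAU -> differential ->
classify -> enrichment -> stratified resampling, with all stage tables,
a JSON run manifest, and a structured log written to the output directory.

The run is idempotent given the seed: rerunning with an identical
configuration reproduces every stage table byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CATEGORIES,
    GENE_NOT_UP,
    SU_UP,
    UNCLASSIFIED,
    Thresholds,
    classify_genes,
)
from .differential import nb_gene_test, usage_test
from .enrich import enrichment_by_category, stratified_enrichment
from .io import (
    dump_json,
    read_enhancer_map,
    read_isoform_table,
    write_table,
)
from .quantify import (
    SU,
    IsoformTable,
    compute_pau,
    compute_size_factors,
    condition_mean_fold_change,
    filter_multi_utr,
    rescale_tpm,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and flags for a full pipeline run.

    Threshold defaults are the printed analysis values: fold change 2,
    10% FDR, dPAU 0.1, usage p 0.05, minimum 3 TPM, 13 strata with upper
    bound 1.
    """

    isoform_table: str | None = None
    enhancer_map: str | None = None
    out_dir: str = "apaenrich_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_tpm: float = 3.0
    min_tpm_level: str = "gene"
    n_strata: int = 13
    strata_upper: float = 1.0
    n_repeats: int = 3
    alpha: float = 0.05
    seed: int = 0
    pseudocount: float = 0.01
    continuity_correction: bool = False
    pooled_pau: bool = False
    pau_scale: str = "fraction"
    stratified_group: str = SU_UP
    reference_category: str = GENE_NOT_UP

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        thr = data.pop("thresholds", None)
        cfg = cls(**data)
        if thr is not None:
            cfg.thresholds = Thresholds(**thr)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    size_factors: pd.Series
    pau_summary: pd.DataFrame
    gene_de: pd.DataFrame
    usage: pd.DataFrame
    categories: pd.DataFrame
    enrichment: pd.DataFrame
    stratified: object
    confusion: pd.DataFrame | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _enrichment_frame(results: dict, reference: str, n_by_cat: pd.Series) -> pd.DataFrame:
    rows = []
    for cat in sorted(set(list(results) + [reference])):
        if cat == reference:
            res = next((r for r in results.values() if r is not None), None)
            n = int(n_by_cat.get(cat, 0))
            n_plus = int(res.table[1, 0]) if res is not None else 0
            rows.append(
                (cat, n, n_plus, n_plus / n if n else np.nan,
                 np.nan, np.nan, np.nan, "reference")
            )
            continue
        res = results[cat]
        n = int(n_by_cat.get(cat, 0))
        if res is None:
            rows.append((cat, n, 0, np.nan, np.nan, np.nan, np.nan, "empty"))
        else:
            rows.append(
                (cat, n, int(res.table[0, 0]), res.frac_group, res.chi2,
                 res.p_value, res.odds_ratio, res.flag)
            )
    return pd.DataFrame(
        rows,
        columns=["category", "n", "n_ery_plus", "frac_ery_plus", "chi2",
                 "p_value", "odds_ratio", "flag"],
    ).set_index("category")


def run_pipeline(
    config: PipelineConfig,
    table: IsoformTable | None = None,
    enhancers: pd.Series | None = None,
    truth: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis and (optionally) write all stage outputs.

    ``table``/``enhancers`` may be passed in memory; otherwise they are read
    from the paths in ``config``.  If a planted-truth frame is supplied, a
    truth-vs-call confusion matrix is emitted alongside the stage tables.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
        root = logging.getLogger("apaenrich")
        root.addHandler(handler)
        root.setLevel(logging.INFO)

    try:
        if table is None:
            if config.isoform_table is None:
                raise StageError("stage 'read' failed: no isoform table provided")
            table = _stage("read")(read_isoform_table)(
                config.isoform_table, pau_scale=config.pau_scale
            )
        if enhancers is None:
            if config.enhancer_map is None:
                raise StageError("stage 'read' failed: no enhancer map provided")
            enhancers = _stage("read")(read_enhancer_map)(config.enhancer_map)

        multi = _stage("filter")(filter_multi_utr)(
            table, min_tpm=config.min_tpm, level=config.min_tpm_level
        )
        logger.info(
            "filter: %d of %d multi-UTR genes pass min_tpm=%g",
            len(multi), len(table.multi_utr_genes), config.min_tpm,
        )

        gene_counts = table.gene_counts()
        size_factors = _stage("normalize")(compute_size_factors)(gene_counts)
        tpm_norm = rescale_tpm(table.tpm, size_factors)
        logger.info("normalize: size factors %s",
                    np.array2string(size_factors.to_numpy(), precision=4))

        pau = _stage("pau")(compute_pau)(
            table, size_factors=size_factors, pooled=config.pooled_pau
        )
        pau_summary = pau.summary.reindex(multi)

        gene_de = _stage("differential")(nb_gene_test)(
            gene_counts, size_factors, table.samples["condition"].to_numpy()
        )
        su_counts = table.class_matrix(SU, values="counts")
        lu_counts = table.class_matrix("LU", values="counts")
        usage = _stage("differential")(usage_test)(
            su_counts.reindex(multi),
            lu_counts.reindex(multi),
            table.samples["condition"].to_numpy(),
        )
        logger.info(
            "differential: %d gene tests, %d usage tests (%d flagged)",
            len(gene_de), len(usage), int((usage["flag"] != "").sum()),
        )

        iso = table.isoforms
        su_tpm = tpm_norm.loc[iso["isoform_class"] == SU]
        su_tpm = su_tpm.set_axis(iso.loc[iso["isoform_class"] == SU, "gene_id"], axis=0)
        su_fc = condition_mean_fold_change(
            su_tpm.reindex(multi), table.samples, pseudocount=config.pseudocount
        )

        categories = _stage("classify")(classify_genes)(
            gene_de.reindex(multi),
            usage,
            pau_summary["dpau"],
            su_fc,
            thresholds=config.thresholds,
        )
        tally = categories["category"].value_counts().reindex(CATEGORIES, fill_value=0)
        logger.info("classify: %s", tally.to_dict())

        enr = _stage("enrich")(enrichment_by_category)(
            categories,
            enhancers,
            reference_category=config.reference_category,
            continuity=config.continuity_correction,
        )
        n_by_cat = categories["category"].value_counts()
        enrichment = _enrichment_frame(enr, config.reference_category, n_by_cat)

        stratified = _stage("stratified")(stratified_enrichment)(
            categories,
            enhancers,
            n_repeats=config.n_repeats,
            seed=config.seed,
            group=config.stratified_group,
            reference=config.reference_category,
            n_strata=config.n_strata,
            upper=config.strata_upper,
            continuity=config.continuity_correction,
        )
        fg, fr = stratified.mean_fractions()
        logger.info(
            "stratified: mean Ery+ fraction %s=%.4f vs %s=%.4f over %d repeats",
            config.stratified_group, fg, config.reference_category, fr,
            config.n_repeats,
        )

        confusion = None
        if truth is not None:
            planted = truth.loc[truth["multi_utr"], "planted_category"].reindex(multi)
            confusion = pd.crosstab(
                planted, categories["category"], dropna=False
            )
            confusion.index.name = "planted"
            confusion.columns.name = "called"

        if write:
            write_table(size_factors.to_frame(), out / "size_factors.tsv")
            write_table(pau_summary, out / "pau.tsv")
            write_table(gene_de, out / "gene_de.tsv")
            write_table(usage, out / "usage.tsv")
            write_table(categories, out / "categories.tsv")
            write_table(enrichment, out / "enrichment.tsv")
            for i, rep in enumerate(stratified.repeats):
                frame = pd.DataFrame(
                    {
                        "gene_id": rep.sampled_group + rep.sampled_reference,
                        "group": [config.stratified_group] * len(rep.sampled_group)
                        + [config.reference_category] * len(rep.sampled_reference),
                    }
                )
                write_table(frame, out / f"stratified_repeat_{i + 1}.tsv", index=False)
            strat_summary = pd.DataFrame(
                {
                    "repeat": range(1, len(stratified.repeats) + 1),
                    "frac_group": [r.frac_group for r in stratified.repeats],
                    "frac_reference": [r.frac_reference for r in stratified.repeats],
                    "chi2": [
                        r.contingency.chi2 if r.contingency else np.nan
                        for r in stratified.repeats
                    ],
                    "p_value": [
                        r.contingency.p_value if r.contingency else np.nan
                        for r in stratified.repeats
                    ],
                }
            )
            write_table(strat_summary, out / "stratified_summary.tsv", index=False)
            if confusion is not None:
                write_table(confusion, out / "confusion.tsv")
            manifest = {
                "package": "apaenrich",
                "version": __version__,
                "seed": config.seed,
                "config": _jsonable(config.to_dict()),
                "n_genes": int(len(gene_counts)),
                "n_multi_utr_filtered": int(len(multi)),
                "category_counts": {k: int(v) for k, v in tally.items()},
            }
            dump_json(manifest, out / "manifest.json")

        return PipelineResult(
            size_factors=size_factors,
            pau_summary=pau_summary,
            gene_de=gene_de,
            usage=usage,
            categories=categories,
            enrichment=enrichment,
            stratified=stratified,
            confusion=confusion,
        )
    finally:
        if write:
            logging.getLogger("apaenrich").removeHandler(handler)
            handler.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
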