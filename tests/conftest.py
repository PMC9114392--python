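import numpy as np
import pandas as pd
import pytest

import apaenrich as ap
from apaenrich.quantify import (
    compute_pau,
    compute_size_factors,
    condition_mean_fold_change,
    filter_multi_utr,
    rescale_tpm,
)
from apaenrich.differential import nb_gene_test, usage_test


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared by read-only tests."""
    cfg = ap.SimConfig(n_multi_utr_genes=400, n_single_utr_genes=80, seed=11)
    return ap.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def classified(small_dataset):
    """Full quantify -> differential -> classify chain on the small dataset."""
    return run_classification(small_dataset)


def run_classification(ds, thresholds=None):
    table = ds.table
    multi = filter_multi_utr(table)
    sf = compute_size_factors(table.gene_counts())
    cond = table.samples["condition"].to_numpy()
    gene_de = nb_gene_test(table.gene_counts(), sf, cond)
    usage = usage_test(
        table.class_matrix("SU", values="counts").reindex(multi),
        table.class_matrix("LU", values="counts").reindex(multi),
        cond,
    )
    pau = compute_pau(table, size_factors=sf)
    iso = table.isoforms
    su = rescale_tpm(table.tpm, sf).loc[iso["isoform_class"] == "SU"]
    su = su.set_axis(iso.loc[iso["isoform_class"] == "SU", "gene_id"], axis=0)
    su_fc = condition_mean_fold_change(su.reindex(multi), table.samples)
    kwargs = {} if thresholds is None else {"thresholds": thresholds}
    cats = ap.classify_genes(
        gene_de.reindex(multi), usage, pau.summary["dpau"], su_fc, **kwargs
    )
    return cats
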