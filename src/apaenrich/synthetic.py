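"""Synthetic two-condition isoform count data with known ground truth.

Emulates a replicated bulk RNA-seq contrast between a stem-like reference
condition (A, HSC-like) and a differentiated condition (B, erythroblast-like)
at the level the pipeline consumes: per-isoform counts and TPM.  Gene totals
are negative-binomial; for multi-UTR genes the total is split into the short
(SU) and long (LU) 3'UTR isoform by a beta-binomial draw whose success
probability is the condition's poly(A) site usage.  Planted effects — a
gene-level log2 fold change, a shift in SU usage, and enrichment of
enhancer association among affected genes — are recorded per gene so every
downstream stage can be audited against truth.

Reads, fragments and peak calling are out of scope: the simulation starts
where transcript quantification ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .quantify import SU, LU, SINGLE, IsoformTable


class ConfigurationError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass
class SimConfig:
    """Parameters of the simulated two-condition design.

    Defaults describe the emulated study conditions: a few thousand
    multi-UTR genes sequenced to moderate depth in triplicate, a minority of
    genes with a strong planted expression change (log2FC 1.5) or a planted
    SU-usage shift (dPAU 0.2 on a low baseline usage of 0.05, as expected
    for intrinsically weak proximal poly(A) sites), and enhancer association
    three times more likely for affected genes than the 10% background.
    """

    n_multi_utr_genes: int = 4000
    n_single_utr_genes: int = 1000
    n_replicates_per_condition: int = 3
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05  # alpha in var = mu + alpha * mu^2
    frac_gene_up: float = 0.15
    gene_log2fc: float = 1.5
    frac_su_up: float = 0.10
    pau_baseline: float = 0.05
    pau_shift: float = 0.20
    bb_overdispersion: float = 0.01  # rho of the beta-binomial SU/LU split
    enhancer_background_rate: float = 0.10
    enhancer_relative_risk: float = 3.0
    library_size_factors: tuple | None = None  # per-sample multipliers, A then B
    isoform_length_kb: float = 1.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        def fail(name, why):
            raise ConfigurationError(f"invalid SimConfig.{name}: {why}")

        for name in ("n_multi_utr_genes", "n_single_utr_genes"):
            if getattr(self, name) < 0:
                fail(name, "must be >= 0")
        if self.n_multi_utr_genes + self.n_single_utr_genes == 0:
            fail("n_multi_utr_genes", "no genes to simulate")
        if self.n_replicates_per_condition < 2:
            fail("n_replicates_per_condition", "need >= 2 replicates")
        if self.baseline_mean <= 0:
            fail("baseline_mean", "must be positive")
        if self.nb_dispersion < 0:
            fail("nb_dispersion", "must be >= 0")
        for name in ("frac_gene_up", "frac_su_up", "pau_baseline",
                     "enhancer_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                fail(name, "must be in [0, 1]")
        if not 0.0 <= self.pau_baseline + self.pau_shift <= 1.0:
            fail("pau_shift", "pau_baseline + pau_shift must be in [0, 1]")
        if not 0.0 <= self.bb_overdispersion < 1.0:
            fail("bb_overdispersion", "must be in [0, 1)")
        if self.enhancer_relative_risk < 0:
            fail("enhancer_relative_risk", "must be >= 0")
        if self.enhancer_background_rate * self.enhancer_relative_risk > 1.0:
            fail("enhancer_relative_risk",
                 "background_rate x relative_risk exceeds 1")
        n_samples = 2 * self.n_replicates_per_condition
        if self.library_size_factors is not None:
            lf = np.asarray(self.library_size_factors, dtype=float)
            if lf.shape != (n_samples,):
                fail("library_size_factors", f"need {n_samples} values")
            if (lf <= 0).any():
                fail("library_size_factors", "must be positive")
        if self.isoform_length_kb <= 0:
            fail("isoform_length_kb", "must be positive")
        return self

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


@dataclass
class SyntheticDataset:
    """An isoform table plus the per-gene planted truth record."""

    table: IsoformTable
    truth: pd.DataFrame  # indexed by gene_id
    config: SimConfig


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    # deterministic per-gene sub-stream, independent of iteration order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(gene_index,))
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with var = mu + alpha mu^2 via gamma-Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def _split_su(
    rng: np.random.Generator, totals: np.ndarray, pau: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial SU/LU split; rho = 0 degenerates to plain binomial."""
    if rho == 0:
        return rng.binomial(totals, pau)
    s = (1.0 - rho) / rho
    p = np.where(
        (pau <= 0) | (pau >= 1), pau, rng.beta(np.maximum(s * pau, 1e-12),
                                               np.maximum(s * (1 - pau), 1e-12))
    )
    return rng.binomial(totals, p)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Draw a full two-condition dataset with planted ground truth.

    Gene-level totals are negative-binomial with mean
    ``baseline_mean * 2**log2fc[condition] * library_factor``; multi-UTR
    totals are split SU/LU beta-binomially with per-condition PAU.  TPM is
    computed from counts per sample by scaling length-normalized rates to
    one million.  Deterministic given ``config.seed``: every gene draws from
    its own sub-stream keyed by gene index.
    """
    config.validate()
    n_multi, n_single = config.n_multi_utr_genes, config.n_single_utr_genes
    n_rep = config.n_replicates_per_condition
    n_samples = 2 * n_rep
    sample_ids = [f"A{r + 1}" for r in range(n_rep)] + [
        f"B{r + 1}" for r in range(n_rep)
    ]
    conditions = ["A"] * n_rep + ["B"] * n_rep
    lib = (
        np.ones(n_samples)
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )

    master = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    planted_gene_up = master.random(n_multi) < config.frac_gene_up
    planted_su_up = master.random(n_multi) < config.frac_su_up

    gene_ids, iso_ids, iso_genes, iso_classes = [], [], [], []
    rows = []
    truth_rows = []
    is_b = np.array([c == "B" for c in conditions])

    for g in range(n_multi):
        gene = f"MU{g:05d}"
        rng = _gene_rng(config.seed, g)
        lfc = config.gene_log2fc if planted_gene_up[g] else 0.0
        mean = config.baseline_mean * lib * np.where(is_b, 2.0 ** lfc, 1.0)
        totals = _nb_draw(rng, mean, config.nb_dispersion)
        pau_b = (
            config.pau_baseline + config.pau_shift
            if planted_su_up[g]
            else config.pau_baseline
        )
        pau = np.where(is_b, pau_b, config.pau_baseline)
        su = _split_su(rng, totals, pau, config.bb_overdispersion)
        lu = totals - su
        iso_ids += [f"{gene}_P", f"{gene}_D"]
        iso_genes += [gene, gene]
        iso_classes += [SU, LU]
        rows += [su, lu]
        if planted_gene_up[g] and planted_su_up[g]:
            cat = "gene_and_su_up"
        elif planted_gene_up[g]:
            cat = "gene_up"
        elif planted_su_up[g]:
            cat = "su_up"
        else:
            cat = "none"
        truth_rows.append(
            (gene, True, cat, lfc, pau_b - config.pau_baseline)
        )
        gene_ids.append(gene)

    for g in range(n_single):
        gene = f"SG{g:05d}"
        rng = _gene_rng(config.seed, n_multi + g)
        mean = config.baseline_mean * lib
        totals = _nb_draw(rng, mean, config.nb_dispersion)
        iso_ids.append(f"{gene}_1")
        iso_genes.append(gene)
        iso_classes.append(SINGLE)
        rows.append(totals)
        truth_rows.append((gene, False, "none", 0.0, 0.0))
        gene_ids.append(gene)

    counts = pd.DataFrame(
        np.vstack(rows).astype(np.int64),
        index=pd.Index(iso_ids, name="isoform_id"),
        columns=sample_ids,
    )
    isoforms = pd.DataFrame(
        {"gene_id": iso_genes, "isoform_class": iso_classes},
        index=counts.index,
    )
    # equal-length isoforms (default 1 kb): lengths cancel and TPM is the
    # per-sample count fraction scaled to 1e6
    rate = counts / config.isoform_length_kb
    colsum = rate.sum(axis=0)
    tpm = rate / colsum.replace(0, np.nan) * 1e6
    tpm = tpm.fillna(0.0)
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = IsoformTable(
        isoforms=isoforms, counts=counts, tpm=tpm, samples=samples
    ).validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "multi_utr",
            "planted_category",
            "planted_log2fc",
            "planted_dpau",
        ],
    ).set_index("gene_id")
    return SyntheticDataset(table=table, truth=truth, config=config)


def assign_enhancers(
    truth: pd.DataFrame,
    background_rate: float,
    relative_risk: float,
    seed: int,
) -> pd.Series:
    """Bernoulli enhancer-association flags, enriched among planted genes.

    Genes with any planted effect (gene-level or SU usage) are flagged with
    probability ``background_rate * relative_risk``; all others with
    ``background_rate``.  Returns a boolean Series (the enhancer map,
    True = Ery+) indexed like ``truth``.
    """
    if truth.empty:
        raise ConfigurationError("truth table is empty")
    if not 0.0 <= background_rate <= 1.0:
        raise ConfigurationError("invalid background_rate: must be in [0, 1]")
    if relative_risk < 0:
        raise ConfigurationError("invalid relative_risk: must be >= 0")
    if background_rate * relative_risk > 1.0:
        raise ConfigurationError(
            "invalid relative_risk: background_rate x relative_risk exceeds 1"
        )
    planted = truth["planted_category"] != "none"
    p = np.where(planted, background_rate * relative_risk, background_rate)
    # dedicated sub-stream: must not reuse the dataset simulation streams,
    # or flags would be correlated with the planted-effect assignment
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0x454E48,))
    )
    flags = rng.random(len(truth)) < p
    return pd.Series(flags, index=truth.index, name="ery_plus")


def simulate_decay_series(
    k: float,
    y0: float,
    timepoints,
    cv_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential decay series y(t) = y0 * e^(k t) with lognormal noise.

    ``k`` is the decay rate per hour and must be negative (growth is not
    modeled); ``cv_noise`` is the coefficient of variation of the
    multiplicative noise (mean-one lognormal).
    """
    if k >= 0:
        raise ConfigurationError("decay rate k must be negative")
    t = np.asarray(timepoints, dtype=float)
    if 0.0 not in t:
        raise ConfigurationError("timepoints must include 0")
    if cv_noise < 0:
        raise ConfigurationError("cv_noise must be >= 0")
    y = y0 * np.exp(k * t)
    if cv_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
        sigma = np.sqrt(np.log1p(cv_noise**2))
        y = y * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.shape)
    return pd.DataFrame({"t_hours": t, "abundance": y})
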