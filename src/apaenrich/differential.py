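"""Differential tests: NB Wald for gene expression, beta-binomial LRT for
SU-isoform usage, and Benjamini-Hochberg FDR.

Both tests are self-contained implementations of the simplest model that
fits the design (two conditions, a few replicates each):

* ``nb_gene_test`` models size-factor-normalized gene counts as negative
  binomial with a per-gene dispersion estimated by the method of moments
  pooled within conditions, and performs a Wald test on the log2 fold
  change.  Because the plug-in dispersion is estimated from very few
  replicates, p-values are referenced against a t distribution with
  ``n_A + n_B - 2`` degrees of freedom rather than the standard normal —
  a small-sample correction that keeps the type-I error near nominal.
* ``usage_test`` models the SU count given the SU+LU total as beta-binomial
  and performs a likelihood-ratio test of a shared usage proportion (H0)
  against per-condition proportions (H1).  The overdispersion rho is shared
  across genes (the common-dispersion approach of edgeR/DEXSeq): a single
  rho maximizing the summed per-condition profile likelihood over all
  covered genes is selected from a fixed log-spaced grid, and each gene is
  then tested at that rho, so H0 cannot absorb a real condition difference
  into a gene's own overdispersion and the statistic is non-negative by
  nestedness.  The maximizing proportion at each rho is found by a
  vectorized, bracketed Newton iteration; the log-likelihood in the
  proportion is concave at fixed rho, so the iteration is safe.
  With a handful of replicates the LRT statistic retains some inflation
  relative to its chi-square(1) limit, so a median-based genomic-control
  factor — the median statistic over genes divided by the chi-square(1)
  median, floored at 1 — rescales the statistics before computing
  p-values.  The median is robust to a minority of truly changing genes;
  the correction is skipped for small gene sets where the median itself is
  unstable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

DISPERSION_FLOOR = 1e-8
_NEWTON_MAX_ITER = 100
_NEWTON_TOL = 1e-8

DEFAULT_RHO_GRID = np.concatenate([[1e-8], np.geomspace(1e-4, 0.5, 24)])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN entries are excluded from the procedure and propagated as NaN; the
    remaining q-values are computed with m equal to the number of non-NaN
    p-values and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(m)
    res[order] = q
    out[mask] = res
    return out


def _condition_columns(conditions, ref: str, alt: str):
    cond = np.asarray(conditions)
    idx_ref = np.flatnonzero(cond == ref)
    idx_alt = np.flatnonzero(cond == alt)
    if idx_ref.size < 2 or idx_alt.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    return idx_ref, idx_alt


def nb_gene_test(
    gene_counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions,
    ref: str = "A",
    alt: str = "B",
) -> pd.DataFrame:
    """Per-gene NB Wald test of condition ``alt`` vs ``ref``.

    Returns a frame indexed by gene with columns ``log2fc``, ``p_value``,
    ``q_value``, ``test_kind`` and ``flag`` (empty, ``all_zero`` or
    ``zero_in_one_condition``).
    """
    counts = np.asarray(gene_counts, dtype=float)
    factors = np.asarray(pd.Series(size_factors).reindex(gene_counts.columns), float)
    if np.isnan(factors).any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    idx_ref, idx_alt = _condition_columns(conditions, ref, alt)
    norm = counts / factors

    x_ref, x_alt = norm[:, idx_ref], norm[:, idx_alt]
    n_ref, n_alt = x_ref.shape[1], x_alt.shape[1]
    m_ref, m_alt = x_ref.mean(axis=1), x_alt.mean(axis=1)
    v_ref, v_alt = x_ref.var(axis=1, ddof=1), x_alt.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a_ref = np.where(m_ref > 0, (v_ref - m_ref) / m_ref**2, 0.0)
        a_alt = np.where(m_alt > 0, (v_alt - m_alt) / m_alt**2, 0.0)
    alpha = ((n_ref - 1) * a_ref + (n_alt - 1) * a_alt) / (n_ref + n_alt - 2)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    all_zero = (m_ref == 0) & (m_alt == 0)
    one_zero = ((m_ref == 0) | (m_alt == 0)) & ~all_zero
    # continuity substitute of half a normalized count for a silent condition
    m_ref_eff = np.where(m_ref > 0, m_ref, 0.5 / n_ref)
    m_alt_eff = np.where(m_alt > 0, m_alt, 0.5 / n_alt)

    log2fc = np.log2(m_alt_eff / m_ref_eff)
    var_mean_ref = (m_ref_eff + alpha * m_ref_eff**2) / n_ref
    var_mean_alt = (m_alt_eff + alpha * m_alt_eff**2) / n_alt
    se = np.sqrt(var_mean_ref / m_ref_eff**2 + var_mean_alt / m_alt_eff**2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    df = n_ref + n_alt - 2
    p = 2.0 * stats.t.sf(np.abs(z), df=df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    flag = np.where(all_zero, "all_zero", np.where(one_zero, "zero_in_one_condition", ""))

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": bh_fdr(p),
            "test_kind": "gene_nb",
            "flag": flag,
        },
        index=gene_counts.index,
    )
    return out


def _bb_loglik(k, n, pi, s):
    """Beta-binomial log-likelihood (data-dependent part) summed over reps.

    k, n: (genes, reps); pi: (genes,); s = (1 - rho) / rho scalar.
    """
    a = s * pi[:, None]
    b = s * (1.0 - pi)[:, None]
    return (
        special.gammaln(k + a)
        + special.gammaln(n - k + b)
        - special.gammaln(n + s)
        - special.gammaln(a)
        - special.gammaln(b)
        + special.gammaln(s)
    ).sum(axis=1)


def _bb_fit_pi(k, n, s, eps=1e-9):
    """Maximize the beta-binomial log-likelihood over the usage proportion.

    Bracketed Newton on the (monotone decreasing) score function with
    bisection fallback; vectorized over genes.  Returns (pi_hat, loglik).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    tot_k, tot_n = k.sum(axis=1), n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(tot_n > 0, tot_k / tot_n, 0.5)
    pi = np.clip(pi, eps, 1.0 - eps)
    lo = np.full(pi.shape, eps)
    hi = np.full(pi.shape, 1.0 - eps)

    def score_and_hess(pi):
        a = s * pi[:, None]
        b = s * (1.0 - pi)[:, None]
        g = s * (
            special.digamma(k + a)
            - special.digamma(a)
            - special.digamma(n - k + b)
            + special.digamma(b)
        ).sum(axis=1)
        h = s**2 * (
            special.polygamma(1, k + a)
            - special.polygamma(1, a)
            + special.polygamma(1, n - k + b)
            - special.polygamma(1, b)
        ).sum(axis=1)
        return g, h

    gtol = _NEWTON_TOL * max(s, 1.0)  # score is proportional to s
    for _ in range(_NEWTON_MAX_ITER):
        g, h = score_and_hess(pi)
        if np.all((np.abs(g) < gtol) | (hi - lo < 1e-12)):
            break
        lo = np.where(g > 0, pi, lo)
        hi = np.where(g < 0, pi, hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(h < 0, pi - g / h, np.nan)
        inside = (step > lo) & (step < hi)
        pi = np.where(inside, step, 0.5 * (lo + hi))
    return pi, _bb_loglik(k, n, pi, s)


def usage_test(
    su_counts: pd.DataFrame,
    lu_counts: pd.DataFrame,
    conditions,
    ref: str = "A",
    alt: str = "B",
    rho_grid=None,
    genomic_control: bool = True,
    min_genes_for_gc: int = 100,
) -> pd.DataFrame:
    """Beta-binomial likelihood-ratio test of differential SU usage.

    Returns a frame indexed by gene with ``effect`` (MLE usage-proportion
    difference, alt minus ref), ``p_value``, ``q_value``, ``test_kind`` and
    ``flag``.  Genes with zero SU+LU coverage in every replicate of either
    condition get an NA result (flag ``insufficient_coverage``) and are
    excluded from the BH correction.

    ``genomic_control`` applies the median-based small-sample rescaling of
    the LR statistics (see module docstring); it only engages when at least
    ``min_genes_for_gc`` covered genes are tested, since the median over a
    handful of statistics carries no calibration information.
    """
    if not su_counts.index.equals(lu_counts.index):
        raise ValueError("SU and LU count frames must share their gene index")
    idx_ref, idx_alt = _condition_columns(conditions, ref, alt)
    k = np.asarray(su_counts, dtype=float)
    n = k + np.asarray(lu_counts, dtype=float)
    if (np.asarray(lu_counts) < 0).any() or (k < 0).any():
        raise ValueError("counts must be non-negative")
    grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, float)

    covered = (n[:, idx_ref].sum(axis=1) > 0) & (n[:, idx_alt].sum(axis=1) > 0)

    k_ref, n_ref = k[:, idx_ref], n[:, idx_ref]
    k_alt, n_alt = k[:, idx_alt], n[:, idx_alt]
    # pass 1: common overdispersion maximizing the summed H1 profile
    # likelihood over covered genes
    best_total, rho_common = -np.inf, grid[0]
    for rho in grid:
        s = (1.0 - rho) / rho
        _, lla = _bb_fit_pi(k_ref, n_ref, s)
        _, llb = _bb_fit_pi(k_alt, n_alt, s)
        total = (lla + llb)[covered].sum()
        if total > best_total:
            best_total, rho_common = total, rho
    # pass 2: per-gene LRT at the common rho
    s = (1.0 - rho_common) / rho_common
    _, ll0 = _bb_fit_pi(k, n, s)
    eff_ref, lla = _bb_fit_pi(k_ref, n_ref, s)
    eff_alt, llb = _bb_fit_pi(k_alt, n_alt, s)
    lr = np.maximum(2.0 * (lla + llb - ll0), 0.0)
    if genomic_control and covered.sum() >= min_genes_for_gc:
        lam = np.median(lr[covered]) / stats.chi2.ppf(0.5, df=1)
        lr = lr / max(lam, 1.0)
    p = stats.chi2.sf(lr, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    effect = eff_alt - eff_ref

    p = np.where(covered, p, np.nan)
    effect = np.where(covered, effect, np.nan)
    flag = np.where(covered, "", "insufficient_coverage")
    out = pd.DataFrame(
        {
            "effect": effect,
            "p_value": p,
            "q_value": bh_fdr(p),
            "test_kind": "usage_bb",
            "flag": flag,
        },
        index=su_counts.index,
    )
    return out
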