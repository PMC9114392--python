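"""Reporter-assay calculus: luciferase ratios, CPA activity, read-through,
mRNA decay and nascent-transcript fractions, and screen-hit banding.

The dual-luciferase design normalizes renilla readout by a co-transfected
firefly control (transcriptional activity).  Cleavage/polyadenylation (CPA)
activity of a test poly(A) site is the ratio of activities between a
reporter terminated by the test PAS and one terminated by the very strong
SV40 late PAS under the same promoter/enhancer context, so a value of 1
means the test PAS processes every produced transcript.  Decay series are
fit to ``y = e^(k t)`` with half-life ``ln(0.5) / k``; nascent fraction is
the 4sU-labeled share of total transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class ReporterMeasurement:
    """Replicate renilla/firefly readouts for one construct."""

    construct_id: str
    promoter: str
    pas: str
    enhancer: bool
    renilla: np.ndarray
    firefly: np.ndarray

    def __post_init__(self):
        self.renilla = np.asarray(self.renilla, dtype=float)
        self.firefly = np.asarray(self.firefly, dtype=float)
        if self.renilla.shape != self.firefly.shape:
            raise ValueError("renilla and firefly readouts must be paired")
        if (self.renilla <= 0).any():
            raise ValueError("renilla readouts must be positive")
        if (self.firefly <= 0).any():
            raise ValueError("firefly readouts must be positive")

    @property
    def context(self) -> tuple:
        return (self.promoter, self.enhancer)


@dataclass
class Activity:
    values: np.ndarray
    mean: float
    sd: float
    n: int


def transcriptional_activity(m: ReporterMeasurement) -> Activity:
    """Renilla normalized by firefly, per replicate, with mean +/- sd."""
    vals = m.renilla / m.firefly
    return Activity(
        values=vals,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n=int(vals.size),
    )


@dataclass
class CpaActivity:
    value: float
    sd: float
    test_construct: str
    sv40_construct: str


def cpa_activity(test: ReporterMeasurement, sv40: ReporterMeasurement) -> CpaActivity:
    """Test-PAS activity over SV40-PAS activity in the same promoter context.

    Uncertainty of the ratio of means is propagated by the delta method
    from the replicate standard deviations.
    """
    if test.context != sv40.context:
        raise ValueError(
            f"mismatched promoter/enhancer context: {test.context} vs {sv40.context}"
        )
    at, As = transcriptional_activity(test), transcriptional_activity(sv40)
    value = at.mean / As.mean
    var = value**2 * (
        (at.sd**2 / at.n) / at.mean**2 + (As.sd**2 / As.n) / As.mean**2
    )
    return CpaActivity(
        value=float(value),
        sd=float(math.sqrt(var)),
        test_construct=test.construct_id,
        sv40_construct=sv40.construct_id,
    )


def read_through_fraction(downstream_signal: float, upstream_signal: float) -> float:
    """Read-through transcripts downstream of the PAS over total transcripts."""
    if upstream_signal <= 0:
        raise ValueError("upstream (total transcript) signal must be positive")
    if downstream_signal < 0:
        raise ValueError("downstream signal must be >= 0")
    return downstream_signal / upstream_signal


def nascent_fraction(nascent_abundance: float, total_abundance: float) -> float:
    """4sU-labeled (nascent) transcripts over total transcripts."""
    if total_abundance <= 0:
        raise ValueError("total abundance must be positive")
    if nascent_abundance < 0:
        raise ValueError("nascent abundance must be >= 0")
    return nascent_abundance / total_abundance


def lu_fraction(lu_abundance: float, total_abundance: float) -> float:
    """Long-3'UTR isoform abundance over total gene abundance."""
    if total_abundance <= 0:
        raise ValueError("total abundance must be positive")
    if lu_abundance < 0:
        raise ValueError("LU abundance must be >= 0")
    return lu_abundance / total_abundance


@dataclass
class DecayFit:
    k: float
    half_life: float
    flag: str = ""


def fit_decay(timepoints, abundances, max_iter: int = 200) -> DecayFit:
    """Fit y = e^(k t) to a decay series normalized to t = 0.

    Nonlinear least squares initialized from a log-linear regression;
    half-life = ln(0.5) / k.  A non-negative fitted k is flagged
    ``stable`` with infinite half-life.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if (y <= 0).any():
        raise ValueError("abundances must be positive (log initialization)")
    order = np.argsort(t)
    t, y = t[order], y[order]
    y = y / y[np.argmin(t)]  # normalize to the earliest (t = 0) point
    slope = stats.linregress(t, np.log(y)).slope
    (k,), _ = optimize.curve_fit(
        lambda tt, kk: np.exp(kk * tt),
        t,
        y,
        p0=[slope],
        maxfev=max_iter * 10,
        xtol=1e-12,
        ftol=1e-10,
    )
    if k >= -1e-12:
        return DecayFit(k=float(k), half_life=math.inf, flag="stable")
    return DecayFit(k=float(k), half_life=float(math.log(0.5) / k))


def classify_screen_hit(
    cpa_kd_replicates,
    cpa_ctrl_replicates,
    alpha: float = 0.05,
    strong_delta: float = 0.30,
) -> str:
    """Band a knock-down by its effect on CPA activity.

    Welch's two-sided unequal-variance t-test at ``alpha``; a significant
    change whose absolute mean difference exceeds ``strong_delta`` is
    ``strong``, a merely significant one ``significant``, otherwise
    ``none``.
    """
    kd = np.asarray(cpa_kd_replicates, dtype=float)
    ctrl = np.asarray(cpa_ctrl_replicates, dtype=float)
    if kd.size < 3 or ctrl.size < 3:
        raise ValueError("need >= 3 replicates per group")
    p = stats.ttest_ind(kd, ctrl, equal_var=False).pvalue
    if np.isnan(p) or p >= alpha:
        return "none"
    delta = abs(kd.mean() - ctrl.mean())
    return "strong" if delta > strong_delta else "significant"
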