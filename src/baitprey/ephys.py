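"""Functional-validation statistics: IV-curve regression and pooled t-tests.

The reversal potential of the GABA-A current (E_GABA) is estimated by
ordinary least squares on peak IPSC amplitude versus holding potential: the
abscissa intercept of the fitted line is E_GABA and its slope the synaptic
conductance (reported in input units, pA/mV for pA amplitudes and mV
potentials). Group comparisons printed as mean +/- SEM with n are
reproduced with the pooled-variance (Student) two-sample t-test, which the
published degrees of freedom (n1 + n2 - 2) identify.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .model import GroupSummary, IVPoint, TTestResult, ValidationError


class NoReversalError(ValidationError):
    """The IV relation has zero slope; no reversal potential exists."""


def fit_iv_reversal(
    points: Sequence[IVPoint], use_absolute: bool = False
) -> tuple[float, float, float]:
    """OLS fit amplitude = m*V + b; returns (e_gaba, conductance, r_squared)
    with e_gaba = -b/m and conductance = m.

    Signed amplitudes are used by default; ``use_absolute`` fits |amplitude|
    instead. Requires >= 3 points over >= 2 distinct potentials.
    """
    if len(points) < 3:
        raise ValidationError("need at least 3 IV points")
    v = np.array([p.holding_potential for p in points], dtype=float)
    a = np.array([p.peak_amplitude for p in points], dtype=float)
    if use_absolute:
        a = np.abs(a)
    if np.unique(v).size < 2:
        raise ValidationError("need at least 2 distinct holding potentials")
    res = stats.linregress(v, a)
    if res.slope == 0.0:
        raise NoReversalError("zero slope: IV line never crosses the abscissa")
    e_gaba = -res.intercept / res.slope
    return float(e_gaba), float(res.slope), float(res.rvalue**2)


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Two-sided pooled (Student) t-test from (mean, SEM, n) summaries.

    sd_i = sem_i * sqrt(n_i); pooled variance
    s^2 = [(n1-1) sd1^2 + (n2-1) sd2^2] / (n1 + n2 - 2);
    t = (mean1 - mean2) / (s sqrt(1/n1 + 1/n2)), df = n1 + n2 - 2.
    Antisymmetric in its arguments: swapping groups flips t's sign only.
    """
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    t = (g1.mean - g2.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=min(p, 1.0))


def summarize_samples(x: Sequence[float]) -> GroupSummary:
    """Collapse a raw sample to the (mean, SEM, n) triple used above."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 samples")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return GroupSummary(mean=float(arr.mean()), sem=sem, n=int(arr.size))
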