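"""Phenotypic rates of change in haldanes.

A haldane is a change of one pooled phenotypic standard deviation per
generation:

    h = (mean_2 - mean_1) / (s_p * g)

with ``s_p`` the pooled SD of the two samples and ``g`` the elapsed time in
generations.  Confidence interval and two-sided p-value come from a
percentile bootstrap over individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class HaldaneEstimate:
    h: float
    s_p: float
    g: float
    ci: tuple[float, float]
    p_value: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.s_p <= 0:
            raise ValueError("s_p must be positive")
        if self.g <= 0:
            raise ValueError("g must be positive")
        lo, hi = self.ci
        if not (lo <= self.h <= hi):
            raise ValueError("ci must contain the point estimate")


def pooled_sd(sample_1: np.ndarray, sample_2: np.ndarray) -> float:
    s1 = np.asarray(sample_1, dtype=float)
    s2 = np.asarray(sample_2, dtype=float)
    n1, n2 = len(s1), len(s2)
    v1 = np.var(s1, ddof=1) if n1 > 1 else 0.0
    v2 = np.var(s2, ddof=1) if n2 > 1 else 0.0
    return math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))


def haldane_rate(sample_1, sample_2, elapsed_weeks: float,
                 generation_time_days: float, *,
                 n_boot: int = 2000, seed: int = 0,
                 ci_level: float = 0.95) -> HaldaneEstimate:
    """Rate of phenotypic change in haldanes between two trait samples.

    ``g = elapsed_weeks * 7 / generation_time_days``.  Bootstrap resamples
    individuals within each sample (percentile interval; two-sided p-value
    as twice the smaller tail probability of the bootstrap distribution
    around zero).
    """
    s1 = np.asarray(sample_1, dtype=float)
    s2 = np.asarray(sample_2, dtype=float)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if elapsed_weeks <= 0:
        raise ValueError("elapsed_weeks must be positive")
    if generation_time_days <= 0:
        raise ValueError("generation_time_days must be positive")
    sp = pooled_sd(s1, s2)
    if sp == 0:
        raise ValueError("zero pooled variance: haldane rate undefined")
    g = elapsed_weeks * 7.0 / generation_time_days
    h = (s2.mean() - s1.mean()) / (sp * g)

    rng = np.random.default_rng(seed)
    n1, n2 = len(s1), len(s2)
    b1 = s1[rng.integers(0, n1, size=(n_boot, n1))]
    b2 = s2[rng.integers(0, n2, size=(n_boot, n2))]
    v1 = b1.var(axis=1, ddof=1)
    v2 = b2.var(axis=1, ddof=1)
    sp_b = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    ok = sp_b > 0
    h_b = np.where(ok, (b2.mean(axis=1) - b1.mean(axis=1)) / np.where(ok, sp_b, 1.0) / g, 0.0)

    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(h_b, [alpha, 1.0 - alpha])
    lo = min(float(lo), h)
    hi = max(float(hi), h)
    p_lo = float(np.mean(h_b <= 0.0))
    p_hi = float(np.mean(h_b >= 0.0))
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return HaldaneEstimate(h=float(h), s_p=float(sp), g=float(g),
                           ci=(lo, hi), p_value=p, n1=n1, n2=n2)
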