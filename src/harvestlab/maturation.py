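"""Logistic maturity ogives: L50 / Lp50 extraction and group contrasts.

Fits are plain maximum-likelihood logistic regressions of maturity status
(or first-maturation events) on length.  Quantile lengths come from
inverting the fitted logit: ``L_p = (logit(p) - intercept) / slope``.
Deterministic maturation rules produce completely separated data by design,
so separation is reported as a flagged fit (infinite slope, quantiles at the
separating threshold) instead of an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class OgiveFit:
    intercept: float
    slope: float
    l50_mm: float
    l25_mm: float
    l75_mm: float
    n_obs: int
    vcov: Optional[np.ndarray] = None
    separated: bool = False
    extra_coefs: dict = field(default_factory=dict)

    def quantile_length(self, p: float) -> float:
        """Length at which the fitted maturity probability equals ``p``."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if self.separated:
            return self.l50_mm
        return (math.log(p / (1.0 - p)) - self.intercept) / self.slope

    def probability(self, length_mm: float) -> float:
        if self.separated:
            return float(length_mm >= self.l50_mm)
        return 1.0 / (1.0 + math.exp(-(self.intercept + self.slope * length_mm)))


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if y.all():
        raise ValueError(f"all records are {what}: cannot fit an ogive on one class")
    if not y.any():
        raise ValueError(f"no records are {what}: cannot fit an ogive on one class")


def _separation_threshold(lengths: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Midpoint of the separating gap if maturity is perfectly split by length."""
    lo = lengths[~y].max()   # largest immature
    hi = lengths[y].min()    # smallest mature
    if hi > lo:
        return float((lo + hi) / 2.0)
    return None


def _flagged_fit(threshold: float, n: int) -> OgiveFit:
    return OgiveFit(intercept=-math.inf, slope=math.inf,
                    l50_mm=threshold, l25_mm=threshold, l75_mm=threshold,
                    n_obs=n, vcov=None, separated=True)


def _logit_fit(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y.astype(float), X)
        try:
            return model.fit(disp=0, maxiter=100, method="newton", tol=1e-12)
        except Exception:
            return model.fit(disp=0, maxiter=500, method="lbfgs")


def fit_ogive(records: Sequence[tuple[float, bool]] | None = None,
              lengths: Optional[np.ndarray] = None,
              mature: Optional[np.ndarray] = None) -> OgiveFit:
    """ML logistic regression of being-mature status on length.

    Accepts either an iterable of ``(length_mm, mature)`` pairs or the two
    arrays separately.  Requires both maturity classes and at least two
    distinct lengths.  Complete separation yields a flagged fit whose
    quantiles all sit at the separating threshold.
    """
    if records is not None:
        arr = np.asarray([(l, bool(m)) for l, m in records], dtype=float)
        if arr.size == 0:
            raise ValueError("no records")
        lengths = arr[:, 0]
        mature = arr[:, 1].astype(bool)
    lengths = np.asarray(lengths, dtype=float)
    mature = np.asarray(mature, dtype=bool)
    if np.unique(lengths).size < 2:
        raise ValueError("need at least 2 distinct lengths")
    _check_two_classes(mature, "mature" if mature.all() else "immature")

    thr = _separation_threshold(lengths, mature)
    if thr is not None:
        return _flagged_fit(thr, len(lengths))

    X = sm.add_constant(lengths)
    try:
        res = _logit_fit(X, mature)
    except Exception:
        # quasi-separation or non-convergence: report the best threshold
        return _flagged_fit(float(np.median(lengths)), len(lengths))
    b0, b1 = res.params
    if abs(b1) > 1e3:   # numerically separated
        return _flagged_fit(float(-b0 / b1) if b1 != 0 else float(np.median(lengths)), len(lengths))

    def q(p: float) -> float:
        return (math.log(p / (1 - p)) - b0) / b1

    return OgiveFit(intercept=float(b0), slope=float(b1),
                    l50_mm=q(0.5), l25_mm=q(0.25), l75_mm=q(0.75),
                    n_obs=len(lengths), vcov=np.asarray(res.cov_params()))


def fit_becoming_mature(records: Sequence[tuple[float, float, bool]] | None = None,
                        lengths: Optional[np.ndarray] = None,
                        ages_weeks: Optional[np.ndarray] = None,
                        events: Optional[np.ndarray] = None,
                        include_age: bool = False) -> OgiveFit:
    """Logistic fit of first-maturation events on length (PMRN midpoint Lp50).

    Records must be restricted to fish immature at the start of each
    observation interval; ``events`` marks those that matured within it.
    With ``include_age`` the fit adds age as a covariate and quantiles are
    evaluated at the mean observed age.
    """
    if records is not None:
        arr = np.asarray([(l, a, bool(e)) for l, a, e in records], dtype=float)
        if arr.size == 0:
            raise ValueError("no records")
        lengths = arr[:, 0]
        ages_weeks = arr[:, 1]
        events = arr[:, 2].astype(bool)
    lengths = np.asarray(lengths, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("no maturation events in records")
    if np.unique(lengths).size < 2:
        raise ValueError("need at least 2 distinct lengths")
    _check_two_classes(events, "maturing")

    thr = _separation_threshold(lengths, events)
    if thr is not None:
        return _flagged_fit(thr, len(lengths))

    if include_age:
        if ages_weeks is None:
            raise ValueError("ages_weeks required when include_age=True")
        ages = np.asarray(ages_weeks, dtype=float)
        X = sm.add_constant(np.column_stack([lengths, ages]))
        try:
            res = _logit_fit(X, events)
        except Exception:
            return _flagged_fit(float(np.median(lengths)), len(lengths))
        b0, b1, b2 = res.params
        offset = b2 * ages.mean()
    else:
        X = sm.add_constant(lengths)
        try:
            res = _logit_fit(X, events)
        except Exception:
            return _flagged_fit(float(np.median(lengths)), len(lengths))
        b0, b1 = res.params
        offset = 0.0
    if abs(b1) > 1e3:
        return _flagged_fit(float(-(b0 + offset) / b1) if b1 != 0 else float(np.median(lengths)),
                            len(lengths))

    def q(p: float) -> float:
        return (math.log(p / (1 - p)) - b0 - offset) / b1

    return OgiveFit(intercept=float(b0 + offset), slope=float(b1),
                    l50_mm=q(0.5), l25_mm=q(0.25), l75_mm=q(0.75),
                    n_obs=len(lengths), vcov=np.asarray(res.cov_params()))


# ---------------------------------------------------------------------------
# grouped fits and odds-ratio contrasts
# ---------------------------------------------------------------------------


class GroupedOgiveFit:
    """Logistic fit of maturity on length with a categorical group term."""

    def __init__(self, result, group_col: str, levels: list[str]):
        self._result = result
        self.group_col = group_col
        self.levels = levels

    def group_coef(self, level: str) -> tuple[float, np.ndarray]:
        """(coefficient, contrast row) for ``level`` on the logit scale."""
        if level not in self.levels:
            raise KeyError(f"group {level!r} not present in fit (levels: {self.levels})")
        names = list(self._result.params.index)
        vec = np.zeros(len(names))
        name = f"C({self.group_col})[T.{level}]"
        if name in names:
            vec[names.index(name)] = 1.0
            return float(self._result.params[name]), vec
        return 0.0, vec  # reference level

    @property
    def params(self):
        return self._result.params

    @property
    def cov(self) -> np.ndarray:
        return np.asarray(self._result.cov_params())


def fit_grouped_ogive(df: pd.DataFrame, group_col: str = "group",
                      length_col: str = "length_mm", mature_col: str = "mature") -> GroupedOgiveFit:
    """Fit ``mature ~ length + C(group)`` by ML logistic regression."""
    data = df[[length_col, mature_col, group_col]].copy()
    data[mature_col] = data[mature_col].astype(float)
    levels = sorted(data[group_col].astype(str).unique().tolist())
    if len(levels) < 1:
        raise ValueError("no groups in data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.logit(f"{mature_col} ~ {length_col} + C({group_col})", data=data).fit(
            disp=0, maxiter=200, method="lbfgs")
    return GroupedOgiveFit(res, group_col, levels)


def odds_ratio_contrast(fit: GroupedOgiveFit, groups: tuple[str, str],
                        ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Odds ratio of being mature between two groups, with a Wald CI.

    Returns ``exp(beta_a - beta_b)`` for ``groups = (a, b)`` at equal length.
    """
    a, b = groups
    ca, va = fit.group_coef(a)
    cb, vb = fit.group_coef(b)
    diff = ca - cb
    contrast = va - vb
    var = float(contrast @ fit.cov @ contrast)
    se = math.sqrt(max(var, 0.0))
    from scipy.stats import norm
    zq = norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    return math.exp(diff), (math.exp(diff - zq * se), math.exp(diff + zq * se))
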