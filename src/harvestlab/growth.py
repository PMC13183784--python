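"""Biphasic growth: forward simulation and least-squares fitting.

Weight grows by a discrete weekly recursion with full allocation to soma
before maturation and a fraction ``1 / (1 + r)`` of the increment after:

    juvenile (t <  t_mature):  w <- w + c * w**alpha
    adult    (t >= t_mature):  w <- w + c * w**alpha / (1 + r)

``c`` is the size-independent energy-acquisition coefficient and ``r`` the
relative reproductive investment.  The allometric exponent ``alpha`` and the
weight-length allometry are fixed inputs, estimated separately (ordinary
least squares on the log-log scale with length standardised to 16 mm) and
never co-estimated with (c, r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares


@dataclass
class GrowthFit:
    c: float
    r: float
    alpha: float
    a_wl: float
    b_wl: float
    rss: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")


def predict_biphasic(c: float, r: float, alpha: float, t_mature: float,
                     w0: float, ages: Sequence[float],
                     t0: float = 0.0) -> np.ndarray:
    """Weights at the requested ages under the weekly biphasic recursion.

    The recursion starts at age ``t0`` with weight ``w0`` and steps in whole
    weeks; non-integer ages are linearly interpolated between weekly nodes.
    A step starting at or past ``t_mature`` uses the adult increment.
    """
    if w0 <= 0:
        raise ValueError("w0 must be positive")
    if c < 0 or r < 0:
        raise ValueError("c and r must be non-negative")
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return np.empty(0)
    if np.any(ages < t0):
        raise ValueError("ages must be >= t0")
    t_end = int(math.ceil(float(ages.max()) - t0))
    weights = np.empty(t_end + 1)
    weights[0] = w0
    w = w0
    for k in range(t_end):
        t = t0 + k
        inc = c * w ** alpha
        if t >= t_mature:
            inc /= 1.0 + r
        w = w + inc
        weights[k + 1] = w
    return np.interp(ages - t0, np.arange(t_end + 1), weights)


class _TrajectorySet:
    """Pre-indexed trajectories for fast vectorised residual evaluation.

    All fish are stepped simultaneously on per-fish weekly grids offset to
    their first observation; observed ages are linearly interpolated
    between weekly nodes (matching :func:`predict_biphasic`).
    """

    def __init__(self, groups, a_wl: float, b_wl: float):
        self.w_ref = math.exp(a_wl)
        self.b_wl = b_wl
        self.t0 = np.array([g[0][0] for g in groups])
        self.w0 = self.w_ref * (np.array([g[1][0] for g in groups]) / 16.0) ** b_wl
        self.t_mat = np.array([g[2] for g in groups])
        fish_idx, rel_age, obs_len = [], [], []
        for i, (ages, lengths, _) in enumerate(groups):
            fish_idx.extend([i] * (len(ages) - 1))
            rel_age.extend(ages[1:] - ages[0])
            obs_len.extend(lengths[1:])
        self.fish_idx = np.asarray(fish_idx)
        self.rel_age = np.asarray(rel_age, dtype=float)
        self.obs_len = np.asarray(obs_len, dtype=float)
        self.n_steps = int(math.ceil(self.rel_age.max()))
        lo = np.floor(self.rel_age).astype(int)
        self._lo = np.minimum(lo, self.n_steps - 1)
        self._frac = self.rel_age - self._lo

    def residuals(self, c: float, r: float, alpha: float) -> np.ndarray:
        n = len(self.w0)
        W = np.empty((n, self.n_steps + 1))
        W[:, 0] = self.w0
        w = self.w0.copy()
        for j in range(self.n_steps):
            inc = c * w ** alpha
            adult = (self.t0 + j) >= self.t_mat
            inc[adult] /= 1.0 + r
            w = w + inc
            W[:, j + 1] = w
        w_lo = W[self.fish_idx, self._lo]
        w_hi = W[self.fish_idx, self._lo + 1]
        w_pred = w_lo + self._frac * (w_hi - w_lo)
        pred_len = 16.0 * (w_pred / self.w_ref) ** (1.0 / self.b_wl)
        return self.obs_len - pred_len


def fit_biphasic(trajectories: pd.DataFrame, alpha: float,
                 allometry: tuple[float, float],
                 t_mature: Mapping, *,
                 id_col: str = "id", age_col: str = "age_weeks",
                 length_col: str = "length_mm",
                 c_bounds: tuple[float, float] = (1e-5, 5.0),
                 r_bounds: tuple[float, float] = (0.0, 50.0),
                 n_starts: int = 3) -> GrowthFit:
    """Nonlinear least squares for (c, r) from longitudinal length-at-age data.

    ``trajectories`` holds one row per (fish, age) observation; ``t_mature``
    maps fish id to its observed maturation age in weeks.  Each fish's curve
    is anchored at its first observation (weight via the fixed allometry) so
    residuals accrue from the second observation on.  A multi-start over a
    log-spaced (c, r) grid guards against local minima.
    """
    a_wl, b_wl = allometry
    groups = []
    n_res = 0
    any_adult = False
    for fid, sub in trajectories.groupby(id_col, sort=True):
        sub = sub.sort_values(age_col)
        ages = sub[age_col].to_numpy(dtype=float)
        lengths = sub[length_col].to_numpy(dtype=float)
        if len(ages) < 2:
            continue
        if fid not in t_mature:
            raise ValueError(f"no maturation age supplied for fish {fid!r}")
        t_mat = float(t_mature[fid])
        groups.append((ages, lengths, t_mat))
        n_res += len(ages) - 1
        if ages.max() > t_mat:
            any_adult = True
    if len(groups) < 2:
        raise ValueError("need >= 2 individuals with >= 2 observations each")
    if n_res < 4:
        raise ValueError("need >= 4 usable observations")
    if not any_adult:
        raise ValueError("no adult-phase observations: r is unidentifiable; "
                         "fit c alone on juvenile data instead")

    traj = _TrajectorySet(groups, a_wl, b_wl)

    def fun(x):
        return traj.residuals(x[0], x[1], alpha)

    c_grid = np.geomspace(max(c_bounds[0], 1e-4), min(c_bounds[1], 1.0), n_starts)
    r_grid = np.geomspace(0.05, min(r_bounds[1], 5.0), n_starts)
    best = None
    for c0 in c_grid:
        for r0 in r_grid:
            try:
                sol = least_squares(fun, x0=[c0, r0],
                                    bounds=([c_bounds[0], r_bounds[0]],
                                            [c_bounds[1], r_bounds[1]]),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("biphasic fit failed from every start")
    rss, (c_hat, r_hat) = best
    n_obs = sum(len(a) for a, _, _ in groups)
    return GrowthFit(c=float(c_hat), r=float(r_hat), alpha=alpha,
                     a_wl=a_wl, b_wl=b_wl, rss=rss, n_obs=n_obs)


def fit_weight_length(pairs: Sequence[tuple[float, float]] | None = None,
                      lengths: Optional[np.ndarray] = None,
                      weights: Optional[np.ndarray] = None,
                      ref_length_mm: float = 16.0) -> tuple[float, float, np.ndarray]:
    """OLS of log(weight) on log(length / 16): returns (a_wl, b_wl, vcov)."""
    if pairs is not None:
        arr = np.asarray(pairs, dtype=float)
        if arr.size == 0:
            raise ValueError("no pairs")
        lengths, weights = arr[:, 0], arr[:, 1]
    lengths = np.asarray(lengths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(lengths) < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(lengths <= 0) or np.any(weights <= 0):
        raise ValueError("lengths and weights must be positive")
    x = np.log(lengths / ref_length_mm)
    if np.allclose(x, x[0]):
        raise ValueError("all lengths equal: allometric exponent unidentifiable")
    X = sm.add_constant(x)
    res = sm.OLS(np.log(weights), X).fit()
    a_wl, b_wl = res.params
    return float(a_wl), float(b_wl), np.asarray(res.cov_params())
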