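"""Closed-form first-order decay: curves, half-lives, half-life intervals.

The working model throughout the package is single-phase exponential
loss, C(t) = C0 * exp(-k t) with k >= 0 in 1/h, fitted over the
initial log-linear phase of degradation.  Half-life is ln(2)/k; a
Wald confidence interval for k maps monotonically onto a half-life
interval by inverting the endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

#: Exact standard-normal 97.5 % quantile used for 95 % Wald intervals.
Z_95 = 1.959964

LN2 = math.log(2.0)


class KineticsDomainError(ValueError):
    """Input outside the domain of a kinetic formula."""


def decay_curve(c0, k, t):
    """Concentration after time t: ``c0 * exp(-k t)``.

    Accepts scalars or arrays; all inputs must be non-negative
    (k is a magnitude, the negative sign lives in the model).
    """
    c0a, ka, ta = np.asarray(c0, float), np.asarray(k, float), np.asarray(t, float)
    if np.any(c0a < 0) or np.any(ka < 0) or np.any(ta < 0):
        raise KineticsDomainError("c0, k and t must all be >= 0")
    out = c0a * np.exp(-ka * ta)
    return float(out) if out.ndim == 0 else out


def half_life(k: float) -> float:
    """Half-life ln(2)/k in hours, for k > 0 (1/h)."""
    if k <= 0:
        raise KineticsDomainError(f"half-life requires k > 0, got {k}")
    return LN2 / k


def half_life_interval(
    k: float,
    se: float,
    z: float = Z_95,
    df: Optional[int] = None,
) -> Tuple[float, float]:
    """Half-life confidence interval from a Wald interval on k.

    The k-interval (k - q*se, k + q*se) maps to the half-life interval
    ``(ln2/(k + q*se), ln2/(k - q*se))``, lower bound first, because
    half-life is strictly decreasing in k.  ``q`` is ``z`` by default;
    passing ``df`` switches to the Student-t quantile at the same
    confidence level (some published tables appear to use one or the
    other, and they differ in the second decimal).

    Raises
    ------
    KineticsDomainError
        If the k-interval crosses zero, where the Wald inversion breaks
        down; use a profile or bootstrap interval instead.
    """
    if se < 0:
        raise KineticsDomainError("se must be >= 0")
    q = z
    if df is not None:
        level = 2.0 * stats.norm.cdf(z) - 1.0
        q = float(stats.t.ppf(0.5 + level / 2.0, df))
    lo_k = k - q * se
    hi_k = k + q * se
    if lo_k <= 0:
        raise KineticsDomainError(
            f"k interval ({lo_k:.4g}, {hi_k:.4g}) crosses zero; the Wald "
            "half-life inversion is undefined — use a profile or bootstrap "
            "interval"
        )
    return (LN2 / hi_k, LN2 / lo_k)


@dataclass(frozen=True)
class DecayFit:
    """A fitted decay constant for one target, with Wald uncertainty.

    Attributes
    ----------
    k_hat : float
        Decay-rate magnitude, 1/h.
    se_k : float
        Standard error of ``k_hat``, 1/h.
    n_obs : int
        Detections used in the fit (>= 2).
    window_h : tuple
        (start, end) hours of the fitted log-linear phase.
    ci_level : float
        Nominal coverage of the reported intervals.
    """

    k_hat: float
    se_k: float
    n_obs: int
    window_h: Tuple[float, float] = (0.0, 72.0)
    ci_level: float = 0.95
    target_label: str = ""

    def __post_init__(self) -> None:
        if self.k_hat < 0:
            raise KineticsDomainError("k_hat is a magnitude and must be >= 0")
        if self.se_k < 0:
            raise KineticsDomainError("se_k must be >= 0")
        if self.n_obs < 2:
            raise KineticsDomainError("a decay fit needs n_obs >= 2")
        if not self.window_h[0] < self.window_h[1]:
            raise KineticsDomainError("window start must precede window end")

    @property
    def _z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.ci_level / 2.0))

    @property
    def k_ci(self) -> Tuple[float, float]:
        z = Z_95 if self.ci_level == 0.95 else self._z
        return (self.k_hat - z * self.se_k, self.k_hat + z * self.se_k)

    @property
    def half_life_h(self) -> float:
        return half_life(self.k_hat)

    @property
    def half_life_ci_h(self) -> Tuple[float, float]:
        z = Z_95 if self.ci_level == 0.95 else self._z
        return half_life_interval(self.k_hat, self.se_k, z=z)

    def to_dict(self) -> dict:
        d = {
            "target": self.target_label,
            "k_hat": self.k_hat,
            "se_k": self.se_k,
            "n_obs": self.n_obs,
            "window_h": list(self.window_h),
            "ci_level": self.ci_level,
        }
        if self.k_hat > 0:
            d["half_life_h"] = self.half_life_h
            try:
                d["half_life_ci_h"] = list(self.half_life_ci_h)
            except KineticsDomainError:
                d["half_life_ci_h"] = None
        return d
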