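"""Instrument strength and statistical power for two-sample MR.

The strength of a multi-variant instrument is summarised by the fraction of
exposure variance it explains,

    R^2 = sum_j 2 f_j (1 - f_j) beta_ZX_j^2

(valid when exposure betas are on a unit-variance scale), and the F statistic

    F = R^2 (n - 1 - k) / ((1 - R^2) k)

with n the exposure-study sample size and k the number of variants.  F well
above ~10 indicates weak-instrument bias is unlikely.

Power for a binary outcome follows Brion's non-centrality approximation:
with N = cases + controls, case fraction K, detectable odds ratio OR per
exposure unit and

    b   = K (OR / (1 + K (OR - 1)) - 1)
    NCP = N R^2 b^2 / (K (1 - K))

the two-sided power at level alpha is Phi(sqrt(NCP) - z_{1-alpha/2}).  (The
second-order term subtracting b^2 from the variance is omitted as
negligible.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .summary_io import HarmonisedVariant

__all__ = [
    "InstrumentStrength",
    "PowerParams",
    "f_statistic",
    "variance_explained",
    "instrument_strength",
    "mr_power_binary",
]


@dataclass(frozen=True)
class InstrumentStrength:
    """Summary of a genetic instrument's association with its exposure."""

    r_squared: float
    f_statistic: float
    n: int
    k: int


@dataclass(frozen=True)
class PowerParams:
    """Design of a two-sample MR power calculation for a binary outcome."""

    n_cases: int
    n_controls: int
    r_squared: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not 0.0 <= self.r_squared < 1.0:
            raise ValueError("r_squared must be in [0, 1)")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def f_statistic(r_squared: float, n: int, k: int) -> float:
    """F = R^2 (n - 1 - k) / ((1 - R^2) k)."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("r_squared must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return r_squared * (n - 1 - k) / ((1.0 - r_squared) * k)


def variance_explained(variants: Iterable[HarmonisedVariant]) -> float:
    """Exposure variance explained: sum of 2 f (1 - f) beta_zx^2.

    Assumes exposure betas on an (approximately) unit-variance scale and
    independent variants.  Clipped to [0, 1).
    """
    variants = list(variants)
    missing = [v.variant_id for v in variants if v.eaf_exposure is None]
    if missing:
        raise ValueError(f"effect-allele frequency missing for: {missing}")
    total = sum(
        2.0 * v.eaf_exposure * (1.0 - v.eaf_exposure) * v.beta_zx**2 for v in variants
    )
    return float(np.clip(total, 0.0, np.nextafter(1.0, 0.0)))


def instrument_strength(
    variants: Iterable[HarmonisedVariant], n: int
) -> InstrumentStrength:
    """R^2 and F statistic for a panel of harmonised variants."""
    variants = list(variants)
    r2 = variance_explained(variants)
    k = len(variants)
    return InstrumentStrength(r_squared=r2, f_statistic=f_statistic(r2, n, k), n=n, k=k)


def mr_power_binary(params: PowerParams) -> float:
    """Power of a two-sample MR test with a binary outcome (Brion).

    Returns the power as a fraction in (0, 1).  At ``odds_ratio = 1`` the
    approximation returns Phi(-z_{1-alpha/2}) = alpha/2, not alpha.
    """
    n = params.n_cases + params.n_controls
    k_frac = params.n_cases / n
    orr = params.odds_ratio
    b = k_frac * (orr / (1.0 + k_frac * (orr - 1.0)) - 1.0)
    ncp = n * params.r_squared * b**2 / (k_frac * (1.0 - k_frac))
    z_crit = stats.norm.ppf(1.0 - params.alpha / 2.0)
    return float(stats.norm.cdf(np.sqrt(ncp) - z_crit))
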