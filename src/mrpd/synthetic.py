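"""Synthetic two-sample summary statistics with known ground truth.

For estimator validation: variant-exposure effects beta_ZX_j are drawn from a
configurable range, and variant-outcome effects are generated under a linear
causal model with optional horizontal pleiotropy,

    beta_ZY_j = theta * beta_ZX_j + alpha_j + e_j,   e_j ~ N(0, se_zy_level^2)

where the pleiotropic effects alpha_j are zero (``none``), centred on zero
(``balanced``) or mean-shifted (``directional``), and are always drawn
independently of beta_ZX_j so the InSIDE condition holds by construction.
Reported outcome SEs equal the noise level, so with no pleiotropy Cochran's
Q is calibrated (Q/df has mean ~1).

Exposure SEs are simulated from a nominal exposure sample size but, matching
the first-order Wald estimator used throughout the package, are ignored by
the estimators; recovery tests are internally consistent with that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .summary_io import HarmonisedVariant

__all__ = ["SyntheticTruth", "generate_two_sample"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of a synthetic two-sample dataset.

    ``pleiotropy_scale`` is the standard deviation of the per-variant
    pleiotropic effect under ``balanced`` mode and its mean under
    ``directional`` mode (sd then ``pleiotropy_scale / 2``).
    """

    theta: float = 0.0
    k: int = 77
    beta_zx_range: tuple[float, float] = (0.015, 0.081)
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.0
    se_zy_level: float = 0.018
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_exposure: int = 339_224
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_scale < 0 or self.se_zy_level < 0:
            raise ValueError("scales must be >= 0")


def generate_two_sample(
    truth: SyntheticTruth,
) -> tuple[list[HarmonisedVariant], SyntheticTruth]:
    """Draw one synthetic instrument panel; deterministic given ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    k = truth.k
    bx = rng.uniform(*truth.beta_zx_range, size=k)
    eaf = rng.uniform(*truth.eaf_range, size=k)
    # Nominal GWAS standard error for a unit-variance trait.
    se_zx = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * truth.n_exposure)

    if truth.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif truth.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, truth.pleiotropy_scale, size=k)
    else:  # directional: mean-shifted, still independent of bx (InSIDE)
        alpha = rng.normal(truth.pleiotropy_scale, truth.pleiotropy_scale / 2.0, size=k)

    by = truth.theta * bx + alpha + rng.normal(0.0, truth.se_zy_level, size=k)
    se_zy = np.full(k, truth.se_zy_level)

    variants = [
        HarmonisedVariant(
            variant_id=f"sim{j:04d}",
            beta_zx=float(bx[j]),
            se_zx=float(se_zx[j]),
            beta_zy=float(by[j]),
            se_zy=float(se_zy[j]),
            eaf_exposure=float(eaf[j]),
            eaf_outcome=float(eaf[j]),
        )
        for j in range(k)
    ]
    return variants, truth
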