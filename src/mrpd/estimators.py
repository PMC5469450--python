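"""Two-sample Mendelian randomisation estimators.

Per-variant causal effects are Wald ratios, the variant-outcome effect
divided by the variant-exposure effect::

    beta_IV_j = beta_ZY_j / beta_ZX_j,   se_j = se_ZY_j / |beta_ZX_j|

(first-order standard error: uncertainty in the variant-exposure effect is
ignored).  The inverse-variance weighted (IVW) estimate pools the ratios with
weights ``w_j = (beta_ZX_j / se_ZY_j)^2``, which is algebraically the slope of
a weighted regression of beta_ZY on beta_ZX constrained through the origin.
MR-Egger regression frees the intercept: the slope remains a causal estimate
under the InSIDE assumption while the intercept estimates average directional
pleiotropy.

Heterogeneity among ratios is summarised by Cochran's Q (with k-1 degrees of
freedom) and ``I^2 = max(0, (Q - df)/Q)``.  Standard errors follow either a
fixed-effect model or, by default, a multiplicative random-effects model in
which the fixed-effect SE is inflated by ``max(1, sqrt(Q/df))``.

The estimators are scikit-learn compatible regressors: ``fit(X, y,
sample_weight)`` takes the exposure betas as a single-column design matrix,
the outcome betas as the response and ``1/se_ZY^2`` as weights.  The
module-level functions :func:`ivw`, :func:`mr_egger`, :func:`leave_one_out`
and :func:`funnel_data` wrap them for lists of harmonised variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .summary_io import HarmonisedVariant

__all__ = [
    "WaldEstimate",
    "MRResult",
    "IVWRegression",
    "EggerRegression",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "leave_one_out",
    "funnel_data",
]


@dataclass(frozen=True)
class WaldEstimate:
    """Single-variant causal estimate (log odds ratio per exposure unit)."""

    variant_id: str
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    or_scale: float


@dataclass(frozen=True)
class MRResult:
    """A pooled causal estimate on the log-odds scale, plus diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    odds_ratio: float
    n_variants: int
    q_statistic: float | None = None
    q_df: int | None = None
    i_squared: float | None = None
    q_p_value: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci_low: float | None = None
    intercept_ci_high: float | None = None
    intercept_p: float | None = None


def wald_ratio(v: HarmonisedVariant, ci_level: float = 0.95) -> WaldEstimate:
    """Wald ratio for one variant: ``beta_zy / beta_zx``.

    The standard error is first-order, ``se_zy / |beta_zx|``; uncertainty in
    the variant-exposure association is ignored.
    """
    if v.beta_zx == 0:
        raise ZeroDivisionError(
            f"{v.variant_id}: Wald ratio undefined for beta_zx = 0"
        )
    ratio = v.beta_zy / v.beta_zx
    se = v.se_zy / abs(v.beta_zx)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return WaldEstimate(
        variant_id=v.variant_id,
        ratio=ratio,
        se=se,
        ci_low=ratio - z * se,
        ci_high=ratio + z * se,
        or_scale=float(np.exp(ratio)),
    )


def _validate_xyw(X, y, sample_weight):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("design must be a single column of exposure betas")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    if X.shape != y.shape:
        raise ValueError("X and y have mismatched lengths")
    if sample_weight is None:
        w = np.ones_like(X)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != X.shape:
            raise ValueError("sample_weight has mismatched length")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(w)):
        raise ValueError("non-finite values in input")
    return X, y, w


class IVWRegression(RegressorMixin, BaseEstimator):
    """Inverse-variance weighted causal estimate (origin-constrained WLS).

    Parameters
    ----------
    se_model : {"multiplicative", "fixed"}
        Standard-error model.  ``"fixed"`` uses the fixed-effect
        meta-analysis SE; ``"multiplicative"`` (default) inflates it by
        ``max(1, sqrt(Q/df))``.
    ci_level : float
        Two-sided confidence level for the reported interval.

    Attributes
    ----------
    beta_ : float
        Pooled causal estimate (log odds ratio per exposure unit).
    se_, ci_low_, ci_high_, p_value_, odds_ratio_ : float
        Inference at ``ci_level`` (normal reference, two-sided p).
    q_statistic_, q_df_, i_squared_, q_p_value_ : float
        Cochran heterogeneity summaries across Wald ratios.
    scale_ : float
        The multiplier applied to the fixed-effect SE (1 under "fixed").
    """

    def __init__(self, se_model: str = "multiplicative", ci_level: float = 0.95):
        self.se_model = se_model
        self.ci_level = ci_level

    def fit(self, X, y, sample_weight=None):
        if self.se_model not in ("multiplicative", "fixed"):
            raise ValueError(f"unknown se_model {self.se_model!r}")
        bx, by, w_y = _validate_xyw(X, y, sample_weight)
        k = bx.size
        if k < 2:
            raise ValueError(
                "IVW pooling needs >= 2 variants; use wald_ratio for a single variant"
            )
        if np.any(bx == 0):
            raise ValueError("beta_zx = 0: Wald ratio undefined for some variant")

        # w_y = 1/se_zy^2; ratio weights w_j = (beta_zx/se_zy)^2.
        w = w_y * bx**2
        ratios = by / bx
        beta = float(np.sum(w * ratios) / np.sum(w))
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = k - 1
        se_fixed = float(np.sum(w) ** -0.5)
        scale = 1.0 if self.se_model == "fixed" else max(1.0, np.sqrt(q / df))
        se = se_fixed * scale

        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        self.n_variants_ = k
        self.beta_ = beta
        self.coef_ = np.array([beta])
        self.se_fixed_ = se_fixed
        self.scale_ = float(scale)
        self.se_ = float(se)
        self.ci_low_ = beta - z * se
        self.ci_high_ = beta + z * se
        self.p_value_ = float(2 * stats.norm.sf(abs(beta) / se))
        self.odds_ratio_ = float(np.exp(beta))
        self.q_statistic_ = q
        self.q_df_ = df
        self.i_squared_ = float(max(0.0, (q - df) / q)) if q > 0 else 0.0
        self.q_p_value_ = float(stats.chi2.sf(q, df))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return X * self.beta_

    def result_(self) -> MRResult:
        """The fit as an :class:`MRResult` record."""
        tag = "ivw_fixed" if self.se_model == "fixed" else "ivw_multiplicative"
        return MRResult(
            method=tag,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            odds_ratio=self.odds_ratio_,
            n_variants=self.n_variants_,
            q_statistic=self.q_statistic_,
            q_df=self.q_df_,
            i_squared=self.i_squared_,
            q_p_value=self.q_p_value_,
        )


class EggerRegression(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression of outcome on exposure betas, free intercept.

    Variants are re-oriented so every exposure beta is positive before the
    fit (flipping both betas of a variant leaves its Wald ratio unchanged but
    gives the intercept a consistent meaning).  The slope estimates the
    causal effect under InSIDE; the intercept estimates average directional
    pleiotropy (log-odds per allele).

    Parameters as :class:`IVWRegression`, plus ``p_reference``
    ({"normal", "t"}): reference distribution for slope and intercept
    p-values (t uses k-2 degrees of freedom).
    """

    def __init__(
        self,
        se_model: str = "multiplicative",
        ci_level: float = 0.95,
        p_reference: str = "normal",
    ):
        self.se_model = se_model
        self.ci_level = ci_level
        self.p_reference = p_reference

    def fit(self, X, y, sample_weight=None):
        if self.se_model not in ("multiplicative", "fixed"):
            raise ValueError(f"unknown se_model {self.se_model!r}")
        if self.p_reference not in ("normal", "t"):
            raise ValueError(f"unknown p_reference {self.p_reference!r}")
        bx, by, w = _validate_xyw(X, y, sample_weight)
        k = bx.size
        if k < 3:
            raise ValueError("MR-Egger needs >= 3 variants")
        if np.any(bx == 0):
            raise ValueError("beta_zx = 0: orientation undefined for some variant")

        flip = np.sign(bx)
        bx = bx * flip
        by = by * flip
        if np.ptp(bx) == 0:
            raise ValueError(
                "all exposure betas identical after orientation: design is collinear"
            )

        Xd = np.column_stack([np.ones(k), bx])
        xtw = Xd.T * w
        xtwx = xtw @ Xd
        coef = np.linalg.solve(xtwx, xtw @ by)
        resid = by - Xd @ coef
        df = k - 2
        sigma2 = float(np.sum(w * resid**2) / df)
        scale2 = 1.0 if self.se_model == "fixed" else max(1.0, sigma2)
        cov = np.linalg.inv(xtwx) * scale2
        se_int, se_slope = np.sqrt(np.diag(cov))

        if self.p_reference == "t":
            z = stats.t.ppf(0.5 + self.ci_level / 2, df)
            pfun = lambda t: 2 * stats.t.sf(abs(t), df)  # noqa: E731
        else:
            z = stats.norm.ppf(0.5 + self.ci_level / 2)
            pfun = lambda t: 2 * stats.norm.sf(abs(t))  # noqa: E731

        self.n_variants_ = k
        self.beta_ = float(coef[1])
        self.coef_ = np.array([coef[1]])
        self.intercept_ = float(coef[0])
        self.sigma_ = float(np.sqrt(sigma2))
        self.scale_ = float(np.sqrt(scale2))
        self.se_ = float(se_slope)
        self.ci_low_ = self.beta_ - z * se_slope
        self.ci_high_ = self.beta_ + z * se_slope
        self.p_value_ = float(pfun(self.beta_ / se_slope))
        self.odds_ratio_ = float(np.exp(self.beta_))
        self.intercept_se_ = float(se_int)
        self.intercept_ci_low_ = self.intercept_ - z * se_int
        self.intercept_ci_high_ = self.intercept_ + z * se_int
        self.intercept_p_ = float(pfun(self.intercept_ / se_int))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.intercept_ + X * self.beta_

    def result_(self) -> MRResult:
        """The fit as an :class:`MRResult` record."""
        return MRResult(
            method="egger",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            odds_ratio=self.odds_ratio_,
            n_variants=self.n_variants_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_ci_low=self.intercept_ci_low_,
            intercept_ci_high=self.intercept_ci_high_,
            intercept_p=self.intercept_p_,
        )


def _arrays(variants: Sequence[HarmonisedVariant]):
    bx = np.array([v.beta_zx for v in variants], dtype=float)
    by = np.array([v.beta_zy for v in variants], dtype=float)
    sy = np.array([v.se_zy for v in variants], dtype=float)
    return bx, by, 1.0 / sy**2


def ivw(
    variants: Iterable[HarmonisedVariant],
    se_model: str = "multiplicative",
    ci_level: float = 0.95,
) -> MRResult:
    """Inverse-variance weighted pooled estimate over harmonised variants."""
    variants = list(variants)
    bx, by, w = _arrays(variants)
    est = IVWRegression(se_model=se_model, ci_level=ci_level).fit(bx, by, sample_weight=w)
    return est.result_()


def mr_egger(
    variants: Iterable[HarmonisedVariant],
    se_model: str = "multiplicative",
    ci_level: float = 0.95,
    p_reference: str = "normal",
) -> MRResult:
    """MR-Egger regression over harmonised variants."""
    variants = list(variants)
    bx, by, w = _arrays(variants)
    est = EggerRegression(
        se_model=se_model, ci_level=ci_level, p_reference=p_reference
    ).fit(bx, by, sample_weight=w)
    return est.result_()


def leave_one_out(
    variants: Sequence[HarmonisedVariant],
    se_model: str = "multiplicative",
    ci_level: float = 0.95,
) -> list[tuple[str, MRResult]]:
    """IVW re-estimated with each variant excluded in turn.

    Flags variants with disproportionate influence on the pooled estimate.
    Refuses fewer than 3 variants (leave-one-out on 2 is a single Wald
    ratio, not a pooled estimate).
    """
    variants = list(variants)
    if len(variants) < 3:
        raise ValueError("leave-one-out needs >= 3 variants")
    out = []
    for i, v in enumerate(variants):
        rest = variants[:i] + variants[i + 1:]
        out.append((v.variant_id, ivw(rest, se_model=se_model, ci_level=ci_level)))
    return out


def funnel_data(
    variants: Iterable[HarmonisedVariant],
) -> list[tuple[str, float, float]]:
    """Funnel-plot coordinates: (variant_id, Wald ratio, precision = 1/SE).

    Under balanced pleiotropy the points scatter symmetrically around the
    pooled estimate; asymmetry suggests directional pleiotropy.
    """
    pts = []
    for v in variants:
        est = wald_ratio(v)
        pts.append((v.variant_id, est.ratio, 1.0 / est.se))
    return pts
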