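"""Causal-effect estimation: Wald ratios, IVW pooling, odds-ratio scale,
Wald p-values, and the Steiger directionality test.

IVW is fixed-effect (inverse squared-SE weights); Cochran's Q is reported
when at least two instruments are pooled but never used to inflate the SE.
The Wald-ratio SE defaults to the first-order delta method se_y/|beta_x|;
the second-order form is available via ``se_order=2``.

Steiger uses the z^2/(z^2 + n - 2) pseudo-r^2 per variant on both sides;
for a binary outcome this is an approximation with the total sample size,
optionally replaced by the effective size 4/(1/n_case + 1/n_control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, UsageError

__all__ = [
    "MRResult",
    "SteigerInput",
    "wald_ratio",
    "ivw_pool",
    "to_odds_ratio",
    "wald_pvalue",
    "pvalue_from_or_ci",
    "r2_from_association",
    "steiger_test",
    "estimate_exposure",
]


@dataclass(frozen=True)
class MRResult:
    """Per-exposure causal estimate on the log-odds-per-SD scale."""

    exposure_id: str
    method: str  # "wald_ratio" iff n_iv == 1, else "ivw"
    n_iv: int
    theta: float
    se_theta: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    steiger_correct: bool
    steiger_pvalue: float
    iv_ids: tuple[str, ...]
    q_stat: float | None = None  # Cochran heterogeneity, n_iv >= 2 only


@dataclass(frozen=True)
class SteigerInput:
    """Explained-variance comparison inputs for the directionality test."""

    r2_x: float
    r2_y: float
    n_x: float
    n_y: float

    def __post_init__(self) -> None:
        for label, r2 in (("r2_x", self.r2_x), ("r2_y", self.r2_y)):
            if not (0.0 <= r2 < 1.0):
                raise DomainError(f"{label} must be in [0, 1), got {r2}")
        if self.n_x < 4 or self.n_y < 4:
            raise DomainError("sample sizes must be >= 4")


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float, se_order: int = 1
) -> tuple[float, float]:
    """Single-instrument causal estimate theta = beta_y / beta_x.

    ``se_order=1`` gives the first-order delta-method SE se_y/|beta_x|;
    ``se_order=2`` adds the beta_y^2 * se_x^2 / beta_x^4 term under the root.
    """
    if beta_x == 0:
        raise DomainError("beta_x = 0: Wald ratio undefined")
    if se_x <= 0 or se_y <= 0:
        raise DomainError("standard errors must be > 0")
    theta = beta_y / beta_x
    if se_order == 1:
        se_theta = se_y / abs(beta_x)
    elif se_order == 2:
        se_theta = math.sqrt(
            se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4
        )
    else:
        raise DomainError("se_order must be 1 or 2")
    return theta, se_theta


def ivw_pool(thetas, ses) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted pooling of per-IV estimates.

    Returns (theta, se, Q); a single element returns it unchanged with Q = 0.
    """
    thetas = np.asarray(thetas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if thetas.size == 0:
        raise UsageError("ivw_pool requires at least one estimate")
    if thetas.shape != ses.shape:
        raise UsageError("thetas and ses must have equal length")
    if np.any(ses <= 0):
        raise DomainError("all SEs must be > 0")
    weights = ses**-2
    total = weights.sum()
    theta = float((weights * thetas).sum() / total)
    se = float(total**-0.5)
    q = float((weights * (thetas - theta) ** 2).sum())
    return theta, se, q


def to_odds_ratio(
    theta: float, se_theta: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Express a log-odds effect as an odds ratio with a two-sided CI."""
    if se_theta <= 0:
        raise DomainError("se_theta must be > 0")
    if not (0 < level < 1):
        raise DomainError("level must be in (0, 1)")
    z_crit = stats.norm.ppf((1 + level) / 2)
    or_ = math.exp(theta)
    return or_, math.exp(theta - z_crit * se_theta), math.exp(theta + z_crit * se_theta)


def wald_pvalue(theta: float, se_theta: float) -> float:
    """Two-sided normal p-value for theta/se; stable far in the tail."""
    if se_theta <= 0:
        raise DomainError("se_theta must be > 0")
    z = abs(theta / se_theta)
    # sf is erfc-based and already accurate for large |z|
    p = 2.0 * stats.norm.sf(z)
    return float(min(max(p, 1e-320), 1.0))


def pvalue_from_or_ci(
    or_: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Reconstruct the two-sided Wald p implied by an OR and its CI.

    The SE is recovered from the log-scale CI width, se =
    (ln ci_high - ln ci_low) / (2 z), then p = wald_pvalue(ln OR, se).
    """
    if not (0 < ci_low < or_ < ci_high):
        raise DomainError("require 0 < ci_low < or < ci_high")
    z_crit = stats.norm.ppf((1 + level) / 2)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * z_crit)
    return wald_pvalue(math.log(or_), se)


def r2_from_association(beta: float, se: float, n: float) -> float:
    """Variance explained by one variant from its summary z-score.

    r2 = z^2 / (z^2 + n - 2), the exact identity for a univariate OLS fit.
    """
    if se <= 0:
        raise DomainError("se must be > 0")
    if n <= 2:
        raise DomainError("n must be > 2")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def steiger_test(si: SteigerInput) -> tuple[bool, float]:
    """Directionality check: does the instrument explain more of the exposure?

    ``correct_direction`` is r2_x > r2_y strictly (a tie is conservatively
    not-correct). The p-value compares Fisher-z-transformed correlations
    between the two independent samples under a normal approximation.
    """
    z_x = math.atanh(math.sqrt(si.r2_x))
    z_y = math.atanh(math.sqrt(si.r2_y))
    denom = math.sqrt(1.0 / (si.n_x - 3) + 1.0 / (si.n_y - 3))
    statistic = (z_x - z_y) / denom
    p = float(min(max(2.0 * stats.norm.sf(abs(statistic)), 1e-320), 1.0))
    return si.r2_x > si.r2_y, p


def _effective_n(n_case: float | None, n_control: float | None) -> float | None:
    if not n_case or not n_control:
        return None
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def estimate_exposure(
    harmonized,
    exposure_id: str,
    se_order: int = 1,
    ci_level: float = 0.95,
    steiger_effective_n: bool = False,
) -> MRResult:
    """Full per-exposure estimate from harmonized instruments.

    Per-IV Wald ratios are pooled by fixed-effect IVW (the method tag is
    ``wald_ratio`` for a single instrument, ``ivw`` otherwise), expressed as
    an OR with CI and two-sided p. Steiger operates on per-side explained
    variance summed over instruments, with each side's own sample size.
    """
    harmonized = list(harmonized)
    if not harmonized:
        raise UsageError(f"no harmonized instruments for exposure {exposure_id!r}")

    thetas, ses = [], []
    for h in harmonized:
        t, s = wald_ratio(h.beta_x, h.se_x, h.beta_y, h.se_y, se_order=se_order)
        thetas.append(t)
        ses.append(s)
    theta, se_theta, q = ivw_pool(thetas, ses)
    n_iv = len(harmonized)
    method = "wald_ratio" if n_iv == 1 else "ivw"
    or_, ci_low, ci_high = to_odds_ratio(theta, se_theta, level=ci_level)
    p = wald_pvalue(theta, se_theta)

    n_x = float(np.mean([h.n_x for h in harmonized]))
    n_y_values = []
    for h in harmonized:
        n_eff = _effective_n(h.n_case_y, h.n_control_y) if steiger_effective_n else None
        n_y_values.append(n_eff if n_eff is not None else h.n_y)
    n_y = float(np.mean(n_y_values))
    r2_x = sum(r2_from_association(h.beta_x, h.se_x, h.n_x) for h in harmonized)
    r2_y = sum(
        r2_from_association(h.beta_y, h.se_y, n_y_i)
        for h, n_y_i in zip(harmonized, n_y_values)
    )
    # summed per-variant r2 can exceed 1 only pathologically; clamp defensively
    r2_x = min(r2_x, 1.0 - 1e-12)
    r2_y = min(r2_y, 1.0 - 1e-12)
    correct, steiger_p = steiger_test(SteigerInput(r2_x, r2_y, n_x, n_y))

    return MRResult(
        exposure_id=exposure_id,
        method=method,
        n_iv=n_iv,
        theta=theta,
        se_theta=se_theta,
        or_=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=p,
        steiger_correct=correct,
        steiger_pvalue=steiger_p,
        iv_ids=tuple(h.variant_id for h in harmonized),
        q_stat=q if n_iv >= 2 else None,
    )
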