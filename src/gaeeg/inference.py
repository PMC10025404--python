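"""Correlation statistics with null-supporting Bayes factors.

Pearson correlations carry a two-sided p-value from the exact t-transform
``t = r sqrt((n−2)/(1−r²))`` with n−2 degrees of freedom (n−2−k for a
partial coefficient controlling k covariates).

Bayes factors use the Zellner–Siow g-prior setup: the linear-model slope
has prior ``b | g, σ² ~ N(0, g σ² (xᵀx)⁻¹)``, the usual reference prior
``1/σ²`` on (a, σ²), and the mixing density

    π(g) = sqrt(n/2) / Γ(1/2) · g^{-3/2} e^{-n/(2g)} .

Integrating the parameters out gives, for a simple correlation with p
covariates in H1,

    BF10 = sqrt(n/2)/Γ(1/2) ∫₀^∞ (1+g)^{(n−p−1)/2}
           (1+(1−r²)g)^{−(n−1)/2} g^{−3/2} e^{−n/(2g)} dg ,

and for nested models (H0 with p covariates, H1 with p′ > p) the ratio of
two such integrals with coefficients of determination R₀², R₁².  BF01 is
the reciprocal, so values above 1 favor the null of no correlation.
The quadrature substitutes g = u/(1−u) to map onto (0, 1) and uses
adaptive Gauss–Kronrod integration to a relative tolerance of 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

_EPSREL = 1e-10


@dataclass
class CorrelationResult:
    r: float
    n: int
    pvalue: float
    bf01: float
    evidence_label: str
    kind: str = "simple"          # or "partial"
    p_covariates: int = 1


@dataclass
class ConditionalProbabilityResult:
    probability: float
    condition_threshold: float
    event_threshold: float
    n_condition: int
    n_joint: int


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the exact two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    return r, pvalue_from_r(r, n)


def pvalue_from_r(r: float, n: int, k_controlled: int = 0) -> float:
    """Two-sided p for a (partial) correlation coefficient."""
    df = n - 2 - k_controlled
    if df <= 0:
        raise ValueError("not enough samples for the t-transform")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _log_integrand(g: float, n: int, p: int, one_minus_r2: float) -> float:
    return (0.5 * (n - p - 1) * np.log1p(g)
            - 0.5 * (n - 1) * np.log1p(one_minus_r2 * g)
            - 1.5 * np.log(g) - n / (2.0 * g))


def _zs_integral(n: int, p: int, one_minus_r2: float,
                 epsrel: float = _EPSREL) -> float:
    """∫₀^∞ (1+g)^{(n−p−1)/2}(1+s·g)^{−(n−1)/2} g^{−3/2} e^{−n/(2g)} dg."""
    def f(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0
        g = u / (1.0 - u)
        return float(np.exp(_log_integrand(g, n, p, one_minus_r2)
                            - 2.0 * np.log1p(-u)))
    val, err = integrate.quad(f, 0.0, 1.0, epsabs=0.0, epsrel=epsrel,
                              limit=500)
    if not np.isfinite(val) or val <= 0 or (err / val) > 1e-6:
        raise RuntimeError(
            f"Bayes-factor quadrature did not converge (value={val}, "
            f"abs err={err}, n={n}, p={p}, 1-r2={one_minus_r2})")
    return val


def bf01_correlation(r: float, n: int, p_covariates: int = 1) -> float:
    """Null-supporting Bayes factor BF01 for a Pearson correlation."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    if n <= p_covariates + 2:
        raise ValueError("n must exceed p_covariates + 2")
    const = np.sqrt(n / 2.0) / np.sqrt(np.pi)    # Γ(1/2) = √π
    bf10 = const * _zs_integral(n, p_covariates, 1.0 - r * r)
    return 1.0 / bf10


def bf01_partial(r2_full: float, r2_reduced: float, n: int, p: int,
                 p_prime: int) -> float:
    """BF01 for nested regressions via the ratio of two g-prior integrals.

    H0 has p covariates and R²=r2_reduced; H1 has p′ > p covariates and
    R²=r2_full (prior normalization constants cancel in the ratio).
    """
    if not (0.0 <= r2_reduced <= r2_full < 1.0):
        raise ValueError("need 0 <= R0^2 <= R1^2 < 1")
    if p_prime < p:
        raise ValueError("p' must be >= p")
    num = _zs_integral(n, p_prime, 1.0 - r2_full)
    den = _zs_integral(n, p, 1.0 - r2_reduced)
    return den / num      # BF01 = 1 / BF10


def partial_correlation(x, y, z) -> float:
    """Partial correlation of x and y controlling for covariates z.

    ``z`` may be a vector or a (n, k) matrix; computed by correlating the
    residuals of least-squares projections onto [1, z], which reduces to
    the classical single-covariate recursion for k = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    design = np.column_stack([np.ones(len(x)), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("degenerate residuals in partial correlation")
    return float(np.clip(rx @ ry / denom, -1.0, 1.0))


def partial_correlation_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Single-covariate partial correlation from the three pairwise r's."""
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise ValueError("degenerate pairwise correlations")
    return float((r_xy - r_xz * r_yz) / denom)


def r_squared(y, design_cols) -> float:
    """Coefficient of determination of y on [1, design_cols]."""
    y = np.asarray(y, dtype=float)
    cols = [np.asarray(c, dtype=float) for c in design_cols]
    design = np.column_stack([np.ones(len(y))] + cols)
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero-variance response")
    return float(max(0.0, 1.0 - np.sum(resid**2) / tss))


def jeffreys_label(bf01: float) -> str:
    """Jeffreys evidence category for a null-supporting Bayes factor."""
    if bf01 <= 0:
        raise ValueError("bf01 must be positive")
    bands = [(1, "anecdotal"), (3, "moderate"), (10, "strong"),
             (30, "very strong"), (100, "decisive")]
    if bf01 >= 1.0:
        label = "no evidence" if bf01 == 1.0 else None
        for lo, name in reversed(bands):
            if bf01 > lo:
                label = f"{name} evidence for H0"
                break
        return label or "anecdotal evidence for H0"
    inv = 1.0 / bf01
    for lo, name in reversed(bands):
        if inv > lo:
            return f"{name} evidence for H1"
    return "anecdotal evidence for H1"


def correlate(x, y, z=None) -> CorrelationResult:
    """Full (r, p, BF01, label) bundle; partial when ``z`` is given."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if z is None:
        r, p = pearson(x, y)
        bf01 = bf01_correlation(r, n)
        return CorrelationResult(r=r, n=n, pvalue=p, bf01=bf01,
                                 evidence_label=jeffreys_label(bf01))
    zmat = np.asarray(z, dtype=float)
    if zmat.ndim == 1:
        zmat = zmat[:, None]
    k = zmat.shape[1]
    r = partial_correlation(x, y, zmat)
    p = pvalue_from_r(r, n, k_controlled=k)
    zcols = list(zmat.T)
    r2_reduced = r_squared(y, zcols)
    r2_full = r_squared(y, zcols + [x])
    bf01 = bf01_partial(max(r2_full, r2_reduced), r2_reduced, n,
                        p=k, p_prime=k + 1)
    return CorrelationResult(r=r, n=n, pvalue=p, bf01=bf01,
                             evidence_label=jeffreys_label(bf01),
                             kind="partial", p_covariates=k + 1)


def conditional_probability(features: pd.DataFrame,
                            condition: tuple[str, float],
                            event: tuple[str, float],
                            condition_is_percentile: bool = True,
                            event_is_percentile: bool = True
                            ) -> ConditionalProbabilityResult:
    """Empirical P(event col > threshold | condition col > threshold).

    Thresholds are either percentiles of the cohort distribution (default,
    e.g. the 70th percentile) or fixed values.
    """
    ccol, cval = condition
    ecol, eval_ = event
    c_thr = float(np.percentile(features[ccol], cval)) \
        if condition_is_percentile else float(cval)
    e_thr = float(np.percentile(features[ecol], eval_)) \
        if event_is_percentile else float(eval_)
    cond = features[ccol] > c_thr
    n_cond = int(cond.sum())
    if n_cond == 0:
        return ConditionalProbabilityResult(
            probability=float("nan"), condition_threshold=c_thr,
            event_threshold=e_thr, n_condition=0, n_joint=0)
    joint = cond & (features[ecol] > e_thr)
    return ConditionalProbabilityResult(
        probability=float(joint.sum() / n_cond),
        condition_threshold=c_thr, event_threshold=e_thr,
        n_condition=n_cond, n_joint=int(joint.sum()))
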