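"""Causal-effect estimators for two-sample MR.

Five methods over harmonized SNP effects (gamma_j on exposure, Gamma_j on
outcome):

* Wald ratio (k = 1): Gamma/gamma with a first-order delta SE.
* IVW: inverse-variance weighted mean of per-SNP ratios, equivalent to a
  zero-intercept weighted regression of Gamma on gamma with weights
  1/se_out^2.  Defaults to multiplicative random effects (SE scaled by
  max(1, sqrt(Q/(k-1)))); fixed effects by flag.
* MR-Egger: the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope is the causal
  estimate, after orienting pairs so gamma_j >= 0.
* Weighted median: the 50% point of the inverse-variance-weighted empirical
  distribution of ratios, robust to up to 50% invalid weight.
* Weighted mode: the peak of a weighted Gaussian kernel density over ratios,
  robust when the largest group of SNPs is valid.

Bootstrap SEs (median, mode) are parametric and seeded.  All estimates are
summarized as OR = exp(beta) with a 95% Wald CI and two-sided normal p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair

Z975 = stats.norm.ppf(0.975)  # exact 0.975 quantile, not 1.96

IVWModel = Literal["fixed", "multiplicative_random"]


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log scale with its OR summary."""

    method: str
    k: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropy per instrument."""

    intercept: float
    se: float
    pval: float


def summarize_estimate(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, CI low, CI high, two-sided p) for a log-scale estimate."""
    if se <= 0:
        raise DomainError(f"se must be positive, got {se}")
    or_ = math.exp(beta)
    ci_low = math.exp(beta - Z975 * se)
    ci_high = math.exp(beta + Z975 * se)
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return or_, ci_low, ci_high, max(pval, np.nextafter(0, 1))


def _make_estimate(method: str, k: int, beta: float, se: float,
                   pval: Optional[float] = None) -> MREstimate:
    or_, lo, hi, p_wald = summarize_estimate(beta, se)
    return MREstimate(method=method, k=k, beta=beta, se=se,
                      pval=p_wald if pval is None else pval,
                      or_=or_, ci_low=lo, ci_high=hi)


def _ratio_arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    r = np.array([p.ratio for p in pairs])
    se_r = np.array([p.ratio_se for p in pairs])
    return r, se_r


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp.

    SE by the first-order delta method, se_out/|beta_exp|, which ignores the
    exposure-side uncertainty.
    """
    if pair.beta_exp == 0:
        raise DomainError(f"{pair.snp_id}: beta_exp = 0, degenerate instrument")
    return _make_estimate("wald_ratio", 1, pair.ratio, pair.ratio_se)


def cochran_q_value(pairs: Sequence[HarmonizedPair], beta_ref: float) -> float:
    """Unnormalized Cochran's Q of the per-SNP ratios about ``beta_ref``."""
    r, se_r = _ratio_arrays(pairs)
    return float(np.sum((r - beta_ref) ** 2 / se_r**2))


def ivw(
    pairs: Sequence[HarmonizedPair],
    model: IVWModel = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = sum(w_j r_j) / sum(w_j) over per-SNP ratios r_j with
    w_j = (beta_exp_j / se_out_j)^2; identical to weighted regression of
    beta_out on beta_exp through the origin with weights 1/se_out^2.
    Fixed-effects SE is (sum w_j)^-1/2; under multiplicative random effects
    it is scaled by max(1, sqrt(Q/(k-1))).
    """
    k = len(pairs)
    if k == 0:
        raise InsufficientInstrumentsError(1, 0, "ivw")
    if k == 1:
        est = wald_ratio(pairs[0])
        return _make_estimate("ivw", 1, est.beta, est.se)
    r, se_r = _ratio_arrays(pairs)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    if model == "multiplicative_random":
        q = float(np.sum(w * (r - beta) ** 2))
        se = se_fe * max(1.0, math.sqrt(q / (k - 1)))
    elif model == "fixed":
        se = se_fe
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    return _make_estimate("ivw", k, beta, se)


def mr_egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: WLS of beta_out on beta_exp with free intercept.

    Pairs are first oriented so beta_exp >= 0 (Egger is not invariant to
    allele orientation).  Weights are 1/se_out^2.  The intercept is tested
    against zero with a two-sided normal test; an exact fit (zero residual)
    gives p = 1 for a zero intercept and p -> 0 otherwise.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "mr_egger")
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = np.array([1.0 / p.se_out**2 for p in pairs])

    # weighted normal equations for [intercept, slope]
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    dof = k - 2
    # residual variance relative to the weighting; floor at 1 is NOT applied
    # here -- Egger conventionally uses the larger of 1 and the scale
    sigma2 = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(xtwx) * scale
    int_se = math.sqrt(cov[0, 0])
    slope_se = math.sqrt(cov[1, 1])

    slope = float(coef[1])
    intercept = float(coef[0])
    if int_se == 0.0:
        int_p = 1.0 if abs(intercept) < 1e-12 else 0.0
    else:
        int_p = 2.0 * stats.norm.sf(abs(intercept / int_se))
    if slope_se == 0.0:
        # exact linear fit: report a tiny but positive SE so the OR summary
        # stays defined
        slope_se = np.finfo(float).tiny ** 0.5
    est = _make_estimate("egger", k, slope, slope_se)
    return est, EggerIntercept(intercept=intercept, se=int_se, pval=int_p)


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of per-SNP ratios with a parametric bootstrap SE.

    Weights are the inverse variances of the ratio estimates, normalized.
    Consistent when SNPs contributing >= 50% of the weight are valid
    instruments.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "weighted_median")
    r, se_r = _ratio_arrays(pairs)
    w = 1.0 / se_r**2
    beta = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r_b = rng.normal(r, se_r)
        boots[b] = _weighted_median(r_b, w)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        se = float(np.finfo(float).tiny ** 0.5)
    return _make_estimate("weighted_median", k, beta, se)


def _mode_bandwidth(r: np.ndarray, factor: float) -> float:
    mad = np.median(np.abs(r - np.median(r))) * 1.4826
    s = min(np.std(r, ddof=1), mad) if mad > 0 else np.std(r, ddof=1)
    return factor * 0.9 * s * len(r) ** (-1 / 5)


def _weighted_mode(r: np.ndarray, w: np.ndarray, bw: float) -> float:
    if bw <= 0:  # degenerate: all ratios (essentially) identical
        return float(r[np.argmax(w)])
    grid = np.linspace(r.min() - 3 * bw, r.max() + 3 * bw, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / bw) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimate: peak of a weighted Gaussian KDE over ratios.

    Bandwidth is ``bandwidth_factor`` times a MAD-based default; the SE
    comes from a seeded parametric bootstrap.  Consistent when the largest
    weight-group of instruments is valid (zero modal pleiotropy).
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "weighted_mode")
    r, se_r = _ratio_arrays(pairs)
    w = 1.0 / se_r**2
    if np.ptp(r) == 0.0:
        beta = float(r[0])
    else:
        beta = _weighted_mode(r, w, _mode_bandwidth(r, bandwidth_factor))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r_b = rng.normal(r, se_r)
        boots[b] = _weighted_mode(r_b, w, _mode_bandwidth(r_b, bandwidth_factor))
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        se = float(np.finfo(float).tiny ** 0.5)
    return _make_estimate("weighted_mode", k, beta, se)
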