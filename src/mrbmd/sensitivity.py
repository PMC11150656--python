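"""Sensitivity diagnostics for one exposure-outcome MR analysis.

Covers the standard battery: Cochran's Q heterogeneity test over per-SNP
ratio estimates, MR-Egger intercept screen for directional pleiotropy,
MR-PRESSO global/outlier/distortion tests, leave-one-out influence with
sign-flip flagging, and the Steiger directionality test comparing variance
explained in exposure versus outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import EggerIntercept, ivw, mr_egger, wald_ratio
from .exceptions import DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""

    q: float
    df: int
    pval: float

    @property
    def heterogeneous(self) -> bool:
        """Heterogeneity is declared at p <= 0.05."""
        return self.pval <= 0.05


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_indices: list  # snp_ids flagged as outliers
    outlier_pvals: dict  # snp_id -> Bonferroni-adjusted outlier p
    beta_raw: float
    beta_corrected: Optional[float] = None
    distortion_pval: Optional[float] = None


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: do instruments explain more exposure than
    outcome variance?"""

    r2_exp: float
    r2_out: float
    correct_direction: bool
    pval: float


@dataclass(frozen=True)
class LooRecord:
    """IVW estimate with one SNP omitted; sign_flip marks influence."""

    omitted_snp: str
    beta: float
    se: float
    pval: float
    sign_flip: bool


def cochran_q(
    pairs: Sequence[HarmonizedPair], beta_ref: Optional[float] = None
) -> QResult:
    """Cochran's Q of per-SNP ratio estimates about ``beta_ref``.

    Q = sum_j w_j (r_j - beta_ref)^2 with w_j the inverse ratio variances;
    chi-square with k - 1 degrees of freedom under homogeneity.  When
    ``beta_ref`` is omitted the fixed-effects IVW estimate is used, which
    minimizes Q.
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "cochran_q")
    if beta_ref is None:
        beta_ref = ivw(pairs, model="fixed").beta
    r = np.array([p.ratio for p in pairs])
    se_r = np.array([p.ratio_se for p in pairs])
    q = float(np.sum((r - beta_ref) ** 2 / se_r**2))
    df = k - 1
    return QResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def leave_one_out(
    pairs: Sequence[HarmonizedPair],
    model: str = "multiplicative_random",
) -> list[LooRecord]:
    """Re-estimate IVW with each SNP omitted in turn.

    With k - 1 = 1 the single remaining SNP yields a Wald ratio.  A record
    is flagged ``sign_flip`` when its estimate's sign differs from the
    full-set IVW estimate — the influence criterion used to mark SNPs for
    exclusion-and-rerun.
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "leave_one_out")
    full = ivw(pairs, model=model)
    records = []
    for i, omitted in enumerate(pairs):
        rest = [p for j, p in enumerate(pairs) if j != i]
        est = wald_ratio(rest[0]) if len(rest) == 1 else ivw(rest, model=model)
        records.append(LooRecord(
            omitted_snp=omitted.snp_id,
            beta=est.beta, se=est.se, pval=est.pval,
            sign_flip=bool(np.sign(est.beta) != np.sign(full.beta)),
        ))
    return records


def _ivw_fixed_slope(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vector of IVW slopes each computed with SNP j left out."""
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    sig_level: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    The observed RSS is the weighted sum of squared residuals of each SNP
    about the IVW fit computed without it.  Its null distribution comes from
    parametric simulation: effects are redrawn as
    beta_exp* ~ N(beta_exp_j, se_exp_j) and
    beta_out* ~ N(slope_(-j) * beta_exp_j, se_out_j), and the RSS recomputed
    the same (leave-one-out) way.  Per-SNP outlier p-values compare each
    SNP's observed squared residual against its simulated distribution,
    Bonferroni-adjusted by k; outliers are reported only when the global
    test is significant.  When outliers are removed, the distortion test
    compares the raw and outlier-corrected estimates against the
    distribution obtained by removing equally many randomly chosen inliers.
    """
    k = len(pairs)
    if k < 4:
        raise InsufficientInstrumentsError(4, k, "mr_presso")
    rng = np.random.default_rng(seed)
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    w = 1.0 / sy**2
    ids = [p.snp_id for p in pairs]

    slope_loo = _loo_slopes(bx, by, w)
    resid_obs = by - slope_loo * bx
    rss_obs = float(np.sum(w * resid_obs**2))

    # parametric null simulations, vectorized over sims
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(slope_loo * bx, sy, size=(n_sim, k))
    slope_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = by_sim - slope_sim * bx_sim
    rss_sim = np.sum(w * resid_sim**2, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    outliers: list[str] = []
    outlier_pvals: dict[str, float] = {}
    if global_pval < sig_level:
        p_snp = (1 + np.sum(resid_sim**2 >= resid_obs[None, :] ** 2, axis=0)) / (1 + n_sim)
        for j, snp in enumerate(ids):
            p_adj = min(1.0, float(p_snp[j]) * k)
            outlier_pvals[snp] = p_adj
            if p_adj < sig_level:
                outliers.append(snp)

    beta_raw = _ivw_fixed_slope(bx, by, w)
    result = PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_indices=outliers,
        outlier_pvals=outlier_pvals,
        beta_raw=beta_raw,
    )
    if outliers:
        keep = np.array([snp not in outliers for snp in ids])
        if keep.sum() >= 1:
            beta_corr = _ivw_fixed_slope(bx[keep], by[keep], w[keep])
            result.beta_corrected = beta_corr
            n_out = int((~keep).sum())
            inlier_idx = np.flatnonzero(keep)
            if len(inlier_idx) > n_out:
                d_obs = (beta_raw - beta_corr) / abs(beta_corr)
                d_sim = np.empty(n_sim)
                for s in range(n_sim):
                    drop = rng.choice(inlier_idx, size=n_out, replace=False)
                    mask = keep.copy()
                    mask[drop] = False
                    b = _ivw_fixed_slope(bx[mask], by[mask], w[mask])
                    d_sim[s] = (beta_raw - b) / abs(b)
                result.distortion_pval = float(
                    (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (1 + n_sim)
                )
    return result


def snp_r2_from_t(t: float, n: int) -> float:
    """Variance in a trait explained by one SNP, from its t statistic:
    r^2 = t^2 / (t^2 + n - 2)."""
    if n <= 3:
        raise DomainError(f"sample size must exceed 3, got {n}")
    return t**2 / (t**2 + n - 2)


def steiger_test(
    pairs: Sequence[HarmonizedPair],
    n_exp: Optional[int] = None,
    n_out: Optional[int] = None,
) -> SteigerResult:
    """Steiger directionality test.

    Per-SNP variance explained is derived from the Wald t statistic
    (r^2 = t^2/(t^2 + n - 2)) and summed over instruments for the exposure
    and the outcome.  The assumed direction (exposure -> outcome) is
    supported when r2_exp > r2_out; the p-value is a two-sample z-test on
    Fisher-transformed |r| values with variances 1/(n-3).
    """
    if len(pairs) < 1:
        raise InsufficientInstrumentsError(1, 0, "steiger_test")
    n_exp = n_exp if n_exp is not None else int(np.median([p.n_exp for p in pairs]))
    n_out = n_out if n_out is not None else int(np.median([p.n_out for p in pairs]))
    if n_exp <= 3 or n_out <= 3:
        raise DomainError("sample sizes must exceed 3 for the Steiger test")
    r2_exp = float(sum(snp_r2_from_t(p.beta_exp / p.se_exp, n_exp) for p in pairs))
    r2_out = float(sum(snp_r2_from_t(p.beta_out / p.se_out, n_out) for p in pairs))
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z_exp = math.atanh(math.sqrt(r2_exp))
    z_out = math.atanh(math.sqrt(r2_out))
    z = (z_exp - z_out) / math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exp=r2_exp, r2_out=r2_out,
        correct_direction=r2_exp > r2_out,
        pval=pval,
    )


def pleiotropy_screen(
    pairs: Sequence[HarmonizedPair], sig_level: float = 0.05
) -> tuple[EggerIntercept, bool]:
    """Egger-intercept screen for horizontal pleiotropy.

    Returns the intercept test and ``pleiotropy_detected``; an intercept
    p-value above ``sig_level`` indicates absence of directional pleiotropy,
    otherwise confounder-SNP exclusion and re-analysis are warranted.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError(3, len(pairs), "pleiotropy_screen")
    _, intercept = mr_egger(pairs)
    return intercept, intercept.pval <= sig_level


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure-outcome analysis."""

    q: Optional[QResult] = None
    egger_intercept: Optional[EggerIntercept] = None
    pleiotropy_detected: Optional[bool] = None
    presso: Optional[PressoResult] = None
    loo: list = field(default_factory=list)
    steiger: Optional[SteigerResult] = None
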