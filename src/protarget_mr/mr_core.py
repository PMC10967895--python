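"""Two-sample MR estimators and sensitivity analyses.

Estimators: Wald ratio for a single instrument, inverse-variance-weighted
meta-analysis of per-instrument Wald ratios for two or more, with a
multiplicative random-effects model triggered by significant heterogeneity.
Diagnostics: Cochran's Q, MR-Egger intercept, Steiger directionality.
Multiple testing: Benjamini-Hochberg step-up with the
significant / suggestive / null trichotomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonizedPair

__all__ = [
    "MRResult",
    "EggerResult",
    "SteigerResult",
    "wald_ratio",
    "ivw",
    "run_mr",
    "cochran_q",
    "egger_intercept",
    "steiger_filter",
    "bh_fdr",
    "classify_significance",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """A causal estimate with confidence interval and diagnostics.

    ``beta`` is the causal log-odds (binary outcome) per unit exposure;
    ``or_`` and the CI bounds are on the odds-ratio scale.
    """

    exposure_id: str
    outcome_id: str
    method: str  # wald_ratio | ivw_fixed | ivw_random
    n_snps: int
    beta: float
    se: float
    pvalue: float
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q_fdr: Optional[float] = None
    cochran_q: Optional[float] = None
    q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    steiger_direction: Optional[bool] = None
    steiger_p: Optional[float] = None
    significance: Optional[str] = None

    def __post_init__(self) -> None:
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - Z95 * self.se)
        self.ci_high = math.exp(self.beta + Z95 * self.se)


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    pvalue: float
    slope: float


@dataclass(frozen=True)
class SteigerResult:
    direction: bool
    pvalue: float
    r2_exp: float
    r2_out: float


def wald_ratio(pair: HarmonizedPair) -> tuple[float, float]:
    """Single-instrument causal estimate: beta_out/beta_exp with the
    first-order delta-method SE se_out/|beta_exp|."""
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.variant_id}: degenerate instrument (beta_exp == 0)")
    return pair.beta_out / pair.beta_exp, pair.se_out / abs(pair.beta_exp)


def _ratio_estimates(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    ests = [wald_ratio(p) for p in pairs]
    b = np.array([e[0] for e in ests])
    se = np.array([e[1] for e in ests])
    return b, se


def ivw(
    pairs: Sequence[HarmonizedPair],
    exposure_id: str = "",
    outcome_id: str = "",
    het_alpha: float = 0.05,
) -> MRResult:
    """Inverse-variance-weighted meta-analysis of per-instrument Wald ratios.

    Fixed-effect SE unless Cochran's Q is significant at ``het_alpha``, in
    which case the SE is inflated multiplicatively by sqrt(max(1, Q/(k-1))).
    """
    if len(pairs) < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio for one")
    b, se = _ratio_estimates(pairs)
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q, q_p = cochran_q(list(zip(b, se)), beta)
    k = len(pairs)
    if q_p is not None and q_p <= het_alpha:
        method = "ivw_random"
        se_used = se_fixed * math.sqrt(max(1.0, q / (k - 1)))
    else:
        method = "ivw_fixed"
        se_used = se_fixed
    p = max(2.0 * stats.norm.sf(abs(beta / se_used)), 1e-300)
    res = MRResult(
        exposure_id=exposure_id, outcome_id=outcome_id, method=method,
        n_snps=k, beta=beta, se=se_used, pvalue=float(p),
    )
    res.cochran_q, res.q_pvalue = q, q_p
    return res


def run_mr(
    pairs: Sequence[HarmonizedPair],
    exposure_id: str = "",
    outcome_id: str = "",
) -> MRResult:
    """Route to the Wald ratio for one instrument, IVW for two or more, and
    attach the Egger intercept where at least three instruments exist."""
    if not pairs:
        raise ValueError("no instruments")
    if len(pairs) == 1:
        beta, se = wald_ratio(pairs[0])
        p = max(2.0 * stats.norm.sf(abs(beta / se)), 1e-300)
        res = MRResult(
            exposure_id=exposure_id, outcome_id=outcome_id, method="wald_ratio",
            n_snps=1, beta=beta, se=se, pvalue=float(p),
        )
    else:
        res = ivw(pairs, exposure_id, outcome_id)
    egger = egger_intercept(pairs)
    if egger is not None:
        res.egger_intercept = egger.intercept
        res.egger_intercept_p = egger.pvalue
    return res


def cochran_q(
    ratio_estimates: Sequence[tuple[float, float]],
    beta_ivw: float,
) -> tuple[Optional[float], Optional[float]]:
    """Heterogeneity statistic Q = sum w_i (b_i - beta_ivw)^2 with a
    chi-square(k-1) p-value; absent (None, None) for fewer than 2 estimates."""
    k = len(ratio_estimates)
    if k < 2:
        return None, None
    b = np.array([e[0] for e in ratio_estimates])
    se = np.array([e[1] for e in ratio_estimates])
    q = float(np.sum((b - beta_ivw) ** 2 / se**2))
    return q, float(stats.chi2.sf(q, k - 1))


def egger_intercept(pairs: Sequence[HarmonizedPair]) -> Optional[EggerResult]:
    """MR-Egger intercept: weighted regression of outcome on exposure effects
    with an intercept, weights 1/se_out^2, after orienting every instrument
    to a non-negative exposure effect.  None when fewer than 3 instruments."""
    k = len(pairs)
    if k < 3:
        return None
    oriented = [
        replace(p, beta_exp=-p.beta_exp, beta_out=-p.beta_out) if p.beta_exp < 0 else p
        for p in pairs
    ]
    x = np.array([p.beta_exp for p in oriented])
    y = np.array([p.beta_out for p in oriented])
    w = np.array([1.0 / p.se_out**2 for p in oriented])
    X = np.column_stack([np.ones(k), x])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    dof = k - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    xtx_inv = np.linalg.inv((X * w[:, None]).T @ X)
    se_int = math.sqrt(max(sigma2 * xtx_inv[0, 0], 0.0))
    if se_int == 0.0:
        p = 1.0 if coef[0] == 0.0 else 0.0
    else:
        p = 2.0 * stats.t.sf(abs(coef[0] / se_int), dof)
    return EggerResult(intercept=float(coef[0]), se=se_int, pvalue=float(p),
                       slope=float(coef[1]))


def _instrument_r2(z: np.ndarray, n: int) -> float:
    """Variance explained by the instrument set: sum z_i^2 / (z_i^2 + n - 2)."""
    r2 = float(np.sum(z**2 / (z**2 + n - 2)))
    if r2 >= 1.0:
        import warnings

        warnings.warn("instrument r2 >= 1; clamping", RuntimeWarning, stacklevel=3)
        r2 = 1.0 - 1e-12
    return r2


def steiger_filter(
    pairs: Sequence[HarmonizedPair],
    n_exp: int,
    n_out: int,
) -> SteigerResult:
    """Directionality check: do the instruments explain more variance in the
    exposure than in the outcome?

    The p-value is a two-sample z-test on the Fisher transforms of the two
    multiple correlations, with variance 1/(n_exp-3) + 1/(n_out-3).
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3")
    z_exp = np.array([p.beta_exp / p.se_exp for p in pairs])
    z_out = np.array([p.beta_out / p.se_out for p in pairs])
    r2_exp = _instrument_r2(z_exp, n_exp)
    r2_out = _instrument_r2(z_out, n_out)
    delta = math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))
    sd = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = 2.0 * stats.norm.sf(abs(delta) / sd)
    return SteigerResult(
        direction=r2_exp > r2_out, pvalue=float(p), r2_exp=r2_exp, r2_out=r2_out
    )


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def classify_significance(p: float, q: float, alpha: float = 0.05) -> str:
    """significant (q < alpha), suggestive (p < alpha <= q), or null."""
    if q < alpha:
        return "significant"
    if p < alpha:
        return "suggestive"
    return "null"
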