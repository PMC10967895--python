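"""Summary-data-based MR at the top cis-eQTL and the HEIDI test.

The SMR test asks whether a gene's expression level mediates a GWAS signal,
using only the top cis-eQTL.  The HEIDI test then distinguishes a single
shared causal variant (pleiotropy/mediation) from distinct variants in LD
(linkage): under the shared-variant null, the ratio estimate b_xy is
identical at every SNP in LD with the top eQTL, so heterogeneity of b_xy
across nearby SNPs is evidence of linkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, stats

from .sumstats import LDMatrix, VariantAssociation

__all__ = [
    "SMRResult",
    "HEIDI_EQTL_P_MAX",
    "HEIDI_R2_MIN",
    "HEIDI_R2_MAX",
    "HEIDI_MAX_SNPS",
    "HEIDI_MIN_SNPS",
    "smr_test",
    "heidi_test",
    "quadform_pvalue",
]

Z95 = stats.norm.ppf(0.975)

# HEIDI SNP-eligibility defaults of the published SMR tool (v1.03)
HEIDI_EQTL_P_MAX = 1.57e-3
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3


@dataclass
class SMRResult:
    """Effect of gene expression on the outcome at the top cis-eQTL."""

    gene_id: str
    outcome_id: str
    top_snp: str
    b_xy: float
    se_bxy: float
    t_smr: float
    p_smr: float
    or_: float
    ci_low: float
    ci_high: float
    p_heidi: Optional[float] = None
    n_heidi_snps: int = 0


def smr_test(
    eqtl_top: VariantAssociation,
    gwas_top: VariantAssociation,
    gene_id: str = "",
    outcome_id: str = "",
) -> SMRResult:
    """SMR causal estimate b_xy = beta_gwas/beta_eqtl at the top eQTL, with
    T_SMR = z_g^2 z_e^2 / (z_g^2 + z_e^2) referred to chi-square(1).

    HEIDI fields are left absent; call :func:`heidi_test` separately.
    """
    if eqtl_top.variant_id != gwas_top.variant_id:
        raise ValueError("eQTL and GWAS records refer to different variants")
    if eqtl_top.beta == 0:
        raise ValueError("degenerate eQTL instrument (beta == 0)")
    b_xy = gwas_top.beta / eqtl_top.beta
    z_e = eqtl_top.beta / eqtl_top.se
    z_g = gwas_top.beta / gwas_top.se
    if z_g * z_g == 0.0:  # exact zero or underflow
        t_smr = 0.0
        se_bxy = gwas_top.se / abs(eqtl_top.beta)
    else:
        t_smr = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
        se_bxy = abs(b_xy) * math.sqrt(1.0 / z_g**2 + 1.0 / z_e**2)
    p_smr = float(stats.chi2.sf(t_smr, 1))
    return SMRResult(
        gene_id=gene_id, outcome_id=outcome_id, top_snp=eqtl_top.variant_id,
        b_xy=b_xy, se_bxy=se_bxy, t_smr=float(t_smr), p_smr=p_smr,
        or_=math.exp(b_xy),
        ci_low=math.exp(b_xy - Z95 * se_bxy),
        ci_high=math.exp(b_xy + Z95 * se_bxy),
    )


def quadform_pvalue(
    q: float,
    lambdas: Sequence[float],
    method: str = "imhof",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Upper-tail probability P(sum_k lambda_k chi2_1 > q).

    ``method="imhof"`` evaluates Imhof's characteristic-function integral
    numerically; ``method="mc"`` uses seeded Monte-Carlo draws.
    """
    lam = np.asarray([l for l in lambdas if l > 1e-12], dtype=float)
    if lam.size == 0 or q <= 0.0:
        return 1.0
    if method == "mc":
        rng = np.random.default_rng(seed)
        # chunked to bound memory at ~ n_draws floats
        exceed = 0
        chunk = 200_000
        done = 0
        while done < n_draws:
            m = min(chunk, n_draws - done)
            draws = rng.standard_normal((m, lam.size)) ** 2 @ lam
            exceed += int(np.sum(draws > q))
            done += m
        return max(exceed / n_draws, 1.0 / n_draws)
    if method != "imhof":
        raise ValueError(f"unknown method {method!r}")

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return math.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf,
                                limit=1000, epsabs=1e-10, epsrel=1e-9)
    p = 0.5 + val / math.pi
    return float(min(max(p, 1e-300), 1.0))


def heidi_test(
    eqtl_region: Sequence[VariantAssociation],
    gwas_region: Sequence[VariantAssociation],
    ld: LDMatrix,
    top_snp: str,
    eqtl_p_max: float = HEIDI_EQTL_P_MAX,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
    max_snps: int = HEIDI_MAX_SNPS,
    min_snps: int = HEIDI_MIN_SNPS,
    mc_fallback_draws: int = 1_000_000,
    seed: int = 0,
) -> tuple[Optional[float], int]:
    """HEIDI heterogeneity test around the top eQTL.

    Candidate SNPs must be nominally strong eQTLs (p < ``eqtl_p_max``) in
    moderate LD with the top SNP (r^2 in [``r2_min``, ``r2_max``]); the
    ``max_snps`` strongest are used.  For each candidate the difference
    d_i = b_xy(i) - b_xy(top) is formed; the statistic sum_i (d_i/sd_i)^2 is
    referred to its null distribution, a weighted sum of chi-square(1)
    variables with weights from the eigenvalues of the correlation matrix of
    d (delta-method covariance, eQTL and GWAS samples independent).

    Returns (p_heidi, n_snps_used); p is None when fewer than ``min_snps``
    candidates are eligible.
    """
    eqtl_by_id = {a.variant_id: a for a in eqtl_region}
    gwas_by_id = {a.variant_id: a for a in gwas_region}
    if top_snp not in eqtl_by_id or top_snp not in gwas_by_id or top_snp not in ld:
        raise KeyError(f"top SNP {top_snp!r} missing from eQTL, GWAS or LD input")

    candidates = []
    for a in eqtl_region:
        if a.variant_id == top_snp or a.variant_id not in gwas_by_id:
            continue
        if a.variant_id not in ld:
            continue
        if a.pvalue >= eqtl_p_max:
            continue
        r2 = ld.r2(a.variant_id, top_snp)
        if not (r2_min <= r2 <= r2_max):
            continue
        candidates.append(a)
    candidates.sort(key=lambda a: (a.pvalue, a.variant_id))
    candidates = candidates[:max_snps]
    if len(candidates) < min_snps:
        return None, len(candidates)

    snps = [top_snp] + [a.variant_id for a in candidates]
    m = len(snps)
    be = np.array([eqtl_by_id[v].beta for v in snps])
    se_e = np.array([eqtl_by_id[v].se for v in snps])
    bg = np.array([gwas_by_id[v].beta for v in snps])
    se_g = np.array([gwas_by_id[v].se for v in snps])
    sub = ld.submatrix(snps)
    r = sub.r

    bxy = bg / be
    # delta-method covariance of b_xy across SNPs; the two traits' estimation
    # errors are independent (two-sample design)
    cov_g = r * np.outer(se_g, se_g)
    cov_e = r * np.outer(se_e, se_e)
    grad_g = 1.0 / be
    grad_e = -bg / be**2
    cov_bxy = np.outer(grad_g, grad_g) * cov_g + np.outer(grad_e, grad_e) * cov_e

    # d_i = b_xy(i) - b_xy(top), i = 1..m-1
    d = bxy[1:] - bxy[0]
    cov_d = (
        cov_bxy[1:, 1:]
        - cov_bxy[1:, [0]]
        - cov_bxy[[0], 1:]
        + cov_bxy[0, 0]
    )
    sd_d = np.sqrt(np.diag(cov_d))
    z_d = d / sd_d
    stat = float(np.sum(z_d**2))
    corr_d = cov_d / np.outer(sd_d, sd_d)
    lam = np.linalg.eigvalsh(corr_d)
    lam = lam[lam > 1e-10]
    try:
        p = quadform_pvalue(stat, lam, method="imhof")
        if not (0.0 < p <= 1.0) or math.isnan(p):
            raise ValueError("imhof out of range")
    except Exception:
        p = quadform_pvalue(stat, lam, method="mc", n_draws=mc_fallback_draws,
                            seed=seed)
    return p, m - 1
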