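"""Seeded generator of LD-structured regional summary statistics.

Summary statistics are simulated directly at the summary level under the
standard two-sample model: for a region with LD correlation matrix R and
true per-SNP joint effects b, the observed z-scores are drawn as

    z_obs ~ MVN(R @ z_true, R),       z_true = b / se,

which is exactly the sampling distribution summary-statistic MR methods
assume.  Per-SNP sampling variance is 1/(2*eaf*(1-eaf)*n), divided by
case_fraction*(1-case_fraction) on the log-odds scale for binary traits.

Scenarios control how the outcome's true effects relate to the exposure's:

    null            outcome has no genetic effects in the region
    shared_causal   outcome effect = theta * exposure effect (same variant)
    exposure_only   alias of shared_causal (effects flow through exposure)
    distinct_causal exposure and outcome have separate causal variants
    reverse_causal  outcome is causal; exposure effect = theta * outcome effect
    pleiotropic     shared causal variant plus a constant direct effect on
                    the outcome at each exposure-causal variant
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    HarmonizedPair,
    LDMatrix,
    VariantAssociation,
    write_ld_matrix,
    write_sumstats,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ld",
    "simulate_region",
    "simulate_mr_pairs",
    "make_study",
]

SCENARIOS = frozenset({
    "null", "shared_causal", "exposure_only", "distinct_causal",
    "reverse_causal", "pleiotropic",
})


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated cis region."""

    n_snps: int = 200
    ld_model: str = "ar1"  # "ar1" or "block"
    ld_rho: float = 0.9
    block_size: int = 20
    block_r: float = 0.8
    eaf_range: tuple[float, float] = (0.05, 0.95)
    scenario: str = "shared_causal"
    theta: float = 0.3
    pleiotropy_intercept: float = 0.0
    exposure_z: float = 12.0
    eqtl_z: float = 10.0
    outcome_z: float = 10.0  # distinct-/reverse-causal target
    n_exp: int = 35_000
    n_out: int = 400_000
    n_eqtl: int = 30_000
    outcome_binary: bool = True
    case_fraction: float = 0.1
    exposure_causal: Optional[int] = None
    outcome_causal: Optional[int] = None
    chrom: str = "1"
    pos_start: int = 10_000_000
    pos_step: int = 500
    variant_prefix: str = "rs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if min(self.n_exp, self.n_out, self.n_eqtl) <= 10:
            raise ValueError("sample sizes must exceed 10")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth recorded exactly as generated."""

    scenario: str
    theta: float
    causal_exposure: list[int]
    causal_outcome: list[int]
    b_exp: np.ndarray
    b_out: np.ndarray
    b_eqtl: np.ndarray


def simulate_ld(
    n_snps: int,
    model: str = "ar1",
    rho: float = 0.9,
    block_size: int = 20,
    block_r: float = 0.8,
    seed: int = 0,
    variant_ids: Optional[Sequence[str]] = None,
) -> LDMatrix:
    """Deterministic LD correlation matrix: AR(1) r_ij = rho^|i-j| or
    constant-within-block structure.  Eigenvalues are floored at 1e-8."""
    if model == "ar1":
        idx = np.arange(n_snps)
        r = rho ** np.abs(idx[:, None] - idx[None, :])
    elif model == "block":
        r = np.zeros((n_snps, n_snps))
        for start in range(0, n_snps, block_size):
            end = min(start + block_size, n_snps)
            r[start:end, start:end] = block_r
        np.fill_diagonal(r, 1.0)
    else:
        raise ValueError(f"unknown LD model {model!r}")

    evals = np.linalg.eigvalsh(r)
    if evals.min() < 1e-8:
        w, v = np.linalg.eigh(r)
        w = np.maximum(w, 1e-8)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1}" for i in range(n_snps)]
    return LDMatrix(variant_ids, r)


def _sampling_se(eaf: np.ndarray, n: int, binary: bool, case_fraction: float) -> np.ndarray:
    var = 1.0 / (2.0 * eaf * (1.0 - eaf) * n)
    if binary:
        var = var / (case_fraction * (1.0 - case_fraction))
    return np.sqrt(var)


def _observe(
    rng: np.random.Generator,
    b_true: np.ndarray,
    se: np.ndarray,
    r: np.ndarray,
    chol: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw observed betas and p-values given true joint effects."""
    z_true = b_true / se
    z_obs = r @ z_true + chol @ rng.standard_normal(len(se))
    beta_hat = z_obs * se
    pvals = 2.0 * stats.norm.sf(np.abs(z_obs))
    return beta_hat, np.clip(pvals, 1e-300, 1.0)


def _records(
    cfg: SimConfig,
    ids: Sequence[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    pvals: np.ndarray,
    n: int,
    binary: bool,
) -> list[VariantAssociation]:
    n_cases = int(round(n * cfg.case_fraction)) if binary else None
    n_controls = (n - n_cases) if binary else None
    return [
        VariantAssociation(
            variant_id=ids[j], chrom=cfg.chrom,
            pos=cfg.pos_start + j * cfg.pos_step,
            effect_allele="A", other_allele="G",
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pvalue=float(pvals[j]), n=n, n_cases=n_cases, n_controls=n_controls,
        )
        for j in range(len(ids))
    ]


def simulate_region(
    cfg: SimConfig,
    ld: Optional[LDMatrix] = None,
) -> tuple[list[VariantAssociation], list[VariantAssociation],
           list[VariantAssociation], SimTruth]:
    """Simulate exposure (pQTL), outcome (GWAS) and eQTL summary statistics
    for one cis region under the configured causal scenario."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps
    if ld is None:
        ld = simulate_ld(
            m, cfg.ld_model, cfg.ld_rho, cfg.block_size, cfg.block_r,
            variant_ids=[f"{cfg.variant_prefix}{j + 1}" for j in range(m)],
        )
    ids = ld.variant_ids
    r = ld.r
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    eaf = rng.uniform(*cfg.eaf_range, size=m)

    se_exp = _sampling_se(eaf, cfg.n_exp, False, cfg.case_fraction)
    se_out = _sampling_se(eaf, cfg.n_out, cfg.outcome_binary, cfg.case_fraction)
    se_eqtl = _sampling_se(eaf, cfg.n_eqtl, False, cfg.case_fraction)

    ci_exp = cfg.exposure_causal if cfg.exposure_causal is not None else m // 8
    ci_out = cfg.outcome_causal if cfg.outcome_causal is not None else m - 1 - m // 8

    b_exp = np.zeros(m)
    b_out = np.zeros(m)
    b_eqtl = np.zeros(m)
    causal_exp: list[int] = []
    causal_out: list[int] = []

    if cfg.scenario == "reverse_causal":
        b_out[ci_out] = cfg.outcome_z * se_out[ci_out]
        b_exp = cfg.theta * b_out
        b_eqtl[ci_out] = cfg.eqtl_z * se_eqtl[ci_out]
        causal_exp, causal_out = [ci_out], [ci_out]
    else:
        b_exp[ci_exp] = cfg.exposure_z * se_exp[ci_exp]
        b_eqtl[ci_exp] = cfg.eqtl_z * se_eqtl[ci_exp]
        causal_exp = [ci_exp]
        if cfg.scenario in ("shared_causal", "exposure_only", "pleiotropic"):
            b_out = cfg.theta * b_exp
            if cfg.scenario == "pleiotropic":
                b_out[ci_exp] += cfg.pleiotropy_intercept
            causal_out = [ci_exp]
        elif cfg.scenario == "distinct_causal":
            b_out[ci_out] = cfg.outcome_z * se_out[ci_out]
            causal_out = [ci_out]
        # null: b_out stays zero

    beta_exp, p_exp = _observe(rng, b_exp, se_exp, r, chol)
    beta_out, p_out = _observe(rng, b_out, se_out, r, chol)
    beta_eqtl, p_eqtl = _observe(rng, b_eqtl, se_eqtl, r, chol)

    exposure = _records(cfg, ids, eaf, beta_exp, se_exp, p_exp, cfg.n_exp, False)
    outcome = _records(cfg, ids, eaf, beta_out, se_out, p_out, cfg.n_out,
                       cfg.outcome_binary)
    eqtl = _records(cfg, ids, eaf, beta_eqtl, se_eqtl, p_eqtl, cfg.n_eqtl, False)

    truth = SimTruth(
        scenario=cfg.scenario, theta=cfg.theta if cfg.scenario != "null" else 0.0,
        causal_exposure=causal_exp, causal_outcome=causal_out,
        b_exp=b_exp, b_out=b_out, b_eqtl=b_eqtl,
    )
    return exposure, outcome, eqtl, truth


def simulate_mr_pairs(
    k: int,
    theta: float,
    n_exp: int = 100_000,
    n_out: int = 100_000,
    seed: int = 0,
    beta_exp_range: tuple[float, float] = (0.1, 0.3),
    eaf_range: tuple[float, float] = (0.1, 0.9),
    pleiotropy_intercept: float = 0.0,
    reverse: bool = False,
    outcome_binary: bool = False,
    case_fraction: float = 0.5,
) -> list[HarmonizedPair]:
    """Draw k independent (LD-free) instruments under the two-sample model.

    Forward model: beta_out_true = theta * beta_exp_true + intercept.
    ``reverse=True`` swaps the dependency (the outcome drives the exposure),
    for exercising directionality tests.
    """
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(*eaf_range, size=k)
    se_exp = _sampling_se(eaf, n_exp, False, case_fraction)
    se_out = _sampling_se(eaf, n_out, outcome_binary, case_fraction)
    mag = rng.uniform(*beta_exp_range, size=k)
    sign = rng.choice([-1.0, 1.0], size=k)
    if reverse:
        b_out = mag * sign
        b_exp = theta * b_out
    else:
        b_exp = mag * sign
        b_out = theta * b_exp + pleiotropy_intercept
    beta_exp = b_exp + se_exp * rng.standard_normal(k)
    beta_out = b_out + se_out * rng.standard_normal(k)
    return [
        HarmonizedPair(
            variant_id=f"iv{i + 1}", effect_allele="A",
            beta_exp=float(beta_exp[i]), se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]), se_out=float(se_out[i]),
            eaf_exp=float(eaf[i]), eaf_out=float(eaf[i]),
            n_exp=n_exp, n_out=n_out,
        )
        for i in range(k)
    ]


DEFAULT_MIX = {"shared_causal": 0.25, "null": 0.75}


def make_study(
    out_dir,
    n_proteins: int,
    scenario_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    n_snps: int = 100,
    ld_rho: float = 0.9,
    theta: float = 0.4,
    n_exp: int = 35_000,
    n_out: int = 300_000,
    n_eqtl: int = 30_000,
    case_fraction: float = 0.1,
    outcome_id: str = "oa",
    force: bool = False,
) -> pd.DataFrame:
    """Write an on-disk study bundle consumable by the CLI end to end.

    Layout: ``annotation.tsv``, ``truth.tsv``, ``pqtl/<gene>.tsv``,
    ``eqtl/<gene>.tsv``, ``ld/<gene>.ld`` and ``gwas/<outcome>.tsv``
    (all regions concatenated).  Scenario assignment cycles through
    ``scenario_mix`` proportions deterministically.  Returns the truth table.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
        shutil.rmtree(out_dir)
    for sub in ("pqtl", "eqtl", "ld", "gwas"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    mix = scenario_mix or DEFAULT_MIX
    scenarios: list[str] = []
    for name, frac in sorted(mix.items()):
        scenarios.extend([name] * int(round(frac * n_proteins)))
    while len(scenarios) < n_proteins:
        scenarios.append("null")
    scenarios = scenarios[:n_proteins]

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_proteins)]

    ann_rows, truth_rows, gwas_records = [], [], []
    for i in range(n_proteins):
        gene = f"GENE{i + 1:03d}"
        chrom = str((i % 22) + 1)
        pos_start = 10_000_000 + (i // 22) * 50_000_000
        cfg = SimConfig(
            n_snps=n_snps, ld_rho=ld_rho, scenario=scenarios[i], theta=theta,
            n_exp=n_exp, n_out=n_out, n_eqtl=n_eqtl,
            case_fraction=case_fraction, chrom=chrom, pos_start=pos_start,
            variant_prefix=f"{gene}_v", seed=child_seeds[i],
        )
        exposure, outcome, eqtl, truth = simulate_region(cfg)
        ld = simulate_ld(n_snps, cfg.ld_model, cfg.ld_rho,
                         variant_ids=[a.variant_id for a in exposure])
        write_sumstats(exposure, out_dir / "pqtl" / f"{gene}.tsv")
        write_sumstats(eqtl, out_dir / "eqtl" / f"{gene}.tsv")
        write_ld_matrix(ld, out_dir / "ld" / f"{gene}.ld")
        gwas_records.extend(outcome)
        gene_end = pos_start + (n_snps - 1) * cfg.pos_step
        ann_rows.append({"gene_id": gene, "chrom": chrom,
                         "start": pos_start, "end": gene_end})
        truth_rows.append({
            "gene_id": gene, "scenario": truth.scenario, "theta": truth.theta,
            "causal_exposure": ";".join(map(str, truth.causal_exposure)),
            "causal_outcome": ";".join(map(str, truth.causal_outcome)),
            "is_causal": truth.scenario in ("shared_causal", "exposure_only",
                                            "pleiotropic") and truth.theta != 0,
        })

    write_sumstats(gwas_records, out_dir / "gwas" / f"{outcome_id}.tsv")
    pd.DataFrame(ann_rows, columns=["gene_id", "chrom", "start", "end"]).to_csv(
        out_dir / "annotation.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "scenario", "theta", "causal_exposure",
                 "causal_outcome", "is_causal"],
    )
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth_df
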