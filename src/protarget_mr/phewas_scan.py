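"""Phenome-wide MR screening and local phenotype scanning of instruments.

The MR-PheWAS screen runs the primary MR estimator for one protein against
every outcome in a catalog (restricted to traits with more than a minimum
number of cases), then corrects across the outcome family.  Phenotype
scanning flags instruments with genome-wide-significant cross-trait
associations from a local lookup table — a stand-in for remote
phenotype-scanner services.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .mr_core import MRResult, bh_fdr, run_mr, steiger_filter
from .sumstats import InstrumentSet, VariantAssociation, read_sumstats

__all__ = [
    "OutcomeCatalogEntry",
    "PhewasResult",
    "InstrumentFlags",
    "filter_outcomes",
    "phewas_screen",
    "phenotype_scan",
    "bonferroni",
]

logger = logging.getLogger(__name__)

GWS_P = 5e-8


@dataclass(frozen=True)
class OutcomeCatalogEntry:
    """One row of the outcome catalog: an ICD-derived binary trait."""

    trait_id: str
    label: str
    n_cases: int
    n_controls: int
    sumstats: Union[str, Sequence[VariantAssociation]]

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError(f"{self.trait_id}: negative case/control count")


@dataclass
class PhewasResult:
    protein_id: str
    trait_id: str
    label: str
    result: MRResult
    q_corrected: Optional[float] = None


@dataclass
class InstrumentFlags:
    variant_id: str
    traits: list[str] = field(default_factory=list)
    pleiotropy_suspect: bool = False


def filter_outcomes(
    catalog: Sequence[OutcomeCatalogEntry],
    min_cases: int = 500,
) -> list[OutcomeCatalogEntry]:
    """Keep traits with strictly more than ``min_cases`` cases."""
    return [e for e in catalog if e.n_cases > min_cases]


def bonferroni(pvalues: Sequence[float]) -> list[float]:
    m = len(pvalues)
    return [min(p * m, 1.0) for p in pvalues]


def _load_outcome(entry: OutcomeCatalogEntry) -> list[VariantAssociation]:
    if isinstance(entry.sumstats, str):
        return read_sumstats(entry.sumstats)
    return list(entry.sumstats)


def phewas_screen(
    instruments: InstrumentSet,
    outcomes: Sequence[OutcomeCatalogEntry],
    correction: str = "fdr_bh",
    drop_palindromic: bool = True,
    failures: Optional[list[tuple[str, str]]] = None,
) -> list[PhewasResult]:
    """Run the MR estimator for one protein against each catalog outcome and
    correct p-values across the outcome family.

    Unreadable outcome files are skipped and recorded in ``failures`` as
    (trait_id, message).  Results are sorted by trait_id for deterministic
    output.
    """
    if len(instruments) == 0:
        raise ValueError("instrument set is empty")
    exp_by_id = {p.variant_id: p for p in instruments.pairs}

    results: list[PhewasResult] = []
    for entry in sorted(outcomes, key=lambda e: e.trait_id):
        try:
            out_assocs = _load_outcome(entry)
        except Exception as exc:  # noqa: BLE001 - logged skip per contract
            logger.warning("skipping outcome %s: %s", entry.trait_id, exc)
            if failures is not None:
                failures.append((entry.trait_id, str(exc)))
            continue
        out_by_id = {a.variant_id: a for a in out_assocs}
        pairs = []
        for vid, exp_pair in exp_by_id.items():
            out_rec = out_by_id.get(vid)
            if out_rec is None:
                continue
            harm = _align_outcome(exp_pair, out_rec)
            if harm is None:
                continue
            pairs.append(harm)
        if not pairs:
            if failures is not None:
                failures.append((entry.trait_id, "no overlapping instruments"))
            continue
        res = run_mr(pairs, exposure_id=instruments.exposure_id,
                     outcome_id=entry.trait_id)
        n_out = entry.n_cases + entry.n_controls
        n_exp = pairs[0].n_exp
        if n_exp > 3 and n_out > 3:
            st = steiger_filter(pairs, n_exp, n_out)
            res.steiger_direction, res.steiger_p = st.direction, st.pvalue
        results.append(PhewasResult(
            protein_id=instruments.exposure_id, trait_id=entry.trait_id,
            label=entry.label, result=res,
        ))

    pvals = [r.result.pvalue for r in results]
    if pvals:
        qs = bh_fdr(pvals) if correction == "fdr_bh" else bonferroni(pvals)
        for r, q in zip(results, qs):
            r.q_corrected = q
            r.result.q_fdr = q
    return results


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _align_outcome(pair, out_rec: VariantAssociation):
    """Align an outcome record onto an already-harmonized instrument's effect
    allele (palindromic instruments were removed at selection time)."""
    from .sumstats import HarmonizedPair

    ea = pair.effect_allele
    if out_rec.effect_allele in (ea, _COMPLEMENT[ea]):
        beta_out, eaf_out = out_rec.beta, out_rec.eaf
    elif out_rec.other_allele in (ea, _COMPLEMENT[ea]):
        beta_out, eaf_out = -out_rec.beta, 1.0 - out_rec.eaf
    else:
        return None
    return HarmonizedPair(
        variant_id=pair.variant_id, effect_allele=ea,
        beta_exp=pair.beta_exp, se_exp=pair.se_exp,
        beta_out=beta_out, se_out=out_rec.se,
        eaf_exp=pair.eaf_exp, eaf_out=eaf_out,
        n_exp=pair.n_exp, n_out=out_rec.n,
    )


def phenotype_scan(
    instruments: InstrumentSet,
    assoc_table: Mapping[str, Sequence[tuple[str, float]]],
    confounder_traits: Sequence[str],
    p_max: float = GWS_P,
) -> list[InstrumentFlags]:
    """Flag each instrument with the traits it is genome-wide-significantly
    associated with in a local variant -> (trait, p) lookup table, and mark
    it pleiotropy-suspect when any flagged trait is a listed confounder."""
    confounders = set(confounder_traits)
    flags = []
    for pair in instruments.pairs:
        hits = [t for t, p in assoc_table.get(pair.variant_id, ()) if p < p_max]
        flags.append(InstrumentFlags(
            variant_id=pair.variant_id,
            traits=hits,
            pleiotropy_suspect=bool(set(hits) & confounders),
        ))
    return flags
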