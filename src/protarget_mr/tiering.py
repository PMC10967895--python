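"""Four-tier classification of candidate drug targets.

Five validation criteria are scored per protein x outcome:

    c1  replication in the expression-level analysis (SMR p < 0.05)
    c2  HEIDI test passed (p > 0.05, i.e. no evidence of linkage)
    c3  pQTL colocalization with the outcome (PPH4 >= 0.8)
    c4  eQTL colocalization with the outcome (PPH4 >= 0.8)
    c5  direction consistency: primary-MR and SMR odds ratios on the same
        side of 1

Direction consistency (c5) is a prerequisite: a protein failing it is tier 4
regardless of the other criteria.  Otherwise tiers 1/2/3 correspond to
passing 5/4/3 criteria and everything else is tier 4.  Proteins with no
eligible blood eQTLs cannot be validated at the expression level and are
classified separately: tier 2 if their pQTLs colocalize (c3), else tier 4.

Absent evidence scores as a failed criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "EvidenceRecord",
    "TierRecord",
    "TierThresholds",
    "evaluate_criteria",
    "assign_tier",
    "classify",
    "classify_table",
    "load_example_evidence",
]


@dataclass(frozen=True)
class TierThresholds:
    p_smr_max: float = 0.05
    p_heidi_min: float = 0.05
    pph4_min: float = 0.8


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-protein evidence feeding the classifier."""

    protein_id: str
    outcome_id: str
    mr_or: float
    smr_or: Optional[float] = None
    p_smr: Optional[float] = None
    p_heidi: Optional[float] = None
    pph4_pqtl: Optional[float] = None
    pph4_eqtl: Optional[float] = None
    eqtl_available: bool = True

    def __post_init__(self) -> None:
        if not self.eqtl_available and any(
            v is not None for v in (self.smr_or, self.p_smr, self.p_heidi, self.pph4_eqtl)
        ):
            raise ValueError(
                f"{self.protein_id}: expression-level fields present despite "
                "eqtl_available=False"
            )


@dataclass
class TierRecord:
    protein_id: str
    outcome_id: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    tier: Optional[int] = None

    @property
    def n_passed(self) -> int:
        return sum((self.c1, self.c2, self.c3, self.c4, self.c5))


def evaluate_criteria(
    rec: EvidenceRecord,
    thresholds: TierThresholds = TierThresholds(),
) -> TierRecord:
    """Score the five criteria; absent inputs fail.  Boundary semantics:
    c1 strict <, c2 strict >, c3/c4 >=, c5 strict same side of 1."""
    if rec.mr_or <= 0:
        raise ValueError(f"{rec.protein_id}: mr_or must be > 0, got {rec.mr_or}")
    c1 = rec.p_smr is not None and rec.p_smr < thresholds.p_smr_max
    c2 = rec.p_heidi is not None and rec.p_heidi > thresholds.p_heidi_min
    c3 = rec.pph4_pqtl is not None and rec.pph4_pqtl >= thresholds.pph4_min
    c4 = rec.pph4_eqtl is not None and rec.pph4_eqtl >= thresholds.pph4_min
    c5 = rec.smr_or is not None and (
        (rec.mr_or > 1 and rec.smr_or > 1) or (rec.mr_or < 1 and rec.smr_or < 1)
    )
    return TierRecord(rec.protein_id, rec.outcome_id, c1, c2, c3, c4, c5)


def assign_tier(tr: TierRecord, eqtl_available: bool = True) -> int:
    """Map criterion booleans to a tier (1 best, 4 worst); see module docs."""
    if not eqtl_available:
        tier = 2 if tr.c3 else 4
    elif not tr.c5:
        tier = 4
    else:
        tier = {5: 1, 4: 2, 3: 3}.get(tr.n_passed, 4)
    tr.tier = tier
    return tier


def classify(
    rec: EvidenceRecord,
    thresholds: TierThresholds = TierThresholds(),
) -> TierRecord:
    tr = evaluate_criteria(rec, thresholds)
    assign_tier(tr, rec.eqtl_available)
    return tr


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() in ("", "NA"):
        return None
    return float(v)


def classify_table(
    evidence: pd.DataFrame,
    thresholds: TierThresholds = TierThresholds(),
) -> pd.DataFrame:
    """Classify a whole evidence table (columns as in the packaged example);
    returns it with c1..c5, n_passed and tier appended."""
    rows = []
    for r in evidence.itertuples(index=False):
        rec = EvidenceRecord(
            protein_id=str(r.protein_id),
            outcome_id=str(r.outcome_id),
            mr_or=float(r.mr_or),
            smr_or=_opt(getattr(r, "smr_or", None)),
            p_smr=_opt(getattr(r, "p_smr", None)),
            p_heidi=_opt(getattr(r, "p_heidi", None)),
            pph4_pqtl=_opt(getattr(r, "pph4_pqtl", None)),
            pph4_eqtl=_opt(getattr(r, "pph4_eqtl", None)),
            eqtl_available=_as_bool(getattr(r, "eqtl_available", True)),
        )
        tr = classify(rec, thresholds)
        rows.append({
            "protein_id": tr.protein_id, "outcome_id": tr.outcome_id,
            "c1": tr.c1, "c2": tr.c2, "c3": tr.c3, "c4": tr.c4, "c5": tr.c5,
            "n_passed": tr.n_passed, "tier": tr.tier,
        })
    return pd.DataFrame(rows)


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def load_example_evidence() -> pd.DataFrame:
    """The packaged 12-protein example evidence table (13 rows; one protein
    is significant in two outcome datasets)."""
    with resources.files("protarget_mr.data").joinpath("paper_evidence.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
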