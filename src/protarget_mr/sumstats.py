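"""Summary-statistics data model, file I/O, allele harmonization and
cis-instrument selection.

The instrument filter chain applies, in order: genome-wide significance,
MHC exclusion, cis-window, minor-allele-frequency, instrument strength (F),
LD clumping, and harmonization against the outcome (including unconditional
removal of palindromic variants).  Every dropped variant is logged with the
first filter that removed it, so reruns on identical input reproduce an
identical selection log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "GeneRegion",
    "HarmonizedPair",
    "InstrumentSet",
    "LDMatrix",
    "SelectionConfig",
    "SchemaError",
    "RowParseError",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_regions",
    "harmonize_pair",
    "f_statistic",
    "ld_clump",
    "select_instruments",
    "minor_allele_frequency",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the summary-statistics TSV schema
SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "n_cases", "n_controls",
]

REQUIRED_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


class SchemaError(ValueError):
    """A required column is missing from a summary-statistics file."""


class RowParseError(ValueError):
    """A data row contains an unparsable numeric field."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is on the log-odds scale for binary traits and in SD units for
    quantitative traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf must be in [0,1], got {self.eaf}")
        ea, oa = self.effect_allele, self.other_allele
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be one of A/C/G/T ({ea}/{oa})")
        if ea == oa:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue must be in (0,1], got {self.pvalue}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class GeneRegion:
    """Genomic footprint of a gene / protein-coding sequence (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    def cis_interval(self, window: int) -> tuple[int, int]:
        """[start - window, end + window], the cis-eligibility interval."""
        return self.start - window, self.end + window


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects aligned to a common effect allele."""

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float = math.nan
    eaf_out: float = math.nan
    n_exp: int = 0
    n_out: int = 0

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


@dataclass
class InstrumentSet:
    """Clumped, harmonized instruments for one exposure plus the per-variant
    record of which filter removed each dropped variant."""

    exposure_id: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    selection_log: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]


class LDMatrix:
    """Square matrix of pairwise LD correlations keyed by variant id."""

    def __init__(self, variant_ids: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if r.shape[0] != len(variant_ids):
            raise ValueError("LD matrix dimensions do not match variant_ids")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(r) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self.variant_ids = list(variant_ids)
        self.r = r
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __len__(self) -> int:
        return len(self.variant_ids)

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        try:
            ia, ib = self._index[a], self._index[b]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} absent from LD matrix") from None
        return float(self.r[ia, ib] ** 2)

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass
class SelectionConfig:
    """Thresholds of the cis-instrument filter chain.

    Defaults are the pQTL-stage values; the eQTL stage uses ``maf_min=0.01``.
    """

    p_max: float = 5e-8
    cis_window: int = 1_000_000
    mhc_chrom: str = "6"
    mhc_start: int = 29_000_000
    mhc_end: int = 33_000_000
    r2_max: float = 0.001
    f_min: float = 10.0
    maf_min: float = 0.0
    drop_palindromic: bool = True


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_sumstats(
    path,
    schema: Optional[Mapping[str, str]] = None,
    drop_log: Optional[list[str]] = None,
) -> list[VariantAssociation]:
    """Parse a tab-delimited summary-statistics file into association records.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    schema:
        Optional mapping of canonical column name -> column name in the file,
        for foreign headers (e.g. ``{"variant_id": "SNP"}``).
    drop_log:
        If given, a human-readable line is appended for every row dropped for
        missing beta/se/allele data.

    Rows with missing beta, se or allele fields are dropped (and logged);
    unparsable numerics raise :class:`RowParseError` with the line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {}
    if schema:
        rename = {src: canon for canon, src in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[VariantAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is header
        rec = row._asdict()
        critical = (rec["beta"], rec["se"], rec["effect_allele"], rec["other_allele"])
        if any(str(v).strip() in ("", "NA", "NaN", "nan", ".") for v in critical):
            if drop_log is not None:
                drop_log.append(f"line {i} ({rec['variant_id'] or '?'}): missing data")
            continue
        try:
            records.append(
                VariantAssociation(
                    variant_id=str(rec["variant_id"]),
                    chrom=str(rec["chrom"]),
                    pos=int(float(rec["pos"])),
                    effect_allele=str(rec["effect_allele"]).upper(),
                    other_allele=str(rec["other_allele"]).upper(),
                    eaf=float(rec["eaf"]),
                    beta=float(rec["beta"]),
                    se=float(rec["se"]),
                    pvalue=float(rec["pvalue"]),
                    n=int(float(rec["n"])),
                    n_cases=_opt_int(rec.get("n_cases")),
                    n_controls=_opt_int(rec.get("n_controls")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"line {i}: {exc}") from exc
    return records


def _opt_int(v) -> Optional[int]:
    if v is None or str(v).strip() in ("", "NA", "NaN", "nan", "."):
        return None
    return int(float(v))


def write_sumstats(records: Iterable[VariantAssociation], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "eaf": repr(r.eaf), "beta": repr(r.beta), "se": repr(r.se),
            "pvalue": repr(r.pvalue), "n": r.n,
            "n_cases": "" if r.n_cases is None else r.n_cases,
            "n_controls": "" if r.n_controls is None else r.n_controls,
        })
    pd.DataFrame(rows, columns=SUMSTATS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read a whitespace-delimited square LD matrix with a one-line variant-id header."""
    with open(path) as fh:
        header = fh.readline().split()
        r = np.loadtxt(fh, ndmin=2)
    return LDMatrix(header, r)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.variant_ids) + "\n")
        np.savetxt(fh, ld.r, fmt="%.10g")


def read_gene_regions(path) -> list[GeneRegion]:
    """Read a gene annotation TSV: gene_id, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneRegion(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# harmonization and filters
# ---------------------------------------------------------------------------

def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    drop_palindromic: bool = True,
) -> Union[HarmonizedPair, str]:
    """Align an exposure/outcome record pair to the exposure's effect allele.

    Returns a :class:`HarmonizedPair`, or the string ``"palindromic"`` /
    ``"allele_mismatch"`` if the pair is dropped.  If the outcome alleles are
    swapped relative to the exposure (directly or on the opposite strand) the
    outcome beta is negated and its frequency complemented.
    """
    if exp.variant_id != out.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exp.variant_id!r} vs {out.variant_id!r}"
        )
    if drop_palindromic and exp.is_palindromic():
        return "palindromic"

    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele
    comp_ea_o, comp_oa_o = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]

    if (ea_o, oa_o) == (ea_e, oa_e) or (comp_ea_o, comp_oa_o) == (ea_e, oa_e):
        beta_out, eaf_out = out.beta, out.eaf
    elif (oa_o, ea_o) == (ea_e, oa_e) or (comp_oa_o, comp_ea_o) == (ea_e, oa_e):
        beta_out, eaf_out = -out.beta, 1.0 - out.eaf
    else:
        return "allele_mismatch"

    return HarmonizedPair(
        variant_id=exp.variant_id,
        effect_allele=ea_e,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        n_exp=exp.n,
        n_out=out.n,
    )


def f_statistic(beta: float, se: float) -> float:
    """Approximate single-instrument F statistic, (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def minor_allele_frequency(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def ld_clump(
    assocs: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_max: float = 0.001,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant variant, discard every
    variant with r^2 above the threshold to any kept variant, repeat.

    Ties in p-value break lexicographically by variant id for determinism.
    Output is in ascending-p order among the kept variants.
    """
    for a in assocs:
        if a.variant_id not in ld:
            raise KeyError(f"variant {a.variant_id!r} absent from LD matrix")
    pending = sorted(assocs, key=lambda a: (a.pvalue, a.variant_id))
    kept: list[VariantAssociation] = []
    for cand in pending:
        if all(ld.r2(cand.variant_id, k.variant_id) <= r2_max for k in kept):
            kept.append(cand)
    return kept


def select_instruments(
    assocs: Sequence[VariantAssociation],
    region: GeneRegion,
    ld: LDMatrix,
    cfg: SelectionConfig,
    outcome: Optional[Mapping[str, VariantAssociation]] = None,
) -> InstrumentSet:
    """Run the full cis-instrument filter chain for one exposure.

    ``outcome`` maps variant id -> outcome association; variants missing from
    it are dropped with reason ``missing_outcome``.  When ``outcome`` is None
    only the exposure-side filters run and pairs carry zero outcome effects
    (useful for instrument accounting without an outcome at hand).
    """
    log: dict[str, str] = {}
    lo, hi = region.cis_interval(cfg.cis_window)

    survivors: list[VariantAssociation] = []
    for a in assocs:
        if a.pvalue >= cfg.p_max:
            log[a.variant_id] = "not_significant"
        elif a.chrom == cfg.mhc_chrom and cfg.mhc_start <= a.pos <= cfg.mhc_end:
            log[a.variant_id] = "mhc"
        elif a.chrom != region.chrom or not (lo <= a.pos <= hi):
            log[a.variant_id] = "not_cis"
        elif a.maf <= cfg.maf_min:
            log[a.variant_id] = "low_maf"
        elif f_statistic(a.beta, a.se) <= cfg.f_min:
            log[a.variant_id] = "weak_instrument"
        else:
            survivors.append(a)

    clumped = ld_clump(survivors, ld, cfg.r2_max)
    clumped_ids = {a.variant_id for a in clumped}
    for a in survivors:
        if a.variant_id not in clumped_ids:
            log[a.variant_id] = "ld_clumped"

    pairs: list[HarmonizedPair] = []
    for a in clumped:
        if outcome is None:
            if cfg.drop_palindromic and a.is_palindromic():
                log[a.variant_id] = "palindromic"
                continue
            pairs.append(HarmonizedPair(
                variant_id=a.variant_id, effect_allele=a.effect_allele,
                beta_exp=a.beta, se_exp=a.se, beta_out=0.0, se_out=1.0,
                eaf_exp=a.eaf, n_exp=a.n,
            ))
            log[a.variant_id] = "kept"
            continue
        out_rec = outcome.get(a.variant_id)
        if out_rec is None:
            log[a.variant_id] = "missing_outcome"
            continue
        res = harmonize_pair(a, out_rec, drop_palindromic=cfg.drop_palindromic)
        if isinstance(res, str):
            log[a.variant_id] = res
        else:
            pairs.append(res)
            log[a.variant_id] = "kept"

    return InstrumentSet(exposure_id=region.gene_id, pairs=pairs, selection_log=log)
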