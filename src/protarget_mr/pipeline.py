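"""End-to-end orchestration: discovery MR -> validation (colocalization,
SMR+HEIDI) -> tier classification, over an on-disk study bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocalization import ColocPriors, colocalize
from .mr_core import bh_fdr, classify_significance, run_mr, steiger_filter
from .smr_heidi import heidi_test, smr_test
from .sumstats import (
    GeneRegion,
    SelectionConfig,
    harmonize_pair,
    read_gene_regions,
    read_ld_matrix,
    read_sumstats,
)
from .tiering import EvidenceRecord, classify

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_discovery", "run_validation_and_tier", "run_all"]


@dataclass
class StudyConfig:
    """Paths and thresholds for one study run."""

    bundle_dir: str
    output_dir: str
    outcome_ids: list[str] = dc_field(default_factory=lambda: ["oa"])
    seed: int = 0
    alpha: float = 0.05
    pqtl_selection: SelectionConfig = dc_field(default_factory=SelectionConfig)
    eqtl_selection: SelectionConfig = dc_field(
        default_factory=lambda: SelectionConfig(maf_min=0.01))
    coloc_priors: ColocPriors = dc_field(default_factory=ColocPriors)
    pph4_min: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sel_p = SelectionConfig(**raw.pop("pqtl_selection", {}))
        sel_e = SelectionConfig(**{"maf_min": 0.01, **raw.pop("eqtl_selection", {})})
        priors = ColocPriors(**raw.pop("coloc_priors", {}))
        return cls(pqtl_selection=sel_p, eqtl_selection=sel_e,
                   coloc_priors=priors, **raw)

    def thresholds_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "pph4_min": self.pph4_min,
            "p_max": self.pqtl_selection.p_max,
            "cis_window": self.pqtl_selection.cis_window,
            "r2_max": self.pqtl_selection.r2_max,
            "f_min": self.pqtl_selection.f_min,
            "eqtl_maf_min": self.eqtl_selection.maf_min,
            "coloc_priors": [self.coloc_priors.p1, self.coloc_priors.p2,
                             self.coloc_priors.p12],
        }


def _bundle_paths(cfg: StudyConfig):
    bundle = Path(cfg.bundle_dir)
    return bundle, read_gene_regions(bundle / "annotation.tsv")


def _load_outcome(bundle: Path, outcome_id: str) -> dict:
    recs = read_sumstats(bundle / "gwas" / f"{outcome_id}.tsv")
    return {a.variant_id: a for a in recs}


def _select_for_gene(cfg: StudyConfig, bundle: Path, region: GeneRegion,
                     outcome_by_id: dict):
    from .sumstats import select_instruments

    pqtl = read_sumstats(bundle / "pqtl" / f"{region.gene_id}.tsv")
    ld = read_ld_matrix(bundle / "ld" / f"{region.gene_id}.ld")
    return select_instruments(pqtl, region, ld, cfg.pqtl_selection,
                              outcome=outcome_by_id), pqtl, ld


def run_discovery(cfg: StudyConfig) -> pd.DataFrame:
    """Per protein x outcome: instrument selection, MR, diagnostics, then a
    per-outcome BH-FDR and the significance trichotomy.

    Writes ``discovery.tsv`` and ``volcano.tsv`` under the output directory.
    """
    bundle, regions = _bundle_paths(cfg)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for outcome_id in cfg.outcome_ids:
        outcome_by_id = _load_outcome(bundle, outcome_id)
        for region in regions:
            iset, _, _ = _select_for_gene(cfg, bundle, region, outcome_by_id)
            base = {"exposure": region.gene_id, "outcome": outcome_id}
            if len(iset) == 0:
                rows.append({**base, "status": "no_instruments"})
                continue
            res = run_mr(iset.pairs, region.gene_id, outcome_id)
            pair0 = iset.pairs[0]
            st = steiger_filter(iset.pairs, pair0.n_exp, pair0.n_out)
            rows.append({
                **base, "status": "ok", "method": res.method,
                "n_snps": res.n_snps, "beta": res.beta, "se": res.se,
                "or": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "pvalue": res.pvalue,
                "cochran_q": res.cochran_q, "q_pvalue": res.q_pvalue,
                "egger_intercept": res.egger_intercept,
                "egger_intercept_p": res.egger_intercept_p,
                "steiger_direction": st.direction, "steiger_p": st.pvalue,
            })

    df = pd.DataFrame(rows, columns=[
        "exposure", "outcome", "status", "method", "n_snps", "beta", "se",
        "or", "ci_low", "ci_high", "pvalue", "cochran_q", "q_pvalue",
        "egger_intercept", "egger_intercept_p", "steiger_direction",
        "steiger_p",
    ])
    df["q_fdr"] = pd.NA
    df["significance"] = pd.NA
    for outcome_id in cfg.outcome_ids:
        mask = (df["outcome"] == outcome_id) & (df["status"] == "ok")
        if mask.any():
            qs = bh_fdr(df.loc[mask, "pvalue"].tolist())
            df.loc[mask, "q_fdr"] = qs
            df.loc[mask, "significance"] = [
                classify_significance(p, q, cfg.alpha)
                for p, q in zip(df.loc[mask, "pvalue"], qs)
            ]
    df.to_csv(out_dir / "discovery.tsv", sep="\t", index=False)

    ok = df[df["status"] == "ok"]
    volcano = pd.DataFrame({
        "exposure": ok["exposure"], "outcome": ok["outcome"],
        "log_or": ok["beta"],
        "neg_log10_p": -np.log10(ok["pvalue"].astype(float).clip(lower=1e-300)),
    })
    volcano.to_csv(out_dir / "volcano.tsv", sep="\t", index=False)
    _write_manifest(cfg, out_dir, stage="discovery")
    return df


def run_validation_and_tier(
    cfg: StudyConfig,
    discovery: pd.DataFrame,
    heidi_seed: Optional[int] = None,
) -> pd.DataFrame:
    """For each FDR-significant protein: pQTL and eQTL colocalization with
    the outcome, SMR + HEIDI at the top eQTL, then tier assignment.

    Writes ``tiers.tsv``; returns the tier table.
    """
    bundle, regions = _bundle_paths(cfg)
    by_gene = {r.gene_id: r for r in regions}
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sig = discovery[(discovery["status"] == "ok")
                    & (discovery["significance"] == "significant")]
    rows = []
    for _, d in sig.iterrows():
        gene, outcome_id = d["exposure"], d["outcome"]
        region = by_gene[gene]
        outcome_by_id = _load_outcome(bundle, outcome_id)
        pqtl = read_sumstats(bundle / "pqtl" / f"{gene}.tsv")
        ld = read_ld_matrix(bundle / "ld" / f"{gene}.ld")
        gwas_region = [outcome_by_id[a.variant_id] for a in pqtl
                       if a.variant_id in outcome_by_id]

        pph4_pqtl = None
        try:
            pph4_pqtl = colocalize(pqtl, gwas_region, cfg.coloc_priors,
                                   ("quant", "cc")).pph4
        except ValueError as exc:
            logger.warning("%s/%s pQTL coloc skipped: %s", gene, outcome_id, exc)

        eqtl_path = bundle / "eqtl" / f"{gene}.tsv"
        eqtl_available = eqtl_path.exists()
        smr_or = p_smr = p_heidi = pph4_eqtl = None
        if eqtl_available:
            eqtl = read_sumstats(eqtl_path)
            eligible = [a for a in eqtl if a.pvalue < cfg.eqtl_selection.p_max
                        and a.maf > cfg.eqtl_selection.maf_min]
            if not eligible:
                eqtl_available = False
            else:
                top = min(eligible, key=lambda a: (a.pvalue, a.variant_id))
                gwas_top = outcome_by_id.get(top.variant_id)
                if gwas_top is None:
                    eqtl_available = False
                else:
                    smr = smr_test(top, gwas_top, gene, outcome_id)
                    smr_or, p_smr = smr.or_, smr.p_smr
                    p_heidi, _ = heidi_test(
                        eqtl, gwas_region, ld, top.variant_id,
                        seed=heidi_seed if heidi_seed is not None else cfg.seed,
                    )
                    try:
                        pph4_eqtl = colocalize(eqtl, gwas_region,
                                               cfg.coloc_priors,
                                               ("quant", "cc")).pph4
                    except ValueError as exc:
                        logger.warning("%s/%s eQTL coloc skipped: %s",
                                       gene, outcome_id, exc)

        rec = EvidenceRecord(
            protein_id=gene, outcome_id=outcome_id, mr_or=float(d["or"]),
            smr_or=smr_or, p_smr=p_smr, p_heidi=p_heidi,
            pph4_pqtl=pph4_pqtl, pph4_eqtl=pph4_eqtl,
            eqtl_available=eqtl_available,
        )
        tr = classify(rec)
        rows.append({
            "protein_id": gene, "outcome_id": outcome_id,
            "mr_or": rec.mr_or, "smr_or": smr_or, "p_smr": p_smr,
            "p_heidi": p_heidi, "pph4_pqtl": pph4_pqtl,
            "pph4_eqtl": pph4_eqtl, "eqtl_available": eqtl_available,
            "c1": tr.c1, "c2": tr.c2, "c3": tr.c3, "c4": tr.c4, "c5": tr.c5,
            "n_passed": tr.n_passed, "tier": tr.tier,
        })

    tiers = pd.DataFrame(rows, columns=[
        "protein_id", "outcome_id", "mr_or", "smr_or", "p_smr", "p_heidi",
        "pph4_pqtl", "pph4_eqtl", "eqtl_available",
        "c1", "c2", "c3", "c4", "c5", "n_passed", "tier",
    ])
    tiers.to_csv(out_dir / "tiers.tsv", sep="\t", index=False)
    _write_manifest(cfg, out_dir, stage="validation")
    return tiers


def run_all(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    discovery = run_discovery(cfg)
    tiers = run_validation_and_tier(cfg, discovery)
    return discovery, tiers


def _write_manifest(cfg: StudyConfig, out_dir: Path, stage: str) -> None:
    bundle = Path(cfg.bundle_dir)
    hashes = {}
    for p in sorted(bundle.rglob("*.tsv")):
        hashes[str(p.relative_to(bundle))] = hashlib.sha256(
            p.read_bytes()).hexdigest()[:16]
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": cfg.thresholds_dict(),
        "inputs": hashes,
    }
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
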