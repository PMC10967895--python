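import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protarget_mr.sumstats import (
    GeneRegion,
    LDMatrix,
    RowParseError,
    SchemaError,
    SelectionConfig,
    f_statistic,
    harmonize_pair,
    ld_clump,
    read_ld_matrix,
    read_sumstats,
    select_instruments,
    write_ld_matrix,
)

from .conftest import make_variant


# ---------------------------------------------------------------------------
# read_sumstats
# ---------------------------------------------------------------------------

HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn"


def _write(tmp_path, lines, name="ss.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


def test_read_sumstats_identity_parse(tmp_path):
    path = _write(tmp_path, [
        HEADER,
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-20\t5000",
        "rs2\t1\t200\tC\tT\t0.5\t-0.2\t0.02\t1e-22\t5000",
        "rs3\t2\t300\tG\tA\t0.1\t0.05\t0.03\t0.09\t5000",
    ])
    recs = read_sumstats(path)
    assert len(recs) == 3
    assert recs[0].variant_id == "rs1"
    assert recs[1].beta == -0.2
    assert recs[2].chrom == "2"


def test_read_sumstats_missing_beta_dropped_and_logged(tmp_path):
    path = _write(tmp_path, [
        HEADER,
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-20\t5000",
        "rs2\t1\t200\tC\tT\t0.5\t\t0.02\t1e-22\t5000",
        "rs3\t2\t300\tG\tA\t0.1\t0.05\t0.03\t0.09\t5000",
    ])
    log = []
    recs = read_sumstats(path, drop_log=log)
    assert [r.variant_id for r in recs] == ["rs1", "rs3"]
    assert len(log) == 1 and "rs2" in log[0]


def test_read_sumstats_shuffled_columns(tmp_path):
    canonical = _write(tmp_path, [
        HEADER,
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-20\t5000",
    ], "a.tsv")
    shuffled = _write(tmp_path, [
        "beta\tse\tvariant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tpvalue\tn",
        "0.1\t0.01\trs1\t1\t100\tA\tG\t0.3\t1e-20\t5000",
    ], "b.tsv")
    assert read_sumstats(canonical) == read_sumstats(shuffled)


def test_read_sumstats_missing_column_names_it(tmp_path):
    path = _write(tmp_path, ["variant_id\tchrom\tpos", "rs1\t1\t100"])
    with pytest.raises(SchemaError, match="effect_allele"):
        read_sumstats(path)


def test_read_sumstats_bad_numeric_reports_line(tmp_path):
    path = _write(tmp_path, [
        HEADER,
        "rs1\t1\t100\tA\tG\tnot_a_number\t0.1\t0.01\t1e-20\t5000",
    ])
    with pytest.raises(RowParseError, match="line 2"):
        read_sumstats(path)


def test_read_sumstats_schema_mapping(tmp_path):
    path = _write(tmp_path, [
        "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN",
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-20\t5000",
    ])
    recs = read_sumstats(path, schema={
        "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
        "effect_allele": "A1", "other_allele": "A2", "eaf": "FREQ",
        "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
    })
    assert recs[0].variant_id == "rs1" and recs[0].beta == 0.1


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_harmonize_allele_flip_is_sign_flip():
    exp = make_variant(effect_allele="A", other_allele="G", beta=0.10)
    out = make_variant(effect_allele="G", other_allele="A", beta=-0.05, eaf=0.7)
    pair = harmonize_pair(exp, out)
    assert pair.beta_out == pytest.approx(0.05)
    assert pair.effect_allele == "A"
    assert pair.eaf_out == pytest.approx(0.3)


def test_harmonize_palindromic_dropped():
    exp = make_variant(effect_allele="A", other_allele="T", beta=0.10)
    out = make_variant(effect_allele="A", other_allele="T", beta=0.02)
    assert harmonize_pair(exp, out) == "palindromic"


def test_harmonize_palindromic_kept_when_flag_off():
    exp = make_variant(effect_allele="C", other_allele="G", beta=0.10)
    out = make_variant(effect_allele="C", other_allele="G", beta=0.02)
    pair = harmonize_pair(exp, out, drop_palindromic=False)
    assert pair.beta_out == 0.02


def test_harmonize_identical_alleles_identity():
    exp = make_variant(beta=0.1)
    out = make_variant(beta=0.02, eaf=0.31)
    pair = harmonize_pair(exp, out)
    assert pair.beta_out == 0.02 and pair.eaf_out == 0.31


def test_harmonize_strand_complement():
    exp = make_variant(effect_allele="A", other_allele="G", beta=0.1)
    out = make_variant(effect_allele="T", other_allele="C", beta=0.02)
    pair = harmonize_pair(exp, out)
    assert pair.beta_out == 0.02


def test_harmonize_strand_complement_swapped():
    exp = make_variant(effect_allele="A", other_allele="G", beta=0.1)
    out = make_variant(effect_allele="C", other_allele="T", beta=0.02, eaf=0.8)
    pair = harmonize_pair(exp, out)
    assert pair.beta_out == pytest.approx(-0.02)
    assert pair.eaf_out == pytest.approx(0.2)


def test_harmonize_allele_mismatch():
    exp = make_variant(effect_allele="A", other_allele="G")
    out = make_variant(effect_allele="A", other_allele="C")
    assert harmonize_pair(exp, out) == "allele_mismatch"


def test_harmonize_variant_id_mismatch_raises():
    with pytest.raises(ValueError, match="variant_id"):
        harmonize_pair(make_variant(variant_id="rs1"), make_variant(variant_id="rs2"))


@given(
    beta=st.floats(-1, 1, allow_nan=False),
    eaf=st.floats(0.01, 0.99),
    swap=st.booleans(),
)
@settings(max_examples=50, deadline=None)
def test_harmonize_involutive(beta, eaf, swap):
    """Harmonizing an already-aligned pair changes nothing."""
    exp = make_variant(effect_allele="A", other_allele="G", beta=0.1)
    if swap:
        out = make_variant(effect_allele="G", other_allele="A", beta=-beta,
                           eaf=1 - eaf)
    else:
        out = make_variant(effect_allele="A", other_allele="G", beta=beta, eaf=eaf)
    pair = harmonize_pair(exp, out)
    aligned = make_variant(effect_allele="A", other_allele="G",
                           beta=pair.beta_out, eaf=pair.eaf_out)
    pair2 = harmonize_pair(exp, aligned)
    assert pair2.beta_out == pytest.approx(pair.beta_out)
    assert pair2.eaf_out == pytest.approx(pair.eaf_out)


# ---------------------------------------------------------------------------
# F statistic
# ---------------------------------------------------------------------------

def test_f_statistic_basic():
    assert f_statistic(0.1, 0.01) == pytest.approx(100.0)
    assert f_statistic(0.0, 0.01) == 0.0


def test_f_statistic_boundary_excluded():
    # 0.0316/0.01 = 3.16 -> F = 9.9856, below the F > 10 bar
    f = f_statistic(0.0316, 0.01)
    assert f == pytest.approx(3.16**2)
    assert f < 10


def test_f_statistic_domain_error():
    with pytest.raises(ValueError):
        f_statistic(0.1, 0.0)


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def _ld_from(ids, r):
    return LDMatrix(ids, np.asarray(r, dtype=float))


def test_clump_singleton():
    ld = _ld_from(["rs1"], [[1.0]])
    a = make_variant("rs1", pvalue=1e-12)
    assert ld_clump([a], ld) == [a]


def test_clump_perfect_proxy():
    ld = _ld_from(["rs1", "rs2"], [[1, 1], [1, 1]])
    a = make_variant("rs1", pvalue=1e-12)
    b = make_variant("rs2", pvalue=1e-9)
    assert ld_clump([a, b], ld) == [a]


def test_clump_below_threshold_keeps_both():
    r = np.sqrt(0.0005)
    ld = _ld_from(["rs1", "rs2"], [[1, r], [r, 1]])
    a = make_variant("rs1", pvalue=1e-12)
    b = make_variant("rs2", pvalue=1e-9)
    assert ld_clump([a, b], ld, r2_max=0.001) == [a, b]


def test_clump_missing_variant_named():
    ld = _ld_from(["rs1"], [[1.0]])
    with pytest.raises(KeyError, match="rs2"):
        ld_clump([make_variant("rs2")], ld)


def _brute_force_clump(assocs, ld, r2_max):
    """Independent re-statement of the greedy-by-p rule."""
    remaining = sorted(assocs, key=lambda a: (a.pvalue, a.variant_id))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [a for a in remaining
                     if ld.r2(a.variant_id, best.variant_id) <= r2_max]
    return kept


@pytest.mark.parametrize("seed", range(10))
def test_clump_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 11))
    # random PSD correlation matrix
    a = rng.standard_normal((m, m + 2))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    r = c / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    ids = [f"rs{i}" for i in range(m)]
    ld = _ld_from(ids, r)
    assocs = [make_variant(ids[i], pos=100 * i,
                           pvalue=float(rng.uniform(1e-12, 1e-6)))
              for i in range(m)]
    r2_max = float(rng.choice([0.001, 0.1, 0.5]))
    assert ld_clump(assocs, ld, r2_max) == _brute_force_clump(assocs, ld, r2_max)


# ---------------------------------------------------------------------------
# select_instruments
# ---------------------------------------------------------------------------

REGION = GeneRegion("GENE1", "6", 40_000_000, 40_050_000)


def _outcome_for(assocs):
    return {a.variant_id: make_variant(a.variant_id, chrom=a.chrom, pos=a.pos,
                                       effect_allele=a.effect_allele,
                                       other_allele=a.other_allele,
                                       beta=0.02, se=0.01)
            for a in assocs}


def _identity_ld(assocs):
    ids = [a.variant_id for a in assocs]
    return _ld_from(ids, np.eye(len(ids)))


def test_select_drops_mhc():
    a = make_variant("rs_mhc", chrom="6", pos=30_000_000, pvalue=1e-20)
    region = GeneRegion("G", "6", 29_500_000, 29_600_000)
    iset = select_instruments([a], region, _identity_ld([a]), SelectionConfig(),
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_mhc"] == "mhc"
    assert len(iset) == 0


def test_select_drops_not_cis():
    a = make_variant("rs_far", chrom="6", pos=REGION.end + 1_000_001, pvalue=1e-20)
    iset = select_instruments([a], REGION, _identity_ld([a]), SelectionConfig(),
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_far"] == "not_cis"


def test_select_cis_boundary_inclusive():
    a = make_variant("rs_edge", chrom="6", pos=REGION.end + 1_000_000, pvalue=1e-20)
    iset = select_instruments([a], REGION, _identity_ld([a]), SelectionConfig(),
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_edge"] == "kept"


def test_select_drops_not_significant():
    a = make_variant("rs_weakp", chrom="6", pos=40_000_000, pvalue=6e-8)
    iset = select_instruments([a], REGION, _identity_ld([a]), SelectionConfig(),
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_weakp"] == "not_significant"


def test_select_drops_weak_instrument():
    a = make_variant("rs_weakf", chrom="6", pos=40_000_000, beta=0.0316,
                     se=0.01, pvalue=1e-9)
    iset = select_instruments([a], REGION, _identity_ld([a]), SelectionConfig(),
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_weakf"] == "weak_instrument"


def test_select_maf_filter_eqtl_stage():
    a = make_variant("rs_rare", chrom="6", pos=40_000_000, eaf=0.995, pvalue=1e-20)
    cfg = SelectionConfig(maf_min=0.01)
    iset = select_instruments([a], REGION, _identity_ld([a]), cfg,
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_rare"] == "low_maf"


def test_select_palindromic_logged():
    a = make_variant("rs_pal", chrom="6", pos=40_000_000, effect_allele="A",
                     other_allele="T", pvalue=1e-20)
    iset = select_instruments([a], REGION, _identity_ld([a]), SelectionConfig(),
                              outcome=_outcome_for([a]))
    assert iset.selection_log["rs_pal"] == "palindromic"


def test_select_empty_survivors_is_not_an_error():
    iset = select_instruments([], REGION, _ld_from([], np.empty((0, 0))),
                              SelectionConfig(), outcome={})
    assert len(iset) == 0


def test_selected_instruments_satisfy_all_criteria():
    rng = np.random.default_rng(0)
    assocs = [
        make_variant(f"rs{i}", chrom="6", pos=39_500_000 + i * 10_000,
                     eaf=float(rng.uniform(0.02, 0.98)),
                     beta=float(rng.uniform(-0.3, 0.3)) or 0.1,
                     se=0.01,
                     pvalue=float(rng.uniform(1e-30, 1e-6)))
        for i in range(20)
    ]
    ld = _identity_ld(assocs)
    cfg = SelectionConfig(maf_min=0.01)
    iset = select_instruments(assocs, REGION, ld, cfg, outcome=_outcome_for(assocs))
    by_id = {a.variant_id: a for a in assocs}
    lo, hi = REGION.cis_interval(cfg.cis_window)
    for pair in iset.pairs:
        a = by_id[pair.variant_id]
        assert a.pvalue < cfg.p_max
        assert not (a.chrom == "6" and 29e6 <= a.pos <= 33e6)
        assert lo <= a.pos <= hi
        assert a.maf > cfg.maf_min
        assert f_statistic(a.beta, a.se) > cfg.f_min
        assert not a.is_palindromic()
    kept_ids = iset.variant_ids
    for i, v in enumerate(kept_ids):
        for w in kept_ids[:i]:
            assert ld.r2(v, w) <= cfg.r2_max


def test_selection_log_deterministic():
    rng = np.random.default_rng(1)
    assocs = [
        make_variant(f"rs{i}", chrom="6", pos=39_500_000 + i * 10_000,
                     pvalue=float(rng.uniform(1e-30, 1e-5)))
        for i in range(15)
    ]
    ld = _identity_ld(assocs)
    out = _outcome_for(assocs)
    log1 = select_instruments(assocs, REGION, ld, SelectionConfig(), out).selection_log
    log2 = select_instruments(assocs, REGION, ld, SelectionConfig(), out).selection_log
    assert log1 == log2


# ---------------------------------------------------------------------------
# LD matrix I/O
# ---------------------------------------------------------------------------

def test_ld_matrix_roundtrip(tmp_path):
    r = np.array([[1.0, 0.5], [0.5, 1.0]])
    ld = LDMatrix(["rs1", "rs2"], r)
    path = tmp_path / "test.ld"
    write_ld_matrix(ld, path)
    ld2 = read_ld_matrix(path)
    assert ld2.variant_ids == ["rs1", "rs2"]
    np.testing.assert_allclose(ld2.r, r)


def test_ld_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        LDMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))


def test_variant_validation():
    with pytest.raises(ValueError, match="se"):
        make_variant(se=0.0)
    with pytest.raises(ValueError, match="eaf"):
        make_variant(eaf=1.5)
    with pytest.raises(ValueError, match="identical"):
        make_variant(effect_allele="A", other_allele="A")
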