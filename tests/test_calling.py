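"""Support counting, sex inference, disposition calls, recombination scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pghaplo as pg
from oracles import brute_count, brute_phase, random_table
from pghaplo.calling import (
    DISP_AFFECTED,
    DISP_CARRIER,
    DISP_NORMAL,
    DISP_UNDETERMINED,
    SUPPORT_AMBIG,
    SUPPORT_NOCALL,
)

PARAMS = pg.CallParams()


def _counts(f_x=0, m_x1=0, m_x2=0):
    return pg.SupportCounts(f_x=f_x, m_x1=m_x1, m_x2=m_x2)


# ---------------------------------------------------------------- count_support

def _fresh_clean_family():
    return pg.simulate_family(
        pg.SimulationConfig(n_snps=120, ado_rate=0.0, adi_rate=0.0,
                            sample_fail_rate=0.0, recomb_rate_per_mb=0.0,
                            n_embryos=6, seed=11)
    )


def test_all_no_call_embryo_gives_zero_counts():
    table, locus, _ = _fresh_clean_family()
    phase, _ = pg.classify_sites(table, locus)
    name = table.embryos[0]
    table.calls[name] = [None] * table.n_sites
    counts = pg.count_support(table, name, phase, "M")
    assert (counts.f_x, counts.m_x1, counts.m_x2) == (0, 0, 0)
    assert all(label == SUPPORT_NOCALL for _, label in counts.per_site)


def test_clean_male_embryo_supports_single_haplotype(clean_family):
    """ADO-free male: every usable informative site supports the transmitted
    haplotype and none the other."""
    table, locus, truth = clean_family
    phase, _ = pg.classify_sites(table, locus)
    males = [e for e in table.embryos if truth.embryos[e].sex == "M"]
    assert males
    for name in males:
        et = truth.embryos[name]
        counts = pg.count_support(table, name, phase, "M")
        transmitted = et.transmitted[0]
        n_usable = sum(
            1 for k in phase.indices if table.depths[name][k] > 10
        )
        if transmitted == "X1":
            assert counts.m_x1 == n_usable and counts.m_x2 == 0
        else:
            assert counts.m_x2 == n_usable and counts.m_x1 == 0


def test_minority_support_only_at_corrupted_sites():
    """Every contradicting site traces to a recorded ADO/ADI event."""
    cfg = pg.SimulationConfig(
        n_snps=400, ado_rate=0.08, adi_rate=0.01, sample_fail_rate=0.0,
        recomb_rate_per_mb=0.0, n_embryos=8, seed=31,
    )
    table, locus, truth = pg.simulate_family(cfg)
    phase, _ = pg.classify_sites(table, locus)
    pos_to_idx = {int(p): int(i) for p, i in zip(phase.positions, phase.indices)}
    for name in table.embryos:
        et = truth.embryos[name]
        corrupted = {i for i, _ in et.ado_sites} | set(et.adi_sites)
        counts = pg.count_support(table, name, phase, et.sex)
        for pos, label in counts.per_site:
            if label in ("X1", "X2"):
                i = pos_to_idx[pos]
                if label != et.transmitted[i]:
                    assert i in corrupted


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("sex", ["M", "F"])
def test_count_support_matches_brute_force(seed, sex):
    rng = np.random.default_rng(200 + seed)
    table = random_table(rng, n_sites=200, n_embryos=2)
    locus = pg.TargetLocus(
        chrom="chrX", gene_start=1_000_000, gene_end=1_010_000,
        mutation_pos=1_005_000, mutation_ref="G", mutation_alt="A",
    )
    phase, _ = pg.classify_sites(table, locus)
    maternal, paternal = brute_phase(table)
    for embryo in table.embryos:
        counts = pg.count_support(table, embryo, phase, sex)
        f_x, m_x1, m_x2, labels = brute_count(table, embryo, maternal, paternal, sex, 10)
        assert (counts.f_x, counts.m_x1, counts.m_x2) == (f_x, m_x1, m_x2)
        assert counts.per_site == labels
        assert counts.m_x1 + counts.m_x2 <= phase.n_informative


# ------------------------------------------------------------------- infer_sex

def test_sry_flag_is_authoritative(clean_family):
    table, locus, _ = clean_family
    phase, _ = pg.classify_sites(table, locus)
    name = table.embryos[0]
    assert pg.infer_sex(table, name, phase, sry_flag=True) == "M"
    assert pg.infer_sex(table, name, phase, sry_flag=False) == "F"


def test_sex_recovered_on_clean_family(clean_family):
    table, locus, truth = clean_family
    phase, _ = pg.classify_sites(table, locus)
    for name in table.embryos:
        assert pg.infer_sex(table, name, phase) == truth.embryos[name].sex


def test_all_no_call_embryo_sex_unknown():
    table, locus, _ = _fresh_clean_family()
    phase, _ = pg.classify_sites(table, locus)
    name = table.embryos[0]
    table.calls[name] = [None] * table.n_sites
    assert pg.infer_sex(table, name, phase) == "unknown"


# ----------------------------------------------------------------- call_embryo

@pytest.mark.parametrize(
    "fx,m1,m2,sex,mutant,hap,disp",
    [
        (0, 137, 1, "M", "X2", "X1", DISP_NORMAL),   # strong male call
        (2, 26, 0, "F", "X2", "X1", DISP_NORMAL),    # smallest called winner
        (0, 0, 0, "F", "X2", None, DISP_UNDETERMINED),
        (0, 50, 50, "F", "X2", None, DISP_UNDETERMINED),  # exact tie
        (0, 9, 0, "M", "X2", None, DISP_UNDETERMINED),    # below min_informative
        (0, 90, 10, "M", "X2", None, DISP_UNDETERMINED),  # 10% minority
        (0, 1, 137, "M", "X2", "X2", DISP_AFFECTED),      # mutant-linked male
        (0, 1, 137, "F", "X2", "X2", DISP_CARRIER),       # mutant-linked female
    ],
)
def test_call_embryo_decision_rule(fx, m1, m2, sex, mutant, hap, disp):
    call = pg.call_embryo(_counts(fx, m1, m2), sex, mutant, PARAMS)
    assert call.haplotype == hap
    assert call.disposition == disp


def test_mutant_haplotype_with_unknown_sex_cannot_be_disposed():
    call = pg.call_embryo(_counts(0, 0, 80), "unknown", "X2", PARAMS)
    assert call.disposition == DISP_UNDETERMINED
    assert call.undetermined_reason == "sex_unknown"
    call2 = pg.call_embryo(_counts(0, 80, 0), "unknown", "X2", PARAMS)
    assert call2.disposition == DISP_NORMAL  # non-mutant haplotype: sex moot


@settings(max_examples=200, derandomize=True)
@given(
    m1=st.integers(0, 300), m2=st.integers(0, 300), extra=st.integers(1, 100),
    sex=st.sampled_from(["M", "F"]), mutant=st.sampled_from(["X1", "X2"]),
)
def test_increasing_winner_never_uncalls(m1, m2, extra, sex, mutant):
    """Monotonicity: adding support to the winner keeps the call."""
    call = pg.call_embryo(_counts(0, m1, m2), sex, mutant, PARAMS)
    if call.haplotype is None:
        return
    if m1 > m2:
        boosted = _counts(0, m1 + extra, m2)
    else:
        boosted = _counts(0, m1, m2 + extra)
    call2 = pg.call_embryo(boosted, sex, mutant, PARAMS)
    assert call2.haplotype == call.haplotype
    assert call2.disposition == call.disposition


@settings(max_examples=200, derandomize=True)
@given(
    m1=st.integers(0, 200), m2=st.integers(0, 200),
    sex=st.sampled_from(["M", "F"]), mutant=st.sampled_from(["X1", "X2"]),
)
def test_haplotype_relabelling_symmetry(m1, m2, sex, mutant):
    """Swapping X1<->X2 everywhere flips the label, leaves disposition fixed."""
    flip = {"X1": "X2", "X2": "X1"}
    a = pg.call_embryo(_counts(0, m1, m2), sex, mutant, PARAMS)
    b = pg.call_embryo(_counts(0, m2, m1), sex, flip[mutant], PARAMS)
    assert b.haplotype == (flip[a.haplotype] if a.haplotype else None)
    assert b.disposition == a.disposition


# ------------------------------------------------------- recombination scan

def _vector(*chunks, start=1_000_000, step=1_000):
    """Build a per-site vector from (label, count) chunks."""
    out, pos = [], start
    for label, n in chunks:
        for _ in range(n):
            out.append((pos, label))
            pos += step
    return out


def test_single_run_has_no_breakpoint():
    assert pg.detect_recombination(_vector(("X1", 20))) == []


def test_clean_switch_yields_one_breakpoint_in_gap():
    v = _vector(("X1", 10), ("X2", 10))
    bps = pg.detect_recombination(v)
    assert len(bps) == 1
    lo, hi = bps[0]
    assert lo == v[9][0] and hi == v[10][0]


def test_short_artifact_run_is_ignored():
    v = _vector(("X1", 10), ("X2", 2), ("X1", 10))
    assert pg.detect_recombination(v) == []


def test_ambiguous_sites_do_not_break_runs():
    v = _vector(("X1", 5), (SUPPORT_AMBIG, 3), ("X1", 5), ("X2", 6))
    bps = pg.detect_recombination(v)
    assert len(bps) == 1


def test_simulated_crossover_is_localised():
    cfg = pg.SimulationConfig(
        n_snps=200, ado_rate=0.0, adi_rate=0.0, sample_fail_rate=0.0,
        recomb_rate_per_mb=0.8, n_embryos=20, seed=41,
    )
    table, locus, truth = pg.simulate_family(cfg)
    phase, _ = pg.classify_sites(table, locus)
    checked = 0
    for name in table.embryos:
        et = truth.embryos[name]
        if len(et.crossovers) != 1:
            continue
        xo = et.crossovers[0]
        flank_left = int((phase.positions < xo).sum())
        flank_right = int((phase.positions > xo).sum())
        if min(flank_left, flank_right) < PARAMS.recomb_min_segment:
            continue
        counts = pg.count_support(table, name, phase, et.sex)
        bps = pg.detect_recombination(counts.per_site)
        assert any(lo <= xo <= hi for lo, hi in bps)
        checked += 1
    assert checked >= 3


def test_mutation_inside_breakpoint_gap_is_unsafe():
    v = _vector(("X1", 10), ("X2", 10))
    bps = pg.detect_recombination(v)
    mid = (bps[0][0] + bps[0][1]) // 2
    assert pg.mutation_segment_unsafe(v, bps, mid)
    assert not pg.mutation_segment_unsafe(v, bps, v[2][0])  # deep in left run


def test_no_breakpoints_is_always_safe():
    assert not pg.mutation_segment_unsafe(_vector(("X1", 20)), [], 1_004_000)


# ------------------------------------------------------------ direct PCR test

@pytest.mark.parametrize(
    "genotype,sry,sex,disp",
    [
        ("alt", True, "M", DISP_AFFECTED),
        ("ref", True, "M", DISP_NORMAL),
        ("het", False, "F", DISP_CARRIER),
        ("ref", False, "F", DISP_NORMAL),
        ("failed", True, "unknown", DISP_UNDETERMINED),
        ("failed", False, "unknown", DISP_UNDETERMINED),
    ],
)
def test_direct_test_interpretation(genotype, sry, sex, disp):
    call = pg.interpret_direct_test(genotype, sry)
    assert call.sex == sex
    assert call.disposition == disp


def test_direct_test_sry_het_is_inconsistent():
    with pytest.raises(pg.DirectTestInconsistencyError):
        pg.interpret_direct_test("het", True)


def test_direct_test_rejects_unknown_genotype_code():
    with pytest.raises(pg.ConfigError):
        pg.interpret_direct_test("hom", True)
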