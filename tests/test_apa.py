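"""APA detection: site calls, usage fractions, Fisher/BH testing, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

from sciso.apa import (
    APASiteCall,
    APAUsage,
    UntestableGene,
    UTRCoverage,
    UTRRegion,
    apa_table,
    build_utr_regions,
    compare_conditions,
    compute_usage,
    find_distal_site,
    find_proximal_site,
)
from sciso.models import TranscriptModel

# ---------------------------------------------------------------------------
# Oracles


def oracle_proximal(w: np.ndarray, L_star: int) -> tuple[int, int, float]:
    """Direct evaluation of the coverage-gap objective over every (c, P)."""
    best = (-1.0, None, None)
    for c in range(w.shape[0]):
        for P in range(51, L_star - 50 + 1):
            after = np.mean([w[c][P + i - 1] for i in range(1, 51)])
            before = np.mean([w[c][P - i - 1] for i in range(1, 51)])
            obj = (after - before) ** 2
            if obj > best[0]:  # first maximum: smallest P, then smallest c
                best = (obj, P, c)
    # re-order tie-break: smallest P then c across equal objectives
    ties = []
    for c in range(w.shape[0]):
        for P in range(51, L_star - 50 + 1):
            after = np.mean([w[c][P + i - 1] for i in range(1, 51)])
            before = np.mean([w[c][P - i - 1] for i in range(1, 51)])
            if abs((after - before) ** 2 - best[0]) < 1e-12:
                ties.append((P, c))
    P, c = min(ties)
    return P, c, best[0]


def oracle_fisher_two_sided(table) -> float:
    """Hypergeometric enumeration over all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, n1 = a + b, a + c
    N = a + b + c + d
    rv = hypergeom(N, r1, n1)
    support = np.arange(max(0, r1 + n1 - N), min(r1, n1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def _cov(arrays: list[list[float]], conditions=None, gene="g1") -> UTRCoverage:
    w = np.asarray(arrays, dtype=float)
    conditions = conditions or [f"c{i + 1}" for i in range(w.shape[0])]
    region = UTRRegion(gene, "chr1", "+", 0, w.shape[1])
    return UTRCoverage(region=region, conditions=conditions, w=w)


STEP = _cov([[20.0] * 100 + [12.0] * 100])  # step 20 -> 12 at position 100


# ---------------------------------------------------------------------------
# Worked example


def test_step_profile_worked_example():
    """20/12 step: L*=200, P*=100, W_d=12, W_p=20, F=0.375."""
    L_star = find_distal_site(STEP, threshold=10)
    assert L_star == 200
    site = find_proximal_site(STEP, L_star)
    assert site.P_star == 100 and site.C_star == "c1"
    usage = compute_usage(STEP, site, "c1")
    assert usage.W_d == pytest.approx(12.0)
    assert usage.W_p == pytest.approx(20.0)
    assert usage.F == pytest.approx(0.375)


def test_proximal_site_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        w = rng.integers(0, 40, size=(2, 250)).astype(float)
        cov = _cov(w.tolist())
        L_star = find_distal_site(cov, threshold=10)
        site = find_proximal_site(cov, L_star)
        P_exp, c_exp, _ = oracle_proximal(w, L_star)
        assert (site.P_star, cov.conditions.index(site.C_star)) == (P_exp, c_exp)


def test_distal_threshold_is_strict():
    cov = _cov([[10.0] * 200])
    with pytest.raises(UntestableGene):
        find_distal_site(cov, threshold=10)


def test_distal_site_any_condition():
    w = [[0.0] * 200, [0.0] * 150 + [15.0] * 50]
    cov = _cov(w)
    assert find_distal_site(cov, threshold=10) == 200


def test_flat_profile_degenerate_tiebreak():
    cov = _cov([[20.0] * 200])
    site = find_proximal_site(cov, 200)
    assert site.degenerate and site.P_star == 51


def test_step_in_condition_two_sets_c_star():
    w = [[20.0] * 200, [30.0] * 100 + [5.0] * 100]
    cov = _cov(w)
    site = find_proximal_site(cov, find_distal_site(cov, 10))
    assert site.C_star == "c2" and site.P_star == 100


def test_flat_profile_usage_fixed_point():
    cov = _cov([[20.0] * 200])
    usage = compute_usage(cov, APASiteCall(200, 100, "c1", True), "c1")
    assert usage.F == pytest.approx(0.5)


def test_zero_coverage_condition_excluded():
    cov = _cov([[20.0] * 100 + [12.0] * 100, [0.0] * 200])
    site = find_proximal_site(cov, 200)
    u1 = compute_usage(cov, site, "c1")
    u2 = compute_usage(cov, site, "c2")
    assert u2.F is None
    with pytest.raises(UntestableGene):
        compare_conditions("g1", site, u1, u2)


# ---------------------------------------------------------------------------
# Comparison


def test_identical_usages_null():
    site = APASiteCall(200, 100, "c1")
    u = APAUsage("c1", 12.0, 20.0, 0.375)
    v = APAUsage("c2", 12.0, 20.0, 0.375)
    comp = compare_conditions("g1", site, u, v)
    assert comp.fraction_change == 0.0
    assert comp.p_value == pytest.approx(1.0)


def test_fisher_p_matches_hypergeometric_enumeration():
    site = APASiteCall(200, 100, "c1")
    u = APAUsage("c1", 12.0, 20.0, 12 / 32)
    v = APAUsage("c2", 20.0, 12.0, 20 / 32)
    comp = compare_conditions("g1", site, u, v)
    assert comp.p_value == pytest.approx(oracle_fisher_two_sided([[12, 20], [20, 12]]))


def test_fraction_change_sign_convention():
    site = APASiteCall(200, 100, "c1")
    u = APAUsage("c1", 90.0, 10.0, 0.9)
    v = APAUsage("c2", 30.0, 70.0, 0.3)
    comp = compare_conditions("g1", site, u, v)
    assert comp.fraction_change == pytest.approx(0.6)  # lengthening is positive


def test_fraction_change_antisymmetric():
    site = APASiteCall(200, 100, "c1")
    u = APAUsage("c1", 90.0, 10.0, 0.9)
    v = APAUsage("c2", 30.0, 70.0, 0.3)
    fwd = compare_conditions("g1", site, u, v)
    rev = compare_conditions("g1", site, v, u)
    assert fwd.fraction_change == pytest.approx(-rev.fraction_change)
    assert fwd.p_value == pytest.approx(rev.p_value)


def test_scaling_coverage_leaves_f_unchanged():
    for scale in (1.0, 3.0, 10.0):
        cov = _cov((np.array([[20.0] * 100 + [12.0] * 100]) * scale).tolist())
        site = find_proximal_site(cov, find_distal_site(cov, 10))
        assert compute_usage(cov, site, "c1").F == pytest.approx(0.375)


# ---------------------------------------------------------------------------
# BH adjustment and direction


def _comp(gene, p, fc=0.5):
    return compare_from_values(gene, p, fc)


def compare_from_values(gene, p, fc):
    from sciso.apa import APAComparison

    return APAComparison(
        gene_id=gene, condition_pair=("c1", "c2"), fraction_change=fc,
        p_value=p, F_c1=0.6, F_c2=0.1, L_star=200, P_star=100, C_star="c1",
    )


def test_bh_single_gene_identity():
    table = apa_table([_comp("g1", 0.03)])
    assert table.loc[0, "p_adjusted"] == pytest.approx(0.03)


def test_bh_step_up_hand_computation():
    ps = [0.01, 0.02, 0.04, 0.8]
    table = apa_table([_comp(f"g{i}", p) for i, p in enumerate(ps)])
    adjusted = table.sort_values("p_value")["p_adjusted"].tolist()
    assert adjusted == pytest.approx([0.04, 0.04, 0.8 / 15, 0.8])


def test_direction_calls():
    table = apa_table(
        [_comp("g1", 1e-5, fc=0.4), _comp("g2", 1e-5, fc=-0.4), _comp("g3", 0.9, fc=0.4)]
    )
    directions = dict(zip(table["gene_id"], table["direction"]))
    assert directions == {"g1": "lengthened", "g2": "shortened", "g3": "none"}


def test_empty_table():
    assert len(apa_table([])) == 0


# ---------------------------------------------------------------------------
# UTR region construction


def _tx(tid, blocks, utr3, strand="+", gene="g1"):
    return TranscriptModel(tid, gene, "chr1", strand, blocks, utr3=utr3)


def test_same_start_utrs_merge_to_union():
    t1 = _tx("t1", [(0, 100), (200, 500)], (300, 500))
    t2 = _tx("t2", [(0, 100), (200, 420)], (300, 420))
    regions = build_utr_regions([t1, t2])
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (300, 500)


def test_different_start_overlapping_utrs_dropped():
    t1 = _tx("t1", [(0, 100), (200, 500)], (300, 500))
    t2 = _tx("t2", [(0, 100), (250, 480)], (350, 480))
    assert build_utr_regions([t1, t2]) == []


def test_non_overlapping_alternative_last_exons_retained():
    t1 = _tx("t1", [(0, 100), (200, 500)], (300, 500))
    t2 = _tx("t2", [(0, 100), (700, 1000)], (800, 1000))
    regions = build_utr_regions([t1, t2])
    assert len(regions) == 2


def test_minus_strand_same_5prime_start_is_the_high_coordinate():
    t1 = _tx("t1", [(300, 700), (800, 900)], (300, 700), strand="-")
    t2 = _tx("t2", [(400, 700), (800, 900)], (400, 700), strand="-")
    regions = build_utr_regions([t1, t2])  # same 5' start (700) -> union
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (300, 700)
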