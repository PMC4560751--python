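"""Filter cascade: depth calibration, missingness, repeat classes, HWE."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import panelforge as pf
from panelforge.filters import (
    UncalibratableSampleError,
    apply_depth_filter,
    depth_concordance,
    genotype_r2,
    hwe_exact_test,
    hwe_filter,
    locus_missingness_filter,
    overall_precision,
    per_individual_load,
    repeat_class_filter,
    repeat_class_precision,
    run_cascade,
    select_depth_range,
    tool_intersection_filter,
    DEPTH_UNBOUNDED,
)
from panelforge.types import MISSING

from conftest import full_truth, make_matrix


# ---------------------------------------------------------------------------
# depth concordance and range selection


def test_perfect_concordance_single_bin():
    gt = np.ones((100, 1), dtype=np.int8)
    m = make_matrix(gt, depth=np.full((100, 1), 30))
    table = depth_concordance(m, full_truth(m), "S0", min_bin_sites=1)
    assert len(table) == 1
    row = table.iloc[0]
    assert row.precision == 1.0 and row.recall == 1.0
    assert row.d_lo == 30


def test_precision_is_concordant_over_calls():
    # 1000 het calls at depth 30, 3 of them discordant with the array
    gt = np.ones((1000, 1), dtype=np.int8)
    truth_gt = gt.copy()
    truth_gt[:3, 0] = 0
    m = make_matrix(gt, depth=np.full((1000, 1), 30))
    table = depth_concordance(m, full_truth(m, truth_gt), "S0",
                              min_bin_sites=1)
    assert table.iloc[0].precision == pytest.approx(0.997)


def test_no_truth_overlap_raises():
    m = make_matrix([[1], [1]])
    empty = pf.ArrayTruth(np.full((2, 1), MISSING, dtype=np.int8))
    with pytest.raises(ValueError, match="no array truth"):
        depth_concordance(m, empty, "S0")


def test_planted_low_depth_errors_separate_by_bin():
    """Seeded cohort with 40x error below depth 8: per-bin precision sits
    below the floor in low bins and above it at normal depth, and every
    table entry equals a direct count of the planted outcomes."""
    mat, truth, _, sim = pf.simulate_cohort(
        n_samples=5, n_sites=40_000, mean_depth=14.0, nb_dispersion=20.0,
        base_error=5e-5, low_depth_cutoff=8, low_depth_multiplier=400.0,
        hwe_artifact_fraction=0.0, array_ascertained=False,
        array_truth_fraction=1.0,
        repeat_error_multipliers={k: 1.0 for k in
                                  pf.simulate.DEFAULT_REPEAT_ERROR_MULTIPLIERS},
        seed=5,
    )
    sample = mat.samples[0]
    table = depth_concordance(mat, truth, sample, min_bin_sites=1)
    low = table[(table.d_hi < 8) & (table.n_calls >= 100)]
    mid = table[(table.d_lo >= 8) & (table.n_calls >= 300)]
    assert len(low) >= 3 and len(mid) >= 5
    assert (low.precision < 0.998).all()
    assert (mid.precision > 0.998).all()
    # direct brute-force count for one bin
    j = mat.samples.index(sample)
    for _, row in table.iloc[:5].iterrows():
        depths = mat.depth[:, j]
        in_bin = (depths >= row.d_lo) & (depths <= row.d_hi)
        calls = in_bin & np.isin(mat.genotype[:, j], (1, 2)) \
            & (truth.genotype[:, j] != MISSING)
        conc = calls & (mat.genotype[:, j] == truth.genotype[:, j])
        assert row.n_calls == calls.sum()
        assert row.n_concordant == conc.sum()


def _table(rows):
    return pd.DataFrame([
        {"d_lo": lo, "d_hi": hi, "n_calls": n, "n_concordant": int(n * p),
         "precision": p, "n_array_variant": n, "n_recovered": n, "recall": 1.0}
        for lo, hi, n, p in rows
    ])


def test_select_longest_contiguous_run():
    rows = [(d, d, 100, 0.999 if 12 <= d <= 80 else 0.99)
            for d in range(5, 91)]
    r = select_depth_range(_table(rows), "s")
    assert (r.d_lo, r.d_hi) == (12, 80)


def test_select_all_pass_returns_observed_span():
    rows = [(d, d, 100, 1.0) for d in (7, 8, 9, 40, 41)]
    r = select_depth_range(_table(rows), "s")
    assert (r.d_lo, r.d_hi) == (7, 41)


def test_select_prefers_longer_run():
    rows = ([(d, d, 10, 0.999) for d in range(10, 15)]      # run of 5
            + [(15, 15, 10, 0.5)]
            + [(d, d, 10, 0.999) for d in range(16, 25)])   # run of 9
    r = select_depth_range(_table(rows), "s")
    assert (r.d_lo, r.d_hi) == (16, 24)


def test_select_tie_broken_by_calls():
    rows = ([(d, d, 10, 0.999) for d in range(10, 13)]
            + [(13, 13, 10, 0.5)]
            + [(d, d, 99, 0.999) for d in range(14, 17)])
    r = select_depth_range(_table(rows), "s")
    assert (r.d_lo, r.d_hi) == (14, 16)


def test_select_no_passing_bin_raises():
    with pytest.raises(UncalibratableSampleError):
        select_depth_range(_table([(10, 10, 100, 0.99)]), "s")


def test_depth_filter_boundaries_inclusive():
    m = make_matrix([[1], [1], [1]], depth=[[5], [12], [80]])
    r = pf.DepthRange("S0", 12, 80)
    out, masked = apply_depth_filter(m, {"S0": r})
    assert out.genotype[:, 0].tolist() == [MISSING, 1, 1]
    assert masked == 1
    assert np.array_equal(out.depth, m.depth)  # depths unchanged


def test_depth_filter_mask_count_matches_brute_force(rng):
    gt = rng.integers(0, 3, size=(300, 4)).astype(np.int8)
    dp = rng.integers(0, 100, size=(300, 4))
    m = make_matrix(gt, depth=dp)
    ranges = {s: pf.DepthRange(s, 10, 60) for s in m.samples}
    out, masked = apply_depth_filter(m, ranges)
    expect = ((dp < 10) | (dp > 60)).sum()
    assert masked == expect
    assert (out.genotype == MISSING).sum() == expect


def test_depth_filter_drops_flagged_samples():
    m = make_matrix([[1, 1]], depth=[[30, 30]])
    out, _ = apply_depth_filter(m, {"S0": pf.DepthRange("S0", 0, 99),
                                    "S1": None})
    assert out.samples == ["S0"]


# ---------------------------------------------------------------------------
# missingness


def test_missingness_boundary_at_ten_percent():
    row_kept = [MISSING] * 107 + [1] * 963    # exactly 10.0%: retained
    row_gone = [MISSING] * 108 + [1] * 962    # strictly above: removed
    m = make_matrix([row_kept, row_gone])
    out = locus_missingness_filter(m, max_missing=0.10)
    assert out.n_sites == 1
    assert out.sites[0].pos == m.sites[0].pos


def test_missingness_no_missing_unchanged():
    m = make_matrix([[0, 1, 2], [1, 1, 1]])
    assert locus_missingness_filter(m) == m


def test_missingness_small_cohort():
    m = make_matrix([[MISSING, MISSING] + [1] * 8])
    assert locus_missingness_filter(m).n_sites == 0


# ---------------------------------------------------------------------------
# repeat classes


def _class_matrix(n_errors, n_calls=1000, cls="Simple_repeat"):
    gt = np.ones((n_calls, 1), dtype=np.int8)
    truth_gt = gt.copy()
    truth_gt[:n_errors, 0] = 0
    m = make_matrix(gt, repeat_classes=[cls] * n_calls)
    return m, full_truth(m, truth_gt)


def test_repeat_class_boundary_exact():
    # precision exactly 0.997 -> removed; 0.998 -> retained
    m, t = _class_matrix(3)
    assert repeat_class_filter(m, t, min_precision=0.997).n_sites == 0
    m, t = _class_matrix(2)
    assert repeat_class_filter(m, t, min_precision=0.997).n_sites == 1000


def test_repeat_class_clean_classes_untouched():
    m, t = _class_matrix(0, cls="none")
    assert repeat_class_filter(m, t) == m


def test_planted_high_error_class_removed_exactly(rng):
    """Only the class with planted errors is removed, and the removal set
    equals the planted site set."""
    mat, truth, _, sim = pf.simulate_cohort(
        n_samples=80, n_sites=6000, base_error=4e-5,
        repeat_error_multipliers={
            **{k: 1.0 for k in pf.simulate.DEFAULT_REPEAT_ERROR_MULTIPLIERS},
            "Simple_repeat": 400.0,
        },
        repeat_proportions={"none": 0.8, "Simple_repeat": 0.2},
        hwe_artifact_fraction=0.0, array_ascertained=False,
        array_truth_fraction=1.0, seed=9,
    )
    out = repeat_class_filter(mat, truth)
    planted = {s.key for s in mat.sites
               if s.repeat_class == pf.RepeatClass.SIMPLE_REPEAT}
    removed = set(mat.site_keys()) - set(out.site_keys())
    assert removed == planted


def test_tool_intersection_set_arithmetic(small_cohort):
    mat = small_cohort[0]
    keys = mat.site_keys()
    assert tool_intersection_filter(mat, set(keys)) == mat
    assert tool_intersection_filter(mat, set()).n_sites == 0
    subset = set(keys[::3])
    out = tool_intersection_filter(mat, subset)
    assert out.n_sites == len(subset)
    assert mat.n_sites - out.n_sites == len(set(keys) - subset)


# ---------------------------------------------------------------------------
# HWE exact test


def _hwe_oracle(a, h, b):
    """Exact enumeration with integer arithmetic: weight(h') = multinomial
    coefficient x 2^h' over all attainable heterozygote counts."""
    n = a + h + b
    n_minor = min(2 * b + h, 2 * a + h)

    def weight(hh):
        aa = (2 * n - n_minor - hh) // 2
        bb = (n_minor - hh) // 2
        num = 1
        # n! / (aa! hh! bb!) * 2^hh, exact
        from math import factorial
        return (factorial(n) * 2**hh
                // (factorial(aa) * factorial(hh) * factorial(bb)))

    hs = range(n_minor % 2, n_minor + 1, 2)
    ws = {hh: weight(hh) for hh in hs}
    total = sum(ws.values())
    w_obs = ws[h]
    return float(Fraction(sum(w for w in ws.values() if w <= w_obs), total))


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


@given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
def test_hwe_symmetric_in_homozygotes(a, h, b):
    if a + h + b == 0:
        return
    assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a))


def test_hwe_matches_enumeration_small_tables():
    for total in range(1, 13):
        for a in range(total + 1):
            for h in range(total - a + 1):
                b = total - a - h
                got = hwe_exact_test(a, h, b)
                want = _hwe_oracle(a, h, b)
                assert got == pytest.approx(want, abs=1e-12), (a, h, b)
                assert 0 < got <= 1.0


def test_hwe_filter_retains_all_missing_site():
    m = make_matrix([[MISSING, MISSING], [1, 1]])
    out, p = hwe_filter(m)
    assert out.n_sites == 2
    assert np.isnan(p[0]) and not np.isnan(p[1])


# ---------------------------------------------------------------------------
# r2 and cascade


def test_r2_identity_and_anticorrelation():
    x = np.array([0, 1, 2, 1, 0, 2])
    assert genotype_r2(x, x) == pytest.approx(1.0)
    assert genotype_r2(2 - x, x) == pytest.approx(1.0)


def test_r2_zero_variance_is_nan():
    assert np.isnan(genotype_r2(np.array([1, 1, 1]), np.array([0, 1, 2])))


def test_r2_matches_two_pass_formula(rng):
    calls = rng.integers(0, 3, size=500)
    truth = np.clip(calls + rng.integers(-1, 2, size=500), 0, 2)
    calls[rng.random(500) < 0.1] = MISSING
    ok = calls != MISSING
    x, y = calls[ok].astype(float), truth[ok].astype(float)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    want = sxy**2 / (((x - x.mean())**2).sum() * ((y - y.mean())**2).sum())
    assert genotype_r2(calls, truth) == pytest.approx(want)


def test_cascade_empty_input():
    m = make_matrix(np.empty((0, 3), dtype=np.int8),
                    depth=np.empty((0, 3), dtype=int))
    out, rep = run_cascade(m, pf.ArrayTruth(m.genotype.copy()), set())
    assert out.n_sites == 0
    assert all(s.sites_in == 0 and s.sites_out == 0 for s in rep.steps)


def test_cascade_identity_on_clean_fixture():
    gt = np.ones((6, 3), dtype=np.int8)
    m = make_matrix(gt, depth=np.full((6, 3), 30))
    out, rep = run_cascade(m, full_truth(m), set(m.site_keys()))
    assert out == m
    assert rep.cells_masked == 0 and rep.samples_dropped == []


def test_cascade_steps_never_increase_sites(small_cohort):
    mat, truth, sens, _ = small_cohort
    cfg = pf.RunConfig(min_bin_sites=50)
    out, rep = run_cascade(mat, truth, sens, cfg)
    counts = [s.sites_in for s in rep.steps] + [rep.steps[-1].sites_out]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    for s in rep.steps:
        assert s.fraction_removed == pytest.approx(
            (s.sites_in - s.sites_out) / s.sites_in if s.sites_in else 0.0)


def test_single_step_filters_idempotent(small_cohort):
    mat, truth, sens, _ = small_cohort
    once = locus_missingness_filter(mat)
    assert locus_missingness_filter(once) == once
    once = tool_intersection_filter(mat, set(list(sens)[:500]))
    assert tool_intersection_filter(once, set(list(sens)[:500])) == once
    once = repeat_class_filter(mat, truth)
    # second pass recomputes on surviving truth rows
    keep = np.array([k in set(once.site_keys()) for k in mat.site_keys()])
    assert repeat_class_filter(once, truth.subset_sites(keep)) == once


# ---------------------------------------------------------------------------
# per-individual load


def test_load_single_site_all_het():
    m = make_matrix([[1, 1, 1]])
    res = per_individual_load(m, lambda s: True, zygosity="het")
    assert res["mean"] == 1.0 and res["sd"] == 0.0


def test_load_empty_predicate():
    m = make_matrix([[1, 2], [0, 1]])
    res = per_individual_load(m, lambda s: False)
    assert res["mean"] == 0.0
    assert set(res["counts"].values()) == {0}


def test_load_matches_direct_tabulation(rng):
    gt = rng.integers(-1, 3, size=(120, 9)).astype(np.int8)
    cats = rng.choice(["intergenic", "nonsynonymous"], size=120)
    m = make_matrix(gt, categories=list(cats))
    pred = lambda s: s.functional_category == pf.FunctionalCategory.NONSYNONYMOUS
    for zyg, codes in (("het", (1,)), ("hom", (2,)), ("any", (1, 2))):
        res = per_individual_load(m, pred, zygosity=zyg)
        mask = cats == "nonsynonymous"
        want = np.isin(gt[mask], codes).sum(axis=0)
        assert list(res["counts"].values()) == want.tolist()
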