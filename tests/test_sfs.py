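"""Hypergeometric projection, folded spectra, FVRV and exact tests."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

import panelforge as pf
from panelforge.sfs import (
    FoldedSFS,
    SiteCount,
    clopper_pearson,
    compare_fractions,
    fisher_2x2,
    fvrv,
    maf_bin,
    project_sfs,
    project_site,
    projection_sample_size,
    site_counts,
)
from panelforge.types import MISSING

from conftest import make_matrix


def enumeration_projection(i, two_n, two_m, fold=True):
    """Brute-force oracle: distribution of minor copies over every
    ``two_m``-subset of ``two_n`` chromosomes carrying ``i`` minor alleles."""
    chroms = [1] * i + [0] * (two_n - i)
    counts = np.zeros(two_m + 1)
    for subset in itertools.combinations(range(two_n), two_m):
        j = sum(chroms[k] for k in subset)
        if fold:
            j = min(j, two_m - j)
        counts[j] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# site counts


def test_site_counts_basic():
    m = make_matrix([[0, 1, 2]])
    (sc,) = site_counts(m)
    assert (sc.minor_count, sc.called_n) == (3, 3)


def test_site_counts_drops_monomorphic():
    m = make_matrix([[0, 0, 0], [2, 2, 2], [0, 1, MISSING]])
    scs = site_counts(m)
    assert len(scs) == 1
    assert (scs[0].minor_count, scs[0].called_n) == (1, 2)


def test_site_counts_match_brute_force(rng):
    gt = rng.integers(-1, 3, size=(200, 15)).astype(np.int8)
    m = make_matrix(gt)
    got = {(i, (sc.minor_count, sc.called_n))
           for i, sc in enumerate(site_counts(m))}
    want = []
    for row in gt:
        called = row[row != MISSING]
        if called.size == 0:
            continue
        ac = int(called.sum())
        minor = min(ac, 2 * called.size - ac)
        if minor > 0:
            want.append((minor, called.size))
    assert sorted(sc for _, sc in got) == sorted(want)


# ---------------------------------------------------------------------------
# projection


def test_projection_identity_when_sizes_match():
    p = project_site(3, 8, 8, fold=False)
    assert p[3] == pytest.approx(1.0)
    assert p.sum() == pytest.approx(1.0)


def test_projection_small_example_unfolded():
    assert project_site(1, 4, 2, fold=False) == pytest.approx([0.5, 0.5, 0.0])


def test_projection_matches_enumeration():
    for two_n in range(2, 11, 2):
        for two_m in range(2, two_n + 1, 2):
            for i in range(two_n + 1):
                got = project_site(i, two_n, two_m, fold=True)
                want = enumeration_projection(i, two_n, two_m, fold=True)
                assert got == pytest.approx(want, abs=1e-12), (i, two_n, two_m)


@given(st.integers(2, 40), st.data())
def test_projection_normalization_and_mean(two_n, data):
    two_m = data.draw(st.integers(2, two_n))
    i = data.draw(st.integers(0, two_n))
    p = project_site(i, two_n, two_m, fold=False)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    # expectation preserves allele frequency
    mean_j = (np.arange(two_m + 1) * p).sum()
    assert mean_j / two_m == pytest.approx(i / two_n, abs=1e-10)


def test_projection_up_raises():
    with pytest.raises(ValueError):
        project_site(1, 4, 6)


def test_project_sfs_identity_case():
    sites = [SiteCount(1, 5), SiteCount(2, 5), SiteCount(2, 5)]
    sfs = project_sfs(sites, 5)
    assert sfs.counts == pytest.approx([1, 2, 0, 0, 0])


def test_project_sfs_two_site_fixture_matches_enumeration():
    sites = [SiteCount(1, 4), SiteCount(3, 4)]  # (i, 2n) = (1,8), (3,8)
    sfs = project_sfs(sites, 2)                 # 2m = 4
    want = (enumeration_projection(1, 8, 4)[1:3]
            + enumeration_projection(3, 8, 4)[1:3])
    assert sfs.counts == pytest.approx(want, abs=1e-12)


def test_project_sfs_linearity_and_mass(rng):
    a = [SiteCount(int(i), 20) for i in rng.integers(1, 20, size=30)]
    b = [SiteCount(int(i), 25) for i in rng.integers(1, 25, size=20)]
    both = project_sfs(a + b, 10)
    assert both.counts == pytest.approx(
        project_sfs(a, 10).counts + project_sfs(b, 10).counts)
    assert both.total <= len(a) + len(b)  # monomorphic leakage only shrinks


def test_project_sfs_excludes_small_sites():
    sfs = project_sfs([SiteCount(1, 3), SiteCount(1, 10)], 5)
    assert sfs.n_excluded == 1


def test_projection_sample_size_rule():
    assert projection_sample_size(1070) == 963
    assert projection_sample_size(100, 0.9) == 90


# ---------------------------------------------------------------------------
# MAF bins


@pytest.mark.parametrize("j,two_m,want", [
    (1, 1926, "very_rare"),    # 1/1926 ~ 0.00052
    (2, 1926, "rare"),         # 2/1926 ~ 0.00104 > 0.001
    (10, 1926, "low"),         # ~0.0052
    (1, 20, "common"),         # 0.05 exactly -> low... see next case
])
def test_maf_bin_examples(j, two_m, want):
    if (j, two_m) == (1, 20):
        assert maf_bin(1, 20) == "low"  # inclusive upper bound at 5%
    else:
        assert maf_bin(j, two_m) == want


def test_maf_bin_half_is_common():
    for two_m in (20, 100, 1926):
        assert maf_bin(two_m // 2, two_m) == "common"


# ---------------------------------------------------------------------------
# FVRV


def _sfs_with(very_rare, common, m=1000):
    counts = np.zeros(m)
    counts[0] = very_rare         # singletons: MAF 1/2000 <= 0.001
    counts[m // 2] = common       # MAF ~ 0.25
    return FoldedSFS(sample_size=m, counts=counts, category="x")


def test_fvrv_fraction_arithmetic():
    r = fvrv(_sfs_with(40, 60))
    assert r.fraction == pytest.approx(0.40)
    assert r.ci_low <= r.fraction <= r.ci_high


def test_fvrv_all_singletons():
    r = fvrv(_sfs_with(50, 0))
    assert r.fraction == 1.0 and r.ci_high == 1.0


def test_fvrv_ci_matches_beta_quantiles():
    r = fvrv(_sfs_with(40, 60))
    assert r.ci_low == pytest.approx(beta_dist.ppf(0.025, 40, 61))
    assert r.ci_high == pytest.approx(beta_dist.ppf(0.975, 41, 60))


def test_fvrv_empty_raises():
    with pytest.raises(ValueError):
        fvrv(FoldedSFS(sample_size=10, counts=np.zeros(10)))


# ---------------------------------------------------------------------------
# Fisher


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x) * comb(r2, c1 - x) / total
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize("table", [
    (2, 8, 8, 2), (10, 0, 0, 10), (5, 5, 5, 5), (0, 3, 7, 1), (1, 0, 0, 0),
])
def test_fisher_matches_enumeration(table):
    assert fisher_2x2(*table) == pytest.approx(fisher_oracle(*table),
                                               abs=1e-9)


def test_fisher_zero_margin_is_one():
    assert fisher_2x2(0, 0, 5, 7) == 1.0
    assert fisher_2x2(3, 0, 4, 0) == 1.0


def test_fisher_transpose_invariance(rng):
    for _ in range(20):
        a, b, c, d = rng.integers(0, 12, size=4)
        if a + b + c + d == 0:
            continue
        assert fisher_2x2(a, b, c, d) == pytest.approx(
            fisher_2x2(a, c, b, d), abs=1e-12)


def test_compare_fractions_identical_and_symmetric():
    x = fvrv(_sfs_with(40, 60))
    y = fvrv(_sfs_with(10, 90))
    assert compare_fractions(x, x) == pytest.approx(1.0)
    assert compare_fractions(x, y) == pytest.approx(compare_fractions(y, x))


def test_clopper_pearson_zero_successes():
    lo, hi = clopper_pearson(0, 174)
    assert lo == 0.0
    assert hi == pytest.approx(1 - 0.025 ** (1 / 174))
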