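"""Unit and property tests for the panel-validation statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlsnp.popgen import (
    GenotypeMatrix,
    LocusCounts,
    UndefinedStatisticError,
    _hw_enumeration,
    bonferroni,
    classify_assay,
    fis,
    hw_exact,
    ld_gtest,
    maf,
    observed_het,
    summarize,
    unbiased_he,
)

# Published per-locus rows whose genotype counts are forced by the printed
# MAF and F_IS: (major hom, het, minor hom) -> (MAF, He, F_IS, HW p).
PANEL_ROWS = [
    ("lepr", (9, 16, 9), 0.500, 0.508, 0.074, 0.7387),
    ("igf1", (32, 2, 0), 0.029, 0.058, -0.015, 1.0),
    ("mstn1", (24, 8, 2), 0.176, 0.296, 0.205, 0.249),
    ("actc", (13, 17, 4), 0.368, 0.471, -0.060, 1.0),
    ("akt3", (26, 8, 0), 0.118, 0.210, -0.119, 1.0),
]


@pytest.mark.parametrize("name,counts,e_maf,e_he,e_fis,e_hw", PANEL_ROWS)
def test_published_panel_rows(name, counts, e_maf, e_he, e_fis, e_hw):
    """MAF, unbiased He, F_IS and exact HW p reproduce the published panel."""
    c = LocusCounts(*counts)
    assert maf(c) == pytest.approx(e_maf, abs=5e-4)
    assert round(unbiased_he(c), 3) == pytest.approx(e_he)
    assert round(fis(c), 3) == pytest.approx(e_fis)
    assert round(hw_exact(c), 4) == pytest.approx(e_hw)


def test_hw_exact_two_individual_hand_enumeration():
    """n=2 with one copy of each homozygote: only h=0 (p 1/3) and h=2
    (p 2/3) are possible; observing h=0 gives p-value 1/3."""
    assert hw_exact(LocusCounts(1, 0, 1)) == pytest.approx(1 / 3)
    assert hw_exact(LocusCounts(0, 2, 0)) == pytest.approx(1.0)


def _hw_oracle(n_major_hom: int, n_het: int, n_minor_hom: int) -> Fraction:
    """Brute-force probability-ordering HW test over genotype multisets.

    Enumerates every (a, h, c) with the same sample size and allele counts,
    weighting each by the exact multinomial count n!/(a!h!c!)·2^h, in
    rational arithmetic.
    """
    n = n_major_hom + n_het + n_minor_hom
    major = 2 * n_major_hom + n_het
    weights = {}
    for a in range(n + 1):
        for h in range(n - a + 1):
            c = n - a - h
            if 2 * a + h != major:
                continue
            weights[(a, h, c)] = Fraction(
                math.factorial(n) * 2**h,
                math.factorial(a) * math.factorial(h) * math.factorial(c),
            )
    total = sum(weights.values())
    p_obs = weights[(n_major_hom, n_het, n_minor_hom)]
    return sum(w for w in weights.values() if w <= p_obs) / total


def test_hw_exact_matches_bruteforce_multiset_oracle():
    """Exact agreement with a rational brute-force oracle for all counts n <= 8."""
    for n in range(1, 9):
        for a in range(n + 1):
            for h in range(n - a + 1):
                c = n - a - h
                counts = LocusCounts(a, h, c)
                got = hw_exact(counts)
                want = float(_hw_oracle(a, h, c))
                assert got == pytest.approx(want, abs=1e-9), (a, h, c)


@given(
    n=st.integers(min_value=1, max_value=200),
    minor=st.integers(min_value=0, max_value=200),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hw_enumeration_normalises(n, minor):
    """The conditional distribution over heterozygote counts sums to 1."""
    minor = min(minor, n)  # keep minor allele the rarer one
    if minor == 0:
        return
    hs, probs = _hw_enumeration(n, minor)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert (hs <= minor).all() and ((hs % 2) == (minor % 2)).all()
    # p-value of any observable configuration lies in (0, 1]
    obs = int(hs[0])
    p = hw_exact(
        LocusCounts((2 * n - minor - obs) // 2, obs, (minor - obs) // 2)
    )
    assert 0.0 < p <= 1.0


def test_fis_extremes_and_signs():
    """F_IS is 1 with no heterozygotes, negative when Ho exceeds He."""
    assert fis(LocusCounts(5, 0, 5)) == pytest.approx(1.0)
    excess = LocusCounts(0, 10, 0)  # all heterozygous
    assert observed_het(excess) > unbiased_he(excess)
    assert fis(excess) < 0


def test_undefined_statistics_raise():
    with pytest.raises(UndefinedStatisticError):
        maf(LocusCounts(0, 0, 0))
    with pytest.raises(UndefinedStatisticError):
        unbiased_he(LocusCounts(1, 0, 0))
    with pytest.raises(UndefinedStatisticError):
        fis(LocusCounts(30, 0, 0))  # monomorphic: He = 0


def test_classify_assay():
    all_missing = np.full(34, -1, dtype=np.int8)
    assert classify_assay(all_missing) == "failed"
    mono = np.zeros(34, dtype=np.int8)
    assert classify_assay(mono) == "monomorphic"
    poly = np.array([0] * 20 + [1] * 10 + [2] * 4, dtype=np.int8)
    assert classify_assay(poly) == "polymorphic"
    half_missing = np.array([0] * 11 + [1] * 6 + [-1] * 17, dtype=np.int8)
    assert classify_assay(half_missing) == "polymorphic"  # exactly 0.5 passes
    mostly_missing = np.array([0] * 10 + [1] * 5 + [-1] * 19, dtype=np.int8)
    assert classify_assay(mostly_missing) == "failed"


def test_ld_gtest_identical_columns():
    """Two identical 5+5 columns give G = 20·ln2 and a minimal p-value."""
    col = np.array([0] * 5 + [2] * 5, dtype=np.int8)
    g, p = ld_gtest(col, col.copy(), m=999, seed=1)
    assert g == pytest.approx(20 * math.log(2), abs=1e-9)
    assert p <= 0.05
    assert p >= 1 / 1000  # (b+1)/(m+1) floor


def test_ld_gtest_requires_polymorphism():
    mono = np.zeros(10, dtype=np.int8)
    poly = np.array([0, 1] * 5, dtype=np.int8)
    with pytest.raises(UndefinedStatisticError):
        ld_gtest(mono, poly, m=10, seed=0)


def test_bonferroni():
    assert bonferroni(0.05, 741) == pytest.approx(0.05 / 741)
    assert round(bonferroni(0.05, 741), 5) == 0.00007
    assert bonferroni(0.05, 1) == 0.05
    assert bonferroni(0.05, 2) == 0.025
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)


def test_summarize_counts_and_pairs():
    """A 45-locus panel with 2 failed and 4 monomorphic assays yields 43
    feasible and 39 polymorphic loci and C(39,2) = 741 LD pairs."""
    rng = np.random.default_rng(5)
    n = 34
    cols = {}
    for i in range(39):  # polymorphic
        cols[f"poly_{i}"] = rng.choice([0, 1, 2], size=n, p=[0.49, 0.42, 0.09])
    for i in range(4):
        cols[f"mono_{i}"] = np.zeros(n, dtype=np.int8)
    for i in range(2):
        cols[f"fail_{i}"] = np.full(n, -1, dtype=np.int8)
    loci = list(cols)
    codes = np.column_stack([cols[l] for l in loci]).astype(np.int8)
    matrix = GenotypeMatrix(loci, [f"i{j}" for j in range(n)], codes)
    res = summarize(matrix, ld_permutations=49, seed=3)
    assert res["n_polymorphic"] == 39
    assert res["n_monomorphic"] == 4
    assert res["n_failed"] == 2
    assert res["n_ld_pairs"] == 741
    assert res["bonferroni_threshold"] == pytest.approx(0.05 / 741)
    assert len(res["ld_pairs"]) == 741
    feasible = res["n_polymorphic"] + res["n_monomorphic"]
    assert feasible / res["n_loci"] == pytest.approx(43 / 45)


def test_summarize_mean_he_is_arithmetic():
    m = GenotypeMatrix.from_counts(
        {"a": LocusCounts(9, 16, 9), "b": LocusCounts(24, 8, 2)}
    )
    res = summarize(m, run_ld=False)
    expected = (unbiased_he(LocusCounts(9, 16, 9)) + unbiased_he(LocusCounts(24, 8, 2))) / 2
    assert res["means"]["he"]["mean"] == pytest.approx(expected)


def test_genotype_matrix_repolarises_counts():
    """counts() always reports the more frequent allele as major."""
    col = np.array([2] * 20 + [1] * 10 + [0] * 4, dtype=np.int8)
    m = GenotypeMatrix(["x"], [f"i{j}" for j in range(34)], col[:, None])
    c = m.counts("x")
    assert (c.n_aa_major, c.n_het, c.n_aa_minor) == (20, 10, 4)
    assert maf(c) <= 0.5
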