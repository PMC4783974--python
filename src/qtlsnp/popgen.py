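"""Validation statistics for a diploid biallelic SNP panel.

Implements the statistics used to validate a genotyped SNP panel in a
single population sample: minor allele frequency, observed heterozygosity,
Nei's unbiased gene diversity (expected heterozygosity with finite-sample
correction), the fixation index F_IS, the exact Hardy–Weinberg probability
test by complete enumeration conditional on allele counts, a genotypic
linkage-disequilibrium G-test with a permutation null, and Bonferroni
correction for the resulting family of tests.

All estimators operate on per-locus genotype counts (``LocusCounts``); a
``GenotypeMatrix`` holds the raw panel with missing data and is reduced to
counts locus by locus.  Statistics use locus-wise (and, for LD, pairwise)
complete cases.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LocusCounts",
    "LocusStats",
    "LDPair",
    "MultipleTesting",
    "classify_assay",
    "maf",
    "observed_het",
    "unbiased_he",
    "fis",
    "hw_exact",
    "ld_gtest",
    "bonferroni",
    "summarize",
]

# Genotype codes used throughout: 0 = AA (major hom), 1 = Aa, 2 = aa,
# -1 = missing.  "Major" is the more frequent allele at the locus.
MISSING = -1


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given counts."""


@dataclass(frozen=True)
class LocusCounts:
    """Genotype counts at one biallelic locus (complete cases only).

    ``n_aa_major`` counts homozygotes for the major (more frequent) allele,
    ``n_het`` heterozygotes, ``n_aa_minor`` homozygotes for the minor allele.
    """

    n_aa_major: int
    n_het: int
    n_aa_minor: int

    def __post_init__(self) -> None:
        if min(self.n_aa_major, self.n_het, self.n_aa_minor) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_aa_major + self.n_het + self.n_aa_minor

    @property
    def minor_allele_count(self) -> int:
        return 2 * self.n_aa_minor + self.n_het

    @property
    def major_allele_count(self) -> int:
        return 2 * self.n_aa_major + self.n_het


@dataclass
class LocusStats:
    """Per-locus validation statistics mirroring a panel report row."""

    locus: str
    status: str  # failed | monomorphic | polymorphic
    n_typed: int
    maf: Optional[float] = None
    ho: Optional[float] = None
    he: Optional[float] = None
    fis: Optional[float] = None
    hw_p: Optional[float] = None


@dataclass
class LDPair:
    locus_a: str
    locus_b: str
    g: float
    p: float
    m: int
    significant_nominal: bool = False
    significant_bonferroni: bool = False


@dataclass(frozen=True)
class MultipleTesting:
    """Bonferroni family: nominal alpha and number of tests."""

    alpha: float = 0.05
    k: int = 1

    @property
    def threshold(self) -> float:
        return bonferroni(self.alpha, self.k)


class GenotypeMatrix:
    """Diploid biallelic genotypes for a panel of loci in one population.

    Stored as an (n_individuals, n_loci) int8 array of codes
    0/1/2 (major hom / het / minor hom) with -1 for missing.  Codes are
    relative to per-locus allele labels in ``alleles`` (major, minor).
    """

    def __init__(
        self,
        loci: Sequence[str],
        individuals: Sequence[str],
        codes: np.ndarray,
        alleles: Optional[dict[str, tuple[str, str]]] = None,
    ) -> None:
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(individuals), len(loci)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"({len(individuals)}, {len(loci)})"
            )
        if not np.isin(codes, [-1, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.codes = codes
        self.alleles = alleles or {}

    @property
    def n(self) -> int:
        return len(self.individuals)

    def column(self, locus: str) -> np.ndarray:
        return self.codes[:, self.loci.index(locus)]

    def counts(self, locus: str) -> LocusCounts:
        """Reduce one locus to complete-case genotype counts.

        Codes are re-polarised so the major allele is the more frequent
        one among typed individuals (ties keep the stored orientation).
        """
        col = self.column(locus)
        typed = col[col != MISSING]
        n0 = int((typed == 0).sum())
        n1 = int((typed == 1).sum())
        n2 = int((typed == 2).sum())
        if 2 * n2 + n1 > 2 * n0 + n1:  # stored "minor" is actually major
            n0, n2 = n2, n0
        return LocusCounts(n0, n1, n2)

    @classmethod
    def from_counts(
        cls,
        locus_counts: dict[str, LocusCounts],
        n_individuals: Optional[int] = None,
        seed: Optional[int] = None,
    ) -> "GenotypeMatrix":
        """Build a matrix whose columns realise the given genotype counts.

        Individuals beyond a locus's typed count are set missing.  Useful
        for recomputing statistics from published genotype counts.  Columns
        are laid out in genotype order, which induces spurious cross-locus
        association; pass ``seed`` to shuffle each column independently
        when between-locus tests (LD) are intended.
        """
        loci = list(locus_counts)
        n = n_individuals or max(c.n_typed for c in locus_counts.values())
        rng = np.random.default_rng(seed) if seed is not None else None
        codes = np.full((n, len(loci)), MISSING, dtype=np.int8)
        for j, name in enumerate(loci):
            c = locus_counts[name]
            if c.n_typed > n:
                raise ValueError(f"{name}: n_typed {c.n_typed} exceeds n {n}")
            col = [0] * c.n_aa_major + [1] * c.n_het + [2] * c.n_aa_minor
            codes[: c.n_typed, j] = col
            if rng is not None:
                rng.shuffle(codes[:, j])
        inds = [f"ind_{i + 1}" for i in range(n)]
        return cls(loci, inds, codes)


def classify_assay(column: np.ndarray, max_missing: float = 0.5) -> str:
    """Classify one assayed locus as failed, monomorphic or polymorphic.

    Failed when the missing fraction exceeds ``max_missing`` (an assay
    where most genotypes could not be scored); monomorphic when a single
    allele is observed among typed individuals; polymorphic otherwise.
    """
    col = np.asarray(column)
    n = len(col)
    if n == 0:
        return "failed"
    missing_frac = float((col == MISSING).sum()) / n
    if missing_frac > max_missing:
        return "failed"
    typed = col[col != MISSING]
    if len(typed) == 0:
        return "failed"
    has_major = ((typed == 0) | (typed == 1)).any()
    has_minor = ((typed == 2) | (typed == 1)).any()
    return "polymorphic" if (has_major and has_minor) else "monomorphic"


def maf(counts: LocusCounts) -> float:
    """Minor allele frequency: rarer allele count over 2·n_typed."""
    if counts.n_typed == 0:
        raise UndefinedStatisticError("MAF undefined with no typed individuals")
    return min(counts.minor_allele_count, counts.major_allele_count) / (
        2 * counts.n_typed
    )


def observed_het(counts: LocusCounts) -> float:
    if counts.n_typed == 0:
        raise UndefinedStatisticError("Ho undefined with no typed individuals")
    return counts.n_het / counts.n_typed


def unbiased_he(counts: LocusCounts) -> float:
    """Nei's unbiased gene diversity.

    He = n/(n−1) · (1 − Σ p̂ᵢ² − Ho/(2n)) with n the typed sample size and
    Ho the observed heterozygote fraction.  The Ho term removes the
    within-individual contribution so the estimator is unbiased for the
    population gene diversity under arbitrary inbreeding.
    """
    n = counts.n_typed
    if n < 2:
        raise UndefinedStatisticError("unbiased He requires n_typed >= 2")
    p = counts.major_allele_count / (2 * n)
    q = counts.minor_allele_count / (2 * n)
    ho = observed_het(counts)
    return n / (n - 1) * (1.0 - p * p - q * q - ho / (2 * n))


def fis(counts: LocusCounts) -> float:
    """Fixation index F_IS = 1 − Ho/He (He unbiased).

    Positive values indicate a heterozygote deficit relative to
    Hardy–Weinberg expectation, negative values an excess.
    """
    he = unbiased_he(counts)
    if he <= 0:
        raise UndefinedStatisticError("F_IS undefined when He = 0")
    return 1.0 - observed_het(counts) / he


def _hw_enumeration(n: int, minor_copies: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote counts and conditional probabilities given allele counts.

    Conditional on n diploids carrying ``minor_copies`` copies of the minor
    allele (and 2n − minor_copies of the major), the possible heterozygote
    counts h run over h ≤ minor_copies with h ≡ minor_copies (mod 2), and

        P(h) ∝ n! · 2^h / (nAA(h)! · h! · naa(h)!)

    Computed in log space and normalised over the enumeration.
    """
    major_copies = 2 * n - minor_copies
    hs = np.arange(minor_copies % 2, min(minor_copies, major_copies) + 1, 2)
    lg = math.lgamma
    logw = np.array(
        [
            h * math.log(2.0)
            - lg((major_copies - h) // 2 + 1)
            - lg(h + 1)
            - lg((minor_copies - h) // 2 + 1)
            for h in hs
        ]
    )
    w = np.exp(logw - logw.max())
    return hs, w / w.sum()


def hw_exact(counts: LocusCounts, tie_tol: float = 1e-12) -> float:
    """Exact Hardy–Weinberg probability test by complete enumeration.

    Conditional on the observed allele counts, every genotype configuration
    (indexed by its heterozygote count) is enumerated with its conditional
    probability; the two-sided p-value is the total probability of all
    configurations no more probable than the observed one
    (probability-ordering test). ``tie_tol`` is the relative tolerance used
    to treat equal probabilities as ties.
    """
    n = counts.n_typed
    if n < 1:
        raise UndefinedStatisticError("HW test undefined with no typed individuals")
    minor = min(counts.minor_allele_count, counts.major_allele_count)
    if minor == 0:
        return 1.0
    hs, probs = _hw_enumeration(n, minor)
    obs = counts.n_het
    idx = np.flatnonzero(hs == obs)
    if idx.size == 0:
        raise ValueError(
            f"inconsistent counts: heterozygote count {obs} impossible "
            f"given {minor} minor-allele copies"
        )
    p_obs = probs[idx[0]]
    return float(probs[probs <= p_obs * (1.0 + tie_tol)].sum())


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood ratio G over a contingency table, skipping zero cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_gtest(
    col_a: np.ndarray,
    col_b: np.ndarray,
    m: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Genotypic linkage-disequilibrium G-test with a permutation null.

    Builds the genotype×genotype contingency table over individuals typed
    at both loci, computes the log-likelihood-ratio G, and estimates its
    p-value by ``m`` random permutations of one locus's genotypes across
    individuals: p = (#{G_perm ≥ G_obs} + 1) / (m + 1).

    Returns (G, p).
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise UndefinedStatisticError(
            "LD G-test requires >= 2 distinct genotypes at each locus"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    joint = 3 * a + b
    obs_table = np.bincount(joint, minlength=9).reshape(3, 3)
    g_obs = _g_statistic(obs_table)
    n = len(a)
    # Permuting one locus leaves both margins fixed, so the expected table
    # is the same for every permutation; G can be computed vectorised.
    expected = (
        np.outer(np.bincount(a, minlength=3), np.bincount(b, minlength=3)) / n
    ).ravel()
    b_perm = rng.permuted(np.broadcast_to(b, (m, n)), axis=1)
    joint_perm = (3 * a)[None, :] + b_perm
    flat = (np.arange(m)[:, None] * 9 + joint_perm).ravel()
    counts = np.bincount(flat, minlength=9 * m).reshape(m, 9)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            counts > 0, counts * np.log(counts / np.maximum(expected, 1e-300)), 0.0
        )
    g_perm = 2.0 * terms.sum(axis=1)
    exceed = int((g_perm >= g_obs - 1e-12).sum())
    return g_obs, (exceed + 1) / (m + 1)


def bonferroni(alpha: float = 0.05, k: int = 1) -> float:
    """Bonferroni-corrected per-test threshold alpha/k."""
    if k < 1:
        raise ValueError("number of tests k must be >= 1")
    return alpha / k


def summarize(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    ld_permutations: int = 10000,
    seed: Optional[int] = None,
    run_ld: bool = True,
    max_missing: float = 0.5,
) -> dict:
    """Full panel validation: per-locus stats, panel means and LD tests.

    Diversity statistics and the HW test are computed only for polymorphic
    loci; LD G-tests run over all C(k, 2) pairs of polymorphic loci with a
    Bonferroni-corrected threshold.  Returns a dict with ``locus_stats``
    (DataFrame), ``ld_pairs`` (list of LDPair), ``means`` and counts.
    """
    rng = np.random.default_rng(seed)
    rows: list[LocusStats] = []
    poly: list[str] = []
    for locus in matrix.loci:
        col = matrix.column(locus)
        status = classify_assay(col, max_missing=max_missing)
        counts = matrix.counts(locus)
        st = LocusStats(locus=locus, status=status, n_typed=counts.n_typed)
        if status == "polymorphic":
            poly.append(locus)
            st.maf = maf(counts)
            st.ho = observed_het(counts)
            st.he = unbiased_he(counts)
            st.fis = fis(counts) if st.he > 0 else None
            st.hw_p = hw_exact(counts)
        elif status == "monomorphic":
            st.maf, st.ho, st.he = 0.0, 0.0, 0.0
        rows.append(st)

    table = pd.DataFrame([vars(r) for r in rows])

    ld_pairs: list[LDPair] = []
    n_pairs = len(poly) * (len(poly) - 1) // 2
    if run_ld and n_pairs:
        thr = bonferroni(alpha, n_pairs)
        for la, lb in itertools.combinations(poly, 2):
            g, p = ld_gtest(
                matrix.column(la), matrix.column(lb), m=ld_permutations, rng=rng
            )
            ld_pairs.append(
                LDPair(
                    la,
                    lb,
                    g=g,
                    p=p,
                    m=ld_permutations,
                    significant_nominal=p < alpha,
                    significant_bonferroni=p < thr,
                )
            )

    def _mean_sd_se(col: str) -> dict:
        vals = table.loc[table.status == "polymorphic", col].dropna().to_numpy(float)
        if vals.size == 0:
            return {"mean": None, "sd": None, "se": None}
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return {
            "mean": float(vals.mean()),
            "sd": sd,
            "se": sd / math.sqrt(vals.size),
        }

    return {
        "locus_stats": table,
        "ld_pairs": ld_pairs,
        "n_loci": len(matrix.loci),
        "n_failed": int((table.status == "failed").sum()),
        "n_monomorphic": int((table.status == "monomorphic").sum()),
        "n_polymorphic": len(poly),
        "n_ld_pairs": n_pairs,
        "bonferroni_threshold": bonferroni(alpha, n_pairs) if n_pairs else None,
        "means": {
            "maf": _mean_sd_se("maf"),
            "he": _mean_sd_se("he"),
            "fis": _mean_sd_se("fis"),
        },
    }
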