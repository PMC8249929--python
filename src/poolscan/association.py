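"""Validation statistics for pooled allele-frequency estimates.

Pool-Seq estimates allele frequencies from read depths; these tests
check those estimates against individual genotyping of the same loci:
Pearson chi-square association of genotype counts with phenotype
groups, Fisher's exact test on allele read depths between two pools,
allele frequencies recomputed from genotype counts, and Kendall's W
concordance between the two frequency estimates. A small helper
classifies annotated variant-consequence terms into the four
loss-of-function categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Sequence Ontology consequence term -> loss-of-function category
LOF_CATEGORIES: dict[str, int] = {
    "stop_gained": 1,
    "stop_lost": 1,
    "frameshift_variant": 2,
    "splice_donor_variant": 3,
    "splice_acceptor_variant": 3,
    "start_lost": 4,  # initiator codon
    "initiator_codon_variant": 4,
}


@dataclass(slots=True)
class GenotypeTable:
    """Genotype counts cross-tabulated by phenotype group.

    Rows are genotypes (two-letter allele pairs such as ``GG``, ``GA``),
    columns are groups.
    """

    genotypes: list[str]
    groups: list[str]
    counts: list[list[int]]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.genotypes), len(self.groups)):
            raise ValueError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.genotypes)} genotypes x {len(self.groups)} groups"
            )
        if (arr < 0).any():
            raise ValueError("genotype counts must be non-negative")

    def matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def column(self, group: str) -> dict[str, int]:
        j = self.groups.index(group)
        return {g: self.counts[i][j] for i, g in enumerate(self.genotypes)}


@dataclass(frozen=True, slots=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    n_small_expected: int  # expected cells < 5 (reported, not blocking)


@dataclass(frozen=True, slots=True)
class AfPair:
    """Paired allele-frequency estimates for one SNP in one group."""

    snp_id: str
    af_pool: float
    af_sanger: float
    group: str

    def __post_init__(self) -> None:
        for v in (self.af_pool, self.af_sanger):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"allele frequency {v} outside [0, 1]")


def chi_square_association(table: GenotypeTable) -> ChiSquareResult:
    """Pearson chi-square test of genotype-by-group independence.

    Rows and columns whose counts are all zero are dropped (an
    unobserved genotype carries no information and would zero an
    expected count); the statistic is Pearson's chi-square without
    continuity correction with ``(rows-1)(cols-1)`` degrees of freedom.
    Expected cells below 5 are counted in the result but do not block —
    small genotype classes are routine in strongly associated tables.
    """
    arr = table.matrix()
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(
            f"table reduces to {arr.shape} after pruning zero rows/columns; "
            "need at least 2x2"
        )
    stat, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        dof=int(dof),
        p_value=float(p),
        n_small_expected=int((expected < 5).sum()),
    )


def fisher_allele_depth(
    depths_a: tuple[int, int], depths_b: tuple[int, int]
) -> float:
    """Two-sided Fisher's exact p-value on allele read depths.

    ``depths_a``/``depths_b`` are (major, minor) read counts of the same
    site in two pools; the test asks whether the allele composition of
    reads differs between pools. Used to rank candidate SNPs ascending
    by p. A zero margin (an allele or a pool with no reads) makes every
    table equally likely, so p = 1 is returned with a warning.
    """
    import warnings

    table = np.array([depths_a, depths_b], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("read counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in allele-depth table; p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def af_from_genotypes(
    genotype_counts: dict[str, int], counted_allele: str
) -> float:
    """Allele frequency from genotype counts of one group.

    ``AF = (2 * hom + het) / (2 * n)`` where ``hom`` counts individuals
    homozygous for the counted allele, ``het`` those carrying one copy,
    and ``n`` is the number of genotyped individuals.
    """
    n = sum(genotype_counts.values())
    if n == 0:
        raise ValueError("no genotyped individuals")
    copies = 0
    for genotype, count in genotype_counts.items():
        if len(genotype) != 2:
            raise ValueError(f"genotype label {genotype!r} is not an allele pair")
        copies += count * sum(1 for a in genotype if a == counted_allele)
    return copies / (2 * n)


@dataclass(frozen=True, slots=True)
class KendallWResult:
    w: float
    chi2: float
    dof: int
    p_value: float


def kendall_w(ratings: Sequence[Sequence[float]] | np.ndarray) -> KendallWResult:
    """Kendall's coefficient of concordance W among m raters of n items.

    ``ratings`` is an ``n_items x m_methods`` value matrix (here
    typically m = 2: pooled-read allele frequency vs genotype-based
    allele frequency). Values are converted to within-method ranks with
    mid-ranks for ties, and

        W = 12 S / (m**2 (n**3 - n) - m T)

    where S is the sum of squared deviations of the item rank sums from
    their mean and T the usual tie correction
    ``sum(t**3 - t)`` over tie groups of each method. W is in [0, 1]
    (1 = identical orderings; with m = 2, exactly reversed orderings
    give 0). Significance is the standard chi-square approximation
    ``chi2 = m (n - 1) W`` on ``n - 1`` degrees of freedom.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an n x m matrix with n >= 2 items, m >= 2 methods")
    n, m = arr.shape
    ranks = np.empty_like(arr)
    tie_correction = 0.0
    for j in range(m):
        col = arr[:, j]
        if np.all(col == col[0]):
            raise ValueError(f"method {j} rates all items identically: W undefined")
        ranks[:, j] = stats.rankdata(col)  # mid-ranks for ties
        _, tie_counts = np.unique(col, return_counts=True)
        tie_correction += float(np.sum(tie_counts**3 - tie_counts))
    rank_sums = ranks.sum(axis=1)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    denom = m**2 * (n**3 - n) - m * tie_correction
    if denom <= 0:
        raise ValueError("degenerate tie structure: W undefined")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, n - 1))
    return KendallWResult(w=float(w), chi2=float(chi2), dof=n - 1, p_value=p)


def lof_categorize(consequence_term: str) -> int | None:
    """Loss-of-function category of a variant-consequence term.

    1 = stop gain/loss, 2 = frameshift, 3 = essential splice site,
    4 = initiator codon; any other term (missense, synonymous, ...)
    returns ``None``.
    """
    return LOF_CATEGORIES.get(consequence_term.strip().lower())
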