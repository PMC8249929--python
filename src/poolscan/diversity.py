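"""Per-site and per-window population-genetic statistics for Pool-Seq.

Allele frequencies are estimated from read depths (the pool is the
sampling unit, not the individual). The window statistics are

* pooled heterozygosity ``Hp = 2 * S_maj * S_min / (S_maj + S_min)**2``
  where ``S_maj`` / ``S_min`` sum, over the SNPs of a window, the read
  counts of each SNP's most and least abundant allele;
* its negated Z-transform ``-ZHp = -(Hp - mu) / sigma`` with moments
  taken over the retained windows of one pool (large positive values
  mark heterozygosity deficits, the footprint of a sweep);
* the Weir-Cockerham two-population FST estimator on pooled allele
  frequencies, aggregated over a window as a ratio of summed variance
  components.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from poolscan.io import PoolSiteCounts, SiteFilterParams

#: deterministic tie-break order for the major allele
ALLELE_ORDER = ("A", "C", "G", "T")


class UndefinedSiteError(ValueError):
    """A site with no informative reads."""


class DegenerateScanError(ValueError):
    """A scan whose statistic distribution has no spread."""


class StatName(str, Enum):
    HP = "Hp"
    ZHP_NEG = "-ZHp"
    FST = "Fst"


@dataclass(slots=True)
class SiteAlleleFreq:
    """Major/minor allele read counts of one site in one pool."""

    scaffold: str
    position: int
    major_allele: str
    minor_allele: str | None
    n_maj: int
    n_min: int

    @property
    def maf(self) -> float:
        """Minor allele frequency over the two top alleles."""
        total = self.n_maj + self.n_min
        return self.n_min / total if total else 0.0

    @property
    def depth(self) -> int:
        return self.n_maj + self.n_min


@dataclass(slots=True)
class WindowStat:
    """One statistic value on one genome window (1-based inclusive)."""

    scaffold: str
    start: int
    end: int
    snp_count: int
    value: float
    stat_name: str
    pool_or_pair: str = ""

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.scaffold, self.start, self.end)


@dataclass(frozen=True, slots=True)
class HpMoments:
    """Mean and standard deviation of Hp over a pool's retained windows."""

    mu_hp: float
    sigma_hp: float
    n_windows: int


def site_allele_freq(site: PoolSiteCounts) -> SiteAlleleFreq:
    """Reduce a site's nucleotide counts to major/minor allele counts.

    The major allele is the most abundant of A/C/G/T (ties broken by the
    fixed order A < C < G < T), the minor allele the second most
    abundant. Monomorphic sites get ``minor_allele=None`` and
    ``n_min=0``.
    """
    counts = [(site.counts.get(a, 0), a) for a in ALLELE_ORDER]
    if all(c == 0 for c, _ in counts):
        raise UndefinedSiteError(
            f"{site.scaffold}:{site.position} has no A/C/G/T reads"
        )
    # sort by count descending; allele order breaks ties deterministically
    ranked = sorted(counts, key=lambda t: (-t[0], ALLELE_ORDER.index(t[1])))
    n_maj, major = ranked[0]
    n_min, minor = ranked[1]
    return SiteAlleleFreq(
        scaffold=site.scaffold,
        position=site.position,
        major_allele=major,
        minor_allele=minor if n_min > 0 else None,
        n_maj=n_maj,
        n_min=n_min,
    )


#: rejection reasons in attribution order
FILTER_REASONS = ("depth", "quality", "maf", "indel")


def filter_sites(
    sites: Sequence[PoolSiteCounts],
    params: SiteFilterParams | None = None,
    indel_positions: Mapping[str, Sequence[int]] | None = None,
) -> tuple[list[PoolSiteCounts], Counter]:
    """Apply the site-level SNP filters to one pool's sites.

    A site is retained iff its A/C/G/T depth lies in
    ``[min_depth, max_depth]``, its phred quality (when available) is at
    least ``min_quality``, its minor allele frequency is at least
    ``min_maf``, and no indel lies within ``indel_exclusion_bp``
    (boundary inclusive). Rejections are tallied by the first failing
    reason in the order depth, quality, MAF, indel; sites without a
    quality value are additionally counted under ``quality_unavailable``
    but are not rejected for it.

    ``indel_positions`` maps scaffold to sorted indel coordinates.
    Input must be sorted by (scaffold, position).
    """
    if params is None:
        params = SiteFilterParams()
    keys = [(s.scaffold, s.position) for s in sites]
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (scaffold, position)")

    indel_arrays = {
        sc: np.asarray(pos, dtype=np.int64)
        for sc, pos in (indel_positions or {}).items()
    }
    retained: list[PoolSiteCounts] = []
    tally: Counter = Counter()
    for site in sites:
        depth = site.depth
        if not params.min_depth <= depth <= params.max_depth:
            tally["depth"] += 1
            continue
        if site.quality is None:
            tally["quality_unavailable"] += 1
        elif site.quality < params.min_quality:
            tally["quality"] += 1
            continue
        if site_allele_freq(site).maf < params.min_maf:
            tally["maf"] += 1
            continue
        indels = indel_arrays.get(site.scaffold)
        if indels is not None and indels.size and _near_indel(
            site.position, indels, params.indel_exclusion_bp
        ):
            tally["indel"] += 1
            continue
        retained.append(site)
        tally["retained"] += 1
    return retained, tally


def _near_indel(position: int, indels: np.ndarray, radius: int) -> bool:
    i = int(np.searchsorted(indels, position))
    for j in (i - 1, i):
        if 0 <= j < indels.size and abs(int(indels[j]) - position) <= radius:
            return True
    return False


def hp_window(sites_in_window: Iterable[SiteAlleleFreq]) -> float | None:
    """Pooled heterozygosity of one window.

    ``Hp = 2 * S_maj * S_min / (S_maj + S_min)**2`` with
    ``S_maj = sum(n_maj)`` and ``S_min = sum(n_min)`` over the window's
    SNPs. An empty window returns ``None`` (undefined, never 0: zero is
    a meaningful value for monomorphic windows).
    """
    s_maj = 0
    s_min = 0
    n = 0
    for s in sites_in_window:
        s_maj += s.n_maj
        s_min += s.n_min
        n += 1
    if n == 0 or (s_maj + s_min) == 0:
        return None
    return 2.0 * s_maj * s_min / (s_maj + s_min) ** 2


def zhp_transform(
    window_hp_values: Sequence[float], ddof: int = 1
) -> tuple[list[float], HpMoments]:
    """Negated Z-transform of a pool's window Hp values.

    ``-ZHp = -(Hp - mu) / sigma`` with ``mu``/``sigma`` the mean and
    standard deviation over exactly the retained windows passed in.
    ``ddof=1`` (sample standard deviation) is the default convention;
    with thousands of windows the choice is immaterial but it is fixed
    for determinism.
    """
    values = np.asarray(window_hp_values, dtype=float)
    if values.size < 2:
        raise DegenerateScanError("need >= 2 windows to Z-transform Hp")
    if np.all(values == values[0]):
        raise DegenerateScanError("zero variance across window Hp values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=ddof))
    if sigma == 0.0:
        raise DegenerateScanError("zero variance across window Hp values")
    zhp = (-(values - mu) / sigma).tolist()
    return zhp, HpMoments(mu_hp=mu, sigma_hp=sigma, n_windows=values.size)


def _wc_site_components(
    p1: float, n1: float, p2: float, n2: float
) -> tuple[float, float]:
    """Weir-Cockerham variance components of one biallelic site.

    Allele-frequency (haploid-sampling) form for two populations with
    effective allele-sample sizes ``n1``/``n2``: returns the
    between-population component ``a`` and within-population component
    ``b``; the single-site estimate is ``a / (a + b)``.
    """
    n_t = n1 + n2
    if n1 <= 0 or n2 <= 0 or n_t <= 2:
        return (math.nan, math.nan)
    nc = n_t - (n1 * n1 + n2 * n2) / n_t
    p_bar = (n1 * p1 + n2 * p2) / n_t
    msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (n_t - 2.0)
    a = (msp - msg) / nc
    return a, msg


def fst_window(
    sites_pool_a: Sequence[SiteAlleleFreq],
    sites_pool_b: Sequence[SiteAlleleFreq],
    pool_sizes: tuple[int, int],
) -> float | None:
    """Weir-Cockerham FST of one window from two pools' paired sites.

    Only positions present in both pools contribute. Per pool and site
    the allele frequency is the read fraction and the effective sample
    size is ``min(read depth, haploid pool size)`` — reads from a pool
    cannot represent more independent chromosomes than were pooled. The
    window estimate is the ratio of summed between-population variance
    components to summed total components (ratio-of-sums, the standard
    multi-locus Weir-Cockerham combination). Negative values are
    reported as computed; truncating at zero would bias the upper-tail
    quantiles the sweep scan thresholds on.

    Returns ``None`` when the pools share no usable site.
    """
    size_a, size_b = pool_sizes
    if size_a <= 0 or size_b <= 0:
        raise ValueError("haploid pool sizes must be positive")
    by_pos_b = {(s.scaffold, s.position): s for s in sites_pool_b}
    num = 0.0
    den = 0.0
    n_shared = 0
    for sa in sites_pool_a:
        sb = by_pos_b.get((sa.scaffold, sa.position))
        if sb is None:
            continue
        da, db = sa.depth, sb.depth
        if da == 0 or db == 0:
            continue
        # express both pools' frequencies on a common reference allele:
        # the major allele of pool A
        p1 = sa.n_maj / da
        p2 = _freq_of_allele(sb, sa.major_allele)
        if p2 is None:
            continue
        a, b = _wc_site_components(
            p1, min(da, size_a), p2, min(db, size_b)
        )
        if math.isnan(a):
            continue
        num += a
        den += a + b
        n_shared += 1
    if n_shared == 0 or den == 0.0:
        return None
    return num / den


def _freq_of_allele(site: SiteAlleleFreq, allele: str) -> float | None:
    """Frequency of ``allele`` in a site's top-two allele counts.

    The two pools may disagree on which alleles segregate; an allele
    absent from the site's major/minor pair has frequency 0.
    """
    if site.depth == 0:
        return None
    if allele == site.major_allele:
        return site.n_maj / site.depth
    if allele == site.minor_allele:
        return site.n_min / site.depth
    return 0.0
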