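"""Window construction, top-quantile thresholding and sweep calling.

The scan tiles each scaffold with fixed non-overlapping windows
(default 10 kb) anchored at position 1, discards windows with too few
SNPs, thresholds each statistic's distribution at its top quantile
(default 3%), and calls sweeps by a three-step intersection:

1. windows in the top quantile of the FST scan of *both* population
   pairs;
2. windows in the top quantile of the -ZHp scan of *both* target pools;
3. the intersection of (1) and (2).

Surviving adjacent windows are merged into contiguous regions, which
are then overlapped against gene models extended by a flanking margin
(default 10 kb) on each side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from poolscan.diversity import WindowStat
from poolscan.io import GeneModel


class MismatchedTilingError(ValueError):
    """Window sets on incompatible tilings cannot be intersected."""


class SweepStep(str, Enum):
    FST_INTERSECT = "fst_intersect"
    ZHP_INTERSECT = "zhp_intersect"
    FINAL_OVERLAP = "final_overlap"


@dataclass(slots=True)
class Window:
    """A genome window with its member sites (any per-site record type)."""

    scaffold: str
    start: int
    end: int
    sites: list
    discarded: bool = False

    @property
    def snp_count(self) -> int:
        return len(self.sites)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.scaffold, self.start, self.end)


@dataclass(slots=True)
class Region:
    """A maximal run of adjacent surviving windows."""

    scaffold: str
    start: int
    end: int
    n_windows: int


@dataclass(slots=True)
class SweepCallSet:
    """Windows surviving one step of the sweep-calling procedure."""

    step: SweepStep
    windows: list[WindowStat]
    thresholds: dict[str, float] = field(default_factory=dict)
    #: all statistic values per surviving window key, by scan label
    values: dict[tuple[str, int, int], dict[str, float]] = field(
        default_factory=dict
    )

    @property
    def keys(self) -> set[tuple[str, int, int]]:
        return {w.key for w in self.windows}

    def regions(self) -> list[Region]:
        return merge_adjacent_windows(self.windows)


@dataclass(slots=True)
class GeneHit:
    """A gene whose flanked span intersects >= 1 called sweep region."""

    gene: GeneModel
    regions: list[Region]
    flank_bp: int = 10_000


def window_index(position: int, window_size: int) -> int:
    """1-based index of the window containing a 1-based position.

    Position ``w * window_size`` is the last base of window ``w``;
    ``w * window_size + 1`` opens window ``w + 1``.
    """
    return (position + window_size - 1) // window_size


def make_windows(
    sites: Sequence,
    window_size: int = 10_000,
    min_snps: int = 10,
) -> list[Window]:
    """Tile one scaffold's sorted sites into fixed windows.

    Windows are ``[1, w]``, ``[w+1, 2w]``, ... anchored at position 1.
    Windows holding fewer than ``min_snps`` sites are marked discarded
    (they are excluded from every downstream distribution); a trailing
    partial window is kept if it meets the SNP minimum. Only windows
    containing at least one site are materialised.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: list[Window] = []
    current: Window | None = None
    last_pos = -1
    for site in sites:
        if site.position < last_pos and current is not None and \
                site.scaffold == current.scaffold:
            raise ValueError("sites must be sorted by position")
        idx = window_index(site.position, window_size)
        start = (idx - 1) * window_size + 1
        if (
            current is None
            or current.scaffold != site.scaffold
            or current.start != start
        ):
            current = Window(site.scaffold, start, idx * window_size, [])
            windows.append(current)
        current.sites.append(site)
        last_pos = site.position
    for w in windows:
        w.discarded = w.snp_count < min_snps
    return windows


def top_quantile_threshold(
    windows: Sequence[WindowStat], top_fraction: float = 0.03
) -> tuple[float, list[WindowStat]]:
    """Empirical top-quantile cutoff and the windows at or above it.

    The cutoff is the ``1 - top_fraction`` quantile under the "higher"
    interpolation rule (the cutoff is always an observed value), and
    every window whose value ties the cutoff is selected — ties inflate
    the selection rather than being broken arbitrarily.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    values = np.asarray([w.value for w in windows], dtype=float)
    if values.size == 0:
        raise ValueError("no defined window values")
    if values.size == 1:
        warnings.warn("single-window scan: degenerate threshold", stacklevel=2)
        return float(values[0]), list(windows)
    if np.all(values == values[0]):
        raise ValueError("all window values identical: no upper tail")
    cutoff = float(np.quantile(values, 1.0 - top_fraction, method="higher"))
    selected = [w for w in windows if w.value >= cutoff]
    return cutoff, selected


def _check_tiling(a: Sequence[WindowStat], b: Sequence[WindowStat]) -> None:
    # overlapping-but-unequal windows on a shared scaffold mean the two
    # scans were windowed differently
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for w in a:
        by_scaffold.setdefault(w.scaffold, []).append((w.start, w.end))
    for w in b:
        for start, end in by_scaffold.get(w.scaffold, ()):
            if start <= w.end and w.start <= end and (start, end) != (w.start, w.end):
                raise MismatchedTilingError(
                    f"{w.scaffold}: window [{w.start},{w.end}] overlaps "
                    f"[{start},{end}] from the other scan"
                )


def intersect_scans(
    selected_a: Sequence[WindowStat], selected_b: Sequence[WindowStat]
) -> list[WindowStat]:
    """Windows selected by both scans, matched by (scaffold, start, end).

    Commutative; the result keeps the first scan's window records (all
    *values* are carried separately by :func:`final_overlap` /
    :class:`SweepCallSet`). Disjoint selections yield an empty list with
    a warning so a pipeline can continue and report zero candidates.
    """
    _check_tiling(selected_a, selected_b)
    keys_b = {w.key for w in selected_b}
    out = [w for w in selected_a if w.key in keys_b]
    if not out and selected_a and selected_b:
        warnings.warn("scan intersection is empty", stacklevel=2)
    return out


def final_overlap(
    fst_intersection: Sequence[WindowStat],
    zhp_intersection: Sequence[WindowStat],
    thresholds: Mapping[str, float] | None = None,
) -> SweepCallSet:
    """Step 3: windows surviving both the FST and the -ZHp intersections."""
    _check_tiling(fst_intersection, zhp_intersection)
    keys_z = {w.key for w in zhp_intersection}
    surviving = [w for w in fst_intersection if w.key in keys_z]
    values: dict[tuple[str, int, int], dict[str, float]] = {}
    for w in surviving:
        values[w.key] = {}
    for w in list(fst_intersection) + list(zhp_intersection):
        if w.key in values:
            label = w.pool_or_pair or w.stat_name
            values[w.key][f"{w.stat_name}:{label}"] = w.value
    return SweepCallSet(
        step=SweepStep.FINAL_OVERLAP,
        windows=surviving,
        thresholds=dict(thresholds or {}),
        values=values,
    )


def merge_adjacent_windows(windows: Sequence[WindowStat]) -> list[Region]:
    """Merge book-ended windows (next start == previous end + 1) into regions."""
    ordered = sorted(windows, key=lambda w: (w.scaffold, w.start))
    regions: list[Region] = []
    for w in ordered:
        if (
            regions
            and regions[-1].scaffold == w.scaffold
            and w.start == regions[-1].end + 1
        ):
            regions[-1].end = w.end
            regions[-1].n_windows += 1
        else:
            regions.append(Region(w.scaffold, w.start, w.end, 1))
    return regions


def overlap_genes(
    call_set: SweepCallSet | Sequence[Region],
    genes: Sequence[GeneModel],
    flank_bp: int = 10_000,
) -> list[GeneHit]:
    """Genes whose flanked span intersects a called sweep region.

    A gene is hit iff some region intersects
    ``[start - flank_bp, end + flank_bp]`` (clipped at 1, boundaries
    inclusive) on the same scaffold. Output is sorted by scaffold then
    gene start.
    """
    regions = (
        call_set.regions() if isinstance(call_set, SweepCallSet) else list(call_set)
    )
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        # interval tree is half-open; +1 makes the end inclusive
        trees.setdefault(r.scaffold, IntervalTree()).addi(r.start, r.end + 1, r)
    hits: list[GeneHit] = []
    for gene in sorted(genes, key=lambda g: (g.scaffold, g.start)):
        tree = trees.get(gene.scaffold)
        if tree is None:
            continue
        lo = max(1, gene.start - flank_bp)
        hi = gene.end + flank_bp
        overlapping = sorted(
            (iv.data for iv in tree.overlap(lo, hi + 1)),
            key=lambda r: r.start,
        )
        if overlapping:
            hits.append(GeneHit(gene=gene, regions=overlapping, flank_bp=flank_bp))
    return hits
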