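"""End-to-end orchestration of the sweep scan.

:func:`run_scan` is the in-memory pipeline: site filters -> windows ->
Hp / -ZHp per target pool -> FST per (reference, target) pair ->
per-scan top-quantile thresholds -> pairwise intersections -> final
overlap. :func:`run_pipeline` wraps it with file I/O, gene overlap and
a checksummed output manifest for reproducible command-line runs.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from poolscan.diversity import (
    HpMoments,
    SiteAlleleFreq,
    StatName,
    WindowStat,
    _near_indel,
    fst_window,
    hp_window,
    site_allele_freq,
    zhp_transform,
)
from poolscan.io import (
    GeneModel,
    PoolSiteCounts,
    SiteFilterParams,
    SyncSite,
    read_genes,
    read_sync,
    write_windows_bed,
)
from poolscan.sweep import (
    GeneHit,
    Region,
    SweepCallSet,
    SweepStep,
    final_overlap,
    intersect_scans,
    make_windows,
    overlap_genes,
    top_quantile_threshold,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults are the scan's standard
    settings (10-kb windows, >= 10 SNPs, top 3%, 10-kb gene flanks)."""

    sync_path: str = ""
    genes_path: str = ""
    out_dir: str = "poolscan_out"
    pool_names: tuple[str, ...] = ("gray", "white1", "white2")
    haploid_sizes: dict[str, int] = field(
        default_factory=lambda: {"gray": 234, "white1": 50, "white2": 174}
    )
    reference_pool: str = "gray"
    target_pools: tuple[str, ...] = ("white1", "white2")
    filter_params: SiteFilterParams = field(default_factory=SiteFilterParams)
    window_size: int = 10_000
    min_snps: int = 10
    top_fraction: float = 0.03
    flank_bp: int = 10_000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file."""
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"config line without '=': {line!r}")
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        cfg = cls()
        fp = {}
        for key, value in raw.items():
            if key in ("sync_path", "genes_path", "out_dir", "reference_pool"):
                setattr(cfg, key, value)
            elif key in ("pool_names", "target_pools"):
                setattr(cfg, key, tuple(v.strip() for v in value.split(",")))
            elif key == "haploid_sizes":
                cfg.haploid_sizes = {
                    kv.split(":")[0].strip(): int(kv.split(":")[1])
                    for kv in value.split(",")
                }
            elif key in ("window_size", "min_snps", "flank_bp", "seed"):
                setattr(cfg, key, int(value))
            elif key == "top_fraction":
                cfg.top_fraction = float(value)
            elif key in ("min_depth", "max_depth", "indel_exclusion_bp"):
                fp[key] = int(value)
            elif key in ("min_maf", "min_quality"):
                fp[key] = float(value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        if fp:
            cfg.filter_params = SiteFilterParams(**fp)
        return cfg


@dataclass
class ScanResult:
    """Everything one scan produced, keyed by pool / pool pair."""

    hp_windows: dict[str, list[WindowStat]]
    hp_moments: dict[str, HpMoments]
    zhp_windows: dict[str, list[WindowStat]]
    fst_windows: dict[str, list[WindowStat]]
    thresholds: dict[str, float]
    fst_intersection: SweepCallSet
    zhp_intersection: SweepCallSet
    final: SweepCallSet
    regions: list[Region]
    filter_tallies: dict[str, Counter]
    n_windows_discarded: dict[str, int]

    def gene_hits(
        self, genes: Sequence[GeneModel], flank_bp: int = 10_000
    ) -> list[GeneHit]:
        return overlap_genes(self.final, genes, flank_bp=flank_bp)


def _pool_sites(sites: Sequence[SyncSite]) -> dict[str, list[PoolSiteCounts]]:
    pools: dict[str, list[PoolSiteCounts]] = {}
    for site in sites:
        for p in site.pools:
            pools.setdefault(p.pool_id, []).append(p)
    return pools


def joint_site_filter(
    sites: Sequence[SyncSite],
    pool_ids: Sequence[str],
    params: SiteFilterParams | None = None,
    indel_positions: Mapping[str, Sequence[int]] | None = None,
) -> tuple[dict[str, dict[tuple[str, int], SiteAlleleFreq]], dict[str, Counter]]:
    """Site filters with the MAF criterion on counts pooled across pools.

    SNP sets for multi-pool scans come from joint variant calling: a
    site's minor-allele frequency is assessed on the combined read
    counts of all pools, so a site monomorphic in a swept population
    but polymorphic in the reference is retained — exactly the sites a
    heterozygosity scan must keep. Depth bounds and quality apply per
    pool; the indel exclusion is a site-level decision.

    Returns per-pool ``{(scaffold, position): SiteAlleleFreq}`` maps of
    the retained sites plus per-pool rejection tallies (reason order:
    indel, maf, depth, quality; ``maf``/``indel`` rejections count in
    every pool's tally since they remove the site everywhere).
    """
    import numpy as np

    if params is None:
        params = SiteFilterParams()
    indel_arrays = {
        sc: np.asarray(pos, dtype=np.int64)
        for sc, pos in (indel_positions or {}).items()
    }
    retained: dict[str, dict[tuple[str, int], SiteAlleleFreq]] = {
        pid: {} for pid in pool_ids
    }
    tallies: dict[str, Counter] = {pid: Counter() for pid in pool_ids}
    wanted = set(pool_ids)
    for site in sites:
        pools = [p for p in site.pools if p.pool_id in wanted]
        if not pools:
            continue
        indels = indel_arrays.get(site.scaffold)
        if indels is not None and indels.size and _near_indel(
            site.position, indels, params.indel_exclusion_bp
        ):
            for p in pools:
                tallies[p.pool_id]["indel"] += 1
            continue
        combined: dict[str, int] = {}
        for p in pools:
            for a, n in p.counts.items():
                combined[a] = combined.get(a, 0) + n
        merged = PoolSiteCounts(
            site.scaffold, site.position, site.ref_allele, combined, "combined"
        )
        if site_allele_freq(merged).maf < params.min_maf:
            for p in pools:
                tallies[p.pool_id]["maf"] += 1
            continue
        key = (site.scaffold, site.position)
        for p in pools:
            if not params.min_depth <= p.depth <= params.max_depth:
                tallies[p.pool_id]["depth"] += 1
                continue
            if p.quality is not None and p.quality < params.min_quality:
                tallies[p.pool_id]["quality"] += 1
                continue
            retained[p.pool_id][key] = site_allele_freq(p)
            tallies[p.pool_id]["retained"] += 1
    return retained, tallies


def _windows_by_scaffold(
    afs: Sequence[SiteAlleleFreq], window_size: int, min_snps: int
):
    by_scaffold: dict[str, list[SiteAlleleFreq]] = {}
    for s in afs:
        by_scaffold.setdefault(s.scaffold, []).append(s)
    windows = []
    for scaffold in sorted(by_scaffold):
        rows = sorted(by_scaffold[scaffold], key=lambda s: s.position)
        windows.extend(make_windows(rows, window_size, min_snps))
    return windows


def run_scan(
    sites: Sequence[SyncSite],
    haploid_sizes: Mapping[str, int],
    reference_pool: str,
    target_pools: Sequence[str],
    filter_params: SiteFilterParams | None = None,
    indel_positions: Mapping[str, Sequence[int]] | None = None,
    window_size: int = 10_000,
    min_snps: int = 10,
    top_fraction: float = 0.03,
) -> ScanResult:
    """Run the full three-step sweep scan in memory.

    ``sites`` is the multi-pool site stream (from :func:`read_sync`, a
    VCF, or the simulator). Site filters run jointly (MAF on combined
    counts, depth per pool; see :func:`joint_site_filter`). Hp / -ZHp
    scans run on each target pool; FST scans on each (reference,
    target) pair over the sites retained in both members of the pair.
    Thresholds are per scan, over that scan's retained windows only.
    """
    pool_ids = [reference_pool, *target_pools]
    seen = {p.pool_id for s in sites[:1] for p in s.pools}
    for pid in pool_ids:
        if sites and pid not in seen:
            raise ValueError(f"pool {pid!r} absent from input")
        if pid not in haploid_sizes:
            raise ValueError(f"no haploid pool size for {pid!r}")

    filtered, tallies = joint_site_filter(
        sites, pool_ids, filter_params, indel_positions
    )
    for pid in pool_ids:
        log.info("pool %s: %d sites retained", pid, len(filtered[pid]))

    hp_windows: dict[str, list[WindowStat]] = {}
    hp_moments: dict[str, HpMoments] = {}
    zhp_windows: dict[str, list[WindowStat]] = {}
    n_discarded: dict[str, int] = {}
    for pid in target_pools:
        windows = _windows_by_scaffold(
            list(filtered[pid].values()), window_size, min_snps
        )
        retained = [w for w in windows if not w.discarded]
        n_discarded[f"hp:{pid}"] = sum(w.discarded for w in windows)
        hp_stats = [
            WindowStat(
                w.scaffold, w.start, w.end, w.snp_count,
                hp_window(w.sites), StatName.HP.value, pid,
            )
            for w in retained
        ]
        hp_windows[pid] = hp_stats
        zhp_values, moments = zhp_transform([w.value for w in hp_stats])
        hp_moments[pid] = moments
        zhp_windows[pid] = [
            WindowStat(
                w.scaffold, w.start, w.end, w.snp_count,
                z, StatName.ZHP_NEG.value, pid,
            )
            for w, z in zip(hp_stats, zhp_values)
        ]

    fst_windows: dict[str, list[WindowStat]] = {}
    ref_sites = filtered[reference_pool]
    for pid in target_pools:
        pair = f"{reference_pool}_vs_{pid}"
        shared_keys = ref_sites.keys() & filtered[pid].keys()
        shared = sorted(shared_keys)
        pair_sites = [ref_sites[k] for k in shared]
        windows = _windows_by_scaffold(pair_sites, window_size, min_snps)
        retained = [w for w in windows if not w.discarded]
        n_discarded[f"fst:{pair}"] = sum(w.discarded for w in windows)
        stats = []
        other = filtered[pid]
        sizes = (haploid_sizes[reference_pool], haploid_sizes[pid])
        for w in retained:
            value = fst_window(
                w.sites,
                [other[(s.scaffold, s.position)] for s in w.sites],
                sizes,
            )
            if value is None:
                continue
            stats.append(
                WindowStat(
                    w.scaffold, w.start, w.end, w.snp_count,
                    value, StatName.FST.value, pair,
                )
            )
        fst_windows[pair] = stats

    thresholds: dict[str, float] = {}
    fst_selected: list[list[WindowStat]] = []
    for pair, stats in fst_windows.items():
        cutoff, selected = top_quantile_threshold(stats, top_fraction)
        thresholds[f"fst:{pair}"] = cutoff
        fst_selected.append(selected)
    zhp_selected: list[list[WindowStat]] = []
    for pid in target_pools:
        cutoff, selected = top_quantile_threshold(zhp_windows[pid], top_fraction)
        thresholds[f"zhp:{pid}"] = cutoff
        zhp_selected.append(selected)

    step1 = fst_selected[0]
    for sel in fst_selected[1:]:
        step1 = intersect_scans(step1, sel)
    step2 = zhp_selected[0]
    for sel in zhp_selected[1:]:
        step2 = intersect_scans(step2, sel)

    fst_call = SweepCallSet(SweepStep.FST_INTERSECT, step1, dict(thresholds))
    zhp_call = SweepCallSet(SweepStep.ZHP_INTERSECT, step2, dict(thresholds))
    final = final_overlap(step1, step2, thresholds)
    return ScanResult(
        hp_windows=hp_windows,
        hp_moments=hp_moments,
        zhp_windows=zhp_windows,
        fst_windows=fst_windows,
        thresholds=thresholds,
        fst_intersection=fst_call,
        zhp_intersection=zhp_call,
        final=final,
        regions=final.regions(),
        filter_tallies=tallies,
        n_windows_discarded=n_discarded,
    )


def _write_windows_tsv(windows: Sequence[WindowStat], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\tn_snps\tstat\tscan\tvalue\n")
        for w in sorted(windows, key=lambda w: (w.scaffold, w.start)):
            fh.write(
                f"{w.scaffold}\t{w.start}\t{w.end}\t{w.snp_count}\t"
                f"{w.stat_name}\t{w.pool_or_pair}\t{w.value:.6f}\n"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """File-based pipeline run; returns {relative path: sha256} manifest.

    Reads the sync file (and gene annotation if configured), runs
    :func:`run_scan`, and writes per-scan window TSVs, the threshold
    report, the final-region BED, the gene-hit TSV and a
    ``manifest.tsv`` of content checksums. Identical config and inputs
    produce identical checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites = read_sync(config.sync_path, pool_names=config.pool_names)
    genes = read_genes(config.genes_path) if config.genes_path else []

    result = run_scan(
        sites,
        haploid_sizes=config.haploid_sizes,
        reference_pool=config.reference_pool,
        target_pools=config.target_pools,
        filter_params=config.filter_params,
        window_size=config.window_size,
        min_snps=config.min_snps,
        top_fraction=config.top_fraction,
    )
    for pid, tally in result.filter_tallies.items():
        log.info("filter tally %s: %s", pid, dict(tally))
    log.info("windows discarded (min_snps): %s", result.n_windows_discarded)

    written: list[Path] = []
    for pid, windows in result.hp_windows.items():
        p = out / f"hp_{pid}.tsv"
        _write_windows_tsv(windows, p)
        written.append(p)
    for pid, windows in result.zhp_windows.items():
        p = out / f"zhp_{pid}.tsv"
        _write_windows_tsv(windows, p)
        written.append(p)
    for pair, windows in result.fst_windows.items():
        p = out / f"fst_{pair}.tsv"
        _write_windows_tsv(windows, p)
        written.append(p)

    p = out / "thresholds.tsv"
    with open(p, "w") as fh:
        fh.write("#scan\tcutoff\n")
        for scan in sorted(result.thresholds):
            fh.write(f"{scan}\t{result.thresholds[scan]:.6f}\n")
    written.append(p)

    p = out / "final_regions.bed"
    with open(p, "w") as fh:
        for r in sorted(result.regions, key=lambda r: (r.scaffold, r.start)):
            fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t{r.n_windows}\n")
    written.append(p)

    p = out / "final_windows.bed"
    write_windows_bed(result.final.windows, p)
    written.append(p)

    p = out / "gene_hits.tsv"
    hits = result.gene_hits(genes, flank_bp=config.flank_bp) if genes else []
    with open(p, "w") as fh:
        fh.write("#gene_id\tscaffold\tstart\tend\tstrand\tn_regions\tregions\n")
        for h in hits:
            regions = ",".join(f"{r.start}-{r.end}" for r in h.regions)
            g = h.gene
            fh.write(
                f"{g.gene_id}\t{g.scaffold}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{len(h.regions)}\t{regions}\n"
            )
    written.append(p)

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("#file\tsha256\n")
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    return manifest
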