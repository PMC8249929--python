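"""Synthetic Pool-Seq data with known truth, for end-to-end testing.

The generator emulates the structure of a three-pool domestication
scan: one reference pool keeping wild-type allele frequencies and two
target pools in which planted "sweep" regions have a derived allele
pushed to high frequency — which depresses pooled heterozygosity in
the target pools and raises their divergence from the reference pool.
Outside sweeps, all pools share a baseline frequency per site plus
small independent drift noise.

Read counts are drawn binomially from each pool's true allele
frequency at a Poisson-distributed depth; sequencing error flips a
read between the site's two alleles at a fixed rate. This targets the
assumptions of the window statistics (independent sites, binomial read
sampling), not population-genetic realism: there is no linkage,
recombination or demography, so the decay of diversity around a sweep
is a step function rather than a valley.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from poolscan.association import GenotypeTable
from poolscan.io import PoolSiteCounts, SyncSite


@dataclass(frozen=True, slots=True)
class PoolSpec:
    """One sequencing pool: who was pooled and how deep it was sequenced."""

    pool_id: str
    n_diploids: int
    mean_depth: float = 44.0

    @property
    def haploid_size(self) -> int:
        return 2 * self.n_diploids


@dataclass(frozen=True, slots=True)
class SweepSpec:
    """A planted sweep: the derived allele is fixed near ``derived_freq``
    in every target pool across the region."""

    scaffold: str
    start: int
    end: int
    target_pools: tuple[str, ...]
    derived_freq: float = 0.98

    def __post_init__(self) -> None:
        if not 0.5 < self.derived_freq <= 1.0:
            raise ValueError("derived_freq must lie in (0.5, 1]")


def default_pools() -> list[PoolSpec]:
    """The study design the generator mirrors: a gray reference pool of
    117 diploids and two white pools of 25 and 87, all near 44x depth."""
    return [
        PoolSpec("gray", 117),
        PoolSpec("white1", 25),
        PoolSpec("white2", 87),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``snp_density`` of 0.002/bp gives ~20 SNPs per 10-kb window, so the
    10-SNP window filter passes most windows while still rejecting
    sparse tails. Baseline minor allele frequencies are uniform on
    ``[maf_low, maf_high]`` so sites pass the 0.05 MAF filter by
    construction; ``low_maf_fraction`` injects sites below the filter
    to exercise the rejection path. ``drift_sd`` is small independent
    per-pool noise standing in for drift between the populations.
    """

    n_scaffolds: int = 5
    scaffold_length_bp: int = 1_000_000
    snp_density: float = 0.002
    pools: tuple[PoolSpec, ...] = field(
        default_factory=lambda: tuple(default_pools())
    )
    sweep_regions: tuple[SweepSpec, ...] = ()
    maf_low: float = 0.05
    maf_high: float = 0.5
    low_maf_fraction: float = 0.0
    drift_sd: float = 0.03
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for sw in self.sweep_regions:
            if sw.start < 1 or sw.end > self.scaffold_length_bp:
                raise ValueError(
                    f"sweep {sw.scaffold}:{sw.start}-{sw.end} outside "
                    f"scaffold bounds [1, {self.scaffold_length_bp}]"
                )
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        for p in self.pools:
            if p.mean_depth <= 0:
                raise ValueError("mean_depth must be positive")

    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(slots=True)
class TruthSet:
    """Per-site true allele frequencies per pool, plus the planted sweeps.

    ``frame`` columns: scaffold, position, ref, alt, and one
    ``freq_<pool_id>`` column per pool holding the true derived (alt)
    allele frequency.
    """

    frame: pd.DataFrame
    sweeps: tuple[SweepSpec, ...]

    def sweep_mask(self, scaffold: np.ndarray, position: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(position), dtype=bool)
        for sw in self.sweeps:
            mask |= (
                (scaffold == sw.scaffold)
                & (position >= sw.start)
                & (position <= sw.end)
            )
        return mask


_NTS = np.array(["A", "C", "G", "T"])


def simulate_pool_counts(
    config: SimulationConfig,
) -> tuple[list[SyncSite], TruthSet]:
    """Draw a synthetic sync-format dataset and its truth.

    Deterministic under ``config.seed`` (identical config => identical
    sites). Emits a warning naming any sweep region that received fewer
    SNPs than the conventional 10-SNP window minimum.
    """
    import warnings

    rng = np.random.default_rng(config.seed)
    pool_ids = [p.pool_id for p in config.pools]
    for sw in config.sweep_regions:
        unknown = set(sw.target_pools) - set(pool_ids)
        if unknown:
            raise ValueError(f"sweep targets unknown pools {sorted(unknown)}")

    sites: list[SyncSite] = []
    truth_rows: list[pd.DataFrame] = []
    for scaffold in config.scaffold_names():
        n_sites = rng.binomial(config.scaffold_length_bp, config.snp_density)
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(config.scaffold_length_bp, size=n_sites, replace=False) + 1
        )
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        ref = _NTS[ref_idx]
        alt = _NTS[alt_idx]

        maf = rng.uniform(config.maf_low, config.maf_high, size=n_sites)
        if config.low_maf_fraction > 0:
            low = rng.random(n_sites) < config.low_maf_fraction
            maf[low] = rng.uniform(0.001, config.maf_low, size=int(low.sum()))
        # alt is the derived allele; orient it randomly so alt can be
        # major or minor at baseline
        flip = rng.random(n_sites) < 0.5
        p0 = np.where(flip, 1.0 - maf, maf)

        freqs: dict[str, np.ndarray] = {}
        for pool in config.pools:
            noise = rng.normal(0.0, config.drift_sd, size=n_sites)
            freqs[pool.pool_id] = np.clip(p0 + noise, 0.0, 1.0)
        for sw in config.sweep_regions:
            if sw.scaffold != scaffold:
                continue
            in_sweep = (positions >= sw.start) & (positions <= sw.end)
            if int(in_sweep.sum()) < 10:
                warnings.warn(
                    f"sweep {sw.scaffold}:{sw.start}-{sw.end} holds only "
                    f"{int(in_sweep.sum())} SNPs",
                    stacklevel=2,
                )
            for pid in sw.target_pools:
                freqs[pid] = np.where(in_sweep, sw.derived_freq, freqs[pid])

        depth: dict[str, np.ndarray] = {}
        alt_reads: dict[str, np.ndarray] = {}
        e = config.error_rate
        for pool in config.pools:
            d = rng.poisson(pool.mean_depth, size=n_sites)
            d = np.clip(d, 1, int(3 * pool.mean_depth))
            p = freqs[pool.pool_id]
            p_obs = p * (1.0 - e) + (1.0 - p) * e
            alt_reads[pool.pool_id] = rng.binomial(d, p_obs)
            depth[pool.pool_id] = d

        for i in range(n_sites):
            pools = tuple(
                PoolSiteCounts(
                    scaffold=scaffold,
                    position=int(positions[i]),
                    ref_allele=str(ref[i]),
                    counts={
                        str(ref[i]): int(depth[pid][i] - alt_reads[pid][i]),
                        str(alt[i]): int(alt_reads[pid][i]),
                    },
                    pool_id=pid,
                )
                for pid in pool_ids
            )
            sites.append(SyncSite(scaffold, int(positions[i]), str(ref[i]), pools))

        truth_rows.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "position": positions,
                    "ref": ref,
                    "alt": alt,
                    **{f"freq_{pid}": freqs[pid] for pid in pool_ids},
                }
            )
        )

    frame = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(
            columns=["scaffold", "position", "ref", "alt"]
            + [f"freq_{pid}" for pid in pool_ids]
        )
    )
    return sites, TruthSet(frame=frame, sweeps=tuple(config.sweep_regions))


def default_sweep_regions(
    config: SimulationConfig,
    n_sweeps: int = 3,
    sweep_length_bp: int = 40_000,
    derived_freq: float = 0.98,
    target_pools: Sequence[str] = ("white1", "white2"),
    seed: int | None = None,
) -> tuple[SweepSpec, ...]:
    """Place sweeps at window-aligned positions on distinct scaffolds.

    The default sweep length keeps the total number of swept windows
    below the scan's top-quantile capacity (3 x 40 kb = 12 windows
    against the ~15-window 3% tail of a 5 x 1 Mb genome): a sweep
    occupying more windows than the tail can hold cannot survive the
    intersection of independently thresholded scans in full.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scaffolds = config.scaffold_names()
    chosen = rng.choice(
        len(scaffolds), size=min(n_sweeps, len(scaffolds)), replace=False
    )
    n_slots = config.scaffold_length_bp // sweep_length_bp
    sweeps = []
    for idx in chosen:
        slot = int(rng.integers(0, max(1, n_slots - 1)))
        start = slot * sweep_length_bp + 1
        sweeps.append(
            SweepSpec(
                scaffold=scaffolds[int(idx)],
                start=start,
                end=start + sweep_length_bp - 1,
                target_pools=tuple(target_pools),
                derived_freq=derived_freq,
            )
        )
    return tuple(sweeps)


def simulate_genotype_table(
    n_per_group: Sequence[int],
    genotype_probs_per_group: Sequence[Sequence[float]],
    genotypes: Sequence[str] = ("AA", "AB", "BB"),
    groups: Sequence[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> GenotypeTable:
    """Multinomial genotype counts per phenotype group.

    ``genotype_probs_per_group[g]`` is the genotype distribution of
    group ``g`` (must sum to 1); identical rows across groups give a
    null table for calibrating the chi-square association test.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if len(n_per_group) != len(genotype_probs_per_group):
        raise ValueError("one probability row per group required")
    cols = []
    for n, probs in zip(n_per_group, genotype_probs_per_group):
        probs = np.asarray(probs, dtype=float)
        if n < 0 or (probs < 0).any():
            raise ValueError("counts and probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("genotype probabilities must sum to 1")
        if len(probs) != len(genotypes):
            raise ValueError("one probability per genotype required")
        cols.append(rng.multinomial(n, probs))
    counts = np.column_stack(cols)
    group_labels = (
        list(groups)
        if groups is not None
        else [f"group{i + 1}" for i in range(len(n_per_group))]
    )
    return GenotypeTable(
        genotypes=list(genotypes),
        groups=group_labels,
        counts=counts.tolist(),
    )
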