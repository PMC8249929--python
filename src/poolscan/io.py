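"""Readers and writers for the formats a Pool-Seq scan touches.

Supported formats: PoPoolation2 ``sync`` (the per-site allele-count
interchange format), VCF with per-sample allele depths, GFF3/BED gene
annotations, and BED/TSV window output.

Internal coordinates are 1-based inclusive throughout (matching sync and
GFF3); BED's 0-based half-open convention is converted at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: allele order of a sync pool column
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

#: alleles that count towards depth and allele frequency ("N" and "del"
#: carry no frequency information for a biallelic SNP set)
NUCLEOTIDES = ("A", "C", "G", "T")


class SyncParseError(ValueError):
    """A malformed line or column in a sync file."""


class StructuralError(ValueError):
    """Structurally inconsistent input (pool counts, interval bounds)."""


@dataclass(slots=True)
class PoolSiteCounts:
    """Read counts of one genomic site in one pool.

    Parameters
    ----------
    scaffold : str
        Scaffold / chromosome identifier.
    position : int
        1-based coordinate.
    ref_allele : str
        Reference base, one of ``A, C, G, T, N``.
    counts : dict
        Map from allele symbol (``A, T, C, G, N, del``) to read count.
    pool_id : str
        Pool label.
    quality : float, optional
        Phred-scaled site quality if the source format provides one
        (VCF QUAL); ``None`` for sync input.
    """

    scaffold: str
    position: int
    ref_allele: str
    counts: dict[str, int]
    pool_id: str
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for allele, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count {n} for allele {allele}")

    @property
    def depth(self) -> int:
        """Total read depth over A/C/G/T (N and del excluded)."""
        return sum(self.counts.get(a, 0) for a in NUCLEOTIDES)

    def nucleotide_counts(self) -> dict[str, int]:
        """Counts restricted to the four nucleotides."""
        return {a: self.counts.get(a, 0) for a in NUCLEOTIDES}


@dataclass(slots=True)
class SyncSite:
    """One genomic site across all pools of a sync file."""

    scaffold: str
    position: int
    ref_allele: str
    pools: tuple[PoolSiteCounts, ...]
    split_from_multiallelic: bool = False


@dataclass(frozen=True)
class SiteFilterParams:
    """Site-level SNP filters.

    Defaults are the conventional Pool-Seq quality-control settings:
    depth within [10, 100], minor allele frequency >= 0.05, phred site
    quality >= 20, and exclusion of SNPs within 15 bp of an indel.
    """

    min_depth: int = 10
    max_depth: int = 100
    min_maf: float = 0.05
    min_quality: float = 20.0
    indel_exclusion_bp: int = 15

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene interval on a scaffold, 1-based inclusive."""

    scaffold: str
    start: int
    end: int
    gene_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise StructuralError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )


def _parse_pool_column(column: str, line_no: int) -> dict[str, int]:
    parts = column.split(":")
    if len(parts) != len(SYNC_ALLELES):
        raise SyncParseError(
            f"line {line_no}: pool column {column!r} has {len(parts)} fields, "
            f"expected {len(SYNC_ALLELES)} (A:T:C:G:N:del)"
        )
    try:
        values = [int(p) for p in parts]
    except ValueError as exc:
        raise SyncParseError(
            f"line {line_no}: non-integer count in pool column {column!r}"
        ) from exc
    if any(v < 0 for v in values):
        raise SyncParseError(f"line {line_no}: negative count in {column!r}")
    return dict(zip(SYNC_ALLELES, values))


def read_sync(
    path: str | Path, pool_names: Sequence[str] | None = None
) -> list[SyncSite]:
    """Read a PoPoolation2 sync file.

    Each line is ``scaffold  position  ref  A:T:C:G:N:del ...`` with one
    count column per pool. Pool identity is positional; ``pool_names``
    overrides the default labels ``pool1..poolK``.
    """
    sites: list[SyncSite] = []
    n_pools: int | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"line {line_no}: expected >= 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            scaffold, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                position = int(pos_s)
            except ValueError as exc:
                raise SyncParseError(
                    f"line {line_no}: non-integer position {pos_s!r}"
                ) from exc
            pool_cols = fields[3:]
            if n_pools is None:
                n_pools = len(pool_cols)
                if pool_names is not None and len(pool_names) != n_pools:
                    raise StructuralError(
                        f"{len(pool_names)} pool names supplied for "
                        f"{n_pools} pool columns"
                    )
            elif len(pool_cols) != n_pools:
                raise StructuralError(
                    f"line {line_no}: {len(pool_cols)} pool columns, "
                    f"previous lines had {n_pools}"
                )
            names = (
                pool_names
                if pool_names is not None
                else [f"pool{i + 1}" for i in range(n_pools)]
            )
            pools = tuple(
                PoolSiteCounts(
                    scaffold=scaffold,
                    position=position,
                    ref_allele=ref,
                    counts=_parse_pool_column(col, line_no),
                    pool_id=names[i],
                )
                for i, col in enumerate(pool_cols)
            )
            sites.append(SyncSite(scaffold, position, ref, pools))
    return sites


def write_sync(sites: Iterable[SyncSite], path: str | Path) -> None:
    """Write sites in sync format (inverse of :func:`read_sync`)."""
    with open(path, "w") as fh:
        for site in sites:
            cols = [
                ":".join(str(p.counts.get(a, 0)) for a in SYNC_ALLELES)
                for p in site.pools
            ]
            fh.write(
                "\t".join([site.scaffold, str(site.position), site.ref_allele, *cols])
                + "\n"
            )


def read_allele_depth_vcf(
    path: str | Path,
    depth_field: str = "AD",
    pool_names: Sequence[str] | None = None,
) -> list[SyncSite]:
    """Read a multi-sample VCF with per-sample allele depths into sites.

    REF/ALT depths from ``depth_field`` (FORMAT tag, e.g. ``AD``) are
    mapped onto the nucleotide count map. Multiallelic records are split
    into one biallelic site per ALT allele (flagged), each carrying the
    REF depth and that ALT's depth. Records where any sample lacks the
    depth field are skipped and counted; if *all* records lack it the
    tag is assumed misconfigured and an error is raised.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(pool_names) if pool_names is not None else list(vcf.samples)
    if len(names) != len(vcf.samples):
        raise StructuralError(
            f"{len(names)} pool names supplied for {len(vcf.samples)} samples"
        )
    sites: list[SyncSite] = []
    n_skipped = 0
    n_records = 0
    for variant in vcf:
        n_records += 1
        try:
            ad = variant.format(depth_field)
        except KeyError:
            ad = None
        if ad is None:
            n_skipped += 1
            continue
        ref = variant.REF
        alts = variant.ALT
        if ref not in NUCLEOTIDES:
            continue  # indel or symbolic record: not a SNP site
        if ad.shape[1] < 1 + len(alts) or (ad < 0).any():
            n_skipped += 1  # missing sample depths encode as negative
            continue
        quality = float(variant.QUAL) if variant.QUAL is not None else None
        for alt_i, alt in enumerate(alts, start=1):
            if alt not in NUCLEOTIDES:
                continue
            pools = tuple(
                PoolSiteCounts(
                    scaffold=variant.CHROM,
                    position=variant.POS,
                    ref_allele=ref,
                    counts={ref: int(ad[s, 0]), alt: int(ad[s, alt_i])},
                    pool_id=names[s],
                    quality=quality,
                )
                for s in range(len(names))
            )
            sites.append(
                SyncSite(
                    variant.CHROM,
                    variant.POS,
                    ref,
                    pools,
                    split_from_multiallelic=len(alts) > 1,
                )
            )
    if n_records > 0 and not sites and n_skipped == n_records:
        raise StructuralError(
            f"depth field {depth_field!r} absent from every record in {path}"
        )
    if n_skipped:
        log.info("read_allele_depth_vcf: skipped %d records without usable %s",
                 n_skipped, depth_field)
    return sites


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene intervals from GFF3 (``gene`` features) or 6-column BED.

    The format is sniffed from the extension and content: files whose
    data lines have a numeric second column and 9 GFF columns are GFF3,
    otherwise BED. BED's 0-based half-open intervals are shifted to the
    1-based inclusive internal convention.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    saw_feature = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gff or len(fields) == 9:
                saw_feature = True
                ftype = fields[2]
                if ftype != "gene":
                    continue
                start, end = int(fields[3]), int(fields[4])
                if end < start:
                    raise StructuralError(f"line {line_no}: end < start")
                attrs = fields[8]
                gene_id = _gff_attribute(attrs, "ID") or _gff_attribute(
                    attrs, "gene_id"
                ) or f"gene_line{line_no}"
                genes.append(
                    GeneModel(fields[0], start, end, gene_id, fields[6] or ".")
                )
            else:
                if len(fields) < 4:
                    raise StructuralError(
                        f"line {line_no}: BED gene line needs >= 4 columns"
                    )
                saw_feature = True
                bed_start, bed_end = int(fields[1]), int(fields[2])
                if bed_end < bed_start:
                    raise StructuralError(f"line {line_no}: end < start")
                strand = fields[5] if len(fields) >= 6 else "."
                genes.append(
                    GeneModel(fields[0], bed_start + 1, bed_end, fields[3], strand)
                )
    if saw_feature and not genes:
        warnings.warn(f"{path}: no 'gene' features found", stacklevel=2)
    return genes


def _gff_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def write_windows_bed(windows: Iterable, path: str | Path) -> None:
    """Write window statistics as BED4+ (0-based half-open, sorted).

    Columns: scaffold, start-1, end, ``<stat>=<value>``, snp_count. The
    statistic is printed at fixed 6-decimal precision so reruns are
    byte-identical.
    """
    rows = sorted(windows, key=lambda w: (w.scaffold, w.start))
    with open(path, "w") as fh:
        for w in rows:
            name = getattr(w, "stat_name", "stat")
            fh.write(
                f"{w.scaffold}\t{w.start - 1}\t{w.end}\t"
                f"{name}={w.value:.6f}\t{w.snp_count}\n"
            )


def read_genotype_table_tsv(path: str | Path):
    """Read a genotype-count table (rows = genotypes, columns = groups).

    Expected layout: a header line (optionally starting with ``#``)
    naming the groups, then one line per genotype with the genotype
    label in the first column.
    """
    from poolscan.association import GenotypeTable

    genotypes: list[str] = []
    rows: list[list[int]] = []
    groups: list[str] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.lstrip("#").split("\t")
            if groups is None:
                groups = fields[1:]
                continue
            genotypes.append(fields[0])
            rows.append([int(x) for x in fields[1:]])
    if groups is None:
        raise StructuralError(f"{path}: empty genotype table")
    return GenotypeTable(genotypes=genotypes, groups=groups, counts=rows)
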