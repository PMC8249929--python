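"""Bundled reference data: published genotype counts for validated SNPs.

Genotype counts of the five Sanger-genotyped SNPs in four
pigmentation-related goose genes (*KITLG*, *MITF*, *TYRO3*, *KIT*),
cross-tabulated over the three phenotype groups (Gray feral, White_1
feral, White_2 domestic). These are the worked examples for the
chi-square genotype-phenotype association test; the two KITLG SNPs are
in perfect linkage and share one table structure.
"""

from __future__ import annotations

from poolscan.association import GenotypeTable

GROUPS = ["Gray", "White_1", "White_2"]


def kitlg_genotypes() -> GenotypeTable:
    """KITLG 3'UTR SNP (G/A; the linked C/T SNP has identical counts)."""
    return GenotypeTable(
        genotypes=["GG", "GA", "AA"],
        groups=list(GROUPS),
        counts=[[37, 22, 84], [77, 3, 0], [0, 0, 0]],
    )


def mitf_genotypes() -> GenotypeTable:
    """MITF 5'UTR G/C SNP."""
    return GenotypeTable(
        genotypes=["GG", "GC", "CC"],
        groups=list(GROUPS),
        counts=[[83, 6, 14], [29, 17, 49], [0, 2, 20]],
    )


def tyro3_genotypes() -> GenotypeTable:
    """TYRO3 coding A/G SNP (S772G)."""
    return GenotypeTable(
        genotypes=["AA", "AG", "GG"],
        groups=list(GROUPS),
        counts=[[31, 20, 86], [76, 5, 0], [0, 0, 0]],
    )


def kit_genotypes() -> GenotypeTable:
    """KIT coding A/G SNP (T887A)."""
    return GenotypeTable(
        genotypes=["AA", "AG", "GG"],
        groups=list(GROUPS),
        counts=[[0, 0, 0], [67, 2, 0], [35, 23, 78]],
    )


def validated_snp_tables() -> dict[str, GenotypeTable]:
    """All four gene tables keyed by gene symbol."""
    return {
        "KITLG": kitlg_genotypes(),
        "MITF": mitf_genotypes(),
        "TYRO3": tyro3_genotypes(),
        "KIT": kit_genotypes(),
    }
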