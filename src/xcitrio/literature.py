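"""Published allele-count summaries used as validation inputs.

These are printed counts from the marsupial and human X-inactivation
literature: per-gene parental read percentages for the 17 annotated
X-linked genes of a tammar wallaby mother-father-daughter RNA-seq study,
chromosome-level escape tallies for that study, the opossum brain/
extraembryonic survey (Wang et al. 2014) re-binned by evolutionary
stratum (strata after Cortez et al. 2014), and the human X-inactivation
profile of Carrel & Willard (2005).  They drive worked examples and the
validation suite; nothing in the pipeline depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneCall:
    """One annotated gene's printed expression summary.

    ``paternal_pct``/``maternal_pct`` are the printed percentages of
    reads from the paternal and maternal allele; ``printed_status`` is
    the published call ("PI" = paternal inactivation, "Biallelic").
    """

    gene_name: str
    coverage: int
    paternal_pct: int
    maternal_pct: int
    printed_status: str


#: The 17 wallaby annotated X genes with parent-of-origin resolved (daughter liver).
WALLABY_GENE_CALLS: tuple[GeneCall, ...] = (
    GeneCall("NAA10", 8, 62, 38, "Biallelic"),
    GeneCall("SMC6", 39, 54, 46, "Biallelic"),
    GeneCall("CHM", 6, 33, 67, "Biallelic"),
    GeneCall("HCFC1", 10, 30, 70, "Biallelic"),
    GeneCall("HTATSF1", 10, 40, 60, "Biallelic"),
    GeneCall("MECP2", 7, 57, 43, "Biallelic"),
    GeneCall("VAMP7", 30, 40, 60, "Biallelic"),
    GeneCall("RAS11LC", 30, 0, 100, "PI"),
    GeneCall("RBMX", 6, 0, 100, "PI"),
    GeneCall("EBP", 50, 0, 100, "PI"),
    GeneCall("LAS1L", 5, 0, 100, "PI"),
    GeneCall("OPHN1", 7, 0, 100, "PI"),
    GeneCall("PFKFB1", 26, 0, 100, "PI"),
    GeneCall("RPS4X", 23, 0, 100, "PI"),
    GeneCall("HAUS7", 20, 0, 100, "PI"),
    GeneCall("ENSMEUG00000003603", 6, 0, 100, "PI"),
    GeneCall("TSPAN6", 5, 0, 100, "PI"),
)

#: Wallaby daughter liver, chromosome-wide: loci with parent of origin resolved.
WALLABY_N_LOCI = 34
WALLABY_N_INACTIVATED = 23
WALLABY_N_ESCAPER = 11
WALLABY_N_SNPS = 42

#: Opossum X survey: whole-X escape tally and the old-stratum subset.
OPOSSUM_WHOLE_X = (24, 176)       # escapers, genes with known XCI status
OPOSSUM_OLD_STRATUM = (5, 52)     # escapers, old-stratum genes
OPOSSUM_NEW_STRATUM = (4, 5)

#: Human X: escape in the X conserved region vs the whole-X escape rate.
HUMAN_XCR = (30, 462)             # escapers, XCR genes sampled
HUMAN_WHOLE_X_ESCAPE_RATE = 0.15

#: Wallaby strata subsets (loci, escapers) among the 34 resolved loci.
WALLABY_OLD_STRATUM = (3, 7)      # escapers, old-stratum loci
WALLABY_NEW_STRATUM = (2, 3)


def reclassify_gene_calls(
    calls: tuple[GeneCall, ...] = WALLABY_GENE_CALLS, escape_threshold: float = 0.10
) -> dict[str, int]:
    """Re-derive each printed gene call from its parental percentages.

    Runs the pipeline's own SNP classifier on the printed read
    percentages (which preserve the allelic ratio exactly) and tallies
    paternal-inactivated ("PI") versus biallelic ("Biallelic") outcomes.
    """
    from .model import PhasedSnp, SnpStatus
    from .xci_classification import classify_snp

    counts = {"PI": 0, "Biallelic": 0}
    for i, call in enumerate(calls):
        snp = PhasedSnp(
            scaffold="X",
            position=i + 1,
            ref_allele="A",
            alt_allele="G",
            maternal_allele="A",
            paternal_allele="G",
            maternal_reads=call.maternal_pct,
            paternal_reads=call.paternal_pct,
        )
        status = classify_snp(snp, escape_threshold)
        counts["Biallelic" if status == SnpStatus.ESCAPER else "PI"] += 1
    return counts
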