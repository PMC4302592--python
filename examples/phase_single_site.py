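"""Phase one daughter SNP by hand: the monoallelic-heterozygote case.

The daughter's liver expresses only allele A at this site (50 reads, 0
for G), so her transcriptome alone cannot distinguish A/A from a
silenced A/G heterozygote.  The trio resolves it: the mother's genome is
homozygous A and the hemizygous father carries G, so the daughter is an
obligate A/G heterozygote whose G (paternal) copy is completely silent —
the imprinted paternal-XCI signature a biallelic-only analysis misses.
"""

from xcitrio import (
    AlleleObservation,
    MotherGenotype,
    Source,
    TrioSite,
    assign_parent_of_origin,
    classify_snp,
    infer_daughter_genotype,
)

site = TrioSite(
    scaffold="ScaffoldX1",
    position=1042,
    ref_allele="A",
    alt_allele="G",
    daughter_transcriptome=AlleleObservation(
        "daughter", Source.TRANSCRIPTOME, "ScaffoldX1", 1042, "A", "G", 50, 0
    ),
    mother_genotype=MotherGenotype.HOM_REF,
    father_allele="G",
)

genotype, _ = infer_daughter_genotype(site)
snp = assign_parent_of_origin(site, genotype)
snp.status = classify_snp(snp)

print(f"daughter genotype call: {genotype.value}")
print(f"maternal allele {snp.maternal_allele}: {snp.maternal_reads} reads")
print(f"paternal allele {snp.paternal_allele}: {snp.paternal_reads} reads")
print(f"XCI status: {snp.status.value}")
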