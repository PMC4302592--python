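"""Genotype inference and parent-of-origin assignment vs a brute-force oracle."""

import itertools

import pytest

from xcitrio.model import (
    AlleleObservation,
    GenotypeCall,
    MotherGenotype,
    Source,
    TrioSite,
)
from xcitrio.snp_filters import classify_informative
from xcitrio.trio_phasing import (
    assemble_trio_sites,
    assign_parent_of_origin,
    infer_daughter_genotype,
)
from conftest import obs

REF, ALT = "A", "G"


def make_site(mother, father, daughter_reads, father_biallelic=False):
    """TrioSite with daughter transcriptome reads (ref, alt)."""
    return TrioSite(
        scaffold="ScaffoldX1",
        position=1000,
        ref_allele=REF,
        alt_allele=ALT,
        daughter_transcriptome=obs(reads_ref=daughter_reads[0], reads_alt=daughter_reads[1]),
        mother_genotype=mother,
        father_allele=father,
        father_biallelic_flag=father_biallelic,
    )


# ---------------------------------------------------------------------------
# brute-force Mendelian oracle: enumerate all consistent phase assignments


def mendelian_oracle(mother, father, observed_alleles):
    """Enumerate Mendelian-consistent (maternal, paternal) assignments.

    Returns (genotype_kind, unique_phase): genotype_kind in
    {"het", "hom", "unknown"}; unique_phase is the single consistent
    (maternal, paternal) ordered pair for a het daughter, else None.
    """
    maternal_options = {
        MotherGenotype.HOM_REF: [REF],
        MotherGenotype.HOM_ALT: [ALT],
        MotherGenotype.HET: [REF, ALT],
        MotherGenotype.UNKNOWN: [REF, ALT],
    }[mother]
    paternal_options = [father] if father is not None else [REF, ALT]

    consistent = [
        (m, p)
        for m, p in itertools.product(maternal_options, paternal_options)
        if observed_alleles <= {m, p}
    ]
    if not consistent:
        return "unknown", None
    kinds = {"het" if m != p else "hom" for m, p in consistent}
    if kinds == {"het"}:
        phases = sorted(set(consistent))
        return "het", (phases[0] if len(phases) == 1 else None)
    if kinds == {"hom"}:
        return "hom", None
    return "unknown", None


DAUGHTER_EXPRESSION = {
    "ref_only": (10, 0),
    "alt_only": (0, 10),
    "both": (6, 4),
}


@pytest.mark.parametrize("mother", list(MotherGenotype))
@pytest.mark.parametrize("father", [REF, ALT, None])
@pytest.mark.parametrize("expression", sorted(DAUGHTER_EXPRESSION))
def test_truth_table_matches_mendelian_oracle(mother, father, expression):
    """Full enumeration: inference + phasing agree with the brute-force oracle."""
    reads = DAUGHTER_EXPRESSION[expression]
    observed = {a for a, n in zip((REF, ALT), reads) if n > 0}
    site = make_site(mother, father, reads)

    genotype, _ = infer_daughter_genotype(site)
    oracle_kind, oracle_phase = mendelian_oracle(mother, father, observed)

    if oracle_kind == "het":
        expected = GenotypeCall.HET_OBSERVED if len(observed) == 2 else GenotypeCall.HET_INFERRED
        assert genotype == expected
    elif oracle_kind == "hom":
        assert genotype == GenotypeCall.HOM
    else:
        assert genotype == GenotypeCall.UNKNOWN

    if genotype in (GenotypeCall.HET_OBSERVED, GenotypeCall.HET_INFERRED):
        snp = assign_parent_of_origin(site, genotype)
        if oracle_phase is None:
            assert snp is None
        else:
            assert snp is not None
            assert (snp.maternal_allele, snp.paternal_allele) == oracle_phase
            # conservation: phased reads partition the daughter's coverage
            assert snp.maternal_reads + snp.paternal_reads == sum(reads)


def test_monoallelic_het_recovered_from_parental_forcing():
    """Daughter expresses only A; mother hom A, father carries G: het A/G."""
    site = make_site(MotherGenotype.HOM_REF, ALT, (50, 0))
    genotype, _ = infer_daughter_genotype(site)
    assert genotype == GenotypeCall.HET_INFERRED
    snp = assign_parent_of_origin(site, genotype)
    assert (snp.maternal_allele, snp.paternal_allele) == (REF, ALT)
    assert (snp.maternal_reads, snp.paternal_reads) == (50, 0)


def test_shared_het_is_non_informative():
    """Mother het, father A, daughter expresses only A: AA and AG both fit."""
    site = make_site(MotherGenotype.HET, REF, (10, 0))
    genotype, reason = infer_daughter_genotype(site)
    assert genotype == GenotypeCall.UNKNOWN
    assert reason == "unresolvable"
    assert classify_informative(site) == "non_informative"


def test_forced_het_is_informative():
    site = make_site(MotherGenotype.HET, REF, (6, 4))
    assert classify_informative(site) == "informative"
    site = make_site(MotherGenotype.HOM_REF, ALT, (6, 4))
    assert classify_informative(site) == "informative"


def test_mendelian_impossibility_logged_not_raised(caplog):
    """Daughter het A/G but mother hom G and father G: nobody donates A."""
    site = make_site(MotherGenotype.HOM_ALT, ALT, (6, 4))
    with caplog.at_level("INFO"):
        genotype, reason = infer_daughter_genotype(site)
    assert genotype == GenotypeCall.UNKNOWN
    assert reason == "mendelian_inconsistent"


def test_father_biallelic_site_rejected():
    site = make_site(MotherGenotype.HOM_REF, ALT, (6, 4), father_biallelic=True)
    with pytest.raises(ValueError, match="father-biallelic"):
        assign_parent_of_origin(site, GenotypeCall.HET_OBSERVED)


def test_assemble_prefers_genome_evidence():
    mother = [
        # transcriptome looks homozygous (XCI-silenced allele) ...
        obs("mother", Source.TRANSCRIPTOME, reads_ref=20, reads_alt=0),
        # ... but the genome shows a heterozygote; genome wins
        obs("mother", Source.GENOME, reads_ref=11, reads_alt=9),
    ]
    father = [obs("father", Source.GENOME, reads_ref=0, reads_alt=15)]
    daughter = [obs("daughter", Source.TRANSCRIPTOME, reads_ref=7, reads_alt=6)]
    (site,) = assemble_trio_sites(mother, father, daughter)
    assert site.mother_genotype == MotherGenotype.HET
    assert site.mother_evidence_source == Source.GENOME
    assert site.father_allele == ALT


def test_assemble_contradictory_parent_sources_marked_unknown():
    """Genome all-G vs transcriptome all-A: the parental call is unreliable."""
    mother = [
        obs("mother", Source.GENOME, reads_ref=0, reads_alt=5),
        obs("mother", Source.TRANSCRIPTOME, reads_ref=32, reads_alt=0),
    ]
    daughter = [obs("daughter", Source.TRANSCRIPTOME, reads_ref=31, reads_alt=0)]
    (site,) = assemble_trio_sites(mother, [], daughter)
    assert site.mother_genotype == MotherGenotype.UNKNOWN
    # partial disagreement (genome het, transcriptome hom) keeps the genome call
    mother[0] = obs("mother", Source.GENOME, reads_ref=3, reads_alt=2)
    (site,) = assemble_trio_sites(mother, [], daughter)
    assert site.mother_genotype == MotherGenotype.HET


def test_assemble_no_parental_data_gives_unknown():
    daughter = [obs("daughter", Source.TRANSCRIPTOME, reads_ref=7, reads_alt=0)]
    (site,) = assemble_trio_sites([], [], daughter)
    assert site.mother_genotype == MotherGenotype.UNKNOWN
    assert site.father_allele is None
    genotype, _ = infer_daughter_genotype(site)
    assert genotype == GenotypeCall.UNKNOWN


def test_assemble_carries_father_biallelic_flag():
    daughter = [obs("daughter", Source.TRANSCRIPTOME, reads_ref=7, reads_alt=6)]
    key = daughter[0].site_key
    (site,) = assemble_trio_sites([], [], daughter, {key})
    assert site.father_biallelic_flag
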