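"""Daughter genotype inference and parent-of-origin assignment on the X.

The father's X hemizygosity is the anchor: the daughter receives his one
X allele, so at any site her genotype is {maternal allele, father's
allele}.  Comparing her expressed allele(s) with the parental genotypes
(genome evidence outranking transcriptome, since transcriptome
homozygosity may itself be an XCI artefact) yields one of three
outcomes: a uniquely phased heterozygote, a homozygote, or an
unresolvable/inconsistent site.

Crucially, heterozygotes that are *monoallelically expressed* — appearing
homozygous in the daughter's transcriptome — are recovered whenever the
parental genotypes force heterozygosity (mother homozygous for M, father
carrying P ≠ M).  Restricting to biallelically expressed heterozygotes,
as single-sample allelic-imbalance analyses must, systematically
overlooks exactly the fully silenced loci.
"""

from __future__ import annotations

import logging
from typing import Optional

from .model import (
    AlleleObservation,
    GenotypeCall,
    MotherGenotype,
    PhasedSnp,
    SiteKey,
    SkipLog,
    Source,
    TrioSite,
)

logger = logging.getLogger(__name__)


def mother_candidate_alleles(site: TrioSite) -> frozenset[str]:
    """Alleles the mother could donate given her genotype call."""
    ref, alt = site.ref_allele, site.alt_allele
    return {
        MotherGenotype.HOM_REF: frozenset({ref}),
        MotherGenotype.HOM_ALT: frozenset({alt}),
        MotherGenotype.HET: frozenset({ref, alt}),
        MotherGenotype.UNKNOWN: frozenset({ref, alt}),
    }[site.mother_genotype]


def infer_daughter_genotype(site: TrioSite) -> tuple[GenotypeCall, Optional[str]]:
    """Classify the daughter's genotype at one site.

    Returns ``(call, reason)`` where *reason* explains UNKNOWN calls
    (``no_expression``, ``mendelian_inconsistent``, ``unresolvable``).
    Mendelian impossibilities are logged, never raised: real data contain
    caller errors.
    """
    observed = site.daughter_observed_alleles
    if not observed:
        return GenotypeCall.UNKNOWN, "no_expression"

    ref, alt = site.ref_allele, site.alt_allele
    mats = mother_candidate_alleles(site)
    father = site.father_allele

    if len(observed) == 2:
        if father is not None:
            maternal = alt if father == ref else ref
            if maternal not in mats:
                logger.info(
                    "Mendelian inconsistency at %s:%d (mother %s cannot donate %s)",
                    site.scaffold, site.position, site.mother_genotype.value, maternal,
                )
                return GenotypeCall.UNKNOWN, "mendelian_inconsistent"
        return GenotypeCall.HET_OBSERVED, None

    (expressed,) = observed
    silent = alt if expressed == ref else ref

    if father is not None:
        if father != expressed:
            # expressed allele must be the maternal one
            if expressed not in mats:
                logger.info(
                    "Mendelian inconsistency at %s:%d (neither parent donates %s)",
                    site.scaffold, site.position, expressed,
                )
                return GenotypeCall.UNKNOWN, "mendelian_inconsistent"
            return GenotypeCall.HET_INFERRED, None
        # father carries the expressed allele
        if mats == frozenset({silent}):
            return GenotypeCall.HET_INFERRED, None  # mother forces the other allele
        if mats == frozenset({expressed}):
            return GenotypeCall.HOM, None
        return GenotypeCall.UNKNOWN, "unresolvable"  # hom and het both consistent

    # no father evidence
    if mats == frozenset({silent}):
        # mother cannot donate the expressed allele, so it is paternal
        return GenotypeCall.HET_INFERRED, None
    return GenotypeCall.UNKNOWN, "unresolvable"


def resolve_phase(
    site: TrioSite, genotype: GenotypeCall
) -> Optional[tuple[str, str]]:
    """Unique ``(maternal_allele, paternal_allele)`` for a het site, or None."""
    if genotype not in (GenotypeCall.HET_OBSERVED, GenotypeCall.HET_INFERRED):
        return None
    ref, alt = site.ref_allele, site.alt_allele
    mats = mother_candidate_alleles(site)
    father = site.father_allele
    observed = site.daughter_observed_alleles

    if len(observed) == 2:
        if father is not None:
            maternal = alt if father == ref else ref
            return (maternal, father) if maternal in mats else None
        if len(mats) == 1:
            (maternal,) = mats
            paternal = alt if maternal == ref else ref
            return (maternal, paternal)
        return None

    (expressed,) = observed
    silent = alt if expressed == ref else ref
    if father is not None:
        if father != expressed:
            return (expressed, father) if expressed in mats else None
        if mats == frozenset({silent}):
            return (silent, father)
        return None
    if mats == frozenset({silent}):
        return (silent, expressed)
    return None


def assign_parent_of_origin(
    site: TrioSite,
    genotype: GenotypeCall,
    skip_log: Optional[SkipLog] = None,
) -> Optional[PhasedSnp]:
    """Build a :class:`PhasedSnp` from a heterozygous daughter site.

    Returns None (the ambiguous marker) when the phase is not unique or
    when no transcriptome observation exists to quantify expression.
    Father-biallelic sites must be excluded before this point.
    """
    if site.father_biallelic_flag:
        raise ValueError(
            f"father-biallelic site {site.scaffold}:{site.position} must be "
            "excluded before phasing"
        )
    phase = resolve_phase(site, genotype)
    if phase is None:
        if skip_log is not None:
            skip_log.add(site.site_key, "assign_parent_of_origin", "ambiguous_phase")
        return None
    if site.daughter_transcriptome is None:
        if skip_log is not None:
            skip_log.add(site.site_key, "assign_parent_of_origin", "no_expression")
        return None
    maternal, paternal = phase
    obs = site.daughter_transcriptome
    return PhasedSnp(
        scaffold=site.scaffold,
        position=site.position,
        ref_allele=site.ref_allele,
        alt_allele=site.alt_allele,
        maternal_allele=maternal,
        paternal_allele=paternal,
        maternal_reads=obs.reads_of(maternal),
        paternal_reads=obs.reads_of(paternal),
    )


# ---------------------------------------------------------------------------
# trio assembly


def _mother_genotype_from(obs: AlleleObservation) -> MotherGenotype:
    if obs.coverage == 0:
        return MotherGenotype.UNKNOWN
    if obs.reads_ref > 0 and obs.reads_alt > 0:
        return MotherGenotype.HET
    return MotherGenotype.HOM_REF if obs.reads_ref > 0 else MotherGenotype.HOM_ALT


def _father_allele_from(obs: AlleleObservation) -> Optional[str]:
    """Major expressed allele; an exact tie is uninterpretable."""
    if obs.coverage == 0 or obs.reads_ref == obs.reads_alt:
        return None
    return obs.ref_allele if obs.reads_ref > obs.reads_alt else obs.alt_allele


def _sources_contradict(
    genome: Optional[AlleleObservation], transcriptome: Optional[AlleleObservation]
) -> bool:
    if genome is None or transcriptome is None:
        return False
    g, t = genome.observed_alleles, transcriptome.observed_alleles
    return bool(g) and bool(t) and g.isdisjoint(t)


def assemble_trio_sites(
    mother_obs: list[AlleleObservation],
    father_obs: list[AlleleObservation],
    daughter_obs: list[AlleleObservation],
    father_biallelic_keys: set[SiteKey] = frozenset(),
) -> list[TrioSite]:
    """One TrioSite per daughter-covered site, parental evidence attached.

    Genome evidence takes precedence over transcriptome evidence for both
    parents (transcriptome homozygosity may be XCI-induced).  The
    father's allele is the major allele of his best observation; sites in
    *father_biallelic_keys* get ``father_biallelic_flag`` set.
    """
    def by_key(observations: list[AlleleObservation]) -> dict[SiteKey, dict[Source, AlleleObservation]]:
        table: dict[SiteKey, dict[Source, AlleleObservation]] = {}
        for obs in observations:
            table.setdefault(obs.site_key, {})[obs.source] = obs
        return table

    mother = by_key(mother_obs)
    father = by_key(father_obs)
    daughter = by_key(daughter_obs)

    sites: list[TrioSite] = []
    for key in sorted(daughter):
        scaffold, position, ref, alt = key
        d = daughter[key]
        m = mother.get(key, {})
        f = father.get(key, {})

        # A parent's genome and transcriptome must overlap in observed
        # alleles; complete contradiction (e.g. genome reads all one
        # allele by undersampling, transcriptome expressing only the
        # other) marks the evidence unreliable rather than trusting
        # either source.
        m_obs = m.get(Source.GENOME) or m.get(Source.TRANSCRIPTOME)
        if _sources_contradict(m.get(Source.GENOME), m.get(Source.TRANSCRIPTOME)):
            m_obs = None
        m_genotype = _mother_genotype_from(m_obs) if m_obs else MotherGenotype.UNKNOWN

        f_obs = f.get(Source.GENOME) or f.get(Source.TRANSCRIPTOME)
        if _sources_contradict(f.get(Source.GENOME), f.get(Source.TRANSCRIPTOME)):
            f_obs = None
        f_allele = _father_allele_from(f_obs) if f_obs else None

        sites.append(
            TrioSite(
                scaffold=scaffold,
                position=position,
                ref_allele=ref,
                alt_allele=alt,
                daughter_transcriptome=d.get(Source.TRANSCRIPTOME),
                daughter_genome=d.get(Source.GENOME),
                mother_genotype=m_genotype,
                mother_evidence_source=m_obs.source if m_obs else None,
                father_allele=f_allele,
                father_biallelic_flag=key in father_biallelic_keys,
            )
        )
    return sites
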