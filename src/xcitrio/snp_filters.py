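"""Site-level curation applied per sample before trio assembly.

Three rules, mirroring standard manual curation of RNA-seq SNP calls:

* a minimum coverage of 5 reads at every SNP position used as evidence;
* suppression of likely-artefactual heterozygotes supported by a single
  read when the surrounding SNPs (same gene, or a ~20 kb window for
  intergenic SNPs) are uniformly homozygous;
* exclusion of X sites where the father — hemizygous, so necessarily
  monoallelic — nonetheless shows both alleles in his transcriptome.
  This is the signature of reads from an unassembled Y-borne gametologue
  (e.g. UBE1Y/ATRY reads best-mapping to UBA1X/ATRX) or of multi-copy X
  genes, and such sites are uninterpretable for parent-of-origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    AlleleObservation,
    GeneAnnotation,
    SiteKey,
    SkipLog,
    TrioSite,
)


@dataclass
class FilterConfig:
    """Thresholds for site-level curation.

    ``neighbor_window`` is the *total* width of the intergenic vicinity
    (±window/2 around the site).  Father-biallelic detection requires the
    minor allele to reach both an absolute read count and a fraction of
    coverage, separating gametologue signal from single-read noise.
    """

    min_coverage: int = 5
    neighbor_window: int = 20_000
    min_hom_neighbors: int = 3
    father_biallelic_min_reads: int = 2
    father_biallelic_min_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.neighbor_window <= 0:
            raise ValueError("neighbor_window must be positive")
        if not 0.0 <= self.father_biallelic_min_fraction <= 1.0:
            raise ValueError("father_biallelic_min_fraction must lie in [0, 1]")


def filter_min_coverage(
    observations: list[AlleleObservation],
    config: Optional[FilterConfig] = None,
    skip_log: Optional[SkipLog] = None,
) -> list[AlleleObservation]:
    """Retain records with coverage >= ``config.min_coverage``; order preserved."""
    config = config or FilterConfig()
    kept = []
    for obs in observations:
        if obs.coverage >= config.min_coverage:
            kept.append(obs)
        elif skip_log is not None:
            skip_log.add(obs.site_key, "filter_min_coverage", "low_coverage")
    return kept


def _in_vicinity(
    obs: AlleleObservation,
    other: AlleleObservation,
    gene: Optional[GeneAnnotation],
    window: int,
) -> bool:
    if other.site_key == obs.site_key:
        return False
    if other.scaffold != obs.scaffold:
        return False
    if gene is not None:
        return gene.contains(other.scaffold, other.position)
    return abs(other.position - obs.position) <= window // 2


def filter_singleton_het(
    observations: list[AlleleObservation],
    annotation: list[GeneAnnotation],
    config: Optional[FilterConfig] = None,
    skip_log: Optional[SkipLog] = None,
) -> list[AlleleObservation]:
    """Drop single-read-supported heterozygotes surrounded by homozygotes.

    A heterozygous site whose minor allele has exactly one supporting read
    is removed iff its vicinity (same annotated gene when genic, otherwise
    a ``neighbor_window``-wide window) contains at least
    ``min_hom_neighbors`` homozygous sites and no heterozygous site.
    Everything else passes through unchanged; the rule never touches a
    site whose minor allele has two or more reads.
    """
    config = config or FilterConfig()
    kept = []
    for obs in observations:
        minor = min(obs.reads_ref, obs.reads_alt)
        if minor != 1:
            kept.append(obs)
            continue
        gene = next(
            (g for g in annotation if g.contains(obs.scaffold, obs.position)), None
        )
        n_hom = 0
        n_het = 0
        for other in observations:
            if not _in_vicinity(obs, other, gene, config.neighbor_window):
                continue
            if other.is_heterozygous:
                n_het += 1
            else:
                n_hom += 1
        if n_het == 0 and n_hom >= config.min_hom_neighbors:
            if skip_log is not None:
                skip_log.add(obs.site_key, "filter_singleton_het", "singleton_het")
        else:
            kept.append(obs)
    return kept


def flag_father_biallelic_x(
    father_obs: list[AlleleObservation],
    x_scaffolds: set[str],
    config: Optional[FilterConfig] = None,
) -> set[SiteKey]:
    """Site keys on X scaffolds where the father's transcriptome is biallelic.

    The father carries a single X, so genuine biallelic expression is
    impossible; both alleles present above the noise thresholds marks the
    site for downstream exclusion.
    """
    config = config or FilterConfig()
    flagged: set[SiteKey] = set()
    for obs in father_obs:
        if obs.scaffold not in x_scaffolds:
            continue
        minor = min(obs.reads_ref, obs.reads_alt)
        if obs.coverage == 0:
            continue
        if minor >= config.father_biallelic_min_reads and (
            minor / obs.coverage >= config.father_biallelic_min_fraction
        ):
            flagged.add(obs.site_key)
    return flagged


def classify_informative(trio_site: TrioSite) -> str:
    """'informative' iff the daughter's two alleles phase uniquely to parents."""
    from .trio_phasing import infer_daughter_genotype, resolve_phase

    genotype, _ = infer_daughter_genotype(trio_site)
    phase = resolve_phase(trio_site, genotype)
    return "informative" if phase is not None else "non_informative"
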