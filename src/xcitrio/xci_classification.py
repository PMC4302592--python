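"""SNP- and locus-level X-inactivation status from phased read counts.

A SNP escapes inactivation when more than 10% of its reads support the
lowly expressed allele (strict inequality: a minor fraction of exactly
0.10 is still called monoallelic).  Otherwise the silenced parent is the
one contributing the minor allele — paternal inactivation being the
expected imprinted pattern in marsupials.

SNPs are aggregated into loci: all SNPs within one annotated gene form a
gene locus; intergenic SNPs are clustered by single linkage at <= 1 kb
(nearby intergenic SNPs share allelic bias, but clusters ~1.3 kb apart
can genuinely differ in status, so they stay separate loci).
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from .model import (
    AlleleObservation,
    EscapeSummary,
    GeneAnnotation,
    Locus,
    LocusKind,
    PhasedSnp,
    SnpStatus,
)

logger = logging.getLogger(__name__)

DEFAULT_ESCAPE_THRESHOLD = 0.10
DEFAULT_INTERGENIC_CLUSTER_BP = 1000


def paternal_fraction(snp: PhasedSnp) -> float:
    """Fraction of reads at the site supporting the paternal allele."""
    total = snp.maternal_reads + snp.paternal_reads
    if total == 0:
        raise ValueError(
            f"zero coverage at {snp.scaffold}:{snp.position}; filter upstream"
        )
    return snp.paternal_reads / total


def classify_snp(
    snp: PhasedSnp, escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD
) -> SnpStatus:
    """Escaper iff the minor-allele fraction exceeds *escape_threshold*."""
    frac = paternal_fraction(snp)
    minor = min(frac, 1.0 - frac)
    if minor > escape_threshold:
        return SnpStatus.ESCAPER
    return (
        SnpStatus.PATERNAL_INACTIVATED
        if frac <= 0.5
        else SnpStatus.MATERNAL_INACTIVATED
    )


def _locus_status(snps: list[PhasedSnp]) -> tuple[SnpStatus, bool]:
    """Aggregate SNP statuses: unanimity, else majority, tie -> escaper.

    Ambiguous SNPs do not vote.  A tie is resolved to escaper because
    biallelic evidence at any SNP demonstrates expression from both X
    chromosomes; any disagreement sets the conflict flag.
    """
    votes = [s.status for s in snps if s.status != SnpStatus.AMBIGUOUS]
    if not votes:
        return SnpStatus.AMBIGUOUS, False
    counts: dict[SnpStatus, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    if len(counts) == 1:
        return votes[0], False
    best = max(counts.values())
    leaders = [s for s, c in counts.items() if c == best]
    if len(leaders) == 1:
        return leaders[0], True
    return SnpStatus.ESCAPER, True


def _read_weighted_paternal_fraction(snps: list[PhasedSnp]) -> float:
    paternal = sum(s.paternal_reads for s in snps)
    total = sum(s.paternal_reads + s.maternal_reads for s in snps)
    return paternal / total if total else float("nan")


def aggregate_loci(
    snps: list[PhasedSnp],
    annotation: list[GeneAnnotation],
    intergenic_cluster_bp: int = DEFAULT_INTERGENIC_CLUSTER_BP,
) -> list[Locus]:
    """Partition classified SNPs into gene and intergenic loci.

    Every input SNP lands in exactly one locus.  Intergenic SNPs on the
    same scaffold are merged by single linkage when consecutive positions
    are at most *intergenic_cluster_bp* apart.
    """
    gene_groups: dict[str, list[PhasedSnp]] = {}
    gene_by_id = {g.gene_id: g for g in annotation}
    intergenic: list[PhasedSnp] = []
    for snp in snps:
        gene = next(
            (g for g in annotation if g.contains(snp.scaffold, snp.position)), None
        )
        if gene is not None:
            gene_groups.setdefault(gene.gene_id, []).append(snp)
        else:
            intergenic.append(snp)

    loci: list[Locus] = []
    for gene_id, members in sorted(gene_groups.items()):
        loci.append(_build_locus(gene_id, LocusKind.GENE, members, gene_id=gene_id,
                                 gene_name=gene_by_id[gene_id].gene_name))

    # single-linkage clustering of intergenic SNPs per scaffold
    intergenic.sort(key=lambda s: (s.scaffold, s.position))
    cluster: list[PhasedSnp] = []
    clusters: list[list[PhasedSnp]] = []
    for snp in intergenic:
        if cluster and (
            snp.scaffold != cluster[-1].scaffold
            or snp.position - cluster[-1].position > intergenic_cluster_bp
        ):
            clusters.append(cluster)
            cluster = []
        cluster.append(snp)
    if cluster:
        clusters.append(cluster)
    for i, members in enumerate(clusters, start=1):
        loci.append(_build_locus(f"X_locus_{i}", LocusKind.INTERGENIC, members))
    return loci


def _build_locus(
    locus_id: str,
    kind: LocusKind,
    members: list[PhasedSnp],
    gene_id: Optional[str] = None,
    gene_name: Optional[str] = None,
) -> Locus:
    members = sorted(members, key=lambda s: s.position)
    for snp in members:
        snp.locus_id = locus_id
    status, conflict = _locus_status(members)
    positions = [s.position for s in members]
    return Locus(
        locus_id=gene_name or locus_id,
        kind=kind,
        gene_id=gene_id,
        scaffold=members[0].scaffold,
        position=positions[len(positions) // 2],
        snps=members,
        status=status,
        conflict_flag=conflict,
        mean_paternal_fraction=_read_weighted_paternal_fraction(members),
    )


def summarize(loci: list[Locus]) -> EscapeSummary:
    """Chromosome-level counts and fractions over classified loci.

    ``escape_fraction`` is taken over loci with a determinate status;
    the escaper paternal-fraction average is reported both per SNP (each
    escaper SNP weighted equally) and per locus (read-weighted locus
    fractions averaged).
    """
    if not loci:
        raise ValueError("cannot summarize an empty locus list")
    n_pat = sum(1 for l in loci if l.status == SnpStatus.PATERNAL_INACTIVATED)
    n_mat = sum(1 for l in loci if l.status == SnpStatus.MATERNAL_INACTIVATED)
    n_esc = sum(1 for l in loci if l.status == SnpStatus.ESCAPER)
    n_amb = sum(1 for l in loci if l.status == SnpStatus.AMBIGUOUS)
    n_called = n_pat + n_mat + n_esc
    escaper_snps = [
        s
        for l in loci
        if l.status == SnpStatus.ESCAPER
        for s in l.snps
        if s.status == SnpStatus.ESCAPER
    ]
    mean_snp = (
        sum(paternal_fraction(s) for s in escaper_snps) / len(escaper_snps)
        if escaper_snps
        else float("nan")
    )
    escaper_loci = [l for l in loci if l.status == SnpStatus.ESCAPER]
    mean_locus = (
        sum(l.mean_paternal_fraction for l in escaper_loci) / len(escaper_loci)
        if escaper_loci
        else float("nan")
    )
    return EscapeSummary(
        n_loci=len(loci),
        n_paternal_inactivated=n_pat,
        n_maternal_inactivated=n_mat,
        n_escaper=n_esc,
        n_ambiguous=n_amb,
        escape_fraction=n_esc / n_called if n_called else float("nan"),
        mean_escaper_paternal_fraction=mean_snp,
        mean_escaper_paternal_fraction_loci=mean_locus,
    )


def classify_biallelic_only(
    observations: list[AlleleObservation],
    annotation: list[GeneAnnotation],
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD,
    intergenic_cluster_bp: int = DEFAULT_INTERGENIC_CLUSTER_BP,
) -> tuple[EscapeSummary, list[Locus]]:
    """Single-sample escape classification from biallelic heterozygotes only.

    No trio is needed: only sites expressing both alleles enter, and the
    minor-allele fraction alone decides escape.  With no parent of origin
    available, the major allele stands in for the "maternal" slot and the
    minor for the "paternal", so monoallelic-leaning sites come out as
    ``paternal_inactivated`` — read that status as plain "inactivated"
    in this mode.  This is the analysis style used by single-individual
    allelic-imbalance surveys, which overlooks fully silenced
    heterozygotes and so underestimates inactivation.
    """
    pseudo: list[PhasedSnp] = []
    for obs in observations:
        if not obs.is_heterozygous:
            continue
        if obs.reads_ref >= obs.reads_alt:
            major, minor = obs.ref_allele, obs.alt_allele
            major_reads, minor_reads = obs.reads_ref, obs.reads_alt
        else:
            major, minor = obs.alt_allele, obs.ref_allele
            major_reads, minor_reads = obs.reads_alt, obs.reads_ref
        snp = PhasedSnp(
            scaffold=obs.scaffold,
            position=obs.position,
            ref_allele=obs.ref_allele,
            alt_allele=obs.alt_allele,
            maternal_allele=major,
            paternal_allele=minor,
            maternal_reads=major_reads,
            paternal_reads=minor_reads,
        )
        snp.status = classify_snp(snp, escape_threshold)
        pseudo.append(snp)
    if not pseudo:
        logger.warning("no biallelically expressed heterozygous sites in input")
        return (
            EscapeSummary(0, 0, 0, 0, 0, float("nan"), float("nan"), float("nan")),
            [],
        )
    loci = aggregate_loci(pseudo, annotation, intergenic_cluster_bp)
    return summarize(loci), loci
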