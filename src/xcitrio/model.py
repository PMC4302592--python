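"""Domain types shared across the pipeline.

The atomic input is one sample's per-allele read support at one biallelic
site (:class:`AlleleObservation`).  Sites are keyed by
``(scaffold, position, ref, alt)`` with 1-based positions everywhere;
BED input is converted at the boundary.  Strand is ignored throughout —
allele counts are strandless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

NUCLEOTIDES = frozenset("ACGT")

#: (scaffold, position, ref_allele, alt_allele)
SiteKey = tuple[str, int, str, str]


class Source(str, Enum):
    """Whether an observation comes from DNA or RNA sequencing."""

    GENOME = "genome"
    TRANSCRIPTOME = "transcriptome"


class SnpStatus(str, Enum):
    PATERNAL_INACTIVATED = "paternal_inactivated"
    MATERNAL_INACTIVATED = "maternal_inactivated"
    ESCAPER = "escaper"
    AMBIGUOUS = "ambiguous"


class GenotypeCall(str, Enum):
    """Outcome of daughter genotype inference at one site."""

    HET_OBSERVED = "het_observed"
    HET_INFERRED = "het_inferred"
    HOM = "hom"
    UNKNOWN = "unknown"


class MotherGenotype(str, Enum):
    HOM_REF = "hom_ref"
    HOM_ALT = "hom_alt"
    HET = "het"
    UNKNOWN = "unknown"


class Stratum(str, Enum):
    """Label in the ordered X gene map: evolutionary stratum membership."""

    OLD = "old"
    NEW = "new"
    UNKNOWN = "unknown"


class StratumCall(str, Enum):
    """Assignment of a locus after applying the flanking-gene rule."""

    OLD = "old"
    NEW = "new"
    EXCLUDED = "excluded"  # between an old and a new flanking gene
    UNASSIGNED = "unassigned"


class XLinkage(str, Enum):
    X = "X"
    AUTOSOME = "autosome"
    UNPLACED = "unplaced"


@dataclass(frozen=True)
class AlleleObservation:
    """Read support for the two alleles of one sample at one site.

    Positions are 1-based.  ``ref_allele``/``alt_allele`` name the two
    segregating nucleotides; they need not match a reference genome in any
    deeper sense than defining the count orientation.
    """

    sample_id: str
    source: Source
    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str
    reads_ref: int
    reads_alt: int

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be A/C/G/T, got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical at {self.scaffold}:{self.position}")
        if self.reads_ref < 0 or self.reads_alt < 0:
            raise ValueError("read counts must be non-negative")
        if self.position < 1:
            raise ValueError("positions are 1-based; got %d" % self.position)

    @property
    def coverage(self) -> int:
        return self.reads_ref + self.reads_alt

    @property
    def site_key(self) -> SiteKey:
        return (self.scaffold, self.position, self.ref_allele, self.alt_allele)

    def reads_of(self, allele: str) -> int:
        if allele == self.ref_allele:
            return self.reads_ref
        if allele == self.alt_allele:
            return self.reads_alt
        raise KeyError(f"allele {allele!r} not segregating at {self.scaffold}:{self.position}")

    @property
    def observed_alleles(self) -> frozenset[str]:
        """Alleles with at least one supporting read."""
        out = set()
        if self.reads_ref > 0:
            out.add(self.ref_allele)
        if self.reads_alt > 0:
            out.add(self.alt_allele)
        return frozenset(out)

    @property
    def is_heterozygous(self) -> bool:
        return self.reads_ref > 0 and self.reads_alt > 0


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with exon sub-intervals, 1-based inclusive."""

    gene_id: str
    gene_name: str
    scaffold: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene body")

    def contains(self, scaffold: str, position: int) -> bool:
        return scaffold == self.scaffold and self.start <= position <= self.end


class HumanRegion(str, Enum):
    XCR = "XCR"          # X conserved region (homologous to the marsupial X)
    X_OTHER = "X_other"  # added region of the human X
    AUTOSOME = "autosome"
    NONE = "none"


@dataclass(frozen=True)
class OrthologyRecord:
    """1:1 orthology evidence used to anchor a gene to the X chromosome."""

    gene_id: str
    human_orthologue: Optional[str] = None
    human_chromosome_region: HumanRegion = HumanRegion.NONE
    opossum_orthologue: Optional[str] = None
    opossum_chromosome: Optional[str] = None
    is_one_to_one: bool = False

    def __post_init__(self) -> None:
        if self.human_orthologue is None and self.human_chromosome_region != HumanRegion.NONE:
            raise ValueError(
                f"{self.gene_id}: human region {self.human_chromosome_region.value} "
                "without a human orthologue"
            )


@dataclass
class TrioSite:
    """All trio evidence assembled at one daughter-covered site."""

    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str
    daughter_transcriptome: Optional[AlleleObservation] = None
    daughter_genome: Optional[AlleleObservation] = None
    mother_genotype: MotherGenotype = MotherGenotype.UNKNOWN
    mother_evidence_source: Optional[Source] = None
    father_allele: Optional[str] = None
    father_biallelic_flag: bool = False

    def __post_init__(self) -> None:
        if self.father_allele is not None and self.father_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise ValueError(
                f"father allele {self.father_allele!r} not segregating at "
                f"{self.scaffold}:{self.position}"
            )
        if self.daughter_transcriptome is None and self.daughter_genome is None:
            raise ValueError("TrioSite requires at least one daughter observation")

    @property
    def site_key(self) -> SiteKey:
        return (self.scaffold, self.position, self.ref_allele, self.alt_allele)

    @property
    def daughter_observed_alleles(self) -> frozenset[str]:
        alleles: set[str] = set()
        for obs in (self.daughter_transcriptome, self.daughter_genome):
            if obs is not None:
                alleles |= obs.observed_alleles
        return frozenset(alleles)


@dataclass
class PhasedSnp:
    """A daughter heterozygous site with alleles assigned to parents."""

    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str
    maternal_allele: str
    paternal_allele: str
    maternal_reads: int
    paternal_reads: int
    status: SnpStatus = SnpStatus.AMBIGUOUS
    locus_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError("phased alleles must differ")

    @property
    def site_key(self) -> SiteKey:
        return (self.scaffold, self.position, self.ref_allele, self.alt_allele)

    @property
    def coverage(self) -> int:
        return self.maternal_reads + self.paternal_reads


class LocusKind(str, Enum):
    GENE = "gene"
    INTERGENIC = "intergenic"


@dataclass
class Locus:
    """A gene or intergenic SNP cluster carrying one XCI call."""

    locus_id: str
    kind: LocusKind
    scaffold: str
    position: int  # representative position (median SNP)
    snps: list[PhasedSnp]
    gene_id: Optional[str] = None
    status: SnpStatus = SnpStatus.AMBIGUOUS
    conflict_flag: bool = False
    mean_paternal_fraction: float = float("nan")
    stratum: StratumCall = StratumCall.UNASSIGNED

    def __post_init__(self) -> None:
        if not self.snps:
            raise ValueError(f"locus {self.locus_id} has no SNPs")
        scaffolds = {s.scaffold for s in self.snps}
        if scaffolds != {self.scaffold}:
            raise ValueError(f"locus {self.locus_id} spans scaffolds {sorted(scaffolds)}")


@dataclass
class EscapeSummary:
    """Chromosome-level tally of XCI status over loci."""

    n_loci: int
    n_paternal_inactivated: int
    n_maternal_inactivated: int
    n_escaper: int
    n_ambiguous: int
    escape_fraction: float
    mean_escaper_paternal_fraction: float
    mean_escaper_paternal_fraction_loci: float

    def __post_init__(self) -> None:
        total = (
            self.n_paternal_inactivated
            + self.n_maternal_inactivated
            + self.n_escaper
            + self.n_ambiguous
        )
        if total != self.n_loci:
            raise ValueError("status counts do not sum to n_loci")


@dataclass(frozen=True)
class StratumGene:
    gene_id: str
    scaffold: str
    map_position: int
    stratum: Stratum


@dataclass
class StratumMap:
    """Ordered X gene list with old/new stratum labels.

    Map positions form a single chromosome-wide coordinate axis (the X
    physical/linkage map); they must be strictly increasing and gene ids
    unique.
    """

    genes: list[StratumGene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene id(s) in stratum map: {dup}")
        pos = [g.map_position for g in self.genes]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("stratum map positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> Optional[StratumGene]:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        return None


@dataclass(frozen=True)
class StratumAssignment:
    locus_id: str
    assignment: StratumCall


@dataclass
class SkipLog:
    """Per-site record of why sites left the pipeline; drives conservation checks."""

    entries: list[tuple[SiteKey, str, str]] = field(default_factory=list)

    def add(self, site_key: SiteKey, stage: str, reason: str) -> None:
        self.entries.append((site_key, stage, reason))

    def count(self, reason: Optional[str] = None) -> int:
        if reason is None:
            return len(self.entries)
        return sum(1 for _, _, r in self.entries if r == reason)

    def count_stage(self, stage: str) -> int:
        return sum(1 for _, s, _ in self.entries if s == stage)


@dataclass(frozen=True)
class StageRecord:
    """Records-in / records-out accounting for one pipeline stage."""

    stage: str
    n_in: int
    n_out: int
    n_skipped: int

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + self.n_skipped:
            raise ValueError(
                f"stage {self.stage}: {self.n_in} in != {self.n_out} out + "
                f"{self.n_skipped} skipped"
            )
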