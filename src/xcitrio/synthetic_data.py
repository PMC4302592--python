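"""Synthetic trio allele-count datasets with known ground truth.

The generator emulates the statistical structure of a family RNA-seq
study of imprinted X inactivation: a mother (XX) and father (XY, hence X
hemizygous) with sequenced genomes and transcriptomes, and a daughter
with a transcriptome only — her genotype must be inferred.  X loci sit
on ordered scaffolds of a single map axis; at each informative SNP the
mother is homozygous and the father carries the other allele, so the
daughter is an obligate heterozygote with known parental phase.

Per locus, escape from paternal XCI is Bernoulli(escape_prob); escaper
loci express the paternal allele at a Beta-distributed fraction (default
mean 0.46), inactivated loci at ``inactivated_leakage`` (default 0,
i.e. complete silencing).  Read counts are negative-binomial coverages
split binomially by the true paternal fraction, with a symmetric
base-error applied per read.  Realistic confounders are injected:
shared heterozygous sites that are uninformative for parent of origin,
and father-biallelic X sites mimicking reads from Y gametologues.

Real data differ in ways deliberately not modelled: mapping/reference
bias, positionally correlated coverage, multi-SNP linkage disequilibrium
beyond shared locus status, and indels/multiallelics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    AlleleObservation,
    GeneAnnotation,
    HumanRegion,
    OrthologyRecord,
    SiteKey,
    SnpStatus,
    Source,
    Stratum,
    StratumGene,
    StratumMap,
)
from . import variant_io

_BASES = np.array(list("ACGT"))

SCAFFOLD_SPAN = 2_000_000  # bp of map axis per scaffold
_MAP_GENES_PER_SCAFFOLD = 5
_OLD_STRATUM_FRACTION = 0.6  # first 60% of the axis is the old stratum


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; defaults reproduce the study-like conditions.

    ``escaper_paternal_fraction`` is (mean, concentration) of a Beta
    distribution for escaper loci.  ``coverage_mean`` and
    ``coverage_dispersion`` parameterize a negative binomial truncated
    at 1 read.
    """

    seed: int = 0
    n_loci: int = 200
    snps_per_locus: float = 1.25
    x_scaffolds: int = 8
    escape_prob: float = 0.32
    escaper_paternal_fraction: tuple[float, float] = (0.46, 20.0)
    inactivated_leakage: float = 0.0
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.001
    frac_shared_noninformative: float = 0.68
    frac_father_biallelic: float = 0.05
    intergenic_fraction: float = 0.5
    include_daughter_genome: bool = False

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.snps_per_locus < 1:
            raise ValueError("snps_per_locus must be >= 1")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        for name in (
            "escape_prob",
            "inactivated_leakage",
            "error_rate",
            "frac_shared_noninformative",
            "frac_father_biallelic",
            "intergenic_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SnpTruth:
    """Per-SNP simulated genotypes for all three individuals."""

    site_key: SiteKey
    mother_alleles: tuple[str, str]
    father_allele: str
    daughter_maternal: str
    daughter_paternal: str


@dataclass(frozen=True)
class TruthRecord:
    locus_id: str
    kind: str  # "gene" or "intergenic"
    gene_id: Optional[str]
    true_status: SnpStatus
    true_paternal_fraction: float
    stratum: str  # expected flanking-rule outcome: old/new/excluded/unassigned
    snps: tuple[SnpTruth, ...] = ()


@dataclass
class TrioDataset:
    """Everything :func:`simulate_trio` produces, in memory."""

    params: SimulationParams
    observations: dict[tuple[str, Source], list[AlleleObservation]]
    truth: list[TruthRecord]
    stratum_map: StratumMap
    annotation: list[GeneAnnotation]
    orthology: list[OrthologyRecord]
    x_scaffold_names: set[str]

    def sample(self, individual: str, source: Source) -> list[AlleleObservation]:
        return self.observations[(individual, source)]


def _truncated_nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial coverage draw, truncated at >= 1 read."""
    p = dispersion / (dispersion + mean)
    return max(1, int(rng.negative_binomial(dispersion, p)))


def _with_error(rng: np.random.Generator, n_a: int, n_b: int, rate: float) -> tuple[int, int]:
    """Flip each read to the other allele independently with probability *rate*."""
    if rate == 0.0:
        return n_a, n_b
    a_to_b = rng.binomial(n_a, rate)
    b_to_a = rng.binomial(n_b, rate)
    return n_a - a_to_b + b_to_a, n_b - b_to_a + a_to_b


class _Simulator:
    def __init__(self, params: SimulationParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.obs: dict[tuple[str, Source], list[AlleleObservation]] = {
            ("mother", Source.GENOME): [],
            ("mother", Source.TRANSCRIPTOME): [],
            ("father", Source.GENOME): [],
            ("father", Source.TRANSCRIPTOME): [],
            ("daughter", Source.TRANSCRIPTOME): [],
        }
        if params.include_daughter_genome:
            self.obs[("daughter", Source.GENOME)] = []
        self.annotation: list[GeneAnnotation] = []
        self.orthology: list[OrthologyRecord] = []
        self.truth: list[TruthRecord] = []
        self.used_positions: set[int] = set()

    # -- coordinate helpers -------------------------------------------------

    def scaffold_of(self, position: int) -> str:
        return f"X_scaffold_{position // SCAFFOLD_SPAN + 1}"

    def fresh_position(self, low: int, high: int) -> int:
        for _ in range(1000):
            pos = int(self.rng.integers(low, high))
            if pos not in self.used_positions:
                self.used_positions.add(pos)
                return pos
        raise RuntimeError("could not place a unique position; axis too crowded")

    # -- observation emission ----------------------------------------------

    def emit(
        self,
        individual: str,
        source: Source,
        position: int,
        ref: str,
        alt: str,
        reads: dict[str, int],
    ) -> None:
        self.obs[(individual, source)].append(
            AlleleObservation(
                sample_id=individual,
                source=source,
                scaffold=self.scaffold_of(position),
                position=position,
                ref_allele=ref,
                alt_allele=alt,
                reads_ref=reads.get(ref, 0),
                reads_alt=reads.get(alt, 0),
            )
        )

    def coverage(self) -> int:
        return _truncated_nb(self.rng, self.params.coverage_mean, self.params.coverage_dispersion)

    def hom_reads(self, allele: str, other: str) -> dict[str, int]:
        cov = self.coverage()
        n_a, n_b = _with_error(self.rng, cov, 0, self.params.error_rate)
        return {allele: n_a, other: n_b}

    def split_reads(self, allele_a: str, allele_b: str, frac_a: float) -> dict[str, int]:
        cov = self.coverage()
        n_a = int(self.rng.binomial(cov, frac_a))
        n_a, n_b = _with_error(self.rng, n_a, cov - n_a, self.params.error_rate)
        return {allele_a: n_a, allele_b: n_b}

    def pick_alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(_BASES, size=2, replace=False)
        return str(ref), str(alt)

    # -- backbone map and strata --------------------------------------------

    def build_map(self) -> StratumMap:
        p = self.params
        axis_len = p.x_scaffolds * SCAFFOLD_SPAN
        boundary = _OLD_STRATUM_FRACTION * axis_len
        n_map = p.x_scaffolds * _MAP_GENES_PER_SCAFFOLD
        genes = []
        step = axis_len // (n_map + 1)
        for i in range(n_map):
            pos = (i + 1) * step
            stratum = Stratum.OLD if pos < boundary else Stratum.NEW
            if self.rng.random() < 0.1:
                stratum = Stratum.UNKNOWN
            gene_id = f"MAPGENE{i + 1}"
            genes.append(
                StratumGene(
                    gene_id=gene_id,
                    scaffold=self.scaffold_of(pos),
                    map_position=pos,
                    stratum=stratum,
                )
            )
            # map genes are real annotated, X-anchored genes
            self.annotation.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    gene_name=gene_id,
                    scaffold=self.scaffold_of(pos),
                    start=max(1, pos - 2000),
                    end=pos + 2000,
                    exons=((max(1, pos - 2000), pos + 2000),),
                )
            )
            self.orthology.append(
                OrthologyRecord(
                    gene_id=gene_id,
                    human_orthologue=f"HS_{gene_id}",
                    human_chromosome_region=HumanRegion.XCR,
                    opossum_orthologue=f"MD_{gene_id}",
                    opossum_chromosome="X",
                    is_one_to_one=True,
                )
            )
        self.map_genes = genes
        return StratumMap(sorted(genes, key=lambda g: g.map_position))

    def expected_stratum(self, stratum_map: StratumMap, position: int) -> str:
        labelled = [g for g in stratum_map if g.stratum in (Stratum.OLD, Stratum.NEW)]
        left = max((g for g in labelled if g.map_position < position),
                   key=lambda g: g.map_position, default=None)
        right = min((g for g in labelled if g.map_position > position),
                    key=lambda g: g.map_position, default=None)
        if left is None or right is None:
            return "unassigned"
        if left.stratum == right.stratum:
            return left.stratum.value
        return "excluded"

    def in_map_gene(self, position: int) -> bool:
        return any(g.contains(self.scaffold_of(position), position)
                   for g in self.annotation)

    def locus_site_position(self, anchor: int, offset: int) -> int:
        for _ in range(1000):
            pos = anchor + offset + int(self.rng.integers(0, 50))
            if pos >= 1 and pos not in self.used_positions and not self.in_map_gene(pos):
                self.used_positions.add(pos)
                return pos
            offset += 60
        raise RuntimeError("could not place locus SNP")

    # -- site emitters ------------------------------------------------------

    def emit_informative_snp(
        self, position: int, paternal_fraction: float
    ) -> SnpTruth:
        """Mother hom M, father hemizygous P != M; daughter het M/P."""
        a, b = self.pick_alleles()
        maternal, paternal = (a, b) if self.rng.random() < 0.5 else (b, a)
        ref, alt = sorted((a, b))
        self.emit("mother", Source.GENOME, position, ref, alt,
                  self.hom_reads(maternal, paternal))
        self.emit("mother", Source.TRANSCRIPTOME, position, ref, alt,
                  self.hom_reads(maternal, paternal))
        self.emit("father", Source.GENOME, position, ref, alt,
                  self.hom_reads(paternal, maternal))
        self.emit("father", Source.TRANSCRIPTOME, position, ref, alt,
                  self.hom_reads(paternal, maternal))
        self.emit("daughter", Source.TRANSCRIPTOME, position, ref, alt,
                  self.split_reads(paternal, maternal, paternal_fraction))
        if self.params.include_daughter_genome:
            self.emit("daughter", Source.GENOME, position, ref, alt,
                      self.split_reads(paternal, maternal, 0.5))
        return SnpTruth(
            site_key=(self.scaffold_of(position), position, ref, alt),
            mother_alleles=(maternal, maternal),
            father_allele=paternal,
            daughter_maternal=maternal,
            daughter_paternal=paternal,
        )

    def emit_noninformative_site(self, position: int) -> None:
        """Shared het: mother het A/B, father A, daughter homozygous A.

        The daughter's single expressed allele is compatible with both AA
        and AB, so parent of origin cannot be established.
        """
        p = self.params
        a, b = self.pick_alleles()
        ref, alt = sorted((a, b))
        self.emit("mother", Source.GENOME, position, ref, alt,
                  self.split_reads(a, b, 0.5))
        # the mother silences her own paternal X; call allele b her paternal
        m_escapes = self.rng.random() < p.escape_prob
        if m_escapes:
            mean, conc = p.escaper_paternal_fraction
            frac_b = float(self.rng.beta(mean * conc, (1 - mean) * conc))
        else:
            frac_b = p.inactivated_leakage
        self.emit("mother", Source.TRANSCRIPTOME, position, ref, alt,
                  self.split_reads(b, a, frac_b))
        self.emit("father", Source.GENOME, position, ref, alt, self.hom_reads(a, b))
        self.emit("father", Source.TRANSCRIPTOME, position, ref, alt,
                  self.hom_reads(a, b))
        self.emit("daughter", Source.TRANSCRIPTOME, position, ref, alt,
                  self.hom_reads(a, b))
        if p.include_daughter_genome:
            self.emit("daughter", Source.GENOME, position, ref, alt,
                      self.hom_reads(a, b))

    def biallelic_reads(self, allele_a: str, allele_b: str, frac_a: float) -> dict[str, int]:
        """Both alleles robustly present: gametologue reads are not rare noise."""
        cov = max(10, self.coverage())
        n_a = int(self.rng.binomial(cov, frac_a))
        n_a = min(max(n_a, 2), cov - 2)
        return {allele_a: n_a, allele_b: cov - n_a}

    def emit_father_biallelic_site(self, position: int) -> SiteKey:
        """X-Y gametologue confounder: the hemizygous father shows both alleles."""
        a, b = self.pick_alleles()
        ref, alt = sorted((a, b))
        minor_frac = float(self.rng.uniform(0.2, 0.5))
        self.emit("father", Source.GENOME, position, ref, alt,
                  self.biallelic_reads(a, b, minor_frac))
        self.emit("father", Source.TRANSCRIPTOME, position, ref, alt,
                  self.biallelic_reads(a, b, minor_frac))
        self.emit("mother", Source.GENOME, position, ref, alt, self.hom_reads(a, b))
        self.emit("mother", Source.TRANSCRIPTOME, position, ref, alt,
                  self.hom_reads(a, b))
        self.emit("daughter", Source.TRANSCRIPTOME, position, ref, alt,
                  self.split_reads(b, a, minor_frac))
        if self.params.include_daughter_genome:
            self.emit("daughter", Source.GENOME, position, ref, alt,
                      self.split_reads(b, a, 0.5))
        return (self.scaffold_of(position), position, ref, alt)

    # -- top level ----------------------------------------------------------

    def run(self) -> TrioDataset:
        p = self.params
        stratum_map = self.build_map()
        axis_len = p.x_scaffolds * SCAFFOLD_SPAN
        mean, conc = p.escaper_paternal_fraction

        for locus_index in range(p.n_loci):
            anchor = self.fresh_position(1, axis_len - 10_000)
            while self.in_map_gene(anchor):
                anchor = self.fresh_position(1, axis_len - 10_000)
            n_snps = 1 + int(self.rng.poisson(p.snps_per_locus - 1))
            is_escaper = self.rng.random() < p.escape_prob
            if is_escaper:
                true_frac = float(self.rng.beta(mean * conc, (1 - mean) * conc))
                status = SnpStatus.ESCAPER
            else:
                true_frac = p.inactivated_leakage
                status = SnpStatus.PATERNAL_INACTIVATED
            genic = self.rng.random() >= p.intergenic_fraction
            snp_truths = []
            offset = 0
            for _ in range(n_snps):
                pos = self.locus_site_position(anchor, offset)
                offset = pos - anchor + 60
                snp_truths.append(self.emit_informative_snp(pos, true_frac))
            gene_id = None
            if genic:
                gene_id = f"GENE{locus_index + 1}"
                start = min(t.site_key[1] for t in snp_truths)
                end = max(t.site_key[1] for t in snp_truths)
                self.annotation.append(
                    GeneAnnotation(
                        gene_id=gene_id,
                        gene_name=gene_id,
                        scaffold=self.scaffold_of(anchor),
                        start=max(1, start - 100),
                        end=end + 100,
                        exons=((max(1, start - 100), end + 100),),
                    )
                )
                self.orthology.append(
                    OrthologyRecord(
                        gene_id=gene_id,
                        human_orthologue=f"HS_{gene_id}",
                        human_chromosome_region=HumanRegion.XCR,
                        opossum_orthologue=f"MD_{gene_id}",
                        opossum_chromosome="X",
                        is_one_to_one=True,
                    )
                )
            self.truth.append(
                TruthRecord(
                    locus_id=f"locus_{locus_index + 1}",
                    kind="gene" if genic else "intergenic",
                    gene_id=gene_id,
                    true_status=status,
                    true_paternal_fraction=true_frac,
                    stratum=self.expected_stratum(stratum_map, anchor),
                    snps=tuple(snp_truths),
                )
            )

        # confounders scale with the main informative site count
        n_main = sum(len(t.snps) for t in self.truth)
        denom = 1.0 - p.frac_shared_noninformative - p.frac_father_biallelic
        if denom <= 0:
            raise ValueError("confounder fractions must sum to < 1")
        n_total = n_main / denom
        n_noninf = int(round(p.frac_shared_noninformative * n_total))
        n_biallelic = int(round(p.frac_father_biallelic * n_total))
        for _ in range(n_noninf):
            pos = self.fresh_position(1, axis_len)
            self.emit_noninformative_site(pos)
        for _ in range(n_biallelic):
            pos = self.fresh_position(1, axis_len)
            self.emit_father_biallelic_site(pos)

        for obs_list in self.obs.values():
            obs_list.sort(key=lambda o: (o.scaffold, o.position))
        self.annotation.sort(key=lambda g: (g.scaffold, g.start))
        self.orthology.sort(key=lambda r: r.gene_id)
        return TrioDataset(
            params=p,
            observations=self.obs,
            truth=self.truth,
            stratum_map=stratum_map,
            annotation=self.annotation,
            orthology=self.orthology,
            x_scaffold_names={f"X_scaffold_{i + 1}" for i in range(p.x_scaffolds)},
        )


def simulate_trio(params: SimulationParams) -> TrioDataset:
    """Generate a fully reproducible trio dataset from *params* (seeded)."""
    return _Simulator(params).run()


def write_fixture(dataset: TrioDataset, directory: str | os.PathLike) -> None:
    """Emit the dataset as TSV/GFF3 files into *directory*.

    Writes one observation TSV per (individual, source), a truth table,
    the stratum map, the orthology table and the GFF3 annotation.
    Existing unrelated files are left untouched.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    for (individual, source), observations in sorted(dataset.observations.items()):
        path = os.path.join(directory, f"{individual}_{source.value}.tsv")
        variant_io.write_allele_observations(observations, path)
    variant_io.write_stratum_map(dataset.stratum_map, os.path.join(directory, "stratum_map.tsv"))
    variant_io.write_gene_annotation_gff3(
        dataset.annotation, os.path.join(directory, "annotation.gff3")
    )
    with open(os.path.join(directory, "orthology.tsv"), "w") as fh:
        fh.write(
            "gene_id\thuman_orthologue\thuman_chromosome_region\t"
            "opossum_orthologue\topossum_chromosome\tis_one_to_one\n"
        )
        for rec in dataset.orthology:
            fh.write(
                f"{rec.gene_id}\t{rec.human_orthologue or '.'}\t"
                f"{rec.human_chromosome_region.value}\t{rec.opossum_orthologue or '.'}\t"
                f"{rec.opossum_chromosome or '.'}\t{int(rec.is_one_to_one)}\n"
            )
    with open(os.path.join(directory, "truth.tsv"), "w") as fh:
        fh.write("locus_id\tkind\tgene_id\ttrue_status\ttrue_paternal_fraction\tstratum\tn_snps\n")
        for rec in dataset.truth:
            fh.write(
                f"{rec.locus_id}\t{rec.kind}\t{rec.gene_id or '.'}\t{rec.true_status.value}\t"
                f"{rec.true_paternal_fraction:.6f}\t{rec.stratum}\t{len(rec.snps)}\n"
            )


def read_orthology(path: str | os.PathLike) -> list[OrthologyRecord]:
    """Read the orthology TSV written by :func:`write_fixture`."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene_id, hs, region, md, md_chrom, one2one = line.rstrip("\n").split("\t")
            records.append(
                OrthologyRecord(
                    gene_id=gene_id,
                    human_orthologue=None if hs == "." else hs,
                    human_chromosome_region=HumanRegion(region),
                    opossum_orthologue=None if md == "." else md,
                    opossum_chromosome=None if md_chrom == "." else md_chrom,
                    is_one_to_one=bool(int(one2one)),
                )
            )
    return records
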