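"""End-to-end orchestration: filter, phase, classify, strata, stats, report.

Every stage accounts for its records: input count equals output count
plus skip-logged count, and the skip log names the reason each site left
the analysis (low coverage, singleton heterozygote, father-biallelic,
non-informative, Mendelian-inconsistent, multiallelic, off-X).  Given
identical inputs and configuration the report is byte-identical across
runs: all collections are processed in sorted order and the only
randomness lives in the (seeded) generator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import variant_io
from .model import (
    AlleleObservation,
    EscapeSummary,
    GeneAnnotation,
    GenotypeCall,
    Locus,
    OrthologyRecord,
    PhasedSnp,
    SkipLog,
    SnpStatus,
    Source,
    StageRecord,
    StratumCall,
    StratumMap,
)
from .snp_filters import (
    FilterConfig,
    filter_min_coverage,
    filter_singleton_het,
    flag_father_biallelic_x,
)
from .strata import assign_strata, x_scaffolds_from_orthology
from .trio_phasing import assemble_trio_sites, assign_parent_of_origin, infer_daughter_genotype
from .xci_classification import (
    DEFAULT_ESCAPE_THRESHOLD,
    DEFAULT_INTERGENIC_CLUSTER_BP,
    aggregate_loci,
    classify_biallelic_only,
    classify_snp,
    summarize,
)
from .xci_stats import ContingencyTable2x2, escape_enrichment

logger = logging.getLogger(__name__)


@dataclass
class StratumEnrichment:
    stratum: str
    n_loci: int
    observed_escapers: int
    expected_escapers: int
    p_value: float


@dataclass
class PipelineResult:
    summary: EscapeSummary
    loci: list[Locus]
    enrichment: list[StratumEnrichment]
    stage_records: list[StageRecord]
    skip_log: SkipLog
    report_path: Optional[str] = None


@dataclass
class PipelineConfig:
    """File-based configuration; see ``run_pipeline``.

    ``observations`` maps "<individual>_<source>" (e.g. "mother_genome")
    to an observation file path.  ``mode`` is "trio" or
    "biallelic_only"; the latter analyses ``biallelic_sample``'s
    transcriptome alone.
    """

    observations: dict[str, str]
    annotation: str
    stratum_map: str
    orthology: Optional[str] = None
    annotation_dialect: str = "gff3"
    observation_dialect: str = "tsv"
    out_dir: str = "xcitrio_out"
    mode: str = "trio"
    biallelic_sample: str = "daughter"
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD
    intergenic_cluster_bp: int = DEFAULT_INTERGENIC_CLUSTER_BP
    filters: FilterConfig = field(default_factory=FilterConfig)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a JSON superset
        filters = FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filters, **raw)


def _log_stage(records: list[StageRecord], stage: str, n_in: int, n_out: int) -> None:
    record = StageRecord(stage=stage, n_in=n_in, n_out=n_out, n_skipped=n_in - n_out)
    records.append(record)
    logger.info("stage %-24s %6d in, %6d out, %5d skipped", stage, n_in, n_out, record.n_skipped)


def run_trio_analysis(
    mother_obs: list[AlleleObservation],
    father_obs: list[AlleleObservation],
    daughter_obs: list[AlleleObservation],
    annotation: list[GeneAnnotation],
    stratum_map: StratumMap,
    orthology: Optional[list[OrthologyRecord]] = None,
    x_scaffolds: Optional[set[str]] = None,
    filters: Optional[FilterConfig] = None,
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD,
    intergenic_cluster_bp: int = DEFAULT_INTERGENIC_CLUSTER_BP,
    skip_log: Optional[SkipLog] = None,
) -> PipelineResult:
    """Run the full in-memory trio analysis.

    X scaffolds are derived from the orthology table (scaffolds with at
    least one 1:1-anchored X gene) unless given explicitly.
    """
    filters = filters or FilterConfig()
    skip_log = skip_log if skip_log is not None else SkipLog()
    stages: list[StageRecord] = []

    # 1) per-sample coverage filter
    samples = {"mother": mother_obs, "father": father_obs, "daughter": daughter_obs}
    n_in = sum(len(v) for v in samples.values())
    samples = {k: filter_min_coverage(v, filters, skip_log) for k, v in samples.items()}
    _log_stage(stages, "filter_min_coverage", n_in, sum(len(v) for v in samples.values()))

    # 2) singleton-heterozygote curation, per sample and source
    n_in = sum(len(v) for v in samples.values())
    for name in samples:
        by_source: dict[Source, list[AlleleObservation]] = {}
        for obs in samples[name]:
            by_source.setdefault(obs.source, []).append(obs)
        cleaned: list[AlleleObservation] = []
        for source_obs in by_source.values():
            cleaned.extend(filter_singleton_het(source_obs, annotation, filters, skip_log))
        samples[name] = sorted(cleaned, key=lambda o: (o.scaffold, o.position, o.source.value))
    _log_stage(stages, "filter_singleton_het", n_in, sum(len(v) for v in samples.values()))

    # 3) X anchoring: restrict the daughter's sites to X scaffolds
    if x_scaffolds is None:
        if orthology is None:
            raise ValueError("need either x_scaffolds or an orthology table")
        scaffold_genes: dict[str, list[str]] = {}
        for gene in annotation:
            scaffold_genes.setdefault(gene.scaffold, []).append(gene.gene_id)
        x_scaffolds = x_scaffolds_from_orthology(scaffold_genes, orthology)
    daughter = samples["daughter"]
    n_in = len(daughter)
    kept = []
    for obs in daughter:
        if obs.scaffold in x_scaffolds:
            kept.append(obs)
        else:
            skip_log.add(obs.site_key, "x_anchoring", "not_x_linked")
    _log_stage(stages, "x_anchoring", n_in, len(kept))
    daughter = kept

    # 4) father-biallelic X sites (Y-gametologue confounders)
    father_tx = [o for o in samples["father"] if o.source == Source.TRANSCRIPTOME]
    flagged = flag_father_biallelic_x(father_tx, x_scaffolds, filters)

    # 5) trio assembly: one site per daughter-covered position
    trio_sites = assemble_trio_sites(samples["mother"], samples["father"], daughter, flagged)
    _log_stage(stages, "assemble_trio_sites", len(daughter),
               sum(1 for s in trio_sites if s.daughter_transcriptome is not None)
               + sum(1 for s in trio_sites if s.daughter_genome is not None))

    # 6) genotype inference and parent-of-origin phasing
    phased: list[PhasedSnp] = []
    for site in trio_sites:
        if site.father_biallelic_flag:
            skip_log.add(site.site_key, "phase", "father_biallelic")
            continue
        genotype, reason = infer_daughter_genotype(site)
        if genotype == GenotypeCall.HOM:
            skip_log.add(site.site_key, "phase", "homozygous")
            continue
        if genotype == GenotypeCall.UNKNOWN:
            skip_log.add(site.site_key, "phase",
                         reason if reason == "mendelian_inconsistent" else "non_informative")
            continue
        snp = assign_parent_of_origin(site, genotype)
        if snp is None:
            reason = (
                "no_expression" if site.daughter_transcriptome is None else "non_informative"
            )
            skip_log.add(site.site_key, "phase", reason)
        else:
            phased.append(snp)
    _log_stage(stages, "phase", len(trio_sites), len(phased))

    # 7) SNP classification and locus aggregation
    for snp in phased:
        snp.status = classify_snp(snp, escape_threshold)
    loci = aggregate_loci(phased, annotation, intergenic_cluster_bp)
    _log_stage(stages, "aggregate_loci", len(phased), sum(len(l.snps) for l in loci))

    # 8) strata and association statistics
    assign_strata(loci, stratum_map)
    summary = summarize(loci) if loci else EscapeSummary(
        0, 0, 0, 0, 0, float("nan"), float("nan"), float("nan")
    )
    enrichment = compute_strata_enrichment(loci)

    return PipelineResult(
        summary=summary,
        loci=loci,
        enrichment=enrichment,
        stage_records=stages,
        skip_log=skip_log,
    )


def run_trio_dataset(dataset, **kwargs) -> PipelineResult:
    """Run the trio analysis directly on a simulated :class:`TrioDataset`."""
    observations = dataset.observations
    def pooled(individual: str) -> list[AlleleObservation]:
        return [
            obs
            for (name, _), obs_list in sorted(observations.items())
            for obs in obs_list
            if name == individual
        ]

    return run_trio_analysis(
        pooled("mother"),
        pooled("father"),
        pooled("daughter"),
        dataset.annotation,
        dataset.stratum_map,
        orthology=dataset.orthology,
        **kwargs,
    )


def compute_strata_enrichment(loci: list[Locus]) -> list[StratumEnrichment]:
    """Observed-vs-expected escaper tests per stratum against the whole set."""
    determinate = [l for l in loci if l.status != SnpStatus.AMBIGUOUS]
    whole_escapers = sum(1 for l in determinate if l.status == SnpStatus.ESCAPER)
    whole_size = len(determinate)
    out = []
    for stratum in (StratumCall.OLD, StratumCall.NEW):
        members = [l for l in determinate if l.stratum == stratum]
        if not members or whole_size == 0:
            continue
        observed = sum(1 for l in members if l.status == SnpStatus.ESCAPER)
        table, expected, p = escape_enrichment(
            observed, len(members), whole_escapers, whole_size
        )
        out.append(
            StratumEnrichment(
                stratum=stratum.value,
                n_loci=len(members),
                observed_escapers=observed,
                expected_escapers=expected,
                p_value=p,
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, run the analysis, write outputs.

    Writes ``report.tsv``, ``skip_log.tsv`` and ``summary.json`` into
    ``config.out_dir`` and returns the in-memory result.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for path in [config.annotation, config.stratum_map, *config.observations.values()]:
        if not os.path.exists(path):
            raise FileNotFoundError(f"configured input does not exist: {path}")
    if config.orthology is not None and not os.path.exists(config.orthology):
        raise FileNotFoundError(f"configured input does not exist: {config.orthology}")

    skip_log = SkipLog()
    annotation = variant_io.read_gene_annotation(config.annotation, config.annotation_dialect)
    stratum_map = variant_io.read_stratum_map(config.stratum_map)
    orthology = None
    if config.orthology is not None:
        from .synthetic_data import read_orthology

        orthology = read_orthology(config.orthology)

    by_sample: dict[str, list[AlleleObservation]] = {}
    for key, path in sorted(config.observations.items()):
        individual, _, source = key.rpartition("_")
        observations = variant_io.read_allele_observations(
            path, config.observation_dialect, skip_log
        )
        by_sample.setdefault(individual, []).extend(observations)

    if config.mode == "trio":
        result = run_trio_analysis(
            by_sample.get("mother", []),
            by_sample.get("father", []),
            by_sample.get("daughter", []),
            annotation,
            stratum_map,
            orthology=orthology,
            filters=config.filters,
            escape_threshold=config.escape_threshold,
            intergenic_cluster_bp=config.intergenic_cluster_bp,
            skip_log=skip_log,
        )
    elif config.mode == "biallelic_only":
        sample_obs = [
            o
            for o in by_sample.get(config.biallelic_sample, [])
            if o.source == Source.TRANSCRIPTOME
        ]
        sample_obs = filter_min_coverage(sample_obs, config.filters, skip_log)
        summary, loci = classify_biallelic_only(
            sample_obs, annotation, config.escape_threshold, config.intergenic_cluster_bp
        )
        assign_strata(loci, stratum_map)
        result = PipelineResult(
            summary=summary,
            loci=loci,
            enrichment=compute_strata_enrichment(loci),
            stage_records=[],
            skip_log=skip_log,
        )
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    os.makedirs(config.out_dir, exist_ok=True)
    report_path = os.path.join(config.out_dir, "report.tsv")
    variant_io.write_report(result.loci, result.summary if result.loci else None, report_path)
    variant_io.write_skip_log(result.skip_log, os.path.join(config.out_dir, "skip_log.tsv"))
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        payload = dataclasses.asdict(result.summary)
        payload["enrichment"] = [dataclasses.asdict(e) for e in result.enrichment]
        json.dump(payload, fh, indent=2, allow_nan=True)
        fh.write("\n")
    result.report_path = report_path
    return result
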