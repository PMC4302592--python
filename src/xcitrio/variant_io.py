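"""Readers and writers for the formats the pipeline touches.

Two observation dialects are supported:

* ``tsv`` — the canonical fixture format, one observation per row::

      sample_id  source  scaffold  position  ref  alt  reads_ref  reads_alt

  with a header line, tab-separated, positions 1-based.

* ``vcf`` — VCF 4.x with a per-sample ``AD`` (allele depth) FORMAT field.
  Sample column names must follow ``<individual>_<source>`` (e.g.
  ``mother_genome``), which carries the tissue/source tag VCF has no
  standard slot for.

Gene annotation is accepted as GFF3 (1-based inclusive, parsed with
gffutils) or BED (0-based half-open, converted on ingest).  All internal
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
import logging
import os
from typing import Iterable, Optional

import pandas as pd

from .model import (
    AlleleObservation,
    EscapeSummary,
    GeneAnnotation,
    Locus,
    LocusKind,
    NUCLEOTIDES,
    SkipLog,
    SnpStatus,
    Source,
    Stratum,
    StratumCall,
    StratumGene,
    StratumMap,
)

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "sample_id",
    "source",
    "scaffold",
    "position",
    "ref",
    "alt",
    "reads_ref",
    "reads_alt",
]

REPORT_COLUMNS = [
    "locus",
    "scaffold",
    "position",
    "n_snps",
    "maternal_reads",
    "paternal_reads",
    "paternal_fraction",
    "status",
    "stratum",
    "conflict_flag",
]


class ParseError(ValueError):
    """Raised for malformed input, naming the offending line or record."""


def read_allele_observations(
    path: str | os.PathLike,
    dialect: str = "tsv",
    skip_log: Optional[SkipLog] = None,
) -> list[AlleleObservation]:
    """Read per-sample allele observations from a TSV or VCF file.

    Multiallelic sites (more than two observed alleles) and non-SNP
    records are dropped and counted in *skip_log*; retained records are
    biallelic SNPs with 1-based positions.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "tsv":
        records = _read_tsv_observations(path, skip_log)
    elif dialect == "vcf":
        records = _read_vcf_observations(path, skip_log)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")
    return _drop_multiallelic(records, skip_log)


def _drop_multiallelic(
    records: list[AlleleObservation], skip_log: Optional[SkipLog]
) -> list[AlleleObservation]:
    """Drop sites where a sample carries conflicting allele pairs (>2 alleles)."""
    pairs: dict[tuple, set[tuple[str, str]]] = {}
    for obs in records:
        loc = (obs.sample_id, obs.source, obs.scaffold, obs.position)
        pairs.setdefault(loc, set()).add((obs.ref_allele, obs.alt_allele))
    kept = []
    for obs in records:
        loc = (obs.sample_id, obs.source, obs.scaffold, obs.position)
        if len(pairs[loc]) > 1:
            if skip_log is not None:
                skip_log.add(obs.site_key, "read_allele_observations", "multiallelic")
            continue
        kept.append(obs)
    return kept


def _read_tsv_observations(path: str, skip_log: Optional[SkipLog]) -> list[AlleleObservation]:
    out: list[AlleleObservation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                if row != TSV_COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: bad header {row!r}; expected {TSV_COLUMNS}"
                    )
                header = row
                continue
            if len(row) != len(TSV_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(TSV_COLUMNS)} fields")
            try:
                obs = AlleleObservation(
                    sample_id=row[0],
                    source=Source(row[1]),
                    scaffold=row[2],
                    position=int(row[3]),
                    ref_allele=row[4],
                    alt_allele=row[5],
                    reads_ref=int(row[6]),
                    reads_alt=int(row[7]),
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(obs)
    return out


def _read_vcf_observations(path: str, skip_log: Optional[SkipLog]) -> list[AlleleObservation]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    parsed: list[tuple[str, Source]] = []
    for name in samples:
        individual, _, source = name.rpartition("_")
        if not individual or source not in (s.value for s in Source):
            raise ParseError(
                f"{path}: sample column {name!r} must be named <individual>_<source> "
                "with source 'genome' or 'transcriptome'"
            )
        parsed.append((individual, Source(source)))

    out: list[AlleleObservation] = []
    for variant in vcf:
        key = (variant.CHROM, variant.POS, variant.REF, ",".join(variant.ALT))
        if len(variant.ALT) != 1:
            if skip_log is not None:
                skip_log.add(key, "read_allele_observations", "multiallelic")
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            if skip_log is not None:
                skip_log.add(key, "read_allele_observations", "not_a_snp")
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} lacks the per-sample "
                "AD (allele depth) FORMAT field"
            )
        for i, (individual, source) in enumerate(parsed):
            reads_ref, reads_alt = int(ad[i][0]), int(ad[i][1])
            if reads_ref < 0 or reads_alt < 0:  # cyvcf2 encodes missing AD as negative
                continue
            out.append(
                AlleleObservation(
                    sample_id=individual,
                    source=source,
                    scaffold=variant.CHROM,
                    position=variant.POS,
                    ref_allele=ref,
                    alt_allele=alt,
                    reads_ref=reads_ref,
                    reads_alt=reads_alt,
                )
            )
    return out


def write_allele_observations(observations: Iterable[AlleleObservation], path: str | os.PathLike) -> None:
    """Write observations in the canonical TSV dialect (round-trips exactly)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for obs in observations:
            writer.writerow(
                [
                    obs.sample_id,
                    obs.source.value,
                    obs.scaffold,
                    obs.position,
                    obs.ref_allele,
                    obs.alt_allele,
                    obs.reads_ref,
                    obs.reads_alt,
                ]
            )


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | os.PathLike, dialect: str = "gff3") -> list[GeneAnnotation]:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "gff3":
        genes = _read_gff3(path)
    elif dialect == "bed":
        genes = _read_bed(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'gff3' or 'bed')")
    if not genes:
        logger.warning("no gene records parsed from %s", path)
    return genes


def _read_gff3(path: str) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            sorted((child.start, child.end) for child in db.children(feat, featuretype="exon"))
        )
        name = feat.attributes.get("Name", [feat.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                gene_name=name,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                exons=exons,
            )
        )
    return genes


def _read_bed(path: str) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs >=3 fields")
            scaffold, start0, end = fields[0], int(fields[1]), int(fields[2])
            start = start0 + 1  # BED is 0-based half-open
            if end < start:
                raise ParseError(f"{path}:{lineno}: empty interval after normalization")
            name = fields[3] if len(fields) > 3 else f"{scaffold}:{start}-{end}"
            genes.append(
                GeneAnnotation(
                    gene_id=name,
                    gene_name=name,
                    scaffold=scaffold,
                    start=start,
                    end=end,
                    exons=((start, end),),
                )
            )
    return genes


def write_gene_annotation_gff3(genes: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    """Emit a minimal GFF3 (gene + exon features) for the given annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_name}"
            fh.write(
                f"{g.scaffold}\txcitrio\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.scaffold}\txcitrio\texon\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# stratum map


def read_stratum_map(path: str | os.PathLike) -> StratumMap:
    """Read the ordered X gene/stratum table.

    Expects TSV columns ``gene``, ``scaffold``, ``position``, ``stratum``
    with stratum in {old, new, unknown}.  Genes are sorted by map
    position; duplicate gene ids or unknown labels are errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "scaffold": str})
    required = {"gene", "scaffold", "position", "stratum"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: stratum map missing column(s) {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            stratum = Stratum(row.stratum)
        except ValueError as exc:
            raise ParseError(f"{path}: unknown stratum label {row.stratum!r}") from exc
        genes.append(
            StratumGene(
                gene_id=row.gene,
                scaffold=row.scaffold,
                map_position=int(row.position),
                stratum=stratum,
            )
        )
    genes.sort(key=lambda g: g.map_position)
    return StratumMap(genes)


def write_stratum_map(stratum_map: StratumMap, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "scaffold", "position", "stratum"])
        for g in stratum_map:
            writer.writerow([g.gene_id, g.scaffold, g.map_position, g.stratum.value])


# ---------------------------------------------------------------------------
# report


def write_report(loci: list[Locus], summary: Optional[EscapeSummary], path: str | os.PathLike) -> None:
    """Write the per-locus report TSV with the summary as commented header lines."""
    with open(path, "w", newline="") as fh:
        if summary is not None:
            fh.write(f"# n_loci={summary.n_loci}\n")
            fh.write(f"# n_paternal_inactivated={summary.n_paternal_inactivated}\n")
            fh.write(f"# n_maternal_inactivated={summary.n_maternal_inactivated}\n")
            fh.write(f"# n_escaper={summary.n_escaper}\n")
            fh.write(f"# n_ambiguous={summary.n_ambiguous}\n")
            fh.write(f"# escape_fraction={summary.escape_fraction:.6f}\n")
            fh.write(
                f"# mean_escaper_paternal_fraction={summary.mean_escaper_paternal_fraction:.6f}\n"
            )
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for locus in sorted(loci, key=lambda l: (l.scaffold, l.position, l.locus_id)):
            maternal = sum(s.maternal_reads for s in locus.snps)
            paternal = sum(s.paternal_reads for s in locus.snps)
            writer.writerow(
                [
                    locus.locus_id,
                    locus.scaffold,
                    locus.position,
                    len(locus.snps),
                    maternal,
                    paternal,
                    f"{locus.mean_paternal_fraction:.6f}",
                    locus.status.value,
                    locus.stratum.value,
                    "conflict" if locus.conflict_flag else ".",
                ]
            )


def read_report(path: str | os.PathLike) -> pd.DataFrame:
    """Re-parse a report written by :func:`write_report` (locus rows only)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != REPORT_COLUMNS:
        raise ParseError(f"{path}: unexpected report columns {list(df.columns)}")
    return df


def write_skip_log(skip_log: SkipLog, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["scaffold", "position", "ref", "alt", "stage", "reason"])
        for (scaffold, pos, ref, alt), stage, reason in skip_log.entries:
            writer.writerow([scaffold, pos, ref, alt, stage, reason])
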