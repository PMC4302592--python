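"""SNP/locus XCI classification, aggregation and summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from xcitrio.model import GeneAnnotation, PhasedSnp, SnpStatus
from xcitrio.xci_classification import (
    aggregate_loci,
    classify_biallelic_only,
    classify_snp,
    paternal_fraction,
    summarize,
)
from conftest import obs


def snp(position=1000, maternal_reads=50, paternal_reads=0, scaffold="ScaffoldX1",
        status=SnpStatus.AMBIGUOUS):
    return PhasedSnp(
        scaffold=scaffold,
        position=position,
        ref_allele="A",
        alt_allele="G",
        maternal_allele="A",
        paternal_allele="G",
        maternal_reads=maternal_reads,
        paternal_reads=paternal_reads,
        status=status,
    )


@pytest.mark.parametrize(
    "paternal,maternal,expected",
    [(0, 50, 0.0), (3, 7, 0.30), (5, 5, 0.5)],
)
def test_paternal_fraction(paternal, maternal, expected):
    assert paternal_fraction(snp(maternal_reads=maternal, paternal_reads=paternal)) == pytest.approx(expected)


def test_paternal_fraction_zero_coverage_errors():
    bad = snp(maternal_reads=0, paternal_reads=0)
    with pytest.raises(ValueError, match="zero coverage"):
        paternal_fraction(bad)


@pytest.mark.parametrize(
    "paternal,maternal,expected",
    [
        (3, 7, SnpStatus.ESCAPER),            # 30%/70%: biallelic
        (0, 50, SnpStatus.PATERNAL_INACTIVATED),
        (50, 0, SnpStatus.MATERNAL_INACTIVATED),
        (1, 9, SnpStatus.PATERNAL_INACTIVATED),  # exactly 10%: strict rule
        (9, 1, SnpStatus.MATERNAL_INACTIVATED),
        (11, 89, SnpStatus.ESCAPER),             # just above 10%
    ],
)
def test_classify_snp_threshold(paternal, maternal, expected):
    assert classify_snp(snp(maternal_reads=maternal, paternal_reads=paternal)) == expected


@settings(derandomize=True, max_examples=100)
@given(
    maternal=st.integers(min_value=0, max_value=200),
    paternal=st.integers(min_value=0, max_value=200),
)
def test_classify_invariant_under_parent_swap(maternal, paternal):
    """Swapping maternal/paternal labels swaps the monoallelic statuses."""
    if maternal + paternal == 0:
        return
    forward = classify_snp(snp(maternal_reads=maternal, paternal_reads=paternal))
    swapped = classify_snp(snp(maternal_reads=paternal, paternal_reads=maternal))
    partner = {
        SnpStatus.ESCAPER: SnpStatus.ESCAPER,
        SnpStatus.PATERNAL_INACTIVATED: SnpStatus.MATERNAL_INACTIVATED,
        SnpStatus.MATERNAL_INACTIVATED: SnpStatus.PATERNAL_INACTIVATED,
    }
    assert swapped == partner[forward]


def test_nearby_intergenic_clusters_split_beyond_1kb():
    """Two biallelic SNPs and a monoallelic SNP 1.3 kb away form two loci."""
    snps = [
        snp(position=10_000, maternal_reads=6, paternal_reads=4, status=SnpStatus.ESCAPER),
        snp(position=10_200, maternal_reads=5, paternal_reads=5, status=SnpStatus.ESCAPER),
        snp(position=11_500, maternal_reads=50, paternal_reads=0,
            status=SnpStatus.PATERNAL_INACTIVATED),
    ]
    loci = aggregate_loci(snps, [])
    assert len(loci) == 2
    by_n = {len(l.snps): l for l in loci}
    assert by_n[2].status == SnpStatus.ESCAPER and not by_n[2].conflict_flag
    assert by_n[1].status == SnpStatus.PATERNAL_INACTIVATED and not by_n[1].conflict_flag


def test_gene_locus_unanimity():
    gene = GeneAnnotation("g1", "G1", "ScaffoldX1", 900, 1500)
    snps = [
        snp(position=p, status=SnpStatus.PATERNAL_INACTIVATED) for p in (950, 1100, 1400)
    ]
    (locus,) = aggregate_loci(snps, [gene])
    assert locus.gene_id == "g1"
    assert locus.status == SnpStatus.PATERNAL_INACTIVATED
    assert not locus.conflict_flag


def test_gene_locus_tie_resolves_to_escaper_with_conflict():
    gene = GeneAnnotation("g1", "G1", "ScaffoldX1", 900, 1500)
    snps = [
        snp(position=950, maternal_reads=6, paternal_reads=4, status=SnpStatus.ESCAPER),
        snp(position=1100, status=SnpStatus.PATERNAL_INACTIVATED),
    ]
    (locus,) = aggregate_loci(snps, [gene])
    assert locus.status == SnpStatus.ESCAPER
    assert locus.conflict_flag


def test_majority_vote_sets_conflict_flag():
    gene = GeneAnnotation("g1", "G1", "ScaffoldX1", 900, 1500)
    snps = [
        snp(position=950, status=SnpStatus.PATERNAL_INACTIVATED),
        snp(position=1000, status=SnpStatus.PATERNAL_INACTIVATED),
        snp(position=1100, maternal_reads=6, paternal_reads=4, status=SnpStatus.ESCAPER),
    ]
    (locus,) = aggregate_loci(snps, [gene])
    assert locus.status == SnpStatus.PATERNAL_INACTIVATED
    assert locus.conflict_flag


def test_ambiguous_snps_do_not_vote_but_are_kept():
    gene = GeneAnnotation("g1", "G1", "ScaffoldX1", 900, 1500)
    snps = [
        snp(position=950, status=SnpStatus.AMBIGUOUS),
        snp(position=1000, status=SnpStatus.PATERNAL_INACTIVATED),
    ]
    (locus,) = aggregate_loci(snps, [gene])
    assert locus.status == SnpStatus.PATERNAL_INACTIVATED
    assert len(locus.snps) == 2


@settings(derandomize=True, max_examples=30)
@given(
    positions=st.lists(
        st.integers(min_value=1, max_value=100_000), min_size=1, max_size=40, unique=True
    )
)
def test_loci_partition_the_snp_set(positions):
    snps = [snp(position=p, status=SnpStatus.PATERNAL_INACTIVATED) for p in positions]
    loci = aggregate_loci(snps, [])
    seen = [s.site_key for l in loci for s in l.snps]
    assert sorted(seen) == sorted(s.site_key for s in snps)
    assert len(seen) == len(set(seen))


def test_summarize_matches_published_style_counts():
    loci = aggregate_loci(
        [snp(position=5000 * i, status=SnpStatus.PATERNAL_INACTIVATED) for i in range(1, 24)]
        + [
            snp(position=1_000_000 + 5000 * i, maternal_reads=6, paternal_reads=4,
                status=SnpStatus.ESCAPER)
            for i in range(1, 12)
        ],
        [],
    )
    summary = summarize(loci)
    assert (summary.n_loci, summary.n_paternal_inactivated, summary.n_escaper) == (34, 23, 11)
    assert summary.escape_fraction == pytest.approx(11 / 34)


def test_summarize_order_invariant(small_result):
    loci = small_result.loci
    forward = summarize(loci)
    backward = summarize(list(reversed(loci)))
    assert (forward.n_loci, forward.n_escaper, forward.n_paternal_inactivated) == (
        backward.n_loci,
        backward.n_escaper,
        backward.n_paternal_inactivated,
    )
    assert forward.escape_fraction == backward.escape_fraction
    assert forward.mean_escaper_paternal_fraction == pytest.approx(
        backward.mean_escaper_paternal_fraction
    )


def test_summarize_empty_errors():
    with pytest.raises(ValueError):
        summarize([])


def test_biallelic_only_counts_escapers_by_minor_fraction():
    observations = [
        obs(position=1000, reads_ref=54, reads_alt=46),   # 46% minor: escaper
        obs(position=50_000, reads_ref=95, reads_alt=5),  # 5% minor: inactivated
        obs(position=90_000, reads_ref=40, reads_alt=0),  # monoallelic: excluded
    ]
    summary, loci = classify_biallelic_only(observations, [])
    assert summary.n_loci == 2
    assert summary.n_escaper == 1
    assert summary.n_paternal_inactivated == 1  # read as plain "inactivated"


def test_biallelic_only_no_sites_warns(caplog):
    observations = [obs(position=1000, reads_ref=40, reads_alt=0)]
    with caplog.at_level("WARNING"):
        summary, loci = classify_biallelic_only(observations, [])
    assert summary.n_loci == 0 and loci == []
    assert any("no biallelic" in r.message for r in caplog.records)
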