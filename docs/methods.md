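# Methods

## Model and assumptions

The pipeline analyses imprinted X chromosome inactivation (XCI) in a
mother–father–daughter trio with bulk RNA-seq from all three and DNA
evidence from the parents. Its assumptions:

- **X hemizygosity of the father.** The father carries one X allele per
  site; any genuine biallelic signal in his X data indicates mismapped
  reads from a Y-borne gametologue or a multi-copy gene, and such sites
  are uninterpretable for parent of origin. The pipeline therefore
  restricts phasing to X-anchored scaffolds and excludes
  father-biallelic sites.
- **Obligate inheritance.** The daughter's X genotype at any site is
  {one maternal allele, the father's allele}. This single fact drives
  both genotype inference (a daughter expressing only allele A with a
  mother homozygous A and a father carrying G is an A/G heterozygote
  despite looking homozygous in RNA) and phasing (the father's allele
  is paternal by definition; the other allele is maternal, and the
  mother's genotype must be able to donate it or the site is flagged
  Mendelian-inconsistent and dropped, never raised — real data contain
  caller errors).
- **Parental genomes outrank transcriptomes.** A parent's transcriptome
  can look homozygous *because of* XCI; the genome cannot. When both
  sources exist the genome call wins — unless the two observed-allele
  sets are completely disjoint (e.g. a genome undersampled to one
  allele while the transcriptome expresses only the other), in which
  case the parental evidence at that site is marked unknown rather than
  trusted. Partial disagreement keeps the genome call; total
  contradiction is a call error a curator would discard.
- **Strandless biallelic SNPs.** Counts are per-allele read totals;
  indels and sites with more than two observed alleles are dropped at
  ingest and counted. Internal coordinates are 1-based inclusive
  (VCF/GFF3 convention); BED is converted at the boundary.

When the father's allele is unavailable at a site, Mendelian
consistency can still force a unique phase (daughter het A/B with
mother homozygous A implies paternal B); the pipeline accepts such
single-parent forcing. A monoallelically expressed daughter with no
father data remains ambiguous.

## Classification

- Paternal fraction of a phased SNP: f = paternal reads / coverage.
- Escape: min(f, 1−f) > 0.10, strictly — a minor fraction of exactly
  10% is monoallelic. Otherwise the parent contributing the minor
  allele is the silenced one.
- Loci: SNPs in one annotated gene form a gene locus; intergenic SNPs
  cluster by single linkage at ≤ 1 kb (configurable). Nearby intergenic
  SNPs share allelic bias, but clusters ~1.3 kb apart can genuinely
  differ, which the 1 kb default keeps separate. Locus status is the
  unanimous SNP status, else the majority with a conflict flag; a tie
  resolves to escaper (flagged), since biallelic evidence at any SNP
  demonstrates expression from both X chromosomes. Ambiguous SNPs do
  not vote but stay in the report. The locus paternal fraction is
  read-weighted across its SNPs, matching the per-SNP ratio definition.
- The chromosome summary reports the escaper paternal-fraction average
  both per SNP and per locus; the per-SNP figure is primary.
- `classify_biallelic_only` reproduces the single-sample shortcut
  (minor-allele fraction at biallelically expressed heterozygotes, no
  trio): it exists to quantify the silenced-locus blind spot, not as a
  recommended analysis.

## Strata and statistics

Genes anchor to the X via 1:1 orthology (human X conserved region
and/or opossum X); a 1:1 orthologue elsewhere makes a gene autosomal;
genes without 1:1 orthologues are unplaced and dropped with a log
entry. Stratum assignment on the ordered X gene map: a locus that is
itself a labelled map gene keeps its label; otherwise both flanking
labelled genes old → old, both new → new, mixed → excluded, and a
missing or unknown flank → unassigned. Assignments are deterministic,
order-independent and invariant under mirroring the map.

The two-sided Fisher exact p uses the minimum-likelihood rule: sum the
hypergeometric point probabilities (over tables with the observed
margins) not exceeding the observed table's, with a relative tolerance
of 1e-7 on the comparison. Point probabilities share the denominator
C(N, c1), so the comparison and summation run in exact integer
arithmetic (`math.comb`) and divide once — stable far beyond the table
sizes a stratum analysis produces (checked to N ≈ 2000). The expected
escaper count for a stratum is the whole-X escape rate times the
stratum size, rounded half away from zero; the default test places
that expectation as the comparator row of a same-sized pseudo-group
(`comparison="expected"`), the construction consistent with the
published old-stratum p-value of 0.7602; stratum-versus-rest-of-X is
available as `comparison="rest"`.

## Synthetic data

`simulate_trio` emulates the statistical structure of the study design,
with defaults set to study-like conditions:

| parameter | default | rationale |
|---|---|---|
| `escape_prob` | 0.32 | observed escape fraction (11 of 34 loci) |
| `escaper_paternal_fraction` | Beta, mean 0.46, conc. 20 | escaper paternal-allele average of 46%; drawn, not fixed, to exercise the 10% boundary |
| `inactivated_leakage` | 0 | silenced loci show complete monoallelic expression |
| `coverage_mean`, `coverage_dispersion` | 20, 5 | negative binomial truncated at 1; printed per-site coverages span 5–50 |
| `snps_per_locus` | 1.25 | 42 SNPs over 34 loci; 1 + Poisson(mean−1) per locus |
| `frac_shared_noninformative` | 0.68 | fraction of SNPs shared across the trio and useless for parent of origin |
| `frac_father_biallelic` | 0.05 | X–Y gametologue confounder sites |
| `intergenic_fraction` | 0.5 | 17 of 34 loci lay outside annotated genes |
| `error_rate` | 0.001 | symmetric per-read allele flip |

Scaffolds are ordered 2 Mb fragments of one X map axis, so SNP
positions, the stratum map and locus positions share a coordinate
system; backbone map genes (five per scaffold, ~10% unlabelled) carry
the old/new strata, with the old stratum occupying the first 60% of the
axis. Informative SNPs use the mother-homozygous/father-different
construction, which guarantees phaseability; shared non-informative
sites make the daughter a homozygote whose expressed allele matches the
father's (A/A vs A/B genuinely unresolvable); father-biallelic
confounders give the father both alleles robustly (coverage ≥ 10,
minor ≥ 2 reads — the gametologue signal is clear biallelic
expression, not noise-floor counts). The mother's own transcriptome is
silenced per-locus with the same escape model, so the biallelic-only
mode has realistic single-sample input. All randomness flows from one
seeded `numpy` generator; identical parameters give identical datasets.

What passing tests on this generator do **not** show about real data:
no mapping or reference bias, no positionally correlated coverage, no
linkage structure beyond shared locus status, no indels or
multiallelic sites, and genotype quality limited to raw allele counts
rather than a likelihood-based caller.

## Numerical and procedural choices

- Coverage filtering (≥ 5) applies to every sample's evidence before
  trio assembly, so parental calls and daughter expression rest on the
  same floor.
- The singleton-heterozygote rule removes a het whose minor allele has
  exactly one read iff its vicinity (same annotated gene when genic,
  else a 20 kb total window, ±10 kb) holds ≥ 3 homozygous and zero
  heterozygous SNPs. It never touches minor counts ≥ 2.
- Father-biallelic detection needs minor reads ≥ 2 *and* a minor
  fraction ≥ 5% in the father's X transcriptome — thresholds chosen to
  separate gametologue signal from single-read noise, both exposed in
  `FilterConfig`.
- The father's allele at a site is the major allele of his best
  observation; an exact read tie is uninterpretable and yields no
  allele.
- Tie-breaks and orderings are fixed (sites sorted by scaffold and
  position, loci by position) so repeat runs produce byte-identical
  reports; every stage logs records-in/out and the skip log names each
  excluded site's reason, with in = out + skipped holding per stage.
- Degenerate inputs: empty locus lists make `summarize` raise; a
  biallelic-only run with no qualifying sites returns an empty summary
  with a warning; zero-coverage phased SNPs cannot reach
  classification (filtered upstream) and raise if constructed.

## Problem sizes

The validation suite runs the full pipeline at 500 simulated loci
(~2,300 daughter sites) for parameter recovery, 200 loci for the null
condition, and sweeps all 135,750 2×2 tables with N ≤ 40 against an
exact-rational enumeration oracle; the whole suite completes in well
under a minute on one core.

## Known limitations

- No statistical model of allelic imbalance (binomial or
  beta-binomial tests): escape is a fixed 10% rule by design, so power
  varies with coverage and escapers near the threshold are read as
  monoallelic at low coverage.
- Single-offspring trios only; no population or read-backed phasing.
- Synteny transfer and stratum labels are consumed as a precomputed
  ordered map, not inferred; BLAST-style annotation of intergenic
  windows is out of scope.
- The human-XCR-style contrast (observed 30/462 vs expected 69/462)
  yields p ≈ 4.4e-05 under the minimum-likelihood two-sided rule;
  published analyses of those counts have reported other values, which
  suggests a different table construction; the machinery here reports
  what its stated construction computes.
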