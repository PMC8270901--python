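# Methods

## Scope and model

`fulquant` reconstructs transcript isoforms from spliced long-read
alignments without using an annotation for discovery.  The central object
is the **intron chain**: the ordered list of (donor, acceptor) genomic
coordinates of a read or isoform.  Terminal exon *ends* are deliberately
excluded from isoform identity — long-read ends are noisy and 5'/3'
variation is not splicing — so two isoforms are the same iff their chains
are equal on the same chromosome and strand.  All internal coordinates are
0-based half-open; GTF and BED conversion happens only at the I/O boundary.

The pipeline assumes: (i) reads are full-length cDNA with an ISPCR adapter
and a polyA/polyT tail when the molecule was intact; (ii) alignments come
from a splice-aware aligner that reports introns as CIGAR `N` operations
and marks chimeric reads with supplementary records; (iii) artifact reads
are a minority at any given locus, so consensus-based filters (count
thresholds, full-length fractions, truncation tests) can separate them from
genuine isoforms.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| qscore cutoff | 6 | minimum mean read quality (error-probability mean, Phred scale) |
| end window | 200 bp | adapter/polyA search range at each read end |
| adapter identity | 0.70 | minimum matching fraction over the 25-mer adapter, semi-global alignment (indels allowed) |
| polyA run | ≥ 10, ≤ 1 mismatch | tail definition, interior mismatch only |
| min read length | 50 nt | post-trim floor; shorter reads are dropped and logged |
| soft-clip limit | 30 bp | per end, after trimming |
| junction insertion | > 5 bp within 10 query bases of an `N` | RT/alignment wobble signature |
| min intron | 20 bp | shorter `N` operations are treated as deletions |
| HFWINSIZE / DISTHRES / PTHRESHOLD / SUMHOLD | 5 / 8 / 3 / 5 | clustering constants (smoothing half-window, cluster radius, peak minimum, cluster-sum minimum); thresholds inclusive |
| transcript filters | count > 3, full-length > 40 %, polyA distance 10 bp, strand known | strict inequalities |
| locus rules | > 3 % of locus maximum; truncation rescue > 25 % | strict inequalities |
| NMD distance | > 55 nt | stop-to-last-junction, transcript coordinates |
| co-association / usage alpha | 0.001 / 0.005 | BH-adjusted significance defaults |
| DE prefilter | > 10 total counts | flag column in the exported matrix |

Every threshold is exposed in `PipelineConfig`; an empty YAML override
section reproduces the default parameterization exactly, and the config
hash in the run manifest records any deviation.

## Numerical and design choices

**Tag position.**  Within an accepted cluster the tag is placed on the
*observed member position closest to the raw-count centroid* (ties: higher
count, then smaller coordinate), not on the raw-count mode.  Under
symmetric per-read junction wobble the rounded-normal distribution is
nearly flat across the central three positions, so the mode misplaces the
tag by ±1 with high probability at any realistic depth, while the centroid
error shrinks as 1/√n.  Keeping the tag on an observed position preserves
the property that tags are real junction coordinates.  When a genome is
available, tags are additionally **motif-refined**: if a cluster member at
comparable distance from the centroid carries the canonical splice
half-motif (GT/GC/AT donors, AG/AC acceptors, strand-aware), the tag moves
there.  This mirrors how splice-aware aligners anchor junctions, uses only
genome sequence (never an annotation), and is what makes low-coverage loci
(≲ 20 reads) recoverable at exact coordinates.  `cluster_sites` itself
remains a pure histogram operation; refinement is a separate, optional
step.

**Medians.**  TSS/TES use the lower-middle value for even member counts,
keeping genomic coordinates integral.  Boundaries are clipped so terminal
exons retain at least 1 bp.

**Misalignment rule.**  "Not a result of misalignment" is implemented as:
a transcript whose *private* junctions (shared with no other surviving
transcript of the locus) are all non-canonical is removed.  The rule is
config-disableable; note that on genomes without canonical motifs (e.g.
synthetic all-`C` fixtures) it fires on everything, which the test suite
accounts for.

**Fisher exact test.**  Two-sided p-values sum hypergeometric
probabilities ≤ the observed table's probability, with a 1e-7 relative
guard against floating-point ties; direction comes from the sample odds
ratio.  The implementation is cross-checked in the tests against an
independent rational-arithmetic enumeration (exact agreement to 1e-9 over
all tables with margins ≤ 12) and against `statsmodels` for BH adjustment.

**NMD.**  The reading frame starts at the 5'-most annotated start codon
whose genomic position maps onto the transcript's exons; the distance runs
from the stop codon's last base to the first base of the last exon, in
transcript coordinates.  Transcripts without a contained annotated start
codon, or where the claimed codon is not ATG on the transcript, are
reported as no-calls with a reason rather than silently skipped.

**Pair counting.**  Only reads whose aligned span covers both exon loci
enter a 2×2 co-association table, so truncated reads cannot inflate the
"absent" cells.  Exons are identified by their internal splice-site pair;
terminal exons never enter pair testing.  Raw read counts are used (not
transcript-weighted counts).

**Isoform usage.**  Genes with multiple isoforms are tested per isoform as
(this isoform vs. the rest) × (condition A vs. B) on replicate-summed
counts, BH-adjusted across all tested isoforms.  Single-isoform genes and
zero-margin tables are skipped.

**Novelty precedence.**  IR is exon-level and detected independently of
junction events.  A junction joining two annotated sites is ES only when a
reference exon lies strictly inside it; an unannotated pairing of two
annotated sites counts as combination-only novelty (NC).  Junction events
flanking a detected novel exon are absorbed into the NE call, so a clean
cassette novel exon is NE, not "multiple".  Transcripts whose members
could not be assigned to tags at > 20 % are "ambiguous".

## The simulator: what it emulates, and what it does not

`fulquant.simulate` models the structure of a spike-in style benchmark: 20
(configurable) multi-exon genes on alternating strands, each with 2–4
isoforms built by internal exon skipping, alternative splice sites (placed
≥ 20 bp from every existing site, since sites within the clustering radius
are unresolvable by construction), and intron retention; canonical GT–AG
motifs at every junction; a planted ATG near each transcription start; a
log-uniform abundance ladder spanning 10^6-fold across genes and a 0.3–1.0
relative range within genes.  Reads get substitution/indel errors
(defaults 5 % / 2.5 % / 2.5 %), junction wobble (sd 1.5 bases, rounded),
5' truncation without adapter (RT drop-off), internal-priming 3'
truncations that still look full-length, and template-switch chimeras
emitted as primary + supplementary alignment pairs.  Reads are emitted
already basecalled, and an exact-placement aligner writes SAM directly
from provenance.

What passing tests on this generator show: the clustering, collapsing,
filter cascade, rescue logic and quantification are correct under
realistic noise magnitudes and artifact rates, at exact-coordinate
resolution.  What they do not show: performance under real basecaller
error profiles (homopolymer-biased, quality-correlated), real aligner
behavior at non-canonical or short introns, intron-position-dependent
wobble, degraded RNA, or genomes with repeats and overlapping genes — the
synthetic genome is random sequence with well-separated loci.  Boundary
(TSS/TES) accuracy on simulated data is optimistic for the same reasons.

## Benchmark problem sizes

The built-in benchmarks use 20 genes (~55 isoforms) with 3,000 molecules
for the noise-free condition and 20,000–50,000 reads for the noisy
condition (5 % substitutions, wobble sd 1.5, 10 % internal priming, 5 %
template switching).  These sizes give stable precision/recall estimates
(the noisy condition evaluates ~30 isoforms above the count threshold)
while keeping a full run in tens of seconds on one core.

## Known limitations

- The cited clustering procedure behind the four constants is implemented
  from its parameter contract (windowed smoothing, greedy peak picking);
  other kernel choices would be drop-in replacements behind
  `cluster_sites`.
- Internal-priming simulation truncates at random transcript positions
  rather than exclusively at genomic A-rich tracts, so the genomic-polyA
  TES filter is exercised by unit tests with planted tracts rather than by
  the end-to-end benchmark (truncation and annotation filters remove those
  reads' products there).
- Differential expression itself is out of scope: the package exports a
  DESeq2-ready count matrix with the > 10-total-count prefilter flag.
- Single-chromosome simulated genomes are held in memory as plain
  strings; for real genomes the pipeline accepts any mapping with string
  slicing (e.g. `pyfaidx.Fasta(..., as_raw=True)`).
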