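# Methods

## Scope and model

`longamp` analyses long-amplicon nanopore sequencing of a single gene.
The unit of data is a full-length read of one PCR amplicon; the unit of
inference is a pileup column. The pipeline assumes:

- a single known reference (gene-oriented, plus strand), so alignment is
  semi-global — the read (or its reverse complement) is placed as a whole
  inside the reference with free end gaps on the reference side;
- diploid samples, so true variant frequencies concentrate near 50%
  (heterozygous) or 100% (homozygous);
- nanopore-like errors: a few percent per base, with indels strongly
  enriched in homopolymer/tandem-repeat context where repeated identical
  bases produce indistinguishable conductance states.

## Pipeline stages

**Gene model** (`gene_model`). Reference sequence plus ordered exon and
CDS intervals; the amplicon panel is a list of reference intervals with
relative molarity weights. Coordinates are 1-based inclusive at the API
surface (HGVS, BED/GFF dialects declared per file, reports) and 0-based
half-open internally. `amplicon_coverage_check` verifies the panel union
covers every coding base.

**HGVS and consequences** (`hgvs`). Substitutions, deletions, insertions
and delins are parsed and formatted; intronic offset positions
(`c.123+5G>A`) are rejected rather than mis-parsed. Consequences are
computed by mutating the cached CDS and translating: substitutions
compare one codon; length-changing indels compare the full translations,
take the first differing residue, and for frame-disrupting indels scan
the shifted frame for the next stop. `ter_offset` counts codons from the
first altered residue (itself = 1), the HGVS `fsTer#` convention; a
shifted frame with no stop before the CDS end is reported as an
extension with no offset.

**Simulator** (`synthetic`). A genotype is a list of variants with
zygosity and (for heterozygous pairs) haplotype assignment; homozygous
variants are applied to both haplotypes. Each read draws haplotype
(uniform), amplicon (molarity weights) and strand (50/50), copies the
full amplicon sequence from that haplotype, and receives errors:
substitutions to a uniformly random other base; indels split 50/50
between deleting the current base and duplicating it (the homopolymer
slip mode). The per-base indel rate is multiplied inside tandem context,
using the same detector as the filter module so simulator and filter
agree on what counts as repeat context. Reverse-strand reads are emitted
reverse-complemented; a strand-asymmetry factor can scale error rates on
them. Qualities are constant placeholders; nothing downstream reads them.
A fixed seed yields byte-identical FASTQ.

The generator deliberately does **not** model read-length distributions
or fragmentation (reads are whole amplicons), chimeras, barcode
demultiplexing, or signal-level artefacts. Passing tests therefore
demonstrate correctness of the calling/filtering/annotation logic under
the stated error model, not robustness to basecaller-specific artefacts
absent from that model.

**Alignment and pileup** (`align`). edlib (infix mode, extended CIGAR)
scores both orientations; orientation is chosen by edit distance with
ties to forward, and the alignment path is computed for the winner only.
Reads shorter than 200 nt or below 70% identity are unmapped (nanopore
error rates up to ~15% leave margin). Identical read sequences share one
alignment computation. The pileup keeps per-strand counts of
A/C/G/T/deletion per column plus insertions anchored to the column left
of the insertion point; column depth equals the number of reads spanning
the column.

**Calling** (`calling`). Defaults: minimum depth 100, minimum variant
frequency 20%, one call per alternate allele. Runs of adjacent deleted
columns merge into one deletion event; indels are left-aligned by the
rotate-while-flanking-base-matches rule, and catalog entries are
normalized identically, so representation shifts can never change a
match. The significance value is the upper binomial tail
`P(X ≥ alt | depth, e₀)` with null per-base error rate `e₀ = 0.05` — a
deliberately simple null whose only job is to separate genotype-scale
support from error-scale support at high depth.

**Filters and zygosity** (`filters`). Strand bias is the majority-strand
share of alternate support; only the exact 100% case is excluded (a
stricter cut risks discarding true variants, since bias varies with local
sequence). Tandem context requires a homopolymer run ≥ 3 nt, or a unit of
2–4 nt with ≥ 2 copies spanning ≥ 6 nt; indel calls in such context are
excluded, substitutions never. The justification is statistical: calls
from two samples are cross-tabulated as (tandem indel vs other) ×
(called in both vs in one), and a one-sided Fisher exact test asks
whether tandem indels are enriched among shared calls, as recurrent
artifacts must be. Zygosity bands: heterozygous 30–70% inclusive
(adopting the field rule), homozygous ≥ 80% (midpoint policy for the
gap), ambiguous otherwise; all thresholds are config-exposed.

**Annotation and report** (`report`). Catalog entries (TSV or VCF) carry
identifier, clinical significance and in-silico predictions verbatim —
the pipeline never computes pathogenicity. Matching is exact on
normalized (position, ref, alt); anything else is `novel`/"not
recorded". Reports enforce the count identities recorded + novel = total
and CDS + non-CDS = total, and carry per-amplicon mean/min coverage.

## The synthetic LDLR-like gene

The real RefSeqGene record is not shipped, so `ldlr_like_gene()` builds a
deterministic stand-in: an 861-codon CDS (the LDL-receptor precursor
length) split over 18 exons with a 400-nt promoter, 60/200-nt UTRs and
introns of 150–300 nt carrying planted homopolymer and dinucleotide runs
(the nanopore error hotspots). Codons at the classic FH variant sites are
pinned — e.g. codon 577 = TGG so `c.1729T>C` is Trp577Arg, codon 218 =
GGT flanked by CAC/ACC so `c.653del` frameshifts Gly218 to Val — and the
downstream sequence is sampled under two constraints checked by direct
translation at build time: no premature stop in frame, and the shifted
frame after `c.653del` first stops at codon 47. Construction never calls
the consequence predictor, so it can serve as its ground truth.

Two further constraints keep the gene realistic at variant sites: exon
boundaries stay > 9 nt away from every variant position, and each
variant's ±9-nt window is kept free of tandem/homopolymer context. The
reason is an alignment effect worth documenting: when an indel error
falls near a true substitution, "delete the variant base" plus a nearby
match ties with "substitute plus delete elsewhere", and the aligner's
canonical path can shift support off the variant. The observed variant
frequency of a homozygous site is therefore roughly 100% minus the local
indel-error mass — which is also why real amplicon runs report
homozygous frequencies of ~87–95% rather than 100%.

## Parameters and calibration

| parameter | default | rationale |
| --- | --- | --- |
| substitution rate | 0.01 /base | with the indel rate, places simulated het frequencies at ~44–48% and hom at ~88–93%, the ranges single-gene amplicon nanopore runs report |
| indel rate | 0.01 /base | see above; split 50/50 delete/duplicate |
| tandem multiplier | 6 | indel rate ×6 in repeat context; makes repeat loci dominate the raw call excess, as observed |
| strand asymmetry | 1 | no strand-specific error by default |
| min depth | 100 | coverage in these assays is ≥ several hundred per amplicon |
| min variant frequency | 20% | wide margin below the 30% het edge; the cohort QC analysis drops it to 10% to expose artifact calls for the recurrence test |
| null error rate e₀ | 0.05 | binomial null for the p-value |
| het band / hom floor | 30–70% / 80% | field rule; gap midpoint |
| repeat thresholds | homopolymer ≥ 3; unit ≤ 4 nt, span ≥ 6 nt, copies ≥ 2 | config-exposed |
| identity floor / min read length | 70% / 200 nt | rejects junk without touching real nanopore reads |

## Problem sizes

The study-scale condition is ~50,000 reads per sample with mean coverage
above 900; the package's own experiments scale the read counts down since
every statistic involved depends on depth only through thresholds that
are exceeded by two orders of magnitude either way. The cohort drivers
use 2,000 reads/sample (mean coverage ~450); depth-driven questions
(heterozygous-frequency concentration, zygosity recovery) run on a tiny
280-nt single-amplicon gene at depth 1,000 over 200–1,000 seeded
replicates; the tandem-recurrence test uses 300–400 reads/sample with an
explicitly inflated error model (substitution 2%, indel 3%, multiplier 8)
over 5 replicate seed pairs.

## Numerical and convention choices

- Indels are reported left-aligned in genomic coordinates; note HGVS
  proper prefers the 3'-most (right-shifted) description in repeat
  context, so a caller-derived `c.652del` and the literature's `c.653del`
  can denote the same molecule. Catalog matching is unaffected because
  both sides are normalized the same way; protein consequences are
  unaffected because the mutated sequence is identical.
- Forward/reverse alignment ties break toward forward; insertion events
  anchor to the left flanking column; merged deletion events average the
  per-column supports.
- Percentiles in the replicate analyses are numpy's linear-interpolation
  percentiles; seeds for replicate streams are spawned from a single
  `SeedSequence`, keeping every derived seed below 2³¹.
- Degenerate Fisher tables (a zero margin) return p = 1.

## Known limitations

- Sharing of indel calls across samples is exact-match on the merged,
  left-aligned event; stochastic differences in a run's called extent can
  split what is biologically the same artifact into "sample-specific"
  entries, making the recurrence test conservative.
- The strand-bias and significance statistics assume reads are
  independent; PCR duplicates (every read is one, by design of the assay)
  make the p-value an understatement. It is used as a ranking/sanity
  value, not a calibrated error probability.
- Variants spanning exon boundaries, intronic HGVS offsets, multi-gene
  panels and structural variants are out of scope; in-frame delins are
  handled structurally but not exercised by the cohort analyses.
- Base qualities are ignored throughout, matching the synthetic
  placeholder qualities.
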