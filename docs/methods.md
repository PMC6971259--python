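# Methods

## Model and procedure

The quantifier assumes the upstream aligner reported **all equal-best
genomic hits** per read (Bowtie v1 "best strata" style, at most one
substitution); it trusts the file rather than re-verifying strata,
which keeps it aligner-agnostic. All coordinates are held 0-based
half-open internally; GTF (1-based inclusive) and SAM (1-based) are
converted at the boundary so off-by-one drift cannot accumulate.

Reads are classed by their number of equal-best loci: UNIQUE (1),
MULTI (2–50), OVERFLOW (> 50), UNALIGNED. Uniquely aligned reads
(UARs) supply two kinds of evidence:

* a coverage track `f_cov(p)` — UAR depth at each genomic position,
  with collapsed-read copies (`id_xN` headers) counted N times;
* UAR clusters — UARs whose 50 nt-extended footprints overlap are
  chained per chromosome and strand (minimum density 1 read).

Each MULTI read locus gets two flags: **A** (≥ 1 nt overlap with a
50 nt-extended annotated feature, strand-specific) and **U** (overlap
with a UAR cluster). The decision tree:

1. ≥ 2 loci with A∧U — the read is split across them in proportion to
   the proximity-weighted density score
   `f_score = Σ_{p∈[x−r, y+r]} f_cov(p)·f_prox(p)` with `f_prox` = 1
   on the read body and exp(−d/n) on the flanks (r = 50, n = 10).
   Each locus' fraction is credited to that locus' top-ranked
   transcript; co-overlapping transcripts are recorded as
   alternatives.
2. Exactly 1 such locus — the whole read goes there.
3. Annotated loci only — candidates from all annotated loci are pooled
   and ranked by the coverage ratio
   `overlap·(L_t + L_r)/(L_t·L_r)`. If a mature miRNA is among them
   the single best-ratio transcript takes the read (exact ratio ties
   split equally); otherwise the read is split equally across each
   locus' top-ratio transcript. The ratio prioritizes short,
   fully-covered features: a 22 nt read inside a 22 nt mature miRNA
   scores 2.0 against 1.275 for an 80 nt precursor.
4. UAR-cluster loci only — density split as in (1), but the fractions
   are kept as a diagnostic tally in the unassigned bucket: novel-locus
   counts remain UAR-only (see design choices).
5. No evidence anywhere — the read joins the salvage queue.

UARs themselves are assigned to their best-ratio overlapping
transcript directly; annotation-free UARs feed novel-locus detection.

**Salvage.** OVERFLOW, UNALIGNED, and case-5 reads are searched
against the transcript sequences with an allowed substitution count
raised stepwise 0 → 3; only the first non-empty stratum is kept (no
indels — consistent with the substitution-only alignment contract).
Among hit transcripts, any that already carry expression from the
genomic stage win (highest count; exact ties split equally); otherwise
the top quality-ranked hit is assigned with up to four runners-up
retained as alternatives (five total). Quality rank is (fewer
mismatches, longer overlap, lexicographic id). The built-in scanner is
a brute-force Hamming sweep over every transcript offset — exact by
construction; an external aligner can replace it for very large
transcriptomes without changing the contract.

**Novel loci.** Unannotated UARs are coordinate-sorted per
chromosome/strand and chained while the end-to-start gap between
consecutive reads is ≤ 50 nt (adjacent reads chain at gap 0); chains
with ≥ 5 reads (copy-weighted) are reported. Detected clusters are
disjoint from all extended annotation by construction. Users looking
for novel sRNA genes should intersect these clusters with
protein-coding exon annotation downstream to exclude mRNA degradation
products; that filter is deliberately out of scope here.

**IsomiRs.** Every read assigned to a mature miRNA — uniquely,
fractionally, or via salvage — is recorded by exact sequence; rows are
grouped by (miRNA name, sequence) with fractional counts summed. No
subtype classification (5′/3′ shift, SNV) is attempted; the raw
sequences are the foundation for downstream isomiR analysis.

**Outputs.** Three TSVs with fixed headers. RPM = count × 10⁶ /
(total count assigned to annotated small-RNA transcripts); novel loci
and unassigned reads are excluded from the denominator, so transcript
RPM sums to 10⁶. Counts are accumulated as floats and only formatted
to 2 decimals at write time, keeping conservation exact. Output is
deterministic byte-for-byte: rows sort by count descending then id,
and no stage uses randomness.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `r` | 50 | nt | proximity range flanking a locus in the density score |
| `n` | 10 | nt | exponential decay scale of the proximity kernel |
| `max_multimaps` | 50 | loci | beyond this a read is OVERFLOW → salvage |
| `extension` | 50 | nt | per-end extension of features and UARs |
| `min_overlap` | 1 | nt | minimum read/feature overlap for assignment |
| `uar_min_density` | 1 | reads | minimum reads per UAR cluster |
| `salvage_max_mismatches` | 3 | subst. | ceiling of the stepwise search |
| `novel_min_reads` | 5 | reads | novel-cluster report threshold |
| `novel_max_gap` | 50 | nt | maximum gap inside a novel cluster |

## Numerical and design choices

* **Summation window endpoints.** The density score sums over the
  closed window [x−r, y+r], whose endpoints the strict inequalities of
  the proximity kernel's flank branches exclude; the kernel is
  extended continuously there to exp(−r/n). This is the only seam
  between the summation bounds and the kernel's case analysis, and the
  continuous extension is the least surprising closure.
* **All-zero density scores.** Possible when UAR clusters exist at
  minimum density but the summation window catches no coverage; the
  split falls back to uniform with a logged warning.
* **Ratio overlap floor.** The coverage ratio uses the unextended
  transcript length and overlap; a read that qualified only through
  the 50 nt extension has unextended overlap 0, which is floored at
  1 nt so flank-only candidates remain rankable.
* **Per-locus credit.** When a locus overlaps several transcripts,
  its density-split fraction goes to the single top-ranked transcript;
  the others are reported as alternatives (capped at 10 per read).
  This keeps counts unambiguous while preserving the information that
  the read had equally plausible homes.
* **UAR-only multimap mass** is *not* added to novel-cluster counts
  (those stay UAR-only); it is tracked as a diagnostic sub-tally of
  the unassigned bucket so the conservation identity
  Σ transcripts + Σ novel + unassigned = total read copies holds
  exactly.
* **Five-case taxonomy.** The diagnostic classifier (audit
  subcommand) is total and mutually exclusive: any A∧U locus → case 3;
  else A and U present at different loci → case 5; else only A →
  case 2; only U → case 1; neither → case 4.
* **Strandedness.** Overlap is strand-specific throughout (a UAR's
  genomic position includes its strand); salvage can search both
  strands for unstranded protocols (`--unstranded`).
* **Feature extension clipping.** Extensions clip at position 0 and,
  when chromosome lengths are known from the SAM header, at the
  chromosome end.
* **Multi-line features.** Duplicate transcript_ids in the GTF merge
  to their enclosing span; sRNA features are effectively
  single-interval.

## The synthetic benchmark

The simulator emulates how sRNA reads arise from biotype-specific
biogenesis. Per-biotype PMFs over relative start position and read
length are sampled by inverse-CDF Monte Carlo: mature miRNA reads
start at the precise 5′ end; tRNA and snoRNA fragments come from both
termini (tRF-style); longer biotypes shed fragments across the body.
Read lengths are triangular around 22 nt (miRNA) or 21 nt (fragments,
16–30 nt support). Each read carries one substitution with probability
0.1, and 1% of reads carry three substitutions — beyond the genomic
aligner's tolerance, so the salvage stage is exercised.

The planted reference (~205 features on a 45 kb chr1 + 2 kb chrM)
contains: 60 mature miRNAs nested in precursor hairpins; a 3-copy
sequence-identical tRNA family (all its reads are multimaps); a snoRNA
paralog pair differing only near the termini, so terminus reads anchor
uniquely while body reads multimap between two loci that carry both
annotation and unique coverage — the density-split route; tRNAs,
mt-tRNAs, rRNAs, mt-rRNAs, snRNAs, snoRNAs, lincRNAs and processed
transcripts at realistic (scaled-down) lengths; three 40 nt expressed
regions absent from the annotation; and one unannotated repeat at 55
loci whose reads exceed the multimap cap. Expression weights are
log-normal with 25% of features silenced; repeat-family members share
one weight because their loci are inherently indistinguishable.
Companion alignments come from a built-in pigeonhole-seeded Hamming
aligner that is provably exhaustive for ≤ 1 substitution and reports
best strata only, so the whole pipeline runs without external
binaries.

What the benchmark does **not** model: sequencing quality scores,
adapter read-through, indels, cross-mapping between near-identical
real families beyond the planted ones, and the full repeat landscape
of a mammalian genome. Passing it demonstrates the placement logic is
correct and beats a unique-reads-only strategy under controlled
multimapping; it does not by itself certify accuracy on real
libraries.

Problem sizes: the default benchmark uses 10⁴ reads over ~205
features — large enough that every read class and placement route
occurs with stable frequencies, small enough to regenerate from
scratch in seconds.

## Known limitations

* Substitutions only throughout (genomic contract and salvage);
  indel-tolerant placement would require a different alignment model.
* Single-pass placement: no EM-style iterative re-weighting.
* The salvage brute-force scanner is quadratic in transcriptome size;
  for genome-scale transcriptomes an external aligner adapter should
  be used.
* Novel-locus counts exclude multimap fractions by design; a locus
  expressed exclusively through multimaps will not be discovered.
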