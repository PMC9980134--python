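# Methods

## Model and assumptions

The pipeline assumes a single linear reference amplicon containing one ORF
and one or two degenerate barcode stretches (written as `N` runs), with
every read covering the amplicon (HiFi-style circular-consensus reads of a
clone library). Reads may arrive in either orientation; orientation is
chosen by the smaller global edit distance and reverse-complemented reads
are normalized before extraction. Coordinates are 1-based inclusive in all
configs and reports.

Reads from one clone are assumed to share a barcode up to a small number
of sequencing errors (the merge limit, default ED ≤ 2) and to share a
genotype up to independent basecalling errors. The clustering criteria
encode exactly these assumptions: genotype coherence (Jaccard ≥ 0.2 after
error filtering), a hard cap on within-cluster barcode edit distance, and
size divergence |log₂(n₁/n₂)| > ED, which accepts a merge only when one
side looks like an error satellite of the other rather than an
independent clone.

## Alignment and extraction

Alignment is affine-gap semi-global dynamic programming
(`Bio.Align.PairwiseAligner`): the read is aligned globally, uncovered
reference ends are free, and read overhangs beyond the amplicon cost twice
the internal gap penalty so that surplus bases near the reference edge are
explained as insertions rather than clipped. Reference `N` positions match
any base. Reads scoring below 0.25·length are dropped as unalignable.
Pre-aligned SAM input is accepted and bypasses the aligner; alignments are
reconstructed from the CIGAR.

Candidate variants are every mismatch or gap outside barcode regions.
Adjacent same-type differences are merged (MNV, multi-base indel) and
indels are left-aligned against the reference. Variant qualities: an SNV
takes the basecall quality of its alternate base (an MNV the minimum over
its bases). Indel placement inside a repeat tract is ambiguous, so an
indel's quality is the minimum basecall quality over its entire
placement-ambiguity window — the read bases that could be "the inserted
bases" (or the deletion's flanks) under any equivalent gap placement.
Without this, a low-quality indel basecall can hide behind an arbitrary
but score-equivalent gap placement and be read off a neighboring
high-quality base, which defeats the downstream error filter on repeat
context — precisely where long-read indel errors concentrate.

Barcode regions claim read bases aligned within them plus insertions
anchored strictly inside; deletions shorten the extracted string.
Insertions anchored exactly on a region boundary belong to the flank when
the context makes that distinction observable. When the region is a
degenerate `N` run the distinction is not observable — any boundary indel
has a score-equivalent placement inside the barcode — so such indels are
absorbed into the barcode rather than emitted as candidate variants. This
keeps genotypes free of phantom flank indels at the cost of a slightly
fuzzier barcode string, which the edit-distance-tolerant clustering is
designed to absorb.

## Error filtering

A candidate variant is removed only when it is supported by exactly one
read **and** its quality is below the threshold (default Q50); recurrence
in ≥ 2 reads or high quality alone retains it. The same rule is applied
inside each identical-barcode set (before seed clustering), on each
proposed merge union, and on the final cluster for the consensus genotype.

A consequence worth understanding: the filter cannot remove an error that
recurs independently in two reads of the same cluster. With n reads per
clone and per-base substitution rate r over an amplicon of length L, the
expected number of retained recurrent errors per clone grows as
L·C(n,2)·r²/3, plus a homopolymer term (indel errors inside a run
left-align to a single variant key, so they collide far more often). At
HiFi-like rates (r ≈ 0.1–0.2 %) this is negligible; at percent-level rates
it dominates the exact-genotype error of the pipeline. The acceptance
script reports the measured adjusted Rand index and exact-genotype rate
under the simulator's default (deliberately harsh) error rates, where
recurrent-error retention is the dominant failure mode — both for
genotypes and for the cluster splits it induces among wild-type reads.

## Merge scheduling and determinism

Cluster pairs are discovered through a deletion-neighborhood index (all
strings reachable by ≤ max_ed deletions; shared signatures are verified
with an exact bounded edit-distance computation), which is complete for
Levenshtein distance and subquadratic in practice. Candidates at each ED
level are evaluated in a canonical order — largest combined size first,
ties broken by plurality barcode then member read ids, with a canonical
orientation within each pair — and each accepted merge restarts the scan
at the same level until a fixpoint, before advancing to the next level.
Lower levels are not revisited. This makes the whole pipeline
deterministic: re-runs (and runs with different worker counts) produce
byte-identical outputs. `cluster.brute_force_cluster` re-implements the
procedure with plain DP distances, union-find components and exhaustive
pair scans, and serves as the independent reference in tests and in the
acceptance script.

## Consensus, translation, QC

The consensus barcode is the plurality member string (ties: highest summed
basecall quality, then lexicographic), which is exact whenever the
dominant, error-free barcode form is the most frequent — avoiding a
multiple-alignment consensus. Genotypes are translated per affected codon
with the standard code; substitutions sharing a codon are applied jointly.
Indels of length ≢ 0 (mod 3) are frameshifts at their left-aligned codon;
clusters also carry a net-frame annotation summing all in-ORF indels,
since multiple frameshifts can restore the frame. Notation is compact
HGVS-like one-letter strings without formal HGVS validation.

Uniqueness classification groups clone calls by virtual barcode (or by
upstream barcode to emulate a run without virtual barcodes, in which case
clones with identical genotypes are pooled first, as they could not have
been separated). The remediable rule is strict: the dominant clone must
hold *more than* two thirds of the group's reads. Chimera detection links
clones that share an upstream barcode, overlap in genotype (both
wild-type, identical sets, or non-empty intersection) and have downstream
barcodes at ED > max_ed — "entirely different" is deliberately tied to the
merge limit so that barcodes clustering could conflate are never called
different. Sets are maximal under the transitive closure; all-wild-type
sets are flagged but annotated `wt_only` since shared wild-type genotype
carries no linkage evidence.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_bc_qual` | Q62 | drop reads whose minimum barcode basecall quality falls below (mean optional via `bc_qual_stat`) |
| `max_ed` | 2 | maximum barcode Levenshtein distance for merging; also the "entirely different" threshold in chimera detection |
| `jaccard_min` | 0.2 | genotype-coherence threshold for seed edges and merges |
| `var_qual_min` | Q50 | quality floor of the single-read error filter; chosen above the simulator's error-quality mode and below consensus-quality maxima |
| `homopolymer_min` | 4 | minimum run length for the frameshift-context annotation and the simulator's indel hotspot model |

## The simulator

`simulate.SimParams` defines the study conditions: 100 clones, 25-nt
barcodes on both flanks, a 501-nt ORF inside a ~615-bp amplicon,
Poisson(2) variants per clone (70 % SNV / 15 % ins / 15 % del), log-normal
reads per clone (median 10, σ 0.4), per-base error rates of 1 %
substitution and 0.5 % indel with a 5× indel multiplier inside homopolymer
runs ≥ 4, a 2 % per-read chance of a single confidently-miscalled barcode
base, 2 % of reads with low-quality barcodes (multi-occupancy emulation),
5 % non-unique barcodes and 5 % crossover chimeras. Chimeras are modeled
at the template level — upstream portion including the upstream barcode
from clone A, downstream from clone B, crossover uniform in the ORF — so
both barcodes survive intact, matching the PCR mechanism. Qualities are
anti-correlated with errors: correct bases ~Q90, error basecalls ~Q30,
barcode miscalls ~Q78 (consensus miscalls are confidently wrong; the Q62
filter targets multi-occupancy wells, which are injected separately).
All randomness flows from one seeded generator; a fixed seed yields a
byte-identical FASTQ.

What the simulator does **not** model: instrument kinetics, true
per-pass CCS consensus behavior, quality miscalibration, coverage bias,
adapter artifacts, or genuine multi-occupancy signal mixtures (only their
low-quality-barcode symptom). Passing recovery tests on this generator
therefore demonstrates the clustering/consensus logic under controlled
error phenomenology, not instrument-accurate performance.

The chimera-recall metric is computed over *informative* crossovers —
those sharing at least one true variant with their upstream donor. A
crossover upstream of every donor variant produces a molecule carrying no
evidence linking it to its donor; no genotype-overlap detector can find
it, and with ~2 variants per clone and a uniform crossover point only
about 60 % of crossovers are informative. The overall detected fraction is
reported alongside.

## Numerical choices and degenerate inputs

Jaccard of two empty sets is defined as 1.0 (two wild-type reads agree).
Equal-size clusters never satisfy size divergence (|log₂ 1| = 0), so
equal clones with distinct barcodes never merge — accepted as the rule's
literal behavior. Identical-barcode seed clusters (pair ED 0) are never
merge candidates; genotype incoherence within a barcode is evidence of
barcode collision, not error. Insertions left-aligned past the reference
start carry anchor position 0 and are reported as non-coding. Empty
inputs produce empty, well-formed reports and a clean exit.

## Known limitations

- Recurrent sequencing errors (≥ 2 reads) are retained by design of the
  error filter; at percent-level error rates they dominate exact-genotype
  error (see above).
- Consensus barcodes are plurality strings, not positionwise consensi; a
  cluster merged from many distinct error forms with no dominant form can
  report a barcode carrying an error.
- Chimera detection reports but does not remove or correct chimeric
  clones, and requires a dual-barcode design.
- Protein consequences are per-codon labels, not full-protein HGVS; long
  compound events are summarized per event plus the net-frame annotation.
- Single machine only; extraction parallelizes over read chunks with
  deterministic collation, but clustering is single-process.
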