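"""Read alignment and extraction of barcodes and candidate variants.

Each HiFi-style read is aligned semi-globally to the reference amplicon
(read global, reference ends free) with affine gap scoring. From the
alignment we pull out the read bases spanning each barcode region, plus
every apparent difference from the reference outside barcode regions
("candidate variants"), each with a Phred-scaled quality. Reads whose
barcode bases dip below a quality threshold (default Q62) are discarded:
in SMRT sequencing such low-confidence barcodes frequently indicate
multi-occupancy wells whose mixed signal cannot be trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator

import edlib
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .layout import AmpliconLayout, Interval

_N_EQUALITIES = [("N", c) for c in "ACGT"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateVariant:
    """One apparent difference from the reference.

    ``pos`` is the 1-based reference position of the first affected base;
    for a pure insertion it is the reference base *after which* the new
    bases sit (the insertion anchor). Exactly one of ``ref``/``alt`` may
    be empty. Set identity is the triple ``(pos, ref, alt)``; the quality
    rides along without affecting equality or hashing.
    """

    pos: int
    ref: str
    alt: str
    qual: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if self.ref == "" and self.alt == "":
            raise ValueError("variant needs a non-empty ref or alt")
        if self.qual < 0:
            raise ValueError("quality must be >= 0")

    @property
    def vtype(self) -> str:
        if self.ref and self.alt:
            return "SNV" if len(self.ref) == len(self.alt) == 1 else "MNV"
        return "insertion" if self.alt else "deletion"

    @property
    def is_indel(self) -> bool:
        return not (self.ref and self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.pos}:{self.ref or '-'}>{self.alt or '-'}:{self.qual}"

    @classmethod
    def parse(cls, text: str) -> "CandidateVariant":
        pos, alleles, qual = text.split(":")
        ref, alt = alleles.split(">")
        return cls(
            int(pos),
            "" if ref == "-" else ref,
            "" if alt == "-" else alt,
            int(qual),
        )


def format_variants(variants: Iterable[CandidateVariant]) -> str:
    return ",".join(str(v) for v in sorted(variants, key=lambda v: v.key))


def parse_variants(text: str) -> frozenset[CandidateVariant]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(CandidateVariant.parse(tok) for tok in text.split(","))


@dataclass(frozen=True)
class ReadRecord:
    """One read's extracted barcodes and candidate variants."""

    read_id: str
    barcode_seqs: tuple[str, ...]
    barcode_quals: tuple[tuple[int, ...], ...]
    variants: frozenset[CandidateVariant]
    min_bc_qual: int
    strand: str = "+"

    @property
    def virtual_barcode(self) -> str:
        return "".join(self.barcode_seqs)

    @property
    def is_wt(self) -> bool:
        return not self.variants

    @property
    def mean_bc_qual(self) -> float:
        quals = [q for region in self.barcode_quals for q in region]
        return sum(quals) / len(quals)


@dataclass(frozen=True)
class DroppedRead:
    read_id: str
    reason: str  # unaligned | no_barcode | low_barcode_qual


@dataclass(frozen=True)
class ExtractParams:
    min_bc_qual: int = 62
    bc_qual_stat: str = "min"  # min | mean
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_score_per_base: float = 0.25


@dataclass(frozen=True)
class Alignment:
    """Read-to-reference alignment as colinear aligned blocks.

    ``blocks`` are ``(ref_start, ref_end, read_start, read_end)`` in
    0-based half-open coordinates; gaps live between blocks.
    """

    ref: str
    read: str
    quals: tuple[int, ...]
    blocks: tuple[tuple[int, int, int, int], ...]
    score: float
    strand: str = "+"


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _aligner(params: ExtractParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # Uncovered reference ends are free (end deletions): the read may sit
    # anywhere inside the amplicon. Read overhangs beyond the amplicon (end
    # insertions) are penalized harder than internal gaps so that extra
    # bases near the reference edge are explained as insertions, not
    # clipped ends.
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    aligner.open_end_insertion_score = 2 * params.gap_open
    aligner.extend_end_insertion_score = 2 * params.gap_extend
    aligner.wildcard = "N"
    return aligner


def _orient(read: str, ref: str) -> str:
    """Pick the read orientation with the smaller global edit distance."""
    fwd = edlib.align(read, ref, mode="NW", task="distance",
                      additionalEqualities=_N_EQUALITIES)["editDistance"]
    rc = edlib.align(reverse_complement(read), ref, mode="NW", task="distance",
                     additionalEqualities=_N_EQUALITIES)["editDistance"]
    return "+" if fwd <= rc else "-"


def align_read(
    seq: str,
    quals: Iterable[int],
    layout: AmpliconLayout,
    params: ExtractParams = ExtractParams(),
) -> Alignment | None:
    """Semi-global affine-gap alignment of one read to the reference.

    Returns ``None`` for unalignable reads (score below the floor of
    ``min_score_per_base * len(read)``). Reads in reverse orientation are
    reverse-complemented first (qualities reversed accordingly).
    """
    seq = seq.upper()
    quals = tuple(quals)
    if not seq:
        return None
    strand = _orient(seq, layout.reference_seq)
    if strand == "-":
        seq = reverse_complement(seq)
        quals = quals[::-1]
    aln = _aligner(params).align(layout.reference_seq, seq)[0]
    if aln.score < params.min_score_per_base * len(seq):
        return None
    target_blocks, query_blocks = aln.aligned
    blocks = tuple(
        (int(t0), int(t1), int(q0), int(q1))
        for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks)
    )
    return Alignment(
        ref=layout.reference_seq,
        read=seq,
        quals=quals,
        blocks=blocks,
        score=float(aln.score),
        strand=strand,
    )


def alignment_from_sam(
    ref: str, read_seq: str, quals: Iterable[int], cigartuples, ref_start: int
) -> Alignment:
    """Build the block representation from a SAM record's CIGAR.

    ``ref_start`` is 0-based (pysam ``reference_start``). Soft-clipped read
    bases are skipped; hard clips are already absent from SEQ.
    """
    blocks: list[tuple[int, int, int, int]] = []
    t = ref_start
    q = 0
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            blocks.append((t, t + length, q, q + length))
            t += length
            q += length
        elif op == 1:  # I
            q += length
        elif op in (2, 3):  # D, N
            t += length
        elif op == 4:  # S
            q += length
        # H (5) and P (6) consume nothing we track
    return Alignment(
        ref=ref,
        read=read_seq.upper(),
        quals=tuple(quals),
        blocks=tuple(blocks),
        score=float("nan"),
        strand="+",
    )


# ---------------------------------------------------------------------------
# indel normalization
# ---------------------------------------------------------------------------


def left_align_deletion(ref: str, pos: int, deleted: str) -> tuple[int, str]:
    """Shift a deletion to its leftmost equivalent representation.

    ``pos`` is the 1-based position of the first deleted base.
    """
    k = len(deleted)
    while pos > 1 and ref[pos - 2] == ref[pos + k - 2]:
        pos -= 1
    return pos, ref[pos - 1 : pos + k - 1]


def left_align_insertion(ref: str, pos: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion (anchored after 1-based ``pos``) leftmost."""
    while pos >= 1 and ref[pos - 1] == inserted[-1]:
        inserted = ref[pos - 1] + inserted[:-1]
        pos -= 1
    return pos, inserted


def right_shift_deletion(ref: str, pos: int, deleted: str) -> int:
    """Rightmost equivalent 1-based position of a deletion."""
    k = len(deleted)
    while pos + k - 1 < len(ref) and ref[pos - 1] == ref[pos + k - 1]:
        pos += 1
    return pos


def right_shift_insertion(ref: str, pos: int, inserted: str) -> int:
    """Rightmost equivalent anchor of an insertion (anchored after pos)."""
    while pos < len(ref) and ref[pos] == inserted[0]:
        inserted = inserted[1:] + ref[pos]
        pos += 1
    return pos


def apply_variants(ref: str, variants: Iterable[CandidateVariant]) -> str:
    """Apply non-overlapping variants to the reference sequence."""
    seq = ref
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        if v.ref == "":  # insertion after pos
            seq = seq[: v.pos] + v.alt + seq[v.pos :]
        elif v.alt == "":  # deletion starting at pos
            seq = seq[: v.pos - 1] + seq[v.pos - 1 + len(v.ref) :]
        else:
            if seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
                raise ValueError(f"reference mismatch applying {v}")
            seq = seq[: v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref) :]
    return seq


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _raw_events(aln: Alignment) -> list[tuple]:
    """Low-level alignment differences.

    Yields ``("sub", ref_pos0, read_pos0, length)`` for maximal mismatch
    stretches, ``("del", ref_pos0, read_pos0, length)`` (read_pos0 = read
    index after the gap) and ``("ins", ref_pos0, read_pos0, length)``
    (ref_pos0 = ref index after the anchor base). Positions 0-based.
    Columns where either side is ``N`` are not differences.
    """
    events: list[tuple] = []
    ref, read = aln.ref, aln.read
    for bi, (t0, t1, q0, q1) in enumerate(aln.blocks):
        if bi > 0:
            pt1, _, pq1 = aln.blocks[bi - 1][1], None, aln.blocks[bi - 1][3]
            if t0 > pt1:
                events.append(("del", pt1, pq1, t0 - pt1))
            if q0 > pq1:
                events.append(("ins", t0, pq1, q0 - pq1))
        run_start = None
        for i in range(t1 - t0):
            rc, qc = ref[t0 + i], read[q0 + i]
            mismatch = rc != qc and rc != "N" and qc != "N"
            if mismatch and run_start is None:
                run_start = i
            elif not mismatch and run_start is not None:
                events.append(("sub", t0 + run_start, q0 + run_start, i - run_start))
                run_start = None
        if run_start is not None:
            events.append(("sub", t0 + run_start, q0 + run_start, t1 - t0 - run_start))
    return events


def _variant_in_barcode(v: CandidateVariant, layout: AmpliconLayout) -> bool:
    """Whether a (left-aligned) variant belongs to a barcode region.

    Insertions exactly at a region boundary count as non-barcode; all
    other overlap with a barcode region claims the variant for the
    barcode side (it is part of the extracted barcode string instead).
    """
    if v.ref == "":
        return any(r.start <= v.pos < r.end for r in layout.barcode_regions)
    lo, hi = v.pos, v.pos + len(v.ref) - 1
    return any(r.start <= hi and lo <= r.end for r in layout.barcode_regions)


def _absorbable_into_barcode(
    v: CandidateVariant, layout: AmpliconLayout, max_shift: int = 60
) -> bool:
    """Whether an indel has a score-equivalent placement inside a barcode.

    Degenerate (N) reference stretches make gap placement near barcode
    boundaries ambiguous: the aligner may park an indel in the flank even
    though an equivalent alignment puts it inside the barcode region. Such
    indels are barcode content, not candidate variants. We slide the indel
    in both directions through positions where the displaced reference
    base matches (N matches anything) and report whether any equivalent
    placement falls to the barcode side.
    """
    if not v.is_indel:
        return False
    ref = layout.reference_seq
    n = len(ref)

    def in_barcode(pos: int, length: int, is_ins: bool) -> bool:
        probe = CandidateVariant(pos, "" if is_ins else "X" * length,
                                 "X" * length if is_ins else "")
        return _variant_in_barcode(probe, layout)

    if v.ref == "":  # insertion after pos
        for step in (1, -1):
            p, ins = v.pos, v.alt
            for _ in range(max_shift):
                if in_barcode(p, len(ins), True):
                    return True
                if step == 1:
                    if p + 1 > n:
                        break
                    c = ref[p]  # base at 1-based p+1
                    if c != "N" and c != ins[0]:
                        break
                    ins = ins[1:] + (ins[0] if c == "N" else c)
                    p += 1
                else:
                    if p < 1:
                        break
                    c = ref[p - 1]
                    if c != "N" and c != ins[-1]:
                        break
                    ins = (ins[-1] if c == "N" else c) + ins[:-1]
                    p -= 1
        return False
    # deletion of k bases starting at pos
    k = len(v.ref)
    for step in (1, -1):
        p = v.pos
        for _ in range(max_shift):
            if in_barcode(p, k, False):
                return True
            if step == 1:
                if p + k > n:
                    break
                a, b = ref[p - 1], ref[p + k - 1]
                if "N" not in (a, b) and a != b:
                    break
                p += 1
            else:
                if p <= 1:
                    break
                a, b = ref[p - 2], ref[p + k - 2]
                if "N" not in (a, b) and a != b:
                    break
                p -= 1
    return False


def extract_variants(
    aln: Alignment, layout: AmpliconLayout
) -> frozenset[CandidateVariant]:
    """Candidate variants (mismatches and indels) outside barcode regions.

    Indels are left-aligned against the reference. Qualities: an SNV takes
    the basecall quality of the alternate base (an MNV the minimum over
    its bases). Indel placement inside a repeat tract is ambiguous and the
    gap may sit on any equivalent position, so an indel's quality is the
    minimum basecall quality over its whole ambiguity window: for an
    insertion the read bases that are "inserted" under any equivalent
    placement, for a deletion the flanking read bases of every equivalent
    placement.
    """
    ref = aln.ref
    out: list[CandidateVariant] = []
    for kind, t, q, length in _raw_events(aln):
        if kind == "sub":
            pos = t + 1
            alt = aln.read[q : q + length]
            qual = min(aln.quals[q : q + length])
            v = CandidateVariant(pos, ref[t : t + length], alt, qual)
        elif kind == "del":
            orig = t + 1
            pos, deleted = left_align_deletion(ref, orig, ref[t : t + length])
            right = right_shift_deletion(ref, orig, ref[t : t + length])
            lo = q - 1 - (orig - pos)
            hi = q + (right - orig)
            window = [
                aln.quals[i]
                for i in range(lo, hi + 1)
                if 0 <= i < len(aln.quals)
            ]
            v = CandidateVariant(pos, deleted, "", min(window) if window else 0)
        else:  # ins
            inserted = aln.read[q : q + length]
            pos, shifted = left_align_insertion(ref, t, inserted)
            right = right_shift_insertion(ref, t, inserted)
            lo = q - (t - pos)
            hi = q + length + (right - t)
            qual = min(aln.quals[max(lo, 0) : min(hi, len(aln.quals))])
            v = CandidateVariant(pos, "", shifted, qual)
        if _variant_in_barcode(v, layout):
            continue
        if v.is_indel and _absorbable_into_barcode(v, layout):
            continue
        out.append(v)
    return frozenset(out)


def extract_barcodes(
    aln: Alignment, layout: AmpliconLayout
) -> tuple[tuple[str, ...], tuple[tuple[int, ...], ...], int] | None:
    """Read bases (with qualities) aligned within each barcode region.

    Insertions anchored strictly inside a region are included; deletions
    shorten the extracted string. Returns ``None`` when any region is
    entirely deleted or not covered by the alignment.
    """
    seqs: list[str] = []
    quals: list[tuple[int, ...]] = []
    for region in layout.barcode_regions:
        chars: list[str] = []
        qs: list[int] = []
        for bi, (t0, t1, q0, q1) in enumerate(aln.blocks):
            if bi > 0:
                prev_t1, prev_q1 = aln.blocks[bi - 1][1], aln.blocks[bi - 1][3]
                if q0 > prev_q1 and t0 == prev_t1:
                    # insertion anchored after 1-based position t0
                    if region.start <= t0 < region.end:
                        chars.extend(aln.read[prev_q1:q0])
                        qs.extend(aln.quals[prev_q1:q0])
            lo = max(t0, region.start - 1)
            hi = min(t1, region.end)
            if lo < hi:
                chars.extend(aln.read[q0 + lo - t0 : q0 + hi - t0])
                qs.extend(aln.quals[q0 + lo - t0 : q0 + hi - t0])
        if not chars:
            return None
        seqs.append("".join(chars))
        quals.append(tuple(qs))
    min_q = min(q for region in quals for q in region)
    return tuple(seqs), tuple(quals), min_q


def filter_barcode_quality(
    rec: ReadRecord, min_qual: int = 62, stat: str = "min"
) -> bool:
    """True to keep the read. Drops iff the barcode quality statistic
    falls below ``min_qual`` (low-confidence barcodes typically flag
    multi-occupancy SMRT wells)."""
    value = rec.min_bc_qual if stat == "min" else rec.mean_bc_qual
    return value >= min_qual


def process_read(
    read_id: str,
    seq: str,
    quals: Iterable[int],
    layout: AmpliconLayout,
    params: ExtractParams = ExtractParams(),
    aln: Alignment | None = None,
) -> ReadRecord | DroppedRead:
    """Align one read and extract barcodes + candidate variants."""
    if aln is None:
        aln = align_read(seq, quals, layout, params)
    if aln is None:
        return DroppedRead(read_id, "unaligned")
    extracted = extract_barcodes(aln, layout)
    if extracted is None:
        return DroppedRead(read_id, "no_barcode")
    bc_seqs, bc_quals, min_q = extracted
    rec = ReadRecord(
        read_id=read_id,
        barcode_seqs=bc_seqs,
        barcode_quals=bc_quals,
        variants=extract_variants(aln, layout),
        min_bc_qual=min_q,
        strand=aln.strand,
    )
    if not filter_barcode_quality(rec, params.min_bc_qual, params.bc_qual_stat):
        return DroppedRead(read_id, "low_barcode_qual")
    return rec


# ---------------------------------------------------------------------------
# input iteration
# ---------------------------------------------------------------------------


def iter_fastq(path: str) -> Iterator[tuple[str, str, tuple[int, ...]]]:
    for record in SeqIO.parse(path, "fastq"):
        yield (
            record.id,
            str(record.seq),
            tuple(record.letter_annotations["phred_quality"]),
        )


def iter_sam(path: str, layout: AmpliconLayout) -> Iterator[tuple[str, Alignment]]:
    """Pre-aligned mode: reconstruct alignments from a SAM file."""
    import pysam

    with pysam.AlignmentFile(path, "r", check_sq=False) as handle:
        for seg in handle:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            quals = seg.query_qualities
            yield seg.query_name, alignment_from_sam(
                layout.reference_seq,
                seg.query_sequence,
                tuple(quals) if quals is not None else (0,) * len(seg.query_sequence),
                seg.cigartuples or [],
                seg.reference_start,
            )
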