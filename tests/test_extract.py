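import pytest
from hypothesis import given
from hypothesis import strategies as st

from barclone.extract import (
    Alignment,
    CandidateVariant,
    DroppedRead,
    ExtractParams,
    ReadRecord,
    align_read,
    apply_variants,
    extract_barcodes,
    extract_variants,
    filter_barcode_quality,
    format_variants,
    left_align_deletion,
    left_align_insertion,
    parse_variants,
    process_read,
)

from conftest import TOY_REF, mk_read

BC1 = "ACGTGACGTGACGTGACGTGACGTG"
BC2 = "TGCATGCATGCATGCATGCATGCAT"


def perfect_read(layout):
    ref = layout.reference_seq
    return ref[:10] + BC1 + ref[35:71] + BC2 + ref[96:]


# ---------------------------------------------------------------------------
# candidate variants
# ---------------------------------------------------------------------------


def test_variant_identity_ignores_quality():
    assert CandidateVariant(5, "A", "T", 90) == CandidateVariant(5, "A", "T", 10)
    assert len({CandidateVariant(5, "A", "T", 90), CandidateVariant(5, "A", "T", 10)}) == 1


@pytest.mark.parametrize(
    "v,vtype",
    [
        (CandidateVariant(5, "A", "T"), "SNV"),
        (CandidateVariant(5, "AC", "TG"), "MNV"),
        (CandidateVariant(5, "", "T"), "insertion"),
        (CandidateVariant(5, "ACG", ""), "deletion"),
    ],
)
def test_variant_types(v, vtype):
    assert v.vtype == vtype


def test_variant_requires_an_allele():
    with pytest.raises(ValueError):
        CandidateVariant(5, "", "")


def test_variant_serialization_round_trip():
    vs = frozenset(
        {CandidateVariant(5, "A", "T", 90), CandidateVariant(9, "", "GG", 30),
         CandidateVariant(12, "AC", "", 55)}
    )
    assert parse_variants(format_variants(vs)) == vs
    assert parse_variants("") == frozenset()


# ---------------------------------------------------------------------------
# alignment (20 bp toy against DP expectations)
# ---------------------------------------------------------------------------


def test_align_identical_read_has_single_block_no_differences(toy_layout):
    read = perfect_read(toy_layout)
    aln = align_read(read, [90] * len(read), toy_layout)
    assert aln is not None
    assert extract_variants(aln, toy_layout) == frozenset()


def test_align_single_substitution_gives_one_mismatch(toy_layout):
    read = perfect_read(toy_layout)
    mutated = read[:45] + "T" + read[46:]  # ref pos 46 is A
    aln = align_read(mutated, [90] * len(mutated), toy_layout)
    variants = extract_variants(aln, toy_layout)
    assert {v.key for v in variants} == {(46, "A", "T")}


def test_align_two_base_deletion_is_one_contiguous_gap(toy_layout):
    read = perfect_read(toy_layout)
    # delete ref 49-50 ("GT" after the AAAA run): affine scoring must give
    # one gap of length 2, not two isolated gaps
    mutated = read[:48] + read[50:]
    aln = align_read(mutated, [90] * len(mutated), toy_layout)
    variants = extract_variants(aln, toy_layout)
    assert len(variants) == 1
    (v,) = variants
    assert v.vtype == "deletion" and len(v.ref) == 2


def test_unalignable_read_is_dropped(toy_layout):
    result = process_read("junk", "T" * 80, [90] * 80, toy_layout)
    assert result == DroppedRead("junk", "unaligned")


def test_reverse_strand_read_is_normalized(toy_layout):
    from Bio.Seq import reverse_complement

    read = perfect_read(toy_layout)
    mutated = read[:45] + "T" + read[46:]
    rec = process_read(
        "rc", reverse_complement(mutated), [90] * len(mutated), toy_layout
    )
    assert isinstance(rec, ReadRecord)
    assert rec.strand == "-"
    assert rec.barcode_seqs == (BC1, BC2)
    assert {v.key for v in rec.variants} == {(46, "A", "T")}


# ---------------------------------------------------------------------------
# barcode extraction on constructed alignments
# ---------------------------------------------------------------------------


def _constructed(read, blocks, quals=None):
    return Alignment(
        ref=TOY_REF,
        read=read,
        quals=tuple(quals or [90] * len(read)),
        blocks=tuple(blocks),
        score=0.0,
    )


def test_extract_barcodes_error_free(toy_layout):
    read = perfect_read(toy_layout)
    aln = _constructed(read, [(0, len(TOY_REF), 0, len(read))])
    seqs, quals, min_q = extract_barcodes(aln, toy_layout)
    assert seqs == (BC1, BC2)
    assert min_q == 90


def test_extract_barcodes_deletion_shortens_string(toy_layout):
    # 1 nt deletion at ref pos 13 (inside upstream barcode, read idx 12)
    read = perfect_read(toy_layout)
    mutated = read[:12] + read[13:]
    aln = _constructed(
        mutated, [(0, 12, 0, 12), (13, len(TOY_REF), 12, len(mutated))]
    )
    seqs, _, _ = extract_barcodes(aln, toy_layout)
    assert len(seqs[0]) == 24
    assert seqs[0] == BC1[:2] + BC1[3:]


def test_extract_barcodes_includes_interior_insertion(toy_layout):
    # insertion of GG after ref pos 13 (strictly inside the region)
    read = perfect_read(toy_layout)
    mutated = read[:13] + "GG" + read[13:]
    aln = _constructed(
        mutated, [(0, 13, 0, 13), (13, len(TOY_REF), 15, len(mutated))]
    )
    seqs, _, _ = extract_barcodes(aln, toy_layout)
    assert len(seqs[0]) == 27
    assert seqs[0] == BC1[:3] + "GG" + BC1[3:]


def test_extract_barcodes_region_deleted_drops_read(toy_layout):
    # entire upstream barcode region deleted
    read = TOY_REF[:10] + TOY_REF[35:71] + BC2 + TOY_REF[96:]
    aln = _constructed(
        read, [(0, 10, 0, 10), (35, len(TOY_REF), 10, len(read))]
    )
    assert extract_barcodes(aln, toy_layout) is None


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "min_bc_qual,keep", [(93, True), (62, True), (61, False), (0, False)]
)
def test_barcode_quality_filter_boundary(min_bc_qual, keep):
    rec = mk_read("r1", bc_qual=min_bc_qual)
    assert filter_barcode_quality(rec, min_qual=62) is keep


@given(st.integers(min_value=0, max_value=93), st.integers(min_value=0, max_value=93))
def test_barcode_filter_monotone_in_threshold(q, threshold):
    rec = mk_read("r1", bc_qual=q)
    if not filter_barcode_quality(rec, threshold):
        assert not filter_barcode_quality(rec, threshold + 1)


# ---------------------------------------------------------------------------
# variant extraction on constructed alignments
# ---------------------------------------------------------------------------


def test_snv_quality_is_alt_basecall_quality(toy_layout):
    read = perfect_read(toy_layout)
    mutated = read[:45] + "T" + read[46:]
    quals = [90] * len(mutated)
    quals[45] = 33
    aln = _constructed(mutated, [(0, len(TOY_REF), 0, len(mutated))], quals)
    (v,) = extract_variants(aln, toy_layout)
    assert (v.pos, v.ref, v.alt, v.qual) == (46, "A", "T", 33)


def test_deletion_left_aligned_in_homopolymer(toy_layout):
    # ORF begins ATGAAAA...: AAAA run at ref 44-47; delete ref pos 47
    read = perfect_read(toy_layout)
    mutated = read[:46] + read[47:]
    aln = _constructed(
        mutated, [(0, 46, 0, 46), (47, len(TOY_REF), 46, len(mutated))]
    )
    (v,) = extract_variants(aln, toy_layout)
    assert v.key == (44, "A", "")


def test_adjacent_mismatches_merge_to_mnv(toy_layout):
    read = perfect_read(toy_layout)
    mutated = read[:45] + "TT" + read[47:]  # ref 46-47 AA -> TT
    aln = _constructed(mutated, [(0, len(TOY_REF), 0, len(mutated))])
    (v,) = extract_variants(aln, toy_layout)
    assert v.key == (46, "AA", "TT") and v.vtype == "MNV"


def test_boundary_insertion_assigned_to_non_barcode_side():
    # non-degenerate context: insertion anchored exactly at the end of a
    # barcode region belongs to the flank, not the barcode
    from barclone.extract import _variant_in_barcode
    from barclone.layout import AmpliconLayout, Interval

    layout = AmpliconLayout(
        "AAATTT" + "N" * 5 + "ATGTAA" + "CCC",
        orf=Interval(12, 17),
        barcode_regions=(Interval(7, 11),),
    )
    inside = CandidateVariant(8, "", "G")
    at_end = CandidateVariant(11, "", "G")
    before_start = CandidateVariant(6, "", "G")
    assert _variant_in_barcode(inside, layout)
    assert not _variant_in_barcode(at_end, layout)
    assert not _variant_in_barcode(before_start, layout)


def test_insertion_quality_spans_ambiguity_window(toy_layout):
    # insert an extra A into the AAAA run (ref 44-47): any of the run's
    # read bases may be "the insertion", so the minimum over the window
    # is the event quality
    read = perfect_read(toy_layout)
    mutated = read[:47] + "A" + read[47:]
    quals = [90] * len(mutated)
    quals[45] = 28  # low-quality basecall inside the run
    aln = _constructed(
        mutated, [(0, 47, 0, 47), (47, len(TOY_REF), 48, len(mutated))], quals
    )
    (v,) = extract_variants(aln, toy_layout)
    assert v.key == (43, "", "A")  # left-aligned before the run
    assert v.qual == 28


# ---------------------------------------------------------------------------
# left alignment and round trips
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref,pos,deleted,expected",
    [
        ("GAAAAC", 5, "A", (2, "A")),
        ("GATATAC", 4, "TA", (2, "AT")),
        ("ACGT", 3, "G", (3, "G")),
    ],
)
def test_left_align_deletion(ref, pos, deleted, expected):
    assert left_align_deletion(ref, pos, deleted) == expected


@pytest.mark.parametrize(
    "ref,pos,inserted,expected",
    [
        ("GAAAC", 4, "A", (1, "A")),
        ("GATAC", 4, "TA", (1, "AT")),
        ("ACGT", 2, "T", (2, "T")),
    ],
)
def test_left_align_insertion(ref, pos, inserted, expected):
    assert left_align_insertion(ref, pos, inserted) == expected


@given(st.data())
def test_left_aligned_deletion_applies_identically(data):
    ref = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
    pos = data.draw(st.integers(min_value=1, max_value=len(ref) - 1))
    length = data.draw(st.integers(min_value=1, max_value=len(ref) - pos))
    deleted = ref[pos - 1 : pos - 1 + length]
    new_pos, new_del = left_align_deletion(ref, pos, deleted)
    original = apply_variants(ref, [CandidateVariant(pos, deleted, "")])
    shifted = apply_variants(ref, [CandidateVariant(new_pos, new_del, "")])
    assert original == shifted
    # idempotence
    assert left_align_deletion(ref, new_pos, new_del) == (new_pos, new_del)


@given(st.data())
def test_left_aligned_insertion_applies_identically(data):
    ref = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=40))
    pos = data.draw(st.integers(min_value=1, max_value=len(ref)))
    ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
    new_pos, new_ins = left_align_insertion(ref, pos, ins)
    original = apply_variants(ref, [CandidateVariant(pos, "", ins)])
    shifted = apply_variants(ref, [CandidateVariant(new_pos, "", new_ins)])
    assert original == shifted
    assert left_align_insertion(ref, new_pos, new_ins) == (new_pos, new_ins)


def test_variant_round_trip_reconstructs_read(toy_layout):
    # apply extracted variants + extracted barcodes to the reference and
    # recover the aligned read exactly
    read = perfect_read(toy_layout)
    mutated = (
        read[:45] + "T" + read[46:50] + read[52:58] + "GG" + read[58:]
    )  # SNV, 2bp del, 2bp ins, all inside the ORF
    rec = process_read("rt", mutated, [90] * len(mutated), toy_layout)
    assert isinstance(rec, ReadRecord)
    reconstructed = list(toy_layout.reference_seq)
    for region, bc in zip(toy_layout.barcode_regions, rec.barcode_seqs):
        reconstructed[region.start - 1 : region.end] = list(bc)
    reconstructed = apply_variants("".join(reconstructed), rec.variants)
    assert reconstructed == mutated


# ---------------------------------------------------------------------------
# SAM pre-aligned mode
# ---------------------------------------------------------------------------


def test_sam_input_matches_fastq_extraction(toy_layout, tmp_path):
    read = perfect_read(toy_layout)
    mutated = read[:45] + "T" + read[46:]
    qual_str = "".join(chr(90 + 33) for _ in mutated)
    sam = tmp_path / "reads.sam"
    sam.write_text(
        "@HD\tVN:1.6\n"
        f"@SQ\tSN:{toy_layout.name}\tLN:{len(TOY_REF)}\n"
        f"r1\t0\t{toy_layout.name}\t1\t60\t{len(mutated)}M\t*\t0\t0\t"
        f"{mutated}\t{qual_str}\n"
    )
    from barclone.extract import iter_sam

    ((read_id, aln),) = list(iter_sam(str(sam), toy_layout))
    rec = process_read(read_id, aln.read, aln.quals, toy_layout, aln=aln)
    assert isinstance(rec, ReadRecord)
    assert rec.barcode_seqs == (BC1, BC2)
    assert {v.key for v in rec.variants} == {(46, "A", "T")}
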