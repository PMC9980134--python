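"""Per-cluster consensus barcodes, final genotypes and protein consequences.

The consensus barcode of a cluster is the plurality member barcode (ties
broken by total basecall quality, then lexicographically). The final
genotype is the cluster's error-filtered variant set; an empty set denotes
wild type. Nucleotide variants inside the ORF are translated to per-codon
protein consequences in compact HGVS-like one-letter notation (without
formal HGVS validation): synonymous ``p.M1=``, missense ``p.M1I``,
nonsense ``p.Q5Ter``, frameshift ``p.K7fs``, in-frame indels ``p.K7del`` /
``p.K7ins``. Variants outside the ORF are labeled non-coding.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .cluster import Cluster, ClusterParams, filter_errors
from .extract import CandidateVariant, apply_variants
from .layout import AmpliconLayout, homopolymer_runs


@dataclass
class CloneCall:
    """Final output row: one clone's barcode(s), genotype and diagnostics."""

    cluster_id: str
    consensus_barcodes: tuple[str, ...]
    n_reads: int
    nt_variants: frozenset[CandidateVariant]
    aa_consequences: tuple[str, ...]
    net_frame: str  # none | in_frame | frameshift
    flags: set[str] = field(default_factory=set)
    read_ids: tuple[str, ...] = ()

    @property
    def virtual_barcode(self) -> str:
        return "".join(self.consensus_barcodes)

    @property
    def is_wt(self) -> bool:
        return not self.nt_variants

    @property
    def genotype_key(self) -> frozenset:
        return frozenset(v.key for v in self.nt_variants)


def consensus_barcode(cluster: Cluster, region_index: int = 0) -> str:
    """Plurality member barcode for one region.

    Ties are broken by the highest summed per-base quality over the reads
    carrying each candidate string, then by lexicographic order, so the
    result is always an element of the cluster's barcode pool.
    """
    counts: Counter = Counter()
    qual_sums: dict[str, int] = defaultdict(int)
    for rec in cluster.members:
        seq = rec.barcode_seqs[region_index]
        counts[seq] += 1
        qual_sums[seq] += sum(rec.barcode_quals[region_index])
    best_count = max(counts.values())
    tied = [s for s, c in counts.items() if c == best_count]
    best_qual = max(qual_sums[s] for s in tied)
    return min(s for s in tied if qual_sums[s] == best_qual)


def final_genotype(
    cluster: Cluster, var_qual_min: int = 50
) -> frozenset[CandidateVariant]:
    """Error-filtered variant set of the final cluster membership."""
    return filter_errors(cluster.members, var_qual_min)


def _codon_number(pos: int, orf_start: int) -> int:
    return (pos - orf_start) // 3 + 1


def _orf_overlap(v: CandidateVariant, orf_start: int, orf_end: int) -> bool:
    if v.ref == "":  # insertion changes sequence after its anchor
        return orf_start <= v.pos < orf_end
    return v.pos <= orf_end and v.pos + len(v.ref) - 1 >= orf_start


def translate_variants(
    nt_variants: frozenset[CandidateVariant] | set[CandidateVariant],
    layout: AmpliconLayout,
) -> tuple[str, ...]:
    """Per-codon protein consequences of a nucleotide genotype.

    Substitutions falling in the same codon are applied jointly before
    translating that codon. Indels with length not divisible by three are
    frameshifts at their (left-aligned) codon; in-frame indels are reported
    as deletions/insertions at the first affected codon.
    """
    ref = layout.reference_seq
    orf_start, orf_end = layout.orf.start, layout.orf.end
    orf_seq = layout.orf_seq
    out: list[tuple[int, str]] = []

    subs: list[CandidateVariant] = []
    for v in sorted(nt_variants, key=lambda v: v.key):
        # an insertion anchor of 0 denotes bases before the reference start
        first = v.pos if v.ref else max(v.pos, 0)
        last = v.pos if v.ref == "" else v.pos + len(v.ref) - 1
        min_pos = 0 if v.ref == "" else 1
        if not (min_pos <= v.pos and last <= len(ref)):
            raise ValueError(f"variant {v} outside the reference")
        if not _orf_overlap(v, orf_start, orf_end):
            out.append((v.pos, f"nc:{v.pos}:{v.ref or '-'}>{v.alt or '-'}"))
        elif v.is_indel:
            first_changed = v.pos + 1 if v.ref == "" else v.pos
            first_changed = max(first_changed, orf_start)
            codon = _codon_number(first_changed, orf_start)
            ref_aa = _translate_codon(orf_seq, codon)
            if v.indel_length % 3 != 0:
                out.append((first_changed, f"p.{ref_aa}{codon}fs"))
            else:
                kind = "del" if v.alt == "" else "ins"
                out.append((first_changed, f"p.{ref_aa}{codon}{kind}"))
        else:
            subs.append(v)

    # apply all in-ORF substitutions jointly, then report per affected codon
    if subs:
        mutated = list(orf_seq)
        affected: set[int] = set()
        for v in subs:
            for offset in range(len(v.ref)):
                pos = v.pos + offset
                if orf_start <= pos <= orf_end:
                    mutated[pos - orf_start] = v.alt[offset]
                    affected.add(_codon_number(pos, orf_start))
                else:
                    out.append(
                        (pos, f"nc:{pos}:{v.ref[offset]}>{v.alt[offset]}")
                    )
        mutated_seq = "".join(mutated)
        for codon in sorted(affected):
            ref_aa = _translate_codon(orf_seq, codon)
            alt_aa = _translate_codon(mutated_seq, codon)
            anchor = orf_start + (codon - 1) * 3
            if alt_aa == ref_aa:
                out.append((anchor, f"p.{ref_aa}{codon}="))
            else:
                out.append((anchor, f"p.{ref_aa}{codon}{alt_aa}"))
    return tuple(text for _, text in sorted(out))


def _translate_codon(seq: str, codon: int) -> str:
    """One-letter amino acid of a codon; stop rendered as ``Ter``."""
    triplet = seq[(codon - 1) * 3 : codon * 3]
    if len(triplet) < 3:
        return "?"
    aa = str(Seq(triplet).translate())
    return "Ter" if aa == "*" else aa


def _net_frame(nt_variants, orf_start: int, orf_end: int) -> str:
    """Cluster-level net reading-frame annotation across all in-ORF indels."""
    net = 0
    any_indel = False
    for v in nt_variants:
        if v.is_indel and _orf_overlap(v, orf_start, orf_end):
            any_indel = True
            net += len(v.alt) - len(v.ref)
    if not any_indel:
        return "none"
    return "in_frame" if net % 3 == 0 else "frameshift"


def annotate_homopolymer_frameshift(
    variant: CandidateVariant, runs: list[tuple[int, int, str]]
) -> bool:
    """Whether a variant is a frameshift-length indel at the 5' end of a
    homopolymer run (its left-aligned position equals a run start or the
    position immediately preceding it). Such calls are enriched among
    long-read sequencing artifacts."""
    if not variant.is_indel or variant.indel_length % 3 == 0:
        return False
    return any(variant.pos in (start - 1, start) for start, _end, _base in runs)


def call_clones(
    clusters: list[Cluster],
    layout: AmpliconLayout,
    params: ClusterParams = ClusterParams(),
    homopolymer_min: int = 4,
) -> list[CloneCall]:
    """Derive one CloneCall per cluster (consensus barcodes, filtered
    genotype, protein consequences, homopolymer context flags)."""
    runs = homopolymer_runs(layout.reference_seq, homopolymer_min)
    calls = []
    for i, cluster in enumerate(clusters):
        genotype = final_genotype(cluster, params.var_qual_min)
        n_regions = len(cluster.members[0].barcode_seqs)
        barcodes = tuple(
            consensus_barcode(cluster, r) for r in range(n_regions)
        )
        flags = set()
        if any(annotate_homopolymer_frameshift(v, runs) for v in genotype):
            flags.add("homopolymer_frameshift")
        calls.append(
            CloneCall(
                cluster_id=f"clone{i + 1:05d}",
                consensus_barcodes=barcodes,
                n_reads=cluster.size,
                nt_variants=genotype,
                aa_consequences=translate_variants(genotype, layout),
                net_frame=_net_frame(genotype, layout.orf.start, layout.orf.end),
                flags=flags,
                read_ids=cluster.read_ids(),
            )
        )
    return calls
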