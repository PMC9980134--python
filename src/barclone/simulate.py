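"""Synthetic barcoded clone libraries with HiFi-like reads and ground truth.

The generator emulates the phenomena the pipeline must handle: clones
carrying 0-n ORF variants behind random barcodes; a log-normal read count
per clone; substitution and indel sequencing errors with indel rates
multiplied inside homopolymer runs; occasional single-base barcode
miscalls; low-quality barcode stretches emulating multi-occupancy wells;
planted non-unique barcodes (two clones sharing a barcode); and PCR
crossover chimeras pairing one clone's upstream barcode with another's
downstream barcode. Per-base qualities are anti-correlated with planted
errors: correct bases draw from a high distribution (median ~Q90), basecall
errors from a low one (median ~Q30, below the variant-quality filter),
while barcode miscalls are "confidently wrong" (median ~Q78, above the Q62
barcode filter) as consensus basecalling errors typically are — the Q62
filter targets multi-occupancy wells, which are modeled separately.

Everything is drawn from one seeded generator, so a fixed seed yields a
byte-identical FASTQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .extract import CandidateVariant, apply_variants
from .layout import AmpliconLayout, Interval, homopolymer_runs

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic library."""

    n_clones: int = 100
    barcode_len: int = 25
    orf_codons: int = 167  # ATG + 165 sense codons + stop
    flank_len: int = 20
    spacer_len: int = 12
    dual_barcode: bool = True
    variants_per_clone: float = 2.0  # Poisson mean
    reads_per_clone_median: float = 10.0  # log-normal median
    reads_per_clone_sigma: float = 0.4
    sub_rate: float = 0.01  # per base
    ins_rate: float = 0.0025
    del_rate: float = 0.0025
    homopolymer_indel_multiplier: float = 5.0
    homopolymer_min: int = 4
    barcode_error_rate: float = 0.02  # per read: prob of one barcode miscall
    lowq_barcode_frac: float = 0.02  # multi-occupancy emulation
    frac_nonunique_barcodes: float = 0.05
    frac_chimeric_templates: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sub_rate", "ins_rate", "del_rate", "barcode_error_rate",
            "lowq_barcode_frac", "frac_nonunique_barcodes",
            "frac_chimeric_templates",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")


@dataclass(frozen=True)
class Template:
    """One physical molecule species: a clone or a crossover chimera."""

    template_id: str
    kind: str  # clone | chimera
    barcodes: tuple[str, ...]
    variants: frozenset[CandidateVariant]
    sequence: str
    barcode_spans: tuple[tuple[int, int], ...]  # 0-based half-open, template coords
    donors: tuple[str, str] | None = None
    crossover: int | None = None

    @property
    def virtual_barcode(self) -> str:
        return "".join(self.barcodes)

    @property
    def genotype_key(self) -> frozenset:
        return frozenset(v.key for v in self.variants)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    template_id: str
    is_chimera: bool
    lowq_barcode: bool
    n_barcode_errors: int
    strand: str


@dataclass
class SimTruth:
    templates: list[Template]
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def template_by_id(self, template_id: str) -> Template:
        return next(t for t in self.templates if t.template_id == template_id)


@dataclass
class SimulatedLibrary:
    layout: AmpliconLayout
    params: SimParams
    truth: SimTruth
    reads: list[tuple[str, str, tuple[int, ...]]]  # id, seq, quals

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for read_id, seq, quals in self.reads:
                qline = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{read_id}\n{seq}\n+\n{qline}\n")

    def write_truth(self, reads_path: str, templates_path: str) -> None:
        from .extract import format_variants

        with open(templates_path, "w") as fh:
            fh.write(
                "template_id\tkind\tbarcodes\tvariants\tdonors\tcrossover\n"
            )
            for t in self.truth.templates:
                donors = ",".join(t.donors) if t.donors else ""
                fh.write(
                    f"{t.template_id}\t{t.kind}\t{','.join(t.barcodes)}\t"
                    f"{format_variants(t.variants)}\t{donors}\t"
                    f"{t.crossover if t.crossover is not None else ''}\n"
                )
        with open(reads_path, "w") as fh:
            fh.write(
                "read_id\ttemplate_id\tis_chimera\tlowq_barcode\t"
                "n_barcode_errors\tstrand\n"
            )
            for read_id in sorted(self.truth.reads):
                r = self.truth.reads[read_id]
                fh.write(
                    f"{r.read_id}\t{r.template_id}\t{int(r.is_chimera)}\t"
                    f"{int(r.lowq_barcode)}\t{r.n_barcode_errors}\t{r.strand}\n"
                )


# ---------------------------------------------------------------------------
# layout and clone generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = _random_seq(rng, 3)
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def make_layout(params: SimParams, rng: np.random.Generator) -> AmpliconLayout:
    """Random amplicon matching the configured geometry: flank, barcode
    (N run), spacer, ORF, then optionally spacer, barcode, flank."""
    parts = [
        _random_seq(rng, params.flank_len),
        "N" * params.barcode_len,
        _random_seq(rng, params.spacer_len),
        _random_orf(rng, params.orf_codons),
    ]
    orf_start = params.flank_len + params.barcode_len + params.spacer_len + 1
    orf_end = orf_start + 3 * params.orf_codons - 1
    regions = [
        Interval(params.flank_len + 1, params.flank_len + params.barcode_len)
    ]
    if params.dual_barcode:
        parts += [
            _random_seq(rng, params.spacer_len),
            "N" * params.barcode_len,
            _random_seq(rng, params.flank_len),
        ]
        down_start = orf_end + params.spacer_len + 1
        regions.append(
            Interval(down_start, down_start + params.barcode_len - 1)
        )
    else:
        parts.append(_random_seq(rng, params.flank_len))
    return AmpliconLayout(
        reference_seq="".join(parts),
        orf=Interval(orf_start, orf_end),
        barcode_regions=tuple(regions),
        name="simulated_amplicon",
    )


def _draw_variant(
    rng: np.random.Generator, layout: AmpliconLayout, taken: list[int]
) -> CandidateVariant | None:
    """One random ORF variant (70% SNV / 15% ins / 15% del), left-aligned,
    kept clear of previously placed variants."""
    ref = layout.reference_seq
    lo, hi = layout.orf.start + 3, layout.orf.end - 3
    pos = int(rng.integers(lo, hi + 1))
    if any(abs(pos - t) < 8 for t in taken):
        return None
    kind = rng.choice(["SNV", "ins", "del"], p=[0.7, 0.15, 0.15])
    length = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
    if kind == "SNV":
        base = ref[pos - 1]
        alt = _BASES[int(rng.integers(0, 4))]
        while alt == base:
            alt = _BASES[int(rng.integers(0, 4))]
        return CandidateVariant(pos, base, alt, 0)
    if kind == "ins":
        inserted = _random_seq(rng, length)
        from .extract import left_align_insertion

        p, ins = left_align_insertion(ref, pos, inserted)
        if p < lo - 1:
            return None
        return CandidateVariant(p, "", ins, 0)
    from .extract import left_align_deletion

    if pos + length - 1 > hi:
        return None
    p, deleted = left_align_deletion(ref, pos, ref[pos - 1 : pos + length - 1])
    if p < lo:
        return None
    return CandidateVariant(p, deleted, "", 0)


def _clone_genotype(
    rng: np.random.Generator, layout: AmpliconLayout, mean: float
) -> frozenset[CandidateVariant]:
    k = int(rng.poisson(mean))
    variants: list[CandidateVariant] = []
    taken: list[int] = []
    attempts = 0
    while len(variants) < k and attempts < 200:
        attempts += 1
        v = _draw_variant(rng, layout, taken)
        if v is None or any(v.key == u.key for u in variants):
            continue
        variants.append(v)
        taken.append(v.pos)
    return frozenset(variants)


def _build_template(
    template_id: str,
    kind: str,
    layout: AmpliconLayout,
    barcodes: tuple[str, ...],
    variants: frozenset[CandidateVariant],
    donors: tuple[str, str] | None = None,
    crossover: int | None = None,
) -> Template:
    ref = layout.reference_seq
    seq = list(ref)
    for region, bc in zip(layout.barcode_regions, barcodes):
        seq[region.start - 1 : region.end] = list(bc)
    seq = apply_variants("".join(seq), variants)
    # barcode spans in template coordinates: variants are confined to the
    # ORF, which lies between the two barcode regions
    net = sum(len(v.alt) - len(v.ref) for v in variants)
    spans = []
    for region in layout.barcode_regions:
        shift = net if region.start > layout.orf.end else 0
        spans.append((region.start - 1 + shift, region.end + shift))
    return Template(
        template_id=template_id,
        kind=kind,
        barcodes=barcodes,
        variants=variants,
        sequence=seq,
        barcode_spans=tuple(spans),
        donors=donors,
        crossover=crossover,
    )


def simulate_clones(
    layout: AmpliconLayout, params: SimParams, rng: np.random.Generator
) -> list[Template]:
    """Clone templates with random barcodes and genotypes, including the
    planted fraction of non-unique barcodes (same barcode, two clones)."""
    n_regions = layout.n_barcodes
    barcode_sets: set[tuple[str, ...]] = set()
    templates: list[Template] = []
    n_dup = int(round(params.frac_nonunique_barcodes * params.n_clones))
    for i in range(params.n_clones):
        genotype = _clone_genotype(rng, layout, params.variants_per_clone)
        if i >= params.n_clones - n_dup and templates:
            donor = templates[int(rng.integers(0, len(templates)))]
            while donor.genotype_key == frozenset(v.key for v in genotype):
                genotype = _clone_genotype(
                    rng, layout, max(params.variants_per_clone, 1.0)
                )
            barcodes = donor.barcodes
        else:
            barcodes = tuple(
                _random_seq(rng, params.barcode_len) for _ in range(n_regions)
            )
            while barcodes in barcode_sets:
                barcodes = tuple(
                    _random_seq(rng, params.barcode_len)
                    for _ in range(n_regions)
                )
            barcode_sets.add(barcodes)
        templates.append(
            _build_template(f"t{i + 1:05d}", "clone", layout, barcodes, genotype)
        )
    return templates


def simulate_chimeras(
    clones: list[Template],
    layout: AmpliconLayout,
    params: SimParams,
    rng: np.random.Generator,
) -> list[Template]:
    """Crossover templates: upstream portion (incl. upstream barcode) from
    clone A, downstream portion (incl. downstream barcode) from clone B,
    crossover point uniform within the ORF."""
    if layout.n_barcodes < 2:
        return []
    n_chim = int(round(params.frac_chimeric_templates * len(clones)))
    out: list[Template] = []
    for i in range(n_chim):
        a, b = (clones[int(k)] for k in rng.choice(len(clones), 2, replace=False))
        for _ in range(100):
            x = int(rng.integers(layout.orf.start, layout.orf.end + 1))
            footprint = [
                (v.pos, v.pos + max(len(v.ref), 1) + 1)
                for v in set(a.variants) | set(b.variants)
            ]
            if all(not lo - 2 <= x <= hi for lo, hi in footprint):
                break
        genotype = frozenset(
            v for v in a.variants if v.pos + max(len(v.ref), 1) - 1 <= x
        ) | frozenset(v for v in b.variants if v.pos > x)
        out.append(
            _build_template(
                f"x{i + 1:05d}",
                "chimera",
                layout,
                (a.barcodes[0], b.barcodes[1]),
                genotype,
                donors=(a.template_id, b.template_id),
                crossover=x,
            )
        )
    return out


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------


def _qual_high(rng) -> int:
    return int(np.clip(round(rng.normal(90, 3)), 70, 93))


def _qual_error(rng) -> int:
    return int(np.clip(round(rng.normal(30, 6)), 3, 93))


def _qual_confident_miscall(rng) -> int:
    return int(np.clip(round(rng.normal(78, 5)), 62, 93))


def _qual_multiocc(rng) -> int:
    return int(np.clip(round(rng.normal(45, 8)), 3, 61))


def _hp_mask(seq: str, min_len: int) -> np.ndarray:
    mask = np.zeros(len(seq), dtype=bool)
    for start, end, _ in homopolymer_runs(seq, min_len):
        mask[start - 1 : end] = True
    return mask


def generate_read(
    template: Template,
    read_id: str,
    params: SimParams,
    rng: np.random.Generator,
    force_lowq: bool | None = None,
) -> tuple[str, tuple[int, ...], ReadTruth]:
    """One read: sequencing errors, barcode artifacts, random orientation."""
    seq = template.sequence
    hp = _hp_mask(seq, params.homopolymer_min)
    in_bc = np.zeros(len(seq), dtype=bool)
    for lo, hi in template.barcode_spans:
        in_bc[lo:hi] = True

    # decide barcode artifacts up front
    lowq = (
        force_lowq
        if force_lowq is not None
        else bool(rng.random() < params.lowq_barcode_frac)
    )
    n_bc_err = int(rng.random() < params.barcode_error_rate)
    bc_indices = np.flatnonzero(in_bc)
    bc_err_pos = int(bc_indices[int(rng.integers(0, len(bc_indices)))]) if n_bc_err else -1
    bc_err_kind = (
        ["sub", "ins", "del"][
            int(rng.choice(3, p=[0.7, 0.15, 0.15]))
        ]
        if n_bc_err
        else None
    )

    chars: list[str] = []
    quals: list[int] = []
    pending_del_depress = False

    def emit(c: str, q: int) -> None:
        nonlocal pending_del_depress
        if pending_del_depress:
            q = min(q, _qual_error(rng))
            pending_del_depress = False
        chars.append(c)
        quals.append(q)

    for i, base in enumerate(seq):
        if in_bc[i]:
            bq = _qual_multiocc(rng) if lowq else _qual_high(rng)
            if i == bc_err_pos:
                if bc_err_kind == "del":
                    # a confident consensus miscall: neighbors keep their
                    # quality, unlike raw-signal deletions elsewhere
                    continue
                if bc_err_kind == "sub":
                    alt = _BASES[int(rng.integers(0, 4))]
                    while alt == base:
                        alt = _BASES[int(rng.integers(0, 4))]
                    emit(alt, bq if lowq else _qual_confident_miscall(rng))
                    continue
                emit(base, bq)
                emit(
                    _BASES[int(rng.integers(0, 4))],
                    bq if lowq else _qual_confident_miscall(rng),
                )
                continue
            emit(base, bq)
            continue
        mult = params.homopolymer_indel_multiplier if hp[i] else 1.0
        r = rng.random()
        if r < params.del_rate * mult:
            if quals:
                quals[-1] = min(quals[-1], _qual_error(rng))
            pending_del_depress = True
            continue
        if r < params.del_rate * mult + params.sub_rate:
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == base:
                alt = _BASES[int(rng.integers(0, 4))]
            emit(alt, _qual_error(rng))
        else:
            emit(base, _qual_high(rng))
        if rng.random() < params.ins_rate * mult:
            emit(_BASES[int(rng.integers(0, 4))], _qual_error(rng))

    read_seq = "".join(chars)
    read_quals = tuple(quals)
    strand = "+"
    if rng.random() < 0.5:
        strand = "-"
        read_seq = read_seq.translate(_COMPLEMENT)[::-1]
        read_quals = read_quals[::-1]
    truth = ReadTruth(
        read_id=read_id,
        template_id=template.template_id,
        is_chimera=template.kind == "chimera",
        lowq_barcode=lowq,
        n_barcode_errors=n_bc_err,
        strand=strand,
    )
    return read_seq, read_quals, truth


def random_micro_library(
    rng: np.random.Generator,
    max_reads: int = 50,
    barcode_len: int = 10,
    var_qual_min: int = 50,
) -> list:
    """Small random set of ReadRecords exercising the clustering paths.

    Generates a handful of clones with short barcodes (some within edit
    distance 1-2 of each other), skewed cluster sizes, occasional per-read
    barcode miscalls and variant noise of mixed quality. Operates at the
    ReadRecord level (no sequences/alignment), which is the clustering
    algorithm's actual input domain.
    """
    from .extract import ReadRecord

    n_clones = int(rng.integers(2, 7))
    variant_pool = [
        CandidateVariant(int(pos), "A", "T", 90)
        for pos in rng.choice(np.arange(100, 400), size=12, replace=False)
    ]
    clones = []
    barcodes: list[str] = []
    for ci in range(n_clones):
        if barcodes and rng.random() < 0.5:
            # barcode near an existing one (satellite / collision material)
            base = list(barcodes[int(rng.integers(0, len(barcodes)))])
            n_edits = int(rng.integers(1, 3))
            for _ in range(n_edits):
                op = rng.choice(["sub", "ins", "del"])
                p = int(rng.integers(0, len(base)))
                if op == "sub":
                    base[p] = _BASES[int(rng.integers(0, 4))]
                elif op == "ins":
                    base.insert(p, _BASES[int(rng.integers(0, 4))])
                elif len(base) > 2:
                    del base[p]
            bc = "".join(base)
        else:
            bc = _random_seq(rng, barcode_len)
        barcodes.append(bc)
        k = int(rng.integers(0, 3))
        genotype = frozenset(
            variant_pool[int(i)]
            for i in rng.choice(len(variant_pool), size=k, replace=False)
        )
        clones.append((bc, genotype))
    records = []
    n_reads = int(rng.integers(n_clones, max_reads + 1))
    sizes = rng.multinomial(n_reads, rng.dirichlet(np.ones(n_clones) * 0.7))
    serial = 0
    for (bc, genotype), size in zip(clones, sizes):
        for _ in range(size):
            serial += 1
            read_bc = bc
            if rng.random() < 0.1:  # barcode miscall
                p = int(rng.integers(0, len(bc)))
                read_bc = bc[:p] + _BASES[int(rng.integers(0, 4))] + bc[p + 1 :]
            variants = set(genotype)
            if rng.random() < 0.3:  # noise variant of random quality
                noise = variant_pool[int(rng.integers(0, len(variant_pool)))]
                qual = int(rng.choice([20, var_qual_min - 1, var_qual_min, 90]))
                variants.add(CandidateVariant(noise.pos, noise.ref, noise.alt, qual))
            records.append(
                ReadRecord(
                    read_id=f"m{serial:04d}",
                    barcode_seqs=(read_bc,),
                    barcode_quals=(tuple([90] * len(read_bc)),),
                    variants=frozenset(variants),
                    min_bc_qual=90,
                )
            )
    return records


def simulate_library(
    params: SimParams, layout: AmpliconLayout | None = None
) -> SimulatedLibrary:
    """Full simulation: layout (unless given), clone and chimera templates,
    and error-bearing reads with per-read ground truth."""
    rng = np.random.default_rng(params.seed)
    if layout is None:
        layout = make_layout(params, rng)
    clones = simulate_clones(layout, params, rng)
    chimeras = simulate_chimeras(clones, layout, params, rng)
    templates = clones + chimeras
    truth = SimTruth(templates=templates)
    reads: list[tuple[str, str, tuple[int, ...]]] = []
    serial = 0
    for template in templates:
        n_reads = max(
            1,
            int(
                round(
                    rng.lognormal(
                        math.log(params.reads_per_clone_median),
                        params.reads_per_clone_sigma,
                    )
                )
            ),
        )
        for _ in range(n_reads):
            serial += 1
            read_id = f"r{serial:06d}"
            seq, quals, rt = generate_read(template, read_id, params, rng)
            reads.append((read_id, seq, quals))
            truth.reads[read_id] = rt
    return SimulatedLibrary(layout=layout, params=params, truth=truth, reads=reads)
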