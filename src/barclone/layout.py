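"""Amplicon layout: reference sequence, ORF and barcode region coordinates.

All user-facing coordinates are 1-based and inclusive. The reference is a
single linear amplicon carrying one open reading frame and one or two
degenerate barcode stretches (written as ``N`` runs in the reference).
When two barcode regions are present, the first by reference position is
the "upstream" barcode and the second the "downstream" barcode.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

_ACGT = set("ACGT")
_ACGTN = set("ACGTN")

START_CODONS = ("ATG",)


class LayoutError(ValueError):
    """Raised when an amplicon layout is internally inconsistent."""


@dataclass(frozen=True)
class Interval:
    """Closed 1-based interval on the reference."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise LayoutError(f"invalid interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class AmpliconLayout:
    """Reference amplicon with ORF and barcode-region annotations."""

    reference_seq: str
    orf: Interval
    barcode_regions: tuple[Interval, ...]
    name: str = "amplicon"

    def __post_init__(self) -> None:
        self._validate()

    # -- derived accessors -------------------------------------------------

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_regions)

    @property
    def upstream(self) -> Interval:
        return self.barcode_regions[0]

    @property
    def downstream(self) -> Interval:
        if len(self.barcode_regions) < 2:
            raise LayoutError("layout has a single barcode region")
        return self.barcode_regions[1]

    @property
    def orf_seq(self) -> str:
        return self.reference_seq[self.orf.start - 1 : self.orf.end]

    def in_barcode(self, pos: int) -> bool:
        return any(r.contains(pos) for r in self.barcode_regions)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        ref = self.reference_seq.upper()
        object.__setattr__(self, "reference_seq", ref)
        n = len(ref)
        if n == 0:
            raise LayoutError("empty reference sequence")
        bad = set(ref) - _ACGTN
        if bad:
            raise LayoutError(f"non-ACGTN characters in reference: {sorted(bad)}")
        if not 1 <= len(self.barcode_regions) <= 2:
            raise LayoutError("need one or two barcode regions")
        regions = tuple(sorted(self.barcode_regions, key=lambda r: r.start))
        object.__setattr__(self, "barcode_regions", regions)
        for r in regions + (self.orf,):
            if r.end > n:
                raise LayoutError(f"interval {r} outside reference of length {n}")
        for i, a in enumerate(regions):
            for b in regions[i + 1 :]:
                if a.overlaps(b):
                    raise LayoutError(f"barcode regions {a} and {b} overlap")
            if a.overlaps(self.orf):
                raise LayoutError(f"barcode region {a} overlaps the ORF {self.orf}")
        for r in regions:
            bases = set(ref[r.start - 1 : r.end])
            if bases - {"N"}:
                warnings.warn(
                    f"barcode region {r} contains non-degenerate bases; "
                    "expected N placeholders",
                    stacklevel=3,
                )
        outside = [
            ref[i]
            for i in range(n)
            if not self.in_barcode(i + 1) and ref[i] not in _ACGT
        ]
        if outside:
            raise LayoutError(
                "degenerate bases outside barcode regions "
                f"({len(outside)} positions)"
            )
        if len(self.orf) % 3 != 0:
            warnings.warn(
                f"ORF length {len(self.orf)} is not a multiple of 3",
                stacklevel=3,
            )
        if ref[self.orf.start - 1 : self.orf.start + 2] not in START_CODONS:
            warnings.warn("ORF does not begin with a start codon", stacklevel=3)

    # -- serialization -----------------------------------------------------

    def to_config_text(self) -> str:
        lines = [
            f"name = {self.name}",
            f"reference_seq = {self.reference_seq}",
            f"orf = {self.orf}",
            f"barcode1 = {self.barcode_regions[0]}",
        ]
        if len(self.barcode_regions) == 2:
            lines.append(f"barcode2 = {self.barcode_regions[1]}")
        return "\n".join(lines) + "\n"

    def reference_fasta(self) -> str:
        return f">{self.name}\n{self.reference_seq}\n"


def _parse_interval(text: str, key: str) -> Interval:
    try:
        lo, hi = text.split("-")
        return Interval(int(lo), int(hi))
    except (ValueError, TypeError) as exc:
        raise LayoutError(f"cannot parse interval for {key!r}: {text!r}") from exc


def load_layout(config_text: str, base_dir: str | None = None) -> AmpliconLayout:
    """Parse a flat key=value layout config into a validated layout.

    Recognized keys: ``name``, ``reference`` (path to a FASTA file, resolved
    against *base_dir*) or ``reference_seq`` (inline sequence), ``orf``,
    ``barcode1`` and optional ``barcode2``, intervals as ``start-end``.
    """
    fields: dict[str, str] = {}
    for raw in config_text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise LayoutError(f"cannot parse config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        fields[key.lower()] = value

    if "reference_seq" in fields:
        ref = fields["reference_seq"]
    elif "reference" in fields:
        path = fields["reference"]
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        record = next(SeqIO.parse(path, "fasta"))
        ref = str(record.seq)
    else:
        raise LayoutError("config must name a reference or reference_seq")

    if "orf" not in fields or "barcode1" not in fields:
        raise LayoutError("config must define orf and barcode1")
    regions = [_parse_interval(fields["barcode1"], "barcode1")]
    if "barcode2" in fields:
        regions.append(_parse_interval(fields["barcode2"], "barcode2"))
    return AmpliconLayout(
        reference_seq=ref,
        orf=_parse_interval(fields["orf"], "orf"),
        barcode_regions=tuple(regions),
        name=fields.get("name", "amplicon"),
    )


def load_layout_file(path: str) -> AmpliconLayout:
    with open(path) as handle:
        return load_layout(handle.read(), base_dir=os.path.dirname(path) or ".")


def homopolymer_runs(
    reference_seq: str, min_len: int = 4
) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases of length >= *min_len*.

    Returns 1-based inclusive ``(start, end, base)`` tuples sorted by start.
    Indel sequencing errors in long reads concentrate at such runs, so
    run coordinates feed both the simulator's error model and the
    frameshift-context annotation.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = reference_seq.upper()
    bad = set(seq) - _ACGTN
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            runs.append((i + 1, j + 1, seq[i]))
        i = j + 1
    return runs
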