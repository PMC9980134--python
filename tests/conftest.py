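import warnings

import pytest
from hypothesis import HealthCheck, settings

from barclone.extract import CandidateVariant, ReadRecord
from barclone.layout import AmpliconLayout, Interval

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# flank(10) | barcode1 N(25) | spacer CCATG | ORF(41..66) | spacer GGCCA |
# barcode2 N(25) | flank(10)
TOY_REF = (
    "GATTACAGTC"
    + "N" * 25
    + "CCATG"
    + "ATGAAAACGTACGTACGCCTAGGTAA"
    + "GGCCA"
    + "N" * 25
    + "TTGACCAGTT"
)


@pytest.fixture
def toy_layout() -> AmpliconLayout:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AmpliconLayout(
            reference_seq=TOY_REF,
            orf=Interval(41, 66),
            barcode_regions=(Interval(11, 35), Interval(72, 96)),
            name="toy",
        )


@pytest.fixture
def single_bc_layout() -> AmpliconLayout:
    ref = "GATTACAGTC" + "N" * 25 + "CCATG" + "ATGAAAACGTACGTACGCCTAGGTAA" + "GG"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AmpliconLayout(
            reference_seq=ref,
            orf=Interval(41, 66),
            barcode_regions=(Interval(11, 35),),
            name="toy_single",
        )


def mk_read(
    read_id: str,
    barcode: str = "ACGTACGTAC",
    variants=(),
    bc_qual: int = 90,
    barcode2: str | None = None,
) -> ReadRecord:
    """Synthetic ReadRecord for cluster/consensus/qc tests."""
    seqs = (barcode,) if barcode2 is None else (barcode, barcode2)
    quals = tuple(tuple([bc_qual] * len(s)) for s in seqs)
    return ReadRecord(
        read_id=read_id,
        barcode_seqs=seqs,
        barcode_quals=quals,
        variants=frozenset(variants),
        min_bc_qual=bc_qual,
    )


def var(pos: int, ref: str = "A", alt: str = "T", qual: int = 90) -> CandidateVariant:
    return CandidateVariant(pos, ref, alt, qual)
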