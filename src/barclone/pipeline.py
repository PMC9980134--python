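"""End-to-end pipeline: extract -> cluster -> consensus -> QC -> reports.

All outputs are plain TSV/JSON, deterministically ordered, so re-running on
identical inputs yields byte-identical files.
"""

from __future__ import annotations

import json
import multiprocessing
import os
from collections import Counter
from dataclasses import dataclass, field

from . import qc
from .cluster import Cluster, ClusterParams, cluster_library
from .consensus import CloneCall, call_clones
from .extract import (
    DroppedRead,
    ExtractParams,
    ReadRecord,
    format_variants,
    iter_fastq,
    iter_sam,
    process_read,
)
from .layout import AmpliconLayout, LayoutError, load_layout_file


@dataclass
class RunConfig:
    fastq: str | None = None
    sam: str | None = None
    layout_path: str | None = None
    layout: AmpliconLayout | None = None
    out_dir: str = "barclone_out"
    min_bc_qual: int = 62
    bc_qual_stat: str = "min"
    max_ed: int = 2
    jaccard_min: float = 0.2
    var_qual_min: int = 50
    homopolymer_min: int = 4
    virtual_barcodes: bool = True
    chimera_detection: str = "auto"  # auto | on | off
    workers: int = 1

    def extract_params(self) -> ExtractParams:
        return ExtractParams(
            min_bc_qual=self.min_bc_qual, bc_qual_stat=self.bc_qual_stat
        )

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            max_ed=self.max_ed,
            jaccard_min=self.jaccard_min,
            var_qual_min=self.var_qual_min,
        )


@dataclass
class RunResult:
    records: list[ReadRecord]
    dropped: list[DroppedRead]
    clusters: list[Cluster]
    clones: list[CloneCall]
    uniqueness: list
    chimeras: list | None
    summary: dict


# -- extraction (optionally multi-process over read chunks) -----------------

_WORKER_STATE: dict = {}


def _init_worker(layout: AmpliconLayout, params: ExtractParams) -> None:
    _WORKER_STATE["layout"] = layout
    _WORKER_STATE["params"] = params


def _extract_one(item: tuple[str, str, tuple[int, ...]]):
    read_id, seq, quals = item
    return process_read(
        read_id, seq, quals, _WORKER_STATE["layout"], _WORKER_STATE["params"]
    )


def extract_all(
    reads, layout: AmpliconLayout, params: ExtractParams, workers: int = 1
) -> tuple[list[ReadRecord], list[DroppedRead]]:
    """Extract every read; results keep input order regardless of worker
    count, so parallelism never changes downstream output."""
    records: list[ReadRecord] = []
    dropped: list[DroppedRead] = []
    if workers > 1:
        with multiprocessing.Pool(
            workers, initializer=_init_worker, initargs=(layout, params)
        ) as pool:
            results = pool.map(_extract_one, list(reads), chunksize=64)
    else:
        _init_worker(layout, params)
        results = [_extract_one(item) for item in reads]
    for res in results:
        (records if isinstance(res, ReadRecord) else dropped).append(res)
    return records, dropped


# -- report writing ----------------------------------------------------------


def _write_tsv(path: str, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_reports(result: RunResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    _write_tsv(
        os.path.join(out_dir, "extractions.tsv"),
        ["read_id", "strand", "barcodes", "virtual_barcode", "min_bc_qual",
         "variants"],
        [
            [r.read_id, r.strand, ",".join(r.barcode_seqs), r.virtual_barcode,
             r.min_bc_qual, format_variants(r.variants)]
            for r in sorted(result.records, key=lambda r: r.read_id)
        ],
    )
    _write_tsv(
        os.path.join(out_dir, "dropped.tsv"),
        ["read_id", "reason"],
        [[d.read_id, d.reason]
         for d in sorted(result.dropped, key=lambda d: d.read_id)],
    )
    _write_tsv(
        os.path.join(out_dir, "clusters.tsv"),
        ["cluster_id", "size", "consensus_barcodes", "virtual_barcode",
         "variants", "read_ids"],
        [
            [c.cluster_id, c.n_reads, ",".join(c.consensus_barcodes),
             c.virtual_barcode, format_variants(c.nt_variants),
             ",".join(c.read_ids)]
            for c in result.clones
        ],
    )
    _write_tsv(
        os.path.join(out_dir, "clone_calls.tsv"),
        ["cluster_id", "virtual_barcode", "barcode_up", "barcode_down",
         "n_reads", "nt_variants", "aa_consequences", "net_frame", "flags"],
        [
            [c.cluster_id, c.virtual_barcode, c.consensus_barcodes[0],
             c.consensus_barcodes[1] if len(c.consensus_barcodes) > 1 else "",
             c.n_reads, format_variants(c.nt_variants),
             ",".join(c.aa_consequences), c.net_frame,
             ",".join(sorted(c.flags))]
            for c in result.clones
        ],
    )
    _write_tsv(
        os.path.join(out_dir, "uniqueness.tsv"),
        ["barcode", "status", "n_clones", "read_counts"],
        [
            [g.key_barcode, g.status, len(g.clones),
             ",".join(str(n) for n in g.read_counts)]
            for g in result.uniqueness
        ],
    )
    if result.chimeras is not None:
        _write_tsv(
            os.path.join(out_dir, "chimeras.tsv"),
            ["upstream_barcode", "evidence", "clone_ids",
             "downstream_barcodes"],
            [
                [s.upstream_barcode, s.evidence,
                 ",".join(c.cluster_id for c in s.members),
                 ",".join(s.downstream_barcodes)]
                for s in result.chimeras
            ],
        )
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- orchestration -----------------------------------------------------------


def run_pipeline(config: RunConfig) -> RunResult:
    """Run extract -> cluster -> consensus -> QC and write all reports."""
    layout = config.layout
    if layout is None:
        if config.layout_path is None:
            raise ValueError("config needs a layout or layout_path")
        layout = load_layout_file(config.layout_path)
    if config.chimera_detection == "on" and layout.n_barcodes < 2:
        raise LayoutError(
            "chimera detection requested but the layout has a single "
            "barcode region"
        )

    if config.sam is not None:
        pre_aligned = list(iter_sam(config.sam, layout))
        params = config.extract_params()
        results = [
            process_read(rid, aln.read, aln.quals, layout, params, aln=aln)
            for rid, aln in pre_aligned
        ]
        records = [r for r in results if isinstance(r, ReadRecord)]
        dropped = [r for r in results if isinstance(r, DroppedRead)]
        n_in = len(results)
    elif config.fastq is not None:
        reads = list(iter_fastq(config.fastq))
        n_in = len(reads)
        records, dropped = extract_all(
            reads, layout, config.extract_params(), config.workers
        )
    else:
        raise ValueError("config needs a fastq or sam input")

    if not config.virtual_barcodes and layout.n_barcodes > 1:
        # collapse to the upstream barcode only
        records = [
            ReadRecord(
                read_id=r.read_id,
                barcode_seqs=r.barcode_seqs[:1],
                barcode_quals=r.barcode_quals[:1],
                variants=r.variants,
                min_bc_qual=min(r.barcode_quals[0]) if r.barcode_quals[0] else 0,
                strand=r.strand,
            )
            for r in records
        ]

    cparams = config.cluster_params()
    clusters = cluster_library(records, cparams)
    clones = call_clones(
        clusters, layout, cparams, homopolymer_min=config.homopolymer_min
    )
    effective_regions = 1 if not config.virtual_barcodes else layout.n_barcodes
    uniqueness = qc.classify_uniqueness(clones, key="virtual", set_flags=True)
    chimeras = None
    if config.chimera_detection != "off" and effective_regions > 1:
        chimeras = qc.detect_chimeras(clones, max_ed=config.max_ed)

    statuses = Counter(g.status for g in uniqueness)
    n_groups = max(1, len(uniqueness))
    summary = {
        "reads_in": n_in,
        "reads_kept": len(records),
        "dropped_by_reason": dict(
            sorted(Counter(d.reason for d in dropped).items())
        ),
        "n_clusters": len(clusters),
        "cluster_size_histogram": dict(
            sorted(Counter(c.size for c in clusters).items())
        ),
        "variant_count_histogram": dict(
            sorted(Counter(len(c.nt_variants) for c in clones).items())
        ),
        "n_barcode_groups": len(uniqueness),
        "frac_non_unique": (
            statuses["non_unique"] + statuses["non_unique_remediable"]
        ) / n_groups,
        "frac_remediable": statuses["non_unique_remediable"] / n_groups,
        "n_chimera_sets": len(chimeras) if chimeras is not None else None,
    }
    result = RunResult(
        records=records,
        dropped=dropped,
        clusters=clusters,
        clones=clones,
        uniqueness=uniqueness,
        chimeras=chimeras,
        summary=summary,
    )
    write_reports(result, config.out_dir)
    return result
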