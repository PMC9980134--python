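"""Barcode-uniqueness classification and PCR-crossover chimera detection.

A barcode carried by more than one clone is "non-unique"; pooled assay
readouts for it mix genotypes. If a single clone contributes more than two
thirds of the reads for that barcode (strictly more), the barcode is
"remediable": one genotype still dominates its readout.

With dual flanking barcodes, PCR template-switching produces molecules
that pair one clone's upstream barcode with another clone's downstream
barcode. Such crossover chimeras surface as sets of clones that share an
upstream barcode and overlap in genotype, yet carry entirely different
downstream barcodes (edit distance beyond what barcode clustering could
conflate).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .cluster import edit_distance
from .consensus import CloneCall
from .layout import LayoutError

REMEDIABLE_FRACTION = 2.0 / 3.0


@dataclass
class BarcodeGroup:
    key_barcode: str
    clones: list[CloneCall]
    status: str  # unique | non_unique_remediable | non_unique

    @property
    def read_counts(self) -> tuple[int, ...]:
        return tuple(c.n_reads for c in self.clones)


@dataclass
class ChimeraSet:
    upstream_barcode: str
    members: list[CloneCall]
    evidence: str  # complete | partial | wt_only

    @property
    def downstream_barcodes(self) -> tuple[str, ...]:
        return tuple(c.consensus_barcodes[1] for c in self.members)


def _group_status(read_counts: list[int]) -> str:
    if len(read_counts) == 1:
        return "unique"
    total = sum(read_counts)
    if max(read_counts) > REMEDIABLE_FRACTION * total:
        return "non_unique_remediable"
    return "non_unique"


def classify_uniqueness(
    clones: list[CloneCall],
    key: str = "virtual",
    merge_identical_genotypes: bool = False,
    set_flags: bool = False,
) -> list[BarcodeGroup]:
    """Group clones by barcode and classify each barcode's uniqueness.

    ``key`` selects the grouping barcode: the full virtual barcode
    (default) or the upstream barcode only — the latter emulates running
    without virtual barcodes. In that emulation, clones with identical
    genotypes would have been clustered together, so
    ``merge_identical_genotypes`` pools their read counts before
    classification. The remediable rule is strict: a clone carrying
    exactly two thirds of the reads does not qualify.
    """
    if key not in ("virtual", "upstream"):
        raise ValueError(f"unknown grouping key {key!r}")
    groups: dict[str, list[CloneCall]] = defaultdict(list)
    for clone in clones:
        bc = (
            clone.virtual_barcode
            if key == "virtual"
            else clone.consensus_barcodes[0]
        )
        groups[bc].append(clone)
    out = []
    for bc in sorted(groups):
        members = sorted(groups[bc], key=lambda c: c.cluster_id)
        if merge_identical_genotypes:
            pooled: dict[frozenset, int] = defaultdict(int)
            for c in members:
                pooled[c.genotype_key] += c.n_reads
            counts = list(pooled.values())
        else:
            counts = [c.n_reads for c in members]
        status = _group_status(counts)
        if set_flags and status != "unique":
            for c in members:
                c.flags.add("non_unique")
                if status == "non_unique_remediable":
                    c.flags.add("remediable")
        out.append(BarcodeGroup(bc, members, status))
    return out


def _genotype_overlap(a: CloneCall, b: CloneCall) -> str | None:
    """complete / partial / wt_only genotype overlap, or None."""
    ga, gb = a.genotype_key, b.genotype_key
    if not ga and not gb:
        return "wt_only"
    if ga == gb:
        return "complete"
    if ga & gb:
        return "partial"
    return None


def detect_chimeras(
    clones: list[CloneCall], max_ed: int = 2
) -> list[ChimeraSet]:
    """Find sets of clones that look like PCR crossover products.

    Within each upstream-barcode group, two clones are chimera-linked when
    their genotypes overlap (both wild-type, identical variant sets, or a
    non-empty intersection) AND their downstream barcodes are entirely
    different (edit distance > ``max_ed``, so clustering could not have
    conflated them). Maximal sets are the connected components of this
    relation. Requires a dual-barcode layout.
    """
    if any(len(c.consensus_barcodes) < 2 for c in clones):
        raise LayoutError(
            "chimera detection requires a dual-barcode layout"
        )
    by_upstream: dict[str, list[CloneCall]] = defaultdict(list)
    for clone in clones:
        by_upstream[clone.consensus_barcodes[0]].append(clone)
    sets: list[ChimeraSet] = []
    for upstream in sorted(by_upstream):
        members = sorted(by_upstream[upstream], key=lambda c: c.cluster_id)
        if len(members) < 2:
            continue
        graph = nx.Graph()
        graph.add_nodes_from(range(len(members)))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _genotype_overlap(members[i], members[j]) is None:
                    continue
                d = edit_distance(
                    members[i].consensus_barcodes[1],
                    members[j].consensus_barcodes[1],
                )
                if d > max_ed:
                    graph.add_edge(i, j)
        for comp in nx.connected_components(graph):
            if len(comp) < 2:
                continue
            group = [members[i] for i in sorted(comp)]
            genotypes = {c.genotype_key for c in group}
            if all(not g for g in genotypes):
                evidence = "wt_only"
            elif len(genotypes) == 1:
                evidence = "complete"
            else:
                evidence = "partial"
            for c in group:
                c.flags.add("chimera_suspect")
            sets.append(ChimeraSet(upstream, group, evidence))
    return sets


@dataclass
class FlagCrossTab:
    """Upstream barcodes cross-tabulated by chimera involvement and by
    non-uniqueness when virtual barcodes are disabled."""

    n_both: int
    n_chimera_only: int
    n_nonunique_only: int
    n_neither: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_chimera_only + self.n_nonunique_only + self.n_neither

    @property
    def p_chimera_given_nonunique(self) -> float:
        denom = self.n_both + self.n_nonunique_only
        return self.n_both / denom if denom else float("nan")

    @property
    def p_unique_given_no_chimera(self) -> float:
        denom = self.n_nonunique_only + self.n_neither
        return self.n_neither / denom if denom else float("nan")

    @property
    def p_nonunique_given_chimera(self) -> float:
        denom = self.n_both + self.n_chimera_only
        return self.n_both / denom if denom else float("nan")


def cross_tabulate_flags(
    clones: list[CloneCall], chimeras: list[ChimeraSet] | None = None,
    max_ed: int = 2,
) -> FlagCrossTab:
    """Relate chimera involvement to non-uniqueness without virtual
    barcodes, per upstream barcode."""
    if chimeras is None:
        chimeras = detect_chimeras(clones, max_ed)
    chimeric = {s.upstream_barcode for s in chimeras}
    nonunique = {
        g.key_barcode
        for g in classify_uniqueness(
            clones, key="upstream", merge_identical_genotypes=True
        )
        if g.status != "unique"
    }
    universe = {c.consensus_barcodes[0] for c in clones}
    both = len(chimeric & nonunique)
    return FlagCrossTab(
        n_both=both,
        n_chimera_only=len(chimeric - nonunique),
        n_nonunique_only=len(nonunique - chimeric),
        n_neither=len(universe - chimeric - nonunique),
    )
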