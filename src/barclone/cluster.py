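"""Barcode- and genotype-aware clustering of reads into clones.

Reads sharing an identical (virtual) barcode are first grouped into "seed
clusters": a graph is built over the reads of each identical-barcode set,
with an edge between two reads when both look wild-type after error
filtering or when their filtered variant sets are sufficiently similar
(Jaccard index); each connected component, including singletons, becomes a
seed cluster. Clusters are then iteratively merged across similar barcodes,
in ascending order of barcode edit distance (ED) up to ``max_ed``. A merge
of two clusters at distance ``ed`` is accepted only if

a) both clusters are wild-type, or their error-filtered variant sets have
   a Jaccard index at or above the threshold (genotype coherence);
b) no pair of reads in the proposed cluster has barcode ED > ``max_ed``;
c) the cluster sizes are sufficiently divergent: ``|log2(n1/n2)| > ed`` —
   a satellite of barcode-miscalled reads is expected to be much smaller
   than the true clone it derives from.

The error filter drops a candidate variant only when it is supported by a
single read AND that support is below the quality threshold; recurrence or
high quality alone retains it.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import networkx as nx

from .extract import CandidateVariant, ReadRecord

VariantKey = tuple[int, str, str]


@dataclass(frozen=True)
class ClusterParams:
    max_ed: int = 2
    jaccard_min: float = 0.2
    var_qual_min: int = 50


@dataclass
class Cluster:
    """A set of reads presumed to derive from one clone."""

    members: tuple[ReadRecord, ...]
    filtered_variants: frozenset[CandidateVariant]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_wt(self) -> bool:
        return not self.filtered_variants

    @property
    def barcode_counts(self) -> Counter:
        return Counter(r.virtual_barcode for r in self.members)

    @property
    def barcodes(self) -> set[str]:
        return {r.virtual_barcode for r in self.members}

    def plurality_barcode(self) -> str:
        """Most frequent member virtual barcode; ties lexicographic."""
        counts = self.barcode_counts
        best = max(counts.values())
        return min(b for b, c in counts.items() if c == best)

    def read_ids(self) -> tuple[str, ...]:
        return tuple(sorted(r.read_id for r in self.members))


@dataclass(frozen=True)
class MergeDecision:
    accept: bool
    reason: str | None = None  # genotype | barcode_ed | size_divergence
    merged: "Cluster | None" = None


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions/indels)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def filter_errors(
    members: Iterable[ReadRecord], var_qual_min: int = 50
) -> frozenset[CandidateVariant]:
    """Error-filtered union of candidate variants over a read set.

    A variant is dropped only when it is seen in exactly one read AND its
    quality is below ``var_qual_min``; the retained variant carries the
    maximum quality over its supporting reads.
    """
    support: dict[VariantKey, int] = Counter()
    best_qual: dict[VariantKey, int] = {}
    for rec in members:
        for v in rec.variants:
            support[v.key] += 1
            if v.qual > best_qual.get(v.key, -1):
                best_qual[v.key] = v.qual
    kept = [
        CandidateVariant(pos, ref, alt, best_qual[(pos, ref, alt)])
        for (pos, ref, alt), n in support.items()
        if n >= 2 or best_qual[(pos, ref, alt)] >= var_qual_min
    ]
    return frozenset(kept)


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a ∩ b| / |a ∪ b| on variant identity; 1.0 when both sets empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def size_divergence_ok(size1: int, size2: int, ed: int) -> bool:
    """Criterion (c): sizes divergent enough, ``|log2(n1/n2)| > ed``."""
    return abs(math.log2(size1 / size2)) > ed


# ---------------------------------------------------------------------------
# seed clustering
# ---------------------------------------------------------------------------


def seed_clusters(
    same_barcode_reads: Sequence[ReadRecord],
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """Connected components of the genotype-coherence graph of one
    identical-barcode read set."""
    reads = sorted(same_barcode_reads, key=lambda r: r.read_id)
    retained = filter_errors(reads, params.var_qual_min)
    retained_keys = {v.key for v in retained}
    eff = [frozenset(v.key for v in r.variants if v.key in retained_keys)
           for r in reads]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(reads)))
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            if (not eff[i] and not eff[j]) or jaccard(
                eff[i], eff[j]
            ) >= params.jaccard_min:
                graph.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(graph):
        members = tuple(reads[i] for i in sorted(comp))
        clusters.append(
            Cluster(members, filter_errors(members, params.var_qual_min))
        )
    clusters.sort(key=lambda c: (-c.size, c.plurality_barcode(), c.read_ids()))
    return clusters


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _cluster_variant_sets(
    c1: Cluster, c2: Cluster, var_qual_min: int
) -> tuple[set[VariantKey], set[VariantKey], frozenset[CandidateVariant]]:
    """Re-filter errors on the union and split the retained set back out
    by which cluster's reads carry each variant."""
    union = c1.members + c2.members
    retained = filter_errors(union, var_qual_min)
    retained_keys = {v.key for v in retained}
    seen1 = {v.key for r in c1.members for v in r.variants}
    seen2 = {v.key for r in c2.members for v in r.variants}
    return seen1 & retained_keys, seen2 & retained_keys, retained


def max_cross_barcode_ed(c1: Cluster, c2: Cluster) -> int:
    return max(
        edit_distance(b1, b2) for b1 in c1.barcodes for b2 in c2.barcodes
    )


def min_cross_barcode_ed(c1: Cluster, c2: Cluster) -> int:
    return min(
        edit_distance(b1, b2) for b1 in c1.barcodes for b2 in c2.barcodes
    )


def evaluate_merge(
    c1: Cluster,
    c2: Cluster,
    ed: int,
    params: ClusterParams = ClusterParams(),
) -> MergeDecision:
    """Apply merge criteria (genotype coherence, barcode ED bound, size
    divergence) to a candidate pair at minimum barcode distance ``ed``.

    Rejection reports the first failed criterion. On acceptance the merged
    cluster carries freshly re-filtered variants.
    """
    set1, set2, retained = _cluster_variant_sets(c1, c2, params.var_qual_min)
    both_wt = not set1 and not set2
    if not both_wt and jaccard(set1, set2) < params.jaccard_min:
        return MergeDecision(False, "genotype")
    # both clusters individually respect the ED bound, so only cross-pairs
    # can violate it
    if max_cross_barcode_ed(c1, c2) > params.max_ed:
        return MergeDecision(False, "barcode_ed")
    if not size_divergence_ok(c1.size, c2.size, ed):
        return MergeDecision(False, "size_divergence")
    members = tuple(
        sorted(c1.members + c2.members, key=lambda r: r.read_id)
    )
    return MergeDecision(True, None, Cluster(members, retained))


# ---------------------------------------------------------------------------
# candidate-pair discovery via deletion neighborhoods
# ---------------------------------------------------------------------------


def _deletion_signatures(s: str, k: int) -> set[int]:
    """Hashes of all strings obtainable from *s* by at most *k* deletions.

    Two strings within Levenshtein distance *k* always share a common
    subsequence reachable by <= *k* deletions from each, so shared
    signatures are a complete candidate filter; hits are verified with an
    exact distance computation afterwards.
    """
    level = {s}
    sigs = {hash(s)}
    for _ in range(k):
        nxt = set()
        for t in level:
            for i in range(len(t)):
                nxt.add(t[:i] + t[i + 1 :])
        sigs.update(hash(t) for t in nxt)
        level = nxt
    return sigs


def barcode_pair_distances(
    barcodes: Sequence[str], max_ed: int
) -> dict[tuple[str, str], int]:
    """Exact EDs for all barcode pairs within ``max_ed``, found via a
    deletion-neighborhood index rather than all-pairs comparison."""
    index: dict[int, list[int]] = defaultdict(list)
    candidates: set[tuple[int, int]] = set()
    for i, bc in enumerate(barcodes):
        for sig in _deletion_signatures(bc, max_ed):
            for j in index[sig]:
                if barcodes[j] != bc:
                    candidates.add((min(i, j), max(i, j)))
            index[sig].append(i)
    out: dict[tuple[str, str], int] = {}
    for i, j in candidates:
        a, b = barcodes[i], barcodes[j]
        d = edlib.align(a, b, mode="NW", task="distance", k=max_ed)[
            "editDistance"
        ]
        if d != -1 and d <= max_ed:
            out[(min(a, b), max(a, b))] = d
    return out


def _pair_min_ed(
    c1: Cluster, c2: Cluster, pair_ed: dict[tuple[str, str], int], max_ed: int
) -> int | None:
    """Minimum member-barcode ED between two clusters, or None if > max_ed."""
    best: int | None = None
    for b1 in c1.barcodes:
        for b2 in c2.barcodes:
            if b1 == b2:
                return 0
            d = pair_ed.get((min(b1, b2), max(b1, b2)))
            if d is not None and (best is None or d < best):
                best = d
    return best


def _merge_pass(
    clusters: list[Cluster],
    ed_level: int,
    pair_ed: dict[tuple[str, str], int],
    params: ClusterParams,
    audit: list | None,
) -> tuple[list[Cluster], bool]:
    """One scheduling pass at a fixed ED level: consider candidate pairs in
    deterministic order (largest combined size first), accept the first
    merge, and report whether anything changed."""
    def order_key(c: Cluster):
        return (c.plurality_barcode(), c.read_ids())

    candidates = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            d = _pair_min_ed(clusters[i], clusters[j], pair_ed, params.max_ed)
            if d == ed_level:
                # canonical orientation so scheduling does not depend on
                # list positions
                if order_key(clusters[j]) < order_key(clusters[i]):
                    candidates.append((j, i))
                else:
                    candidates.append((i, j))
    candidates.sort(
        key=lambda ij: (
            -(clusters[ij[0]].size + clusters[ij[1]].size),
            order_key(clusters[ij[0]]),
            order_key(clusters[ij[1]]),
        )
    )
    for i, j in candidates:
        decision = evaluate_merge(clusters[i], clusters[j], ed_level, params)
        if audit is not None:
            audit.append(
                (
                    ed_level,
                    clusters[i].plurality_barcode(),
                    clusters[j].plurality_barcode(),
                    "accept" if decision.accept else f"reject:{decision.reason}",
                )
            )
        if decision.accept:
            merged = decision.merged
            remaining = [
                c for k, c in enumerate(clusters) if k not in (i, j)
            ]
            remaining.append(merged)
            return remaining, True
    return clusters, False


def cluster_library(
    records: Iterable[ReadRecord],
    params: ClusterParams = ClusterParams(),
    audit: list | None = None,
) -> list[Cluster]:
    """Full clustering: seed clusters per identical virtual barcode, then
    iterative merging at ascending barcode edit distance.

    Each ED level is iterated to a fixpoint before advancing; accepted
    merges replace the pair by its union with re-filtered variants. The
    procedure is deterministic for a given input set.
    """
    groups: dict[str, list[ReadRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.virtual_barcode].append(rec)
    clusters: list[Cluster] = []
    for barcode in sorted(groups):
        clusters.extend(seed_clusters(groups[barcode], params))
    if params.max_ed > 0:
        pair_ed = barcode_pair_distances(sorted(groups), params.max_ed)
        for ed_level in range(1, params.max_ed + 1):
            changed = True
            while changed:
                clusters, changed = _merge_pass(
                    clusters, ed_level, pair_ed, params, audit
                )
    clusters.sort(key=lambda c: (-c.size, c.plurality_barcode(), c.read_ids()))
    return clusters


# ---------------------------------------------------------------------------
# reference implementation (validation oracle)
# ---------------------------------------------------------------------------


def _levenshtein(a: str, b: str) -> int:
    """Plain DP Levenshtein, independent of the aligned-library fast path."""
    if a == b:
        return 0
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def brute_force_cluster(
    records: Iterable[ReadRecord],
    params: ClusterParams = ClusterParams(),
) -> list[frozenset[str]]:
    """Exhaustive re-implementation of the clustering procedure.

    Recomputes every pairwise member edit distance with a plain DP and
    re-evaluates all cluster pairs to fixpoint at each ED level, without
    the deletion-neighborhood index or any cached state. Intended as an
    independent check of :func:`cluster_library` on small inputs; returns
    the partition as frozensets of read ids.
    """
    records = sorted(records, key=lambda r: r.read_id)

    def filt(members):
        support, best = Counter(), {}
        for r in members:
            for v in r.variants:
                support[v.key] += 1
                best[v.key] = max(best.get(v.key, -1), v.qual)
        return {
            k for k, n in support.items()
            if n >= 2 or best[k] >= params.var_qual_min
        }

    def jac(a, b):
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)

    # seed clusters per identical barcode, via union-find
    parent = list(range(len(records)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    by_bc: dict[str, list[int]] = defaultdict(list)
    for idx, r in enumerate(records):
        by_bc[r.virtual_barcode].append(idx)
    for idxs in by_bc.values():
        kept = filt([records[i] for i in idxs])
        eff = {
            i: frozenset(v.key for v in records[i].variants if v.key in kept)
            for i in idxs
        }
        for ai, i in enumerate(idxs):
            for j in idxs[ai + 1 :]:
                if (not eff[i] and not eff[j]) or jac(eff[i], eff[j]) >= params.jaccard_min:
                    union(i, j)
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(len(records)):
        comps[find(i)].append(i)
    clusters = [sorted(c) for c in comps.values()]

    def plurality(c):
        counts = Counter(records[i].virtual_barcode for i in c)
        best = max(counts.values())
        return min(b for b, n in counts.items() if n == best)

    def ids(c):
        return tuple(sorted(records[i].read_id for i in c))

    for ed_level in range(1, params.max_ed + 1):
        while True:
            def okey(c):
                return (plurality(c), ids(c))

            cand = []
            for x in range(len(clusters)):
                for y in range(x + 1, len(clusters)):
                    d = min(
                        _levenshtein(
                            records[i].virtual_barcode,
                            records[j].virtual_barcode,
                        )
                        for i in clusters[x]
                        for j in clusters[y]
                    )
                    if d == ed_level:
                        cand.append(
                            (y, x) if okey(clusters[y]) < okey(clusters[x]) else (x, y)
                        )
            cand.sort(
                key=lambda xy: (
                    -(len(clusters[xy[0]]) + len(clusters[xy[1]])),
                    okey(clusters[xy[0]]),
                    okey(clusters[xy[1]]),
                )
            )
            merged_any = False
            for x, y in cand:
                u = clusters[x] + clusters[y]
                kept = filt([records[i] for i in u])
                s1 = {
                    v.key for i in clusters[x] for v in records[i].variants
                } & kept
                s2 = {
                    v.key for i in clusters[y] for v in records[i].variants
                } & kept
                ok_a = (not s1 and not s2) or jac(s1, s2) >= params.jaccard_min
                ok_b = (
                    max(
                        _levenshtein(
                            records[i].virtual_barcode,
                            records[j].virtual_barcode,
                        )
                        for i in u
                        for j in u
                    )
                    <= params.max_ed
                )
                ok_c = (
                    abs(math.log2(len(clusters[x]) / len(clusters[y])))
                    > ed_level
                )
                if ok_a and ok_b and ok_c:
                    clusters = [
                        c for k, c in enumerate(clusters) if k not in (x, y)
                    ]
                    clusters.append(sorted(u))
                    merged_any = True
                    break
            if not merged_any:
                break
    return [
        frozenset(records[i].read_id for i in c) for c in clusters
    ]
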