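"""Truth-based evaluation of pipeline output on simulated libraries.

Used by the test suite and the acceptance script to score clone recovery
(adjusted Rand index of the read partition, exact-genotype rate) and
chimera detection (recall over informative chimeras, false-flag rate)
against the simulator's ground truth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .pipeline import RunResult
from .simulate import SimulatedLibrary, Template


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of one item set."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        return 1.0
    contingency: Counter = Counter(zip(labels_a, labels_b))
    a_sizes: Counter = Counter(labels_a)
    b_sizes: Counter = Counter(labels_b)

    def comb2(x):
        return x * (x - 1) / 2.0

    index = sum(comb2(c) for c in contingency.values())
    sum_a = sum(comb2(c) for c in a_sizes.values())
    sum_b = sum(comb2(c) for c in b_sizes.values())
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


@dataclass
class RecoveryScore:
    ari: float
    n_reads_scored: int
    exact_genotypes: int
    n_templates_recoverable: int

    @property
    def exact_fraction(self) -> float:
        if self.n_templates_recoverable == 0:
            return float("nan")
        return self.exact_genotypes / self.n_templates_recoverable


def _majority_template(cluster_read_ids, truth) -> str:
    counts = Counter(truth.reads[rid].template_id for rid in cluster_read_ids)
    return counts.most_common(1)[0][0]


def score_recovery(lib: SimulatedLibrary, result: RunResult) -> RecoveryScore:
    """Adjusted Rand index of read-to-clone assignment plus the fraction of
    templates whose dominant cluster calls the true genotype exactly."""
    truth = lib.truth
    read_cluster: dict[str, int] = {}
    for ci, cluster in enumerate(result.clusters):
        for rid in cluster.read_ids():
            read_cluster[rid] = ci
    scored = sorted(read_cluster)
    ari = adjusted_rand_index(
        [truth.reads[rid].template_id for rid in scored],
        [read_cluster[rid] for rid in scored],
    )
    kept_templates = {truth.reads[rid].template_id for rid in scored}
    tmap = {t.template_id: t for t in truth.templates}
    best: dict[str, tuple[int, frozenset]] = {}
    for cluster, call in zip(result.clusters, result.clones):
        tid = _majority_template(call.read_ids, truth)
        if tid not in best or cluster.size > best[tid][0]:
            best[tid] = (cluster.size, call.genotype_key)
    exact = sum(
        1
        for tid in kept_templates
        if tid in best and best[tid][1] == tmap[tid].genotype_key
    )
    return RecoveryScore(
        ari=ari,
        n_reads_scored=len(scored),
        exact_genotypes=exact,
        n_templates_recoverable=len(kept_templates),
    )


@dataclass
class ChimeraScore:
    n_chimeric_templates: int
    n_informative: int
    n_informative_detected: int
    n_detected_total: int
    n_false_flag_barcodes: int
    n_clean_barcodes: int

    @property
    def recall_informative(self) -> float:
        if self.n_informative == 0:
            return float("nan")
        return self.n_informative_detected / self.n_informative

    @property
    def detected_fraction_overall(self) -> float:
        if self.n_chimeric_templates == 0:
            return float("nan")
        return self.n_detected_total / self.n_chimeric_templates

    @property
    def false_flag_rate(self) -> float:
        if self.n_clean_barcodes == 0:
            return 0.0
        return self.n_false_flag_barcodes / self.n_clean_barcodes


def informative_chimera(template: Template, truth) -> bool:
    """Whether a crossover left recoverable genotype evidence: the chimera
    shares at least one true variant with its upstream donor. Crossovers
    upstream of every donor variant are indistinguishable from an unrelated
    clone (wild-type/wild-type coincidences are uninformative)."""
    tmap = {t.template_id: t for t in truth.templates}
    donor_a = tmap[template.donors[0]]
    return bool(template.genotype_key & donor_a.genotype_key)


def score_chimeras(lib: SimulatedLibrary, result: RunResult) -> ChimeraScore:
    """Template-level chimera detection score: a planted crossover counts
    as detected when any cluster dominated by its reads is flagged."""
    truth = lib.truth
    tmap = {t.template_id: t for t in truth.templates}
    detected_templates: set[str] = set()
    present_templates: set[str] = set()
    for call in result.clones:
        tid = _majority_template(call.read_ids, truth)
        if tmap[tid].kind != "chimera":
            continue
        present_templates.add(tid)
        if "chimera_suspect" in call.flags:
            detected_templates.add(tid)
    informative = {
        tid for tid in present_templates
        if informative_chimera(tmap[tid], truth)
    }
    detected_inf = informative & detected_templates
    detected_all = detected_templates
    involved_upstreams = {
        t.barcodes[0] for t in truth.templates if t.kind == "chimera"
    }
    flagged_upstreams = (
        {s.upstream_barcode for s in result.chimeras}
        if result.chimeras is not None
        else set()
    )
    universe = {call.consensus_barcodes[0] for call in result.clones}
    clean = universe - involved_upstreams
    false_flags = flagged_upstreams - involved_upstreams
    return ChimeraScore(
        n_chimeric_templates=len(present_templates),
        n_informative=len(informative),
        n_informative_detected=len(detected_inf),
        n_detected_total=len(detected_all),
        n_false_flag_barcodes=len(false_flags),
        n_clean_barcodes=len(clean),
    )


def nonunique_upstream_barcodes(result: RunResult) -> set[str]:
    """Upstream barcodes that surface as non-unique when virtual barcodes
    are disabled (clusters with identical genotypes pooled first)."""
    from .qc import classify_uniqueness

    return {
        g.key_barcode
        for g in classify_uniqueness(
            result.clones, key="upstream", merge_identical_genotypes=True
        )
        if g.status != "unique"
    }
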