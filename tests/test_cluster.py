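import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barclone.cluster import (
    Cluster,
    ClusterParams,
    brute_force_cluster,
    _levenshtein,
    cluster_library,
    edit_distance,
    evaluate_merge,
    filter_errors,
    jaccard,
    seed_clusters,
    size_divergence_ok,
)
from barclone.simulate import random_micro_library

from conftest import mk_read, var


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,d",
    [
        ("ACGT", "ACGT", 0),
        ("ACGT", "AGT", 1),
        ("AAAA", "TTTT", 4),
        ("", "ACG", 3),
        ("ACGTACGT", "ACGGACGT", 1),
    ],
)
def test_edit_distance_examples(a, b, d):
    assert edit_distance(a, b) == d


@given(st.text(alphabet="ACGT", max_size=25), st.text(alphabet="ACGT", max_size=25))
def test_edit_distance_matches_dp_oracle(a, b):
    assert edit_distance(a, b) == _levenshtein(a, b)


@pytest.mark.parametrize(
    "support,qual,kept",
    [
        (2, 20, True),   # recurrent, low quality -> kept
        (1, 20, False),  # single read, low quality -> dropped
        (1, 60, True),   # single read, high quality -> kept
        (3, 20, True),
    ],
)
def test_error_filter_conjunction(support, qual, kept):
    v = var(150, "A", "T", qual)
    reads = [mk_read(f"r{i}", variants=[v]) for i in range(support)]
    reads += [mk_read(f"w{i}") for i in range(3)]
    result = filter_errors(reads, var_qual_min=50)
    assert (v in result) is kept


def test_error_filter_reports_max_quality():
    reads = [
        mk_read("r1", variants=[var(150, "A", "T", 31)]),
        mk_read("r2", variants=[var(150, "A", "T", 88)]),
    ]
    (kept,) = filter_errors(reads, var_qual_min=50)
    assert kept.qual == 88


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({1, 2}, {1, 2}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1}, {1, 2, 3, 4}, 0.25),
        (set(), set(), 1.0),
        (set(), {1}, 0.0),
    ],
)
def test_jaccard_examples(a, b, expected):
    assert jaccard(a, b) == expected


@pytest.mark.parametrize(
    "s1,s2,ed,ok",
    [
        (8, 1, 2, True),   # |log2 8| = 3 > 2
        (4, 4, 1, False),  # equal sizes never divergent
        (5, 1, 2, True),   # log2 5 ~ 2.32 > 2
        (4, 1, 2, False),  # exactly 2 is not > 2
        (1, 8, 2, True),   # symmetric
    ],
)
def test_size_divergence_rule(s1, s2, ed, ok):
    assert size_divergence_ok(s1, s2, ed) is ok


# ---------------------------------------------------------------------------
# seed clusters
# ---------------------------------------------------------------------------


def test_three_wt_reads_form_one_cluster():
    reads = [mk_read(f"r{i}") for i in range(3)]
    (cluster,) = seed_clusters(reads)
    assert cluster.size == 3 and cluster.is_wt


def test_disjoint_genotypes_split_within_identical_barcode():
    x, y = var(100, "A", "T", 90), var(200, "C", "G", 90)
    reads = [
        mk_read("r1", variants=[x]),
        mk_read("r2", variants=[x]),
        mk_read("r3", variants=[y]),
    ]
    clusters = seed_clusters(reads)
    assert sorted(c.size for c in clusters) == [1, 2]


def test_singleton_read_is_a_cluster():
    (cluster,) = seed_clusters([mk_read("r1", variants=[var(100)])])
    assert cluster.size == 1


def test_seed_cluster_filters_private_low_quality_noise():
    # one read has an extra low-quality variant; after filtering both reads
    # are WT and connect
    noise = var(300, "G", "A", 20)
    reads = [mk_read("r1", variants=[noise]), mk_read("r2")]
    (cluster,) = seed_clusters(reads)
    assert cluster.size == 2 and cluster.is_wt


# ---------------------------------------------------------------------------
# merge criteria truth table
# ---------------------------------------------------------------------------


def _cluster(reads, params=ClusterParams()):
    return Cluster(tuple(reads), filter_errors(reads, params.var_qual_min))


def test_merge_accepts_wt_satellite():
    big = _cluster([mk_read(f"b{i}", barcode="ACGTACGTAC") for i in range(8)])
    sat = _cluster([mk_read("s1", barcode="ACGTACGTAT")])
    decision = evaluate_merge(big, sat, ed=2)
    assert decision.accept and decision.merged.size == 9


def test_merge_rejects_low_jaccard_genotypes():
    x, y = var(100, "A", "T", 90), var(200, "C", "G", 90)
    c1 = _cluster([mk_read(f"a{i}", barcode="ACGTACGTAC", variants=[x]) for i in range(8)])
    c2 = _cluster([mk_read("b1", barcode="ACGTACGTAT", variants=[y])])
    decision = evaluate_merge(c1, c2, ed=1)
    assert not decision.accept and decision.reason == "genotype"


def test_merge_rejects_equal_sizes():
    c1 = _cluster([mk_read(f"a{i}", barcode="ACGTACGTAC") for i in range(4)])
    c2 = _cluster([mk_read(f"b{i}", barcode="ACGTACGTAT") for i in range(4)])
    decision = evaluate_merge(c1, c2, ed=1)
    assert not decision.accept and decision.reason == "size_divergence"


def test_merge_rejects_barcode_ed_violation():
    # c2's barcode is 2 edits from c1's primary barcode but c1 already
    # contains a member 1 edit the other way: the union would span ED 3
    c1 = _cluster(
        [mk_read(f"a{i}", barcode="AAAAAAAAAA") for i in range(8)]
        + [mk_read("a8", barcode="TAAAAAAAAA")]
    )
    c2 = _cluster([mk_read("b1", barcode="AAAAAAAATT")])
    decision = evaluate_merge(c1, c2, ed=2, params=ClusterParams(max_ed=2))
    assert not decision.accept and decision.reason == "barcode_ed"


def test_merge_refilters_union_variants():
    # the satellite's private low-quality variant gains support from the
    # big cluster: the union filter retains it and both sides stay coherent
    x = var(100, "A", "T", 20)
    c1 = _cluster([mk_read(f"a{i}", barcode="ACGTACGTAC", variants=[x]) for i in range(6)])
    sat = _cluster([mk_read("s1", barcode="ACGTACGTAT", variants=[x])])
    assert sat.is_wt  # private low-qual variant filtered within the singleton
    decision = evaluate_merge(c1, sat, ed=1)
    assert decision.accept
    assert {v.key for v in decision.merged.filtered_variants} == {x.key}


# ---------------------------------------------------------------------------
# full clustering
# ---------------------------------------------------------------------------


def test_identical_reads_single_cluster():
    reads = [mk_read(f"r{i}", variants=[var(100)]) for i in range(10)]
    (cluster,) = cluster_library(reads)
    assert cluster.size == 10


def test_satellite_merges_into_big_clone():
    reads = [mk_read(f"b{i}", barcode="ACGTACGTAC") for i in range(10)]
    reads.append(mk_read("sat", barcode="ACGTACGTAT"))
    (cluster,) = cluster_library(reads)
    assert cluster.size == 11


def test_equal_clones_at_ed1_stay_separate():
    x, y = var(100, "A", "T", 90), var(200, "C", "G", 90)
    reads = [mk_read(f"a{i}", barcode="ACGTACGTAC", variants=[x]) for i in range(6)]
    reads += [mk_read(f"b{i}", barcode="ACGTACGTAT", variants=[y]) for i in range(6)]
    clusters = cluster_library(reads)
    assert sorted(c.size for c in clusters) == [6, 6]


def test_max_ed_zero_reproduces_seed_clustering():
    rng = np.random.default_rng(11)
    records = random_micro_library(rng)
    zero = cluster_library(records, ClusterParams(max_ed=0))
    by_bc = {}
    for r in records:
        by_bc.setdefault(r.virtual_barcode, []).append(r)
    expected = []
    for bc in sorted(by_bc):
        expected.extend(seed_clusters(by_bc[bc]))
    assert {frozenset(c.read_ids()) for c in zero} == {
        frozenset(c.read_ids()) for c in expected
    }


def test_clustering_is_a_partition():
    rng = np.random.default_rng(5)
    records = random_micro_library(rng)
    clusters = cluster_library(records)
    seen = [rid for c in clusters for rid in c.read_ids()]
    assert sorted(seen) == sorted(r.read_id for r in records)


def test_final_clusters_respect_pairwise_ed_bound():
    params = ClusterParams(max_ed=2)
    for seed in range(10):
        rng = np.random.default_rng(seed)
        records = random_micro_library(rng)
        for c in cluster_library(records, params):
            barcodes = [r.virtual_barcode for r in c.members]
            assert all(
                edit_distance(a, b) <= params.max_ed
                for i, a in enumerate(barcodes)
                for b in barcodes[i + 1 :]
            )


@pytest.mark.parametrize("seed", range(40))
def test_matches_brute_force_reference(seed):
    rng = np.random.default_rng(seed)
    records = random_micro_library(rng)
    fast = {frozenset(c.read_ids()) for c in cluster_library(records)}
    assert fast == set(brute_force_cluster(records))


def test_recovery_on_simulated_micro_clones():
    # clones with >=5 reads and ~2% per-read barcode miscalls are recovered
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(123)
    truth_labels, records = [], []
    serial = 0
    for clone in range(30):
        bc = "".join(rng.choice(list("ACGT"), size=20))
        genotype = [var(int(p), "A", "T", 90) for p in rng.choice(800, size=2)]
        for _ in range(int(rng.integers(5, 12))):
            serial += 1
            read_bc = bc
            if rng.random() < 0.02:
                p = int(rng.integers(0, len(bc)))
                read_bc = bc[:p] + "ACGT"[int(rng.integers(0, 4))] + bc[p + 1 :]
            records.append(mk_read(f"r{serial:04d}", barcode=read_bc, variants=genotype))
            truth_labels.append(clone)
    clusters = cluster_library(records)
    assignment = {rid: ci for ci, c in enumerate(clusters) for rid in c.read_ids()}
    predicted = [assignment[r.read_id] for r in records]
    assert adjusted_rand_score(truth_labels, predicted) >= 0.95
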