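"""Distance definition, greedy clustering vs the all-pairs oracle, and the
small analytic utilities."""

import itertools

import numpy as np
import pytest

import hidiv as hd
from hidiv.cluster import distance_if_within
from hidiv.synth import random_sequence


def nw_edit_distance(a: str, b: str) -> int:
    """Independent full dynamic-programming unit-cost alignment (classic
    Needleman-Wunsch / Levenshtein recurrence) used as the oracle for the
    production distance routine."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", 0.0),
        ("AAAA", "AATA", 0.25),  # 1 mismatch / 4 columns
        ("AAAA", "AAAAA", 0.2),  # 1 indel / 5 columns
    ],
)
def test_distance_examples(a, b, expected):
    assert hd.pairwise_distance(a, b) == pytest.approx(expected)


def test_distance_agrees_with_full_dp_on_random_pairs():
    """Dual-route check: the distance numerator equals the independent DP
    edit distance, the denominator is a plausible alignment length, and the
    measure is symmetric with identity of indiscernibles."""
    rng = np.random.default_rng(21)
    for _ in range(25):
        la, lb = rng.integers(20, 200, size=2)
        a, b = random_sequence(int(la), rng), random_sequence(int(lb), rng)
        edits = nw_edit_distance(a, b)
        d_ab = hd.pairwise_distance(a, b)
        d_ba = hd.pairwise_distance(b, a)
        assert d_ab == pytest.approx(d_ba)
        # d = edits / L for some alignment length L in [max(la,lb), la+lb]
        assert edits / (len(a) + len(b)) <= d_ab <= edits / max(len(a), len(b))
        assert (d_ab == 0.0) == (a == b)


def test_banded_distance_matches_full_within_threshold():
    rng = np.random.default_rng(22)
    seq = random_sequence(300, rng)
    near = hd.mutate_to_distance(seq, 0.02, hd.MutationSpec(), rng)
    assert distance_if_within(seq, near, 0.03) == pytest.approx(hd.pairwise_distance(seq, near))
    far = random_sequence(300, rng)
    assert distance_if_within(seq, far, 0.03) is None


def test_kmer_filter_keeps_identical_and_handles_empty():
    assert 0 in hd.kmer_candidate_filter("ACGTACGTACGT", ["ACGTACGTACGT"])
    assert hd.kmer_candidate_filter("ACGTACGTACGT", []) == []
    with pytest.raises(ValueError):
        hd.kmer_candidate_filter("ACGT", [], k=2)


def test_kmer_filter_never_excludes_true_seed(community_25):
    """Superset guarantee at defaults: for every planted read, its own seed
    survives the prefilter."""
    seeds = [s.sequence for s in community_25.seeds]
    index = {s.id: i for i, s in enumerate(community_25.seeds)}
    for rec in community_25.reads:
        candidates = hd.kmer_candidate_filter(rec.sequence, seeds)
        assert index[rec.annotations["otu"]] in candidates


def test_greedy_empty_and_identical_inputs():
    assert hd.greedy_cluster([], 0.03).n_clusters == 0
    reads = [hd.SequenceRecord(f"r{i}", "ACGTACGTACGT" * 5) for i in range(7)]
    cm = hd.greedy_cluster(reads, 0.03)
    assert cm.n_clusters == 1
    assert cm.abundance_vector() == [7]


def _partition(cm: hd.ClusterMap) -> set[frozenset]:
    clusters: dict[int, set] = {}
    for rid, cid in cm.assignments.items():
        clusters.setdefault(cid, set()).add(rid)
    return {frozenset(v) for v in clusters.values()}


def test_greedy_matches_oracle_on_planted_community(community_25):
    """On well-separated planted data greedy first-fit clustering and the
    all-pairs single-linkage oracle give the same partition, equal to the
    planted truth."""
    greedy = hd.greedy_cluster(community_25.reads, 0.03)
    brute = hd.brute_force_cluster(community_25.reads, 0.03)
    assert greedy.n_clusters == brute.n_clusters == community_25.n_otus
    assert _partition(greedy) == _partition(brute)
    # and the partition is exactly the planted one
    planted = {}
    for rec in community_25.reads:
        planted.setdefault(rec.annotations["otu"], set()).add(rec.id)
    assert _partition(greedy) == {frozenset(v) for v in planted.values()}


def test_greedy_centroid_and_membership_guarantees(community_25):
    """Post-hoc audit: all centroids pairwise > d, every read within d of
    its centroid."""
    cm = hd.greedy_cluster(community_25.reads, 0.03)
    seq_by_id = {r.id: r.sequence for r in community_25.reads}
    cent = [seq_by_id[cm.centroids[cid]] for cid in sorted(cm.centroids)]
    for x, y in itertools.combinations(cent, 2):
        assert hd.pairwise_distance(x, y) > 0.03
    for rid, cid in cm.assignments.items():
        assert hd.pairwise_distance(seq_by_id[rid], seq_by_id[cm.centroids[cid]]) <= 0.03


def test_greedy_order_variants_agree_on_separated_data(community_25):
    for order in ("abundance", "length", "input"):
        cm = hd.greedy_cluster(community_25.reads, 0.03, order=order)
        assert cm.n_clusters == community_25.n_otus
    best = hd.greedy_cluster(community_25.reads, 0.03, best_fit=True)
    assert best.n_clusters == community_25.n_otus


def test_brute_force_two_read_cases():
    rng = np.random.default_rng(23)
    seq = random_sequence(200, rng)
    near = hd.mutate_to_distance(seq, 0.01, hd.MutationSpec(), rng)
    reads = [hd.SequenceRecord("a", seq), hd.SequenceRecord("b", near)]
    assert hd.brute_force_cluster(reads, 0.03).n_clusters == 1
    far = hd.mutate_to_distance(seq, 0.10, hd.MutationSpec(), rng, tol=0.01)
    reads = [hd.SequenceRecord("a", seq), hd.SequenceRecord("b", far)]
    assert hd.brute_force_cluster(reads, 0.03).n_clusters == 2


def test_brute_force_single_linkage_chains():
    """a-b and b-c within d but a-c beyond d still form one component."""
    rng = np.random.default_rng(24)
    b = random_sequence(100, rng)
    # substitutions at disjoint positions: d(a,b)=d(b,c)=0.02, d(a,c)=0.04
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    a = flip[b[0]] + b[1] + flip[b[2]] + b[3:]
    c = b[:4] + flip[b[4]] + b[5] + flip[b[6]] + b[7:]
    assert hd.pairwise_distance(a, b) == pytest.approx(0.02)
    assert hd.pairwise_distance(b, c) == pytest.approx(0.02)
    assert hd.pairwise_distance(a, c) == pytest.approx(0.04)
    reads = [hd.SequenceRecord(x, s) for x, s in [("a", a), ("b", b), ("c", c)]]
    assert hd.brute_force_cluster(reads, 0.03).n_clusters == 1


def test_pairwise_comparison_count_matches_enumeration():
    for n in (0, 1, 2, 20, 100):
        assert hd.pairwise_comparison_count(n) == len(
            list(itertools.combinations(range(n), 2))
        )
    with pytest.raises(ValueError):
        hd.pairwise_comparison_count(-1)


@pytest.mark.parametrize("length,d,expected", [(200, 0.03, 6), (300, 0.03, 9), (100, 0.0, 0)])
def test_max_tolerated_errors(length, d, expected):
    assert hd.max_tolerated_errors(length, d) == expected


def test_singleton_ids():
    rng = np.random.default_rng(25)
    identical = [hd.SequenceRecord(f"r{i}", "ACGT" * 30) for i in range(4)]
    assert hd.singleton_ids(hd.greedy_cluster(identical, 0.03)) == set()
    distant = [hd.SequenceRecord(f"d{i}", random_sequence(120, rng)) for i in range(6)]
    assert hd.singleton_ids(hd.greedy_cluster(distant, 0.03)) == {f"d{i}" for i in range(6)}


def test_abundance_vector_sums_to_reads(community_25):
    cm = hd.greedy_cluster(community_25.reads, 0.03)
    av = cm.abundance_vector()
    assert sum(av) == len(community_25.reads)
    assert all(x >= 1 for x in av)
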