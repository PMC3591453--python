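"""Quality filtering, taxonomy partition, unclassified-singleton removal,
pooling, and the end-to-end pipeline."""

import numpy as np
import pytest

import hidiv as hd
from hidiv.io import RunConfig, TaxonomyTable
from hidiv.synth import random_sequence


def _reads(specs):
    return [hd.SequenceRecord(rid, seq) for rid, seq in specs]


def test_quality_filter_rules():
    rng = np.random.default_rng(41)
    ok = random_sequence(100, rng)
    reads = _reads(
        [("short1", "ACGT"), ("short2", "ACGTA"), ("short3", "ACGTAC")]
        + [(f"n{i}", ok[:50] + "N" + ok[51:]) for i in range(2)]
        + [(f"good{i}", random_sequence(100, rng)) for i in range(5)]
    )
    kept, dropped = hd.quality_filter(reads, min_len=50, max_len=200, max_n=0)
    assert len(kept) == 5 and len(dropped) == 5
    assert all(rid.startswith("good") for rid in (r.id for r in kept))

    boundary = _reads([("b", "A" * 50)])
    kept, _ = hd.quality_filter(boundary, min_len=50, max_len=50, max_n=0)
    assert len(kept) == 1  # inclusive bounds

    one_n = _reads([("n", "A" * 49 + "N")])
    assert hd.quality_filter(one_n, max_n=0)[0] == []
    assert len(hd.quality_filter(one_n, max_n=1)[0]) == 1


def test_remove_excluded():
    reads = _reads([(f"r{i}", "ACGT" * 10) for i in range(10)])
    assert hd.remove_excluded(reads, set()) == reads
    assert hd.remove_excluded(reads, {r.id for r in reads}) == []
    out = hd.remove_excluded(reads, {"r3", "r7"})
    assert [r.id for r in out] == [f"r{i}" for i in range(10) if i not in (3, 7)]
    with pytest.warns(UserWarning, match="not found"):
        hd.remove_excluded(reads, {"ghost"})


def test_partition_groups_and_ratio():
    rng = np.random.default_rng(42)
    reads = _reads([(f"r{i}", random_sequence(60, rng)) for i in range(100)])
    table = TaxonomyTable(
        {f"r{i}": "target" for i in range(80)} | {f"r{i}": "contaminant" for i in range(80, 83)}
    )
    part = hd.partition_by_taxonomy(reads, table)
    assert len(part.target) == 80
    assert len(part.contaminant) == 3
    assert len(part.unclassified) == 17  # absent from the table
    assert part.u_n == pytest.approx(0.17)
    assert part.n_total == 100

    all_target = hd.partition_by_taxonomy(reads[:5], TaxonomyTable({r.id: "target" for r in reads[:5]}))
    assert not all_target.contaminant and not all_target.unclassified


def test_naive_classifier(community_25):
    rng = np.random.default_rng(43)
    seed = community_25.seeds[0]
    member_seq = hd.mutate_to_distance(seed.sequence, 0.0125, hd.MutationSpec(), rng)
    unrelated_ref = hd.SequenceRecord("euk", random_sequence(250, rng))
    refs = [(seed, "target"), (unrelated_ref, "contaminant")]

    reads = _reads(
        [("exact", seed.sequence), ("member", member_seq), ("noise", random_sequence(250, rng))]
    )
    table = hd.naive_classifier(reads, refs, k=8, min_score=0.5)
    assert table.group_of("exact") == "target"
    assert table.group_of("member") == "target"
    assert table.group_of("noise") == "unclassified"
    with pytest.raises(ValueError):
        hd.naive_classifier(reads, [])


def test_filter_unclassified_singletons_planted_sizes():
    """5 planted OTUs of sizes 8,5,4,2,1: the one singleton is dropped,
    the other 19 reads survive."""
    rng = np.random.default_rng(44)
    seeds = hd.generate_seed_set(5, 250, 0.06, rng)
    reads = []
    for seed, size in zip(seeds, (8, 5, 4, 2, 1)):
        reads.append(hd.SequenceRecord(f"{seed.id}.0", seed.sequence))
        for j in range(1, size):
            reads.append(
                hd.SequenceRecord(
                    f"{seed.id}.{j}",
                    hd.mutate_to_distance(seed.sequence, 0.0125, hd.MutationSpec(), rng),
                )
            )
    survivors, dropped = hd.filter_unclassified_singletons(reads, 0.03)
    assert len(survivors) == 19
    assert dropped == [f"{seeds[4].id}.0"]


def test_filter_unclassified_singletons_extremes():
    rng = np.random.default_rng(45)
    distant = _reads([(f"d{i}", random_sequence(200, rng)) for i in range(6)])
    survivors, dropped = hd.filter_unclassified_singletons(distant, 0.03)
    assert survivors == [] and len(dropped) == 6

    duplicated = distant + [hd.SequenceRecord(f"{r.id}.b", r.sequence) for r in distant]
    survivors, dropped = hd.filter_unclassified_singletons(duplicated, 0.03)
    assert len(survivors) == 12 and dropped == []
    assert hd.filter_unclassified_singletons([], 0.03) == ([], [])


def test_pool():
    rng = np.random.default_rng(46)
    target = _reads([(f"t{i}", random_sequence(60, rng)) for i in range(80)])
    survivors = _reads([(f"u{i}", random_sequence(60, rng)) for i in range(15)])
    pooled = hd.pool(target, survivors)
    assert len(pooled) == 95
    assert pooled[:80] == target and pooled[80:] == survivors
    assert hd.pool(target, []) == target
    with pytest.raises(ValueError, match="collision"):
        hd.pool(target, target[:1])


def test_pipeline_degenerate_equals_plain_clustering(community_25):
    """All-target taxonomy and no exclusions: the pipeline estimate equals
    plain clustering of the quality-filtered reads."""
    reads = community_25.reads
    taxonomy = TaxonomyTable({r.id: "target" for r in reads})
    report = hd.run_pipeline(reads, taxonomy, set(), RunConfig(rng_seed=5))
    plain = hd.greedy_cluster(reads, 0.03)
    assert report.stage_counts["pooled"] == len(reads)
    assert report.estimate.s_obs == plain.n_clusters
    assert report.estimate.chao1 == pytest.approx(hd.chao1_corrected(plain.abundance_vector()))


def test_pipeline_bookkeeping_matches_truth(scenario_100):
    """The central end-to-end check: every per-stage count in the pipeline
    report equals the scenario's planted truth."""
    sc = scenario_100
    report = hd.run_pipeline(sc.reads, sc.taxonomy, sc.chimera_ids, RunConfig(rng_seed=1))
    for key in (
        "input",
        "after_quality",
        "after_chimera",
        "target",
        "contaminant",
        "unclassified",
        "unclassified_dropped",
        "unclassified_survivors",
        "pooled",
    ):
        assert report.stage_counts[key] == sc.truth[key], key
    assert report.u_n == pytest.approx(sc.truth["u_n"])
    assert report.estimate.s_obs == sc.truth["final_otus"]
    assert sorted(report.dropped_unclassified_singletons) == sorted(
        rid for rid in (r.id for r in sc.reads) if rid.startswith("sing_")
    )


def test_pipeline_stage_counts_monotone(scenario_100):
    sc = scenario_100
    report = hd.run_pipeline(sc.reads, sc.taxonomy, sc.chimera_ids, RunConfig(rng_seed=1))
    c = report.stage_counts
    assert c["input"] >= c["after_quality"] >= c["after_chimera"]
    assert c["target"] + c["contaminant"] + c["unclassified"] == c["after_chimera"]
    assert c["pooled"] == c["target"] + c["unclassified_survivors"] <= c["after_chimera"]


def test_removing_questionable_reads_lowers_chao1(scenario_100):
    """The filtered ("-euk -uc1") Chao1 never exceeds the unfiltered one
    when the removed unclassified reads are all cluster singletons."""
    sc = scenario_100
    filtered = hd.run_pipeline(sc.reads, sc.taxonomy, sc.chimera_ids, RunConfig(rng_seed=1))
    # "clean" analysis: everything after chimera removal, no taxonomy filtering
    clean_reads = hd.remove_excluded(sc.reads, sc.chimera_ids)
    clean_av = hd.greedy_cluster(clean_reads, 0.03).abundance_vector()
    assert filtered.estimate.chao1 <= hd.chao1_corrected(clean_av)


def test_pipeline_deterministic(scenario_100):
    sc = scenario_100
    r1 = hd.run_pipeline(sc.reads, sc.taxonomy, sc.chimera_ids, RunConfig(rng_seed=9))
    r2 = hd.run_pipeline(sc.reads, sc.taxonomy, sc.chimera_ids, RunConfig(rng_seed=9))
    assert r1.stage_counts == r2.stage_counts
    assert r1.cluster_map.assignments == r2.cluster_map.assignments
    np.testing.assert_array_equal(r1.curve.mean_chao1, r2.curve.mean_chao1)
    np.testing.assert_array_equal(r1.curve.mean_ace, r2.curve.mean_ace)


def test_pipeline_empty_pool_errors():
    rng = np.random.default_rng(47)
    reads = _reads([("r0", random_sequence(60, rng))])
    taxonomy = TaxonomyTable({"r0": "contaminant"})
    with pytest.raises(ValueError, match="empty"):
        hd.run_pipeline(reads, taxonomy, set(), RunConfig())
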