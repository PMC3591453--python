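"""End-to-end test scenarios binding the community simulator to the
filtering workflow.

A scenario is a planted community dressed up with the nuisance reads a real
amplicon study carries: contaminant reads from a disjoint seed pool, a
slice of community reads left without taxonomic labels, planted unlabeled
singletons far from everything (so the singleton filter must drop exactly
them), and an externally reported chimera list. Because every nuisance read
is planted with a known fate, the scenario ships a truth report of expected
per-stage counts that the pipeline report can be compared against exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import greedy_cluster, pairwise_distance
from .io import SequenceRecord, TaxonomyTable, write_fasta, write_taxonomy
from .richness import ace, chao1_corrected
from .synth import (
    CommunityDesign,
    PlantedCommunity,
    build_community,
    random_sequence,
    replicate_community,
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Composition of an end-to-end scenario.

    Fractions are relative to the community read count; unlabeled community
    reads are drawn as same-OTU pairs so they deterministically survive the
    singleton filter, while ``n_planted_singletons`` extra unlabeled reads
    are placed far from everything so they are deterministically dropped.
    """

    design: CommunityDesign
    contaminant_fraction: float = 0.0
    unlabeled_fraction: float = 0.0
    n_planted_singletons: int = 0
    n_chimeras: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if not 0 <= self.unlabeled_fraction <= 1:
            raise ValueError("unlabeled_fraction must be in [0, 1]")
        if self.contaminant_fraction + self.unlabeled_fraction > 1:
            raise ValueError("contaminant + unlabeled fractions must be <= 1")
        if self.n_planted_singletons < 0 or self.n_chimeras < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class Scenario:
    """A generated scenario: reads, taxonomy, chimera list, the underlying
    community, and the truth report of expected pipeline stage counts."""

    spec: ScenarioSpec
    reads: list[SequenceRecord]
    taxonomy: TaxonomyTable
    chimera_ids: set[str]
    community: PlantedCommunity
    truth: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reads, outdir / "reads.fasta")
        write_taxonomy(self.taxonomy, outdir / "tax.tsv")
        (outdir / "chimeras.txt").write_text(
            "".join(f"{rid}\n" for rid in sorted(self.chimera_ids))
        )
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def _distant_sequence(
    length: int,
    anchors: list[str],
    min_dist: float,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> str:
    """Rejection-sample a random sequence farther than ``min_dist`` from
    every anchor."""
    for _ in range(max_attempts):
        cand = random_sequence(length, rng)
        if all(pairwise_distance(cand, a) > min_dist for a in anchors):
            return cand
    raise RuntimeError(f"could not place a sequence > {min_dist} from all anchors")


def make_scenario(spec: ScenarioSpec, outdir: str | Path | None = None) -> Scenario:
    """Build a scenario per ``spec`` and (optionally) write its files.

    Construction guarantees making the truth report exact:
      - unlabeled community reads come in (seed read, mutated member) pairs
        from distinct multi-member OTUs, at most member_distance + tol
        apart, so each pair forms one size-2 cluster among the unclassified
        and survives the singleton filter;
      - planted singletons sit farther than 2*d + member_distance from all
        community seeds and from each other, so each is its own cluster and
        is dropped;
      - contaminants and chimeras are removed before clustering, so the
        final OTU count is exactly the planted n_otus (given a design with
        seed separation > d + 2*member_distance).
    """
    rng = np.random.default_rng(spec.seed)
    community = build_community(spec.design, rng)
    reads = [SequenceRecord(r.id, r.sequence, dict(r.annotations)) for r in community.reads]
    n_community = len(reads)
    d = 0.03
    tax: dict[str, str] = {rec.id: "target" for rec in reads}
    seed_seqs = [s.sequence for s in community.seeds]

    # unlabeled same-OTU pairs: seed read + one mutated member of that OTU
    n_unlabeled_goal = round(spec.unlabeled_fraction * n_community)
    by_otu: dict[str, list[SequenceRecord]] = {}
    for rec in reads:
        by_otu.setdefault(rec.annotations["otu"], []).append(rec)
    n_unlabeled = 0
    for otu, members in by_otu.items():
        if n_unlabeled + 2 > n_unlabeled_goal:
            break
        if len(members) >= 2:
            seed_read = min(members, key=lambda m: m.id)  # first member is the seed
            other = next(m for m in members if m.id != seed_read.id)
            del tax[seed_read.id]
            del tax[other.id]
            n_unlabeled += 2

    # contaminants: random sequences labeled as such (never clustered)
    n_contaminants = round(spec.contaminant_fraction * n_community)
    for i in range(n_contaminants):
        rec = SequenceRecord(f"cont_{i:05d}", random_sequence(spec.design.seed_length, rng))
        reads.append(rec)
        tax[rec.id] = "contaminant"

    # planted unlabeled singletons: far from every seed and from each other,
    # so each forms its own cluster among the unclassified and is dropped
    singleton_anchor_dist = 2 * d + spec.design.member_distance + 0.003
    singleton_seqs: list[str] = []
    for i in range(spec.n_planted_singletons):
        seq = _distant_sequence(
            spec.design.seed_length, seed_seqs + singleton_seqs, singleton_anchor_dist, rng
        )
        singleton_seqs.append(seq)
        reads.append(SequenceRecord(f"sing_{i:05d}", seq))

    # chimeras: reported externally by id; removed before any analysis
    chimera_ids = set()
    for i in range(spec.n_chimeras):
        rec = SequenceRecord(f"chim_{i:05d}", random_sequence(spec.design.seed_length, rng))
        reads.append(rec)
        chimera_ids.add(rec.id)

    reads = [reads[i] for i in rng.permutation(len(reads))]

    n_input = len(reads)
    n_after_chimera = n_input - spec.n_chimeras
    n_unclassified = n_unlabeled + spec.n_planted_singletons
    truth = {
        "input": n_input,
        "after_quality": n_input,
        "after_chimera": n_after_chimera,
        "target": n_community - n_unlabeled,
        "contaminant": n_contaminants,
        "unclassified": n_unclassified,
        "unclassified_dropped": spec.n_planted_singletons,
        "unclassified_survivors": n_unlabeled,
        "pooled": n_community,
        "u_n": n_unclassified / n_after_chimera if n_after_chimera else 0.0,
        "final_otus": spec.design.n_otus,
    }
    scenario = Scenario(spec, reads, TaxonomyTable(tax), chimera_ids, community, truth)
    if outdir is not None:
        scenario.write(outdir)
    return scenario


def estimator_behavior_suite(
    mus: list[float],
    sigmas: list[float],
    n_otus: int,
    replications: list[int] = (1, 2, 3),
    seed: int = 0,
    design_kwargs: dict | None = None,
    d: float = 0.03,
) -> pd.DataFrame:
    """Full-depth estimator behavior across a (mu, sigma, replication)
    grid: for each cell, build a planted community, cluster it at ``d`` and
    record observed richness, Chao1, ACE and the true richness.

    Well-separated defaults (seed separation 0.06 > d + 2*member_distance)
    make clustering recover the planted OTUs, isolating estimator behavior
    from clustering error. Qualitative expectations: base communities full
    of singleton lineages are grossly overestimated; x2/x3 replication
    forces F1 = 0 so Chao1 collapses onto S_obs = true richness.
    """
    design_kwargs = {"seed_min_separation": 0.06, **(design_kwargs or {})}
    seeds = np.random.SeedSequence(seed).spawn(len(mus) * len(sigmas))
    rows = []
    idx = 0
    for mu in mus:
        for sigma in sigmas:
            rng = np.random.default_rng(seeds[idx])
            idx += 1
            design = CommunityDesign(n_otus=n_otus, mu=mu, sigma=sigma, **design_kwargs)
            base = build_community(design, rng)
            for rep in replications:
                community = replicate_community(base, rep) if rep > 1 else base
                av = greedy_cluster(community.reads, d).abundance_vector()
                rows.append(
                    {
                        "mu": mu,
                        "sigma": sigma,
                        "replication": rep,
                        "n_reads": len(community.reads),
                        "true_richness": n_otus,
                        "s_obs": len(av),
                        "chao1": chao1_corrected(av),
                        "ace": ace(av),
                    }
                )
    return pd.DataFrame(rows)
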