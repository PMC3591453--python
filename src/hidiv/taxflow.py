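"""The taxonomy-guided read-filtering workflow.

The recommended analysis for high-biodiversity amplicon data keeps as much
high-quality signal as possible: quality-filter, drop externally reported
chimeras, partition reads by taxonomic assignment into target (e.g.
bacterial), contaminant (e.g. eukaryotic) and unclassified groups, cluster
the unclassified group separately and discard only its singleton OTUs
(erroneous reads are very unlikely to share an error pattern, so they
surface as singletons), pool the surviving unclassified reads back with the
target group, and estimate richness on the pooled set. The result retains
10-20% of reads that a strict pipeline would discard while removing the
reads most likely to inflate singleton-driven estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterMap, greedy_cluster, singleton_ids, _kmer_set
from .io import RunConfig, SequenceRecord, TaxonomyTable
from .richness import (
    LogNormalFit,
    RarefactionCurve,
    RichnessEstimate,
    estimate_richness,
    fit_lognormal,
    rarefaction_curve,
)


@dataclass
class PartitionResult:
    """Reads routed into the three disjoint taxonomic groups, with counts
    and the U/N ratio (unclassified reads over all reads)."""

    target: list[SequenceRecord]
    contaminant: list[SequenceRecord]
    unclassified: list[SequenceRecord]

    @property
    def n_total(self) -> int:
        return len(self.target) + len(self.contaminant) + len(self.unclassified)

    @property
    def u_n(self) -> float:
        return len(self.unclassified) / self.n_total if self.n_total else 0.0

    def counts(self) -> dict[str, float]:
        return {
            "n": self.n_total,
            "target": len(self.target),
            "contaminant": len(self.contaminant),
            "unclassified": len(self.unclassified),
            "u_n": self.u_n,
        }


@dataclass
class PipelineReport:
    """Bookkeeping of one full pipeline run: per-stage read counts, dropped
    id lists, and the final clustering with its richness outputs."""

    stage_counts: dict[str, int]
    u_n: float
    dropped_quality: list[str]
    dropped_chimera: list[str]
    dropped_unclassified_singletons: list[str]
    cluster_map: ClusterMap
    estimate: RichnessEstimate
    curve: RarefactionCurve
    fit: LogNormalFit | None


def quality_filter(
    reads: list[SequenceRecord],
    min_len: int = 0,
    max_len: int = 10**9,
    max_n: int = 0,
) -> tuple[list[SequenceRecord], list[str]]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds) and
    at most ``max_n`` undetermined bases; return (kept, dropped ids)."""
    if not 0 <= min_len <= max_len:
        raise ValueError("require 0 <= min_len <= max_len")
    kept, dropped = [], []
    for rec in reads:
        if min_len <= len(rec) <= max_len and rec.sequence.count("N") <= max_n:
            kept.append(rec)
        else:
            dropped.append(rec.id)
    return kept, dropped


def remove_excluded(
    reads: list[SequenceRecord], exclusion_ids: set[str]
) -> list[SequenceRecord]:
    """Drop reads whose id is in ``exclusion_ids`` (a chimera report),
    preserving order; exclusion ids not present in the reads only warn."""
    present = {rec.id for rec in reads}
    missing = exclusion_ids - present
    if missing:
        warnings.warn(
            f"{len(missing)} exclusion id(s) not found among reads", stacklevel=2
        )
    return [rec for rec in reads if rec.id not in exclusion_ids]


def partition_by_taxonomy(
    reads: list[SequenceRecord], table: TaxonomyTable
) -> PartitionResult:
    """Route reads into target / contaminant / unclassified according to the
    taxonomy table; reads absent from the table are unclassified."""
    buckets: dict[str, list[SequenceRecord]] = {
        "target": [],
        "contaminant": [],
        "unclassified": [],
    }
    for rec in reads:
        buckets[table.group_of(rec.id)].append(rec)
    return PartitionResult(**buckets)


def naive_classifier(
    reads: list[SequenceRecord],
    labeled_refs: list[tuple[SequenceRecord, str]],
    k: int = 8,
    min_score: float = 0.5,
) -> TaxonomyTable:
    """A deliberately simple shared-k-mer classifier for testing the
    workflow without an external search-and-assign toolchain: each read gets
    the label of its best-scoring reference (score = fraction of the read's
    distinct k-mers shared) if the score reaches ``min_score``, else it
    stays unclassified. Not a reconstruction of any production assigner.
    """
    if not labeled_refs:
        raise ValueError("labeled_refs must be non-empty")
    for _, grp in labeled_refs:
        if grp not in ("target", "contaminant"):
            raise ValueError(f"reference label must be target or contaminant, got {grp!r}")
    ref_sets = [(_kmer_set(ref.sequence, k), grp) for ref, grp in labeled_refs]
    groups: dict[str, str] = {}
    for rec in reads:
        qset = _kmer_set(rec.sequence, k)
        best_score, best_grp = 0.0, "unclassified"
        for rset, grp in ref_sets:
            score = len(qset & rset) / len(qset) if qset else 0.0
            if score > best_score:
                best_score, best_grp = score, grp
        groups[rec.id] = best_grp if best_score >= min_score else "unclassified"
    return TaxonomyTable(groups)


def filter_unclassified_singletons(
    unclassified_reads: list[SequenceRecord], d: float = 0.03
) -> tuple[list[SequenceRecord], list[str]]:
    """Cluster ONLY the unclassified subset at threshold ``d`` and drop
    every read sitting in a size-1 cluster; return (survivors, dropped ids).
    Survivors — reads corroborated by at least one near-identical companion
    — are safe to pool back with the target group."""
    if not unclassified_reads:
        return [], []
    cm = greedy_cluster(unclassified_reads, d)
    drop = singleton_ids(cm)
    survivors = [rec for rec in unclassified_reads if rec.id not in drop]
    return survivors, sorted(drop)


def pool(
    target_reads: list[SequenceRecord], survivors: list[SequenceRecord]
) -> list[SequenceRecord]:
    """Concatenate the target group with the unclassified survivors; the id
    sets must be disjoint."""
    collision = {r.id for r in target_reads} & {r.id for r in survivors}
    if collision:
        raise ValueError(f"id collision between target and survivors: {sorted(collision)[:5]}")
    return list(target_reads) + list(survivors)


def run_pipeline(
    reads: list[SequenceRecord],
    taxonomy: TaxonomyTable,
    exclusions: set[str] | None = None,
    config: RunConfig | None = None,
) -> PipelineReport:
    """Run the full workflow: quality filter -> chimera exclusion ->
    taxonomy partition -> unclassified-singleton removal -> pool -> cluster
    at the configured threshold -> richness estimate, rarefaction curve and
    log-normal abundance fit on the pooled set.

    The estimates therefore carry "-euk -uc1" semantics: contaminants and
    unclassified singletons have been removed before any richness figure is
    computed. The log-normal fit is None when fewer than 10 OTUs remain.
    """
    config = config or RunConfig()
    exclusions = exclusions or set()

    after_quality, dropped_quality = quality_filter(
        reads, config.min_len, config.max_len, config.max_n
    )
    after_chimera = remove_excluded(after_quality, exclusions) if exclusions else after_quality
    dropped_chimera = sorted({r.id for r in after_quality} & exclusions)

    part = partition_by_taxonomy(after_chimera, taxonomy)
    survivors, dropped_uc1 = filter_unclassified_singletons(
        part.unclassified, config.dissimilarity_threshold
    )
    pooled = pool(part.target, survivors)
    if not pooled:
        raise ValueError("pooled read set is empty; nothing to analyse")

    cm = greedy_cluster(pooled, config.dissimilarity_threshold)
    av = cm.abundance_vector()
    rng = np.random.default_rng(config.rng_seed)
    curve = rarefaction_curve(
        cm, config.rarefaction_step, config.rarefaction_iters, rng, config.rare_cutoff
    )
    fit = fit_lognormal(av) if len(av) >= 10 else None

    stage_counts = {
        "input": len(reads),
        "after_quality": len(after_quality),
        "after_chimera": len(after_chimera),
        "target": len(part.target),
        "contaminant": len(part.contaminant),
        "unclassified": len(part.unclassified),
        "unclassified_dropped": len(dropped_uc1),
        "unclassified_survivors": len(survivors),
        "pooled": len(pooled),
    }
    return PipelineReport(
        stage_counts=stage_counts,
        u_n=part.u_n,
        dropped_quality=dropped_quality,
        dropped_chimera=dropped_chimera,
        dropped_unclassified_singletons=dropped_uc1,
        cluster_map=cm,
        estimate=estimate_richness(av, rare_cutoff=config.rare_cutoff),
        curve=curve,
        fit=fit,
    )
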