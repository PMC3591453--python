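"""Pairwise sequence dissimilarity and OTU clustering.

Two routes to an OTU partition are provided: a fast greedy centroid
clusterer (dereplicate, abundance-sort, first-fit against existing
centroids — the strategy of the usual amplicon pipelines) and a brute-force
all-pairs single-linkage clusterer that serves as an oracle on small,
well-separated inputs.

Dissimilarity between two reads is defined on a unit-cost global
(Needleman-Wunsch) alignment as

    d(a, b) = (mismatches + indel columns) / alignment length,

so identical sequences are at distance 0 and indels count as differences.
OTU counts depend on this convention, hence it is stated explicitly.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import SequenceRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ClusterMap:
    """A read -> cluster assignment with centroid bookkeeping.

    Cluster ids are consecutive integers assigned in centroid-creation
    order starting at 0; every centroid read is assigned to its own cluster.
    """

    assignments: dict[str, int]
    centroids: dict[int, str]
    threshold: float

    def __post_init__(self) -> None:
        clusters = set(self.assignments.values())
        if clusters != set(self.centroids):
            raise ValueError("assignments and centroids reference different clusters")
        for cid, rid in self.centroids.items():
            if self.assignments.get(rid) != cid:
                raise ValueError(f"centroid {rid!r} not assigned to its own cluster {cid}")

    @property
    def n_reads(self) -> int:
        return len(self.assignments)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def sizes(self) -> Counter:
        return Counter(self.assignments.values())

    def abundance_vector(self) -> list[int]:
        """Cluster sizes ordered by cluster id; sums to the number of reads."""
        sizes = self.sizes()
        return [sizes[cid] for cid in sorted(self.centroids)]


def _alignment_length(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


def pairwise_distance(a: str, b: str) -> float:
    """Global-alignment dissimilarity between two sequences (see module
    docstring for the exact definition). Symmetric; 0 iff identical."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 0.0
    # canonical argument order: among co-optimal alignments the reported
    # alignment length may differ between (a, b) and (b, a); fixing the
    # order makes the measure exactly symmetric
    if a > b:
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    return res["editDistance"] / _alignment_length(res["cigar"])


def distance_if_within(a: str, b: str, d: float, band_pad: int = 8) -> float | None:
    """Banded variant: return d(a, b) if it is <= d, else None.

    The alignment is bounded at ``ceil(2 * d * max_len) + band_pad`` edits;
    any pair beyond the band is beyond d anyway.
    """
    if a > b:
        a, b = b, a
    k = math.ceil(2 * d * max(len(a), len(b))) + band_pad
    res = edlib.align(a, b, mode="NW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    dist = res["editDistance"] / _alignment_length(res["cigar"])
    return dist if dist <= d else None


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_candidate_filter(
    query: str,
    centroid_seqs: list[str],
    k: int = 8,
    min_shared_fraction: float = 0.5,
) -> list[int]:
    """Indices of centroids sharing at least ``min_shared_fraction`` of the
    query's distinct k-mers — a cheap superset guard before alignment.

    At the defaults (k=8, 0.5) no centroid within the clustering threshold
    of the query should be excluded for amplicon-length reads: t errors
    destroy at most t*k of the roughly L-k+1 query k-mers.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    qset = _kmer_set(query, k)
    if not qset:
        return list(range(len(centroid_seqs)))
    cutoff = min_shared_fraction * len(qset)
    out = []
    for i, cseq in enumerate(centroid_seqs):
        if len(_kmer_set(cseq, k) & qset) >= cutoff:
            out.append(i)
    return out


def greedy_cluster(
    reads: list[SequenceRecord],
    d: float,
    order: str = "abundance",
    best_fit: bool = False,
    prefilter: bool = True,
    kmer_k: int = 8,
    min_shared_fraction: float = 0.5,
) -> ClusterMap:
    """Greedy centroid clustering at dissimilarity threshold ``d``.

    Identical sequences are dereplicated first; unique sequences are then
    processed in decreasing duplicate count (ties broken by decreasing
    length, then id) — or by ``order`` in {"abundance", "length", "input"}.
    Each sequence joins the first existing centroid within ``d``
    (first-fit; ``best_fit=True`` picks the closest centroid within ``d``
    instead), otherwise it founds a new cluster with itself as centroid.
    Duplicates inherit their representative's cluster.

    By construction all centroids are pairwise farther than ``d`` apart and
    every read is within ``d`` of its cluster centroid.
    """
    if order not in ("abundance", "length", "input"):
        raise ValueError(f"unknown order {order!r}")
    if not reads:
        return ClusterMap({}, {}, d)

    # dereplicate: sequence -> ids in first-occurrence order
    derep: dict[str, list[str]] = {}
    for rec in reads:
        derep.setdefault(rec.sequence, []).append(rec.id)
    uniques = list(derep.items())
    if order == "abundance":
        uniques.sort(key=lambda kv: (-len(kv[1]), -len(kv[0]), kv[1][0]))
    elif order == "length":
        uniques.sort(key=lambda kv: (-len(kv[0]), kv[1][0]))

    assignments: dict[str, int] = {}
    centroids: dict[int, str] = {}
    centroid_seqs: list[str] = []
    centroid_kmers: list[frozenset] = []

    for seq, ids in uniques:
        qset = _kmer_set(seq, kmer_k) if prefilter else None
        if prefilter and qset:
            cutoff = min_shared_fraction * len(qset)
            candidates = [
                i for i, cset in enumerate(centroid_kmers) if len(cset & qset) >= cutoff
            ]
        else:
            candidates = range(len(centroid_seqs))

        chosen: int | None = None
        if best_fit:
            best_d = math.inf
            for i in candidates:
                dist = distance_if_within(seq, centroid_seqs[i], d)
                if dist is not None and dist < best_d:
                    best_d, chosen = dist, i
        else:
            for i in candidates:
                if distance_if_within(seq, centroid_seqs[i], d) is not None:
                    chosen = i
                    break

        if chosen is None:
            chosen = len(centroid_seqs)
            centroids[chosen] = ids[0]
            centroid_seqs.append(seq)
            centroid_kmers.append(qset if qset is not None else _kmer_set(seq, kmer_k))
        for rid in ids:
            assignments[rid] = chosen

    return ClusterMap(assignments, centroids, d)


def brute_force_cluster(reads: list[SequenceRecord], d: float) -> ClusterMap:
    """All-pairs single-linkage clustering at threshold ``d`` — the oracle.

    Computes every C(n,2) full (unbanded) alignment distance and takes
    connected components of the graph with edges at distance <= d. On
    planted communities whose seeds are separated by more than
    d + 2*member_distance this agrees exactly with greedy_cluster; it is
    quadratic, so a warning is emitted above 2000 reads.
    """
    n = len(reads)
    if n == 0:
        return ClusterMap({}, {}, d)
    if n > 2000:
        warnings.warn(f"brute_force_cluster on {n} reads: O(n^2) alignments", stacklevel=2)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_distance(reads[i].sequence, reads[j].sequence) <= d:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)

    # relabel components in order of first read appearance, for determinism
    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    centroids: dict[int, str] = {}
    for i, rec in enumerate(reads):
        comp = labels[i]
        if comp not in relabel:
            relabel[comp] = len(relabel)
            centroids[relabel[comp]] = rec.id
        assignments[rec.id] = relabel[comp]
    return ClusterMap(assignments, centroids, d)


def pairwise_comparison_count(n: int) -> int:
    """Number of unordered pairs among n sequences, n(n-1)/2 — the cost of a
    full all-vs-all distance matrix."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) // 2


def max_tolerated_errors(length: int, d: float) -> int:
    """Largest error count keeping a read of the given length within
    dissimilarity ``d`` of its error-free original: floor(length * d)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return int(math.floor(length * d + 1e-9))


def singleton_ids(cm: ClusterMap) -> set[str]:
    """Ids of all reads sitting in size-1 clusters (singleton OTUs)."""
    sizes = cm.sizes()
    return {rid for rid, cid in cm.assignments.items() if sizes[cid] == 1}
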