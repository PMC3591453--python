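"""Planted-truth synthetic 16S community generation.

A community is built from seed sequences that are mutually separated by
more than a minimum dissimilarity (default 3%, the species-level OTU
radius), one seed per OTU. Per-OTU member counts are drawn from a discrete
log-normal with parameters mu and sigma (the mean and standard deviation of
the logarithm of abundance); each additional member is the seed mutated —
by random transitions, transversions, insertions and deletions — out to a
target dissimilarity (default 1.25%) from the seed. Duplicated (x2) and
triplicated (x3) variants guarantee every genetic lineage at least two or
three individuals.

Because membership and mutation distances are known exactly ("planted"),
these communities carry a ground truth that downstream clustering and
richness estimation can be audited against: with seed separation s and
member distance m, members of different OTUs are farther than s - 2m apart
(triangle bound), so clustering at threshold d < s - 2m must recover
exactly the planted OTUs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cluster import pairwise_distance
from .io import SequenceRecord

_BASES = ("A", "C", "G", "T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class MutationSpec:
    """Relative probabilities of the four point-mutation event types.

    Defaults weight substitutions over indels (0.35/0.35/0.15/0.15) —
    balanced substitutions dominate while all listed event types occur.
    """

    p_transition: float = 0.35
    p_transversion: float = 0.35
    p_insertion: float = 0.15
    p_deletion: float = 0.15

    def __post_init__(self) -> None:
        probs = self.probabilities
        if any(p < 0 for p in probs):
            raise ValueError("event probabilities must be nonnegative")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError("event probabilities must sum to 1")

    @property
    def probabilities(self) -> tuple[float, float, float, float]:
        return (self.p_transition, self.p_transversion, self.p_insertion, self.p_deletion)


@dataclass(frozen=True)
class CommunityDesign:
    """Parameters of a planted community.

    mu/sigma parameterize the log-normal membership distribution;
    member_distance is the per-member dissimilarity from the seed;
    seed_min_separation the minimum pairwise seed dissimilarity;
    replication k produces the x2/x3 variants.
    """

    n_otus: int
    mu: float = 1.0
    sigma: float = 1.0
    member_distance: float = 0.0125
    seed_min_separation: float = 0.03
    seed_length: int = 250
    replication: int = 1

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.member_distance < self.seed_min_separation:
            raise ValueError("require 0 < member_distance < seed_min_separation")
        if self.seed_length < 50:
            raise ValueError("seed_length must be >= 50 nt")
        if self.replication < 1:
            raise ValueError("replication must be >= 1")


@dataclass
class PlantedCommunity:
    """A simulated read set with ground truth: the design, the seed of each
    OTU, the shuffled reads (annotated with their true OTU id), and the
    planted per-OTU member counts."""

    design: CommunityDesign
    seeds: list[SequenceRecord]
    reads: list[SequenceRecord]
    truth: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.truth.values()) != len(self.reads):
            raise ValueError("truth counts must sum to the number of reads")
        seed_ids = {s.id for s in self.seeds}
        for rec in self.reads:
            if rec.annotations.get("otu") not in seed_ids:
                raise ValueError(f"read {rec.id!r}: true OTU id not among seeds")

    @property
    def n_otus(self) -> int:
        return len(self.seeds)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate_sequence(
    seq: str, n_events: int, spec: MutationSpec, rng: np.random.Generator
) -> str:
    """Apply exactly ``n_events`` point-mutation events, each at an
    independently chosen uniform position, with the event type drawn from
    ``spec``. Substitutions honor transition/transversion identity
    (A<->G, C<->T are transitions; all other substitutions transversions).
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not seq:
        raise ValueError("sequence must be non-empty")
    chars = list(seq)
    for _ in range(n_events):
        event = rng.choice(4, p=spec.probabilities)
        if event == 3 and len(chars) == 1:
            raise ValueError("cannot delete from a length-1 sequence")
        if event == 0:  # transition
            pos = int(rng.integers(len(chars)))
            base = chars[pos]
            # N carries no purine/pyrimidine identity; fall back to a random base
            chars[pos] = _TRANSITION.get(base) or str(rng.choice(_BASES))
        elif event == 1:  # transversion
            pos = int(rng.integers(len(chars)))
            partners = _TRANSVERSION.get(chars[pos], _BASES)
            chars[pos] = str(rng.choice(partners))
        elif event == 2:  # insertion
            pos = int(rng.integers(len(chars) + 1))
            chars.insert(pos, str(rng.choice(_BASES)))
        else:  # deletion
            pos = int(rng.integers(len(chars)))
            del chars[pos]
    return "".join(chars)


def mutate_to_distance(
    seq: str,
    target_d: float,
    spec: MutationSpec,
    rng: np.random.Generator,
    tol: float = 0.003,
) -> str:
    """Mutate ``seq`` one event at a time, re-measuring the alignment
    distance to the original after each event, until the distance lands in
    [target_d - tol, target_d + tol].

    Overshoot (possible when one event moves the distance across the whole
    band) restarts from the original; a mutation budget of
    10 * target_d * len(seq) events (min 50) bounds the total work, and a
    RuntimeError past the budget signals an infeasible target/tolerance
    combination for the sequence length.
    """
    if not 0 <= target_d < 1:
        raise ValueError("target_d must be in [0, 1)")
    if target_d <= tol:
        return seq
    budget = max(50, math.ceil(10 * target_d * len(seq)))
    spent = 0
    while spent < budget:
        current = seq
        while spent < budget:
            current = mutate_sequence(current, 1, spec, rng)
            spent += 1
            dist = pairwise_distance(seq, current)
            if target_d - tol <= dist <= target_d + tol:
                return current
            if dist > target_d + tol:
                break  # overshot the band; restart from the original
    raise RuntimeError(
        f"could not reach distance {target_d}±{tol} within {budget} events "
        f"(sequence length {len(seq)}; try a longer sequence or wider tol)"
    )


def generate_seed_set(
    n: int,
    length: int,
    min_separation: float,
    rng: np.random.Generator,
    max_attempts_per_seed: int = 50,
) -> list[SequenceRecord]:
    """Draw ``n`` random sequences whose pairwise dissimilarities all exceed
    ``min_separation``, by rejection sampling; separation is verified during
    construction. Random sequences of amplicon length are typically ~50%
    apart, so rejections are rare at realistic separations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds: list[str] = []
    attempts = 0
    budget = max_attempts_per_seed * n
    while len(seeds) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"placed only {len(seeds)}/{n} seeds within {budget} attempts; "
                "try longer sequences or fewer seeds"
            )
        attempts += 1
        cand = random_sequence(length, rng)
        if all(pairwise_distance(cand, s) > min_separation for s in seeds):
            seeds.append(cand)
    return [SequenceRecord(f"seed_{i:05d}", s) for i, s in enumerate(seeds)]


def select_seed_representatives(
    pool: list[SequenceRecord], min_separation: float
) -> list[SequenceRecord]:
    """Greedy scan of ``pool`` in input order keeping each sequence iff its
    distance to every already-kept sequence exceeds ``min_separation`` —
    the cleanup applied to a reference pool before it can seed a community."""
    kept: list[SequenceRecord] = []
    for rec in pool:
        if all(pairwise_distance(rec.sequence, k.sequence) > min_separation for k in kept):
            kept.append(rec)
    return kept


def sample_abundances(
    n_otus: int, mu: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-OTU member counts: max(1, round(exp(Normal(mu, sigma)))) — a
    discretized log-normal floored at 1 so every OTU has at least one
    member."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    counts = np.rint(np.exp(rng.normal(mu, sigma, size=n_otus)))
    return np.maximum(counts, 1).astype(int)


def build_community(
    design: CommunityDesign,
    rng: np.random.Generator,
    spec: MutationSpec | None = None,
    tol: float = 0.003,
) -> PlantedCommunity:
    """Build a planted community per ``design``: generate separated seeds,
    draw per-OTU counts, mutate members to ``member_distance`` from their
    seed (the first member of each OTU is the unmutated seed itself),
    shuffle the reads, record the truth, and apply x2/x3 replication if
    requested."""
    spec = spec or MutationSpec()
    seeds = generate_seed_set(
        design.n_otus, design.seed_length, design.seed_min_separation, rng
    )
    counts = sample_abundances(design.n_otus, design.mu, design.sigma, rng)
    reads: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    serial = 0
    for seed, count in zip(seeds, counts):
        truth[seed.id] = int(count)
        for j in range(int(count)):
            seq = (
                seed.sequence
                if j == 0
                else mutate_to_distance(seed.sequence, design.member_distance, spec, rng, tol)
            )
            reads.append(SequenceRecord(f"read_{serial:06d}", seq, {"otu": seed.id}))
            serial += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    community = PlantedCommunity(replace(design, replication=1), seeds, reads, truth)
    if design.replication > 1:
        community = replicate_community(community, design.replication)
    return community


def replicate_community(c: PlantedCommunity, k: int) -> PlantedCommunity:
    """The x2/x3 construction: every read appears exactly ``k`` times (fresh
    unique ids suffixed .dup1/.dup2/…, same sequence and true OTU), and all
    truth counts are multiplied by ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return c
    reads: list[SequenceRecord] = []
    for rec in c.reads:
        reads.append(SequenceRecord(rec.id, rec.sequence, dict(rec.annotations)))
        for i in range(1, k):
            reads.append(
                SequenceRecord(f"{rec.id}.dup{i}", rec.sequence, dict(rec.annotations))
            )
    truth = {otu: n * k for otu, n in c.truth.items()}
    return PlantedCommunity(replace(c.design, replication=k), c.seeds, reads, truth)
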