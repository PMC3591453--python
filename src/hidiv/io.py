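"""Readers and writers for on-disk formats, plus run configuration.

Every other module in the package is pure in-memory computation; all file
handling (FASTA reads, taxonomy tables, id exclusion lists, key=value run
configs) funnels through here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

#: the three taxonomic groups every read is routed into
GROUPS = ("target", "contaminant", "unclassified")


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the record contract."""


@dataclass
class SequenceRecord:
    """One amplicon read: unique id, uppercase A/C/G/T/N sequence, free-form
    annotations (e.g. the planted OTU id for simulated reads)."""

    id: str
    sequence: str
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(only A, C, G, T, N allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TaxonomyTable:
    """Mapping read_id -> group, where group is one of GROUPS.

    Reads absent from the table are treated as unclassified by consumers.
    """

    groups: dict[str, str]

    def __post_init__(self) -> None:
        for rid, grp in self.groups.items():
            if grp not in GROUPS:
                raise ValueError(f"read {rid!r}: unknown group {grp!r}")

    def group_of(self, read_id: str) -> str:
        return self.groups.get(read_id, "unclassified")

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class RunConfig:
    """Tunable knobs for a full analysis run.

    dissimilarity_threshold is the OTU radius d (0.03 = species-level);
    rarefaction proceeds on a grid of `rarefaction_step` reads averaged over
    `rarefaction_iters` subsamples; quality filtering keeps reads of length
    in [min_len, max_len] with at most max_n undetermined bases.
    """

    dissimilarity_threshold: float = 0.03
    rarefaction_step: int = 100
    rarefaction_iters: int = 10
    rng_seed: int = 0
    min_len: int = 0
    max_len: int = 10**9
    max_n: int = 0
    rare_cutoff: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.dissimilarity_threshold < 1:
            raise ValueError("dissimilarity_threshold must be in (0, 1)")
        if self.rarefaction_step < 1:
            raise ValueError("rarefaction_step must be >= 1")
        if self.rarefaction_iters < 1:
            raise ValueError("rarefaction_iters must be >= 1")
        if self.min_len < 0 or self.max_len < 0 or self.max_n < 0:
            raise ValueError("lengths and max_n must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a key=value config file (blank lines and # comments ignored)."""
        kwargs: dict[str, object] = {}
        float_keys = {"dissimilarity_threshold"}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = float(value) if key in float_keys else int(value)
        return cls(**kwargs)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords, preserving file order.

    Sequences are uppercased; header tokens of the form ``key=value`` after
    the id become annotations. Duplicate ids, empty sequences and characters
    outside A/C/G/T/N raise FastaParseError rather than being skipped
    silently — silent loss would distort downstream richness counts.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for idx, bio in enumerate(SeqIO.parse(str(path), "fasta")):
        if bio.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {bio.id!r} (record {idx + 1})")
        seen.add(bio.id)
        annotations = {}
        for token in bio.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                annotations[key] = value
        try:
            records.append(SequenceRecord(bio.id, str(bio.seq), annotations))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record {idx + 1}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 80 columns; annotations are
    serialized as ``key=value`` tokens on the header line after the id."""
    bio_records = []
    for rec in records:
        desc = " ".join(f"{k}={v}" for k, v in rec.annotations.items())
        bio_records.append(_BioSeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=80)
        writer.write_file(bio_records)


def read_taxonomy(path: str | Path, mapping: dict[str, str]) -> TaxonomyTable:
    """Read a 2+-column TSV of (read_id, taxon) — the shape of a BLAST+MEGAN
    export — and map raw taxon strings onto the three-group alphabet.

    `mapping` sends taxon strings (e.g. "Bacteria", "Eukaryota") to a group
    in GROUPS; taxon strings already naming a group pass through; anything
    unmapped becomes "unclassified". Duplicate read ids are an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: taxonomy table needs >= 2 tab-separated columns")
    dup = df[0][df[0].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate read_id {dup.iloc[0]!r}")
    groups = {}
    for rid, taxon in zip(df[0], df[1]):
        if taxon in GROUPS:
            groups[rid] = taxon
        else:
            groups[rid] = mapping.get(taxon, "unclassified")
    return TaxonomyTable(groups)


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    pd.DataFrame(sorted(table.groups.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_id_list(path: str | Path) -> set[str]:
    """Read a plain-text id list (one per line; blank lines ignored) into a
    set — the shape of a chimera exclusion list."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            ids.add(line)
    return ids
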