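"""Shared domain types for the SV meta-calling pipeline.

Coordinates are 1-based and inclusive throughout (the VCF/GFF convention);
parsers convert at the boundary and nothing downstream ever re-converts.
Every structural variant is either an interval (DEL/DUP/INV, with
``length = end - start + 1``) or a point insertion (INS, ``end == start``,
``length`` = inserted-sequence length), so each SV carries exactly one
unambiguous length.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounding up.

    Consensus coordinates are arithmetic means of integer breakpoints;
    genome coordinates must stay integral downstream.
    """
    return int(math.floor(x + 0.5))


class SVType(str, enum.Enum):
    """The four structural-variant classes handled by the pipeline."""

    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"


class Technology(str, enum.Enum):
    """Sequencing technology that produced the evidence for a call."""

    SHORT = "short"
    LONG = "long"


@dataclass
class SVCall:
    """One variant reported by a single caller.

    Parameters
    ----------
    id
        Opaque identifier, unique within one caller's output.
    caller
        Caller name (e.g. ``"lumpy"``, ``"sniffles"``, ``"pairdist"``).
    technology
        Whether the caller consumed short or long reads.
    sv_type
        One of DEL/DUP/INS/INV.
    start, end
        1-based inclusive reference coordinates.  For INS, ``end == start``.
    length
        Interval span for DEL/DUP/INV; inserted-sequence length for INS.
    read_support
        Number of reads (or read pairs) supporting the call; >= 1.
    read_ids
        Optional identifiers of the supporting reads.
    source_frequency
        Optional caller-reported allele proportion in [0, 1].
    """

    id: str
    caller: str
    technology: Technology
    sv_type: SVType
    start: int
    end: int
    length: int
    read_support: int
    read_ids: list[str] | None = None
    source_frequency: float | None = None

    def __post_init__(self) -> None:
        self.technology = Technology(self.technology)
        self.sv_type = SVType(self.sv_type)
        if self.start < 1:
            raise ValueError(f"SV {self.id}: start must be >= 1, got {self.start}")
        if self.sv_type is SVType.INS:
            if self.end != self.start:
                raise ValueError(f"INS {self.id}: end must equal start")
            if self.length < 1:
                raise ValueError(f"INS {self.id}: length must be >= 1")
        elif self.end < self.start:
            raise ValueError(f"SV {self.id}: end < start")
        if self.read_support < 1:
            raise ValueError(f"SV {self.id}: read_support must be >= 1")

    @property
    def point(self) -> tuple[int, int]:
        """The (start, end) breakpoint pair used as the clustering feature.

        INS calls degenerate to ``(start, start)`` by construction.
        """
        return (self.start, self.end)


@dataclass
class CoverageTrack:
    """Per-base read depth over a (circular) viral genome."""

    genome_length: int
    depth: np.ndarray
    circular: bool = True

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape != (self.genome_length,):
            raise ValueError(
                f"depth has {self.depth.shape[0]} entries for a "
                f"{self.genome_length}-bp genome"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def depth_at(self, pos: int) -> int:
        """Depth at a 1-based position."""
        if not 1 <= pos <= self.genome_length:
            raise IndexError(f"position {pos} outside [1, {self.genome_length}]")
        return int(self.depth[pos - 1])

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())


FEATURE_KINDS = ("gene", "hr", "intergenic")


@dataclass(frozen=True)
class Feature:
    """One annotated genomic feature (gene, homologous region, or intergenic)."""

    feature_id: str
    kind: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.end < self.start or self.start < 1:
            raise ValueError(
                f"feature {self.feature_id}: invalid interval "
                f"{self.start}..{self.end}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def intergenic_complement(
    features: Sequence[Feature], genome_length: int
) -> list[Feature]:
    """Synthesize intergenic features as the complement of gene + hr intervals."""
    covered = sorted(
        (f.start, f.end) for f in features if f.kind in ("gene", "hr")
    )
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out: list[Feature] = []
    cursor = 1
    n = 1
    for s, e in merged:
        if s > cursor:
            out.append(Feature(f"intergenic_{n}", "intergenic", cursor, s - 1))
            n += 1
        cursor = max(cursor, e + 1)
    if cursor <= genome_length:
        out.append(Feature(f"intergenic_{n}", "intergenic", cursor, genome_length))
    return out


@dataclass
class GenomeAnnotation:
    """Feature annotation of one viral genome.

    ``features`` holds genes, homologous regions (hr) and the synthesized
    intergenic complement; together the three kinds tile [1, genome_length].
    """

    genome_length: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.feature_id} extends past genome end"
                )

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def genes(self) -> list[Feature]:
        return self.features_of("gene")

    def overlapping(self, start: int, end: int) -> list[Feature]:
        return [f for f in self.features if f.overlaps(start, end)]


TARGET_KINDS = ("virus", "host_te", "host_other")


@dataclass
class ReadAlignment:
    """One local alignment of a read against the virus or a host database."""

    read_id: str
    read_start: int
    read_end: int
    target_id: str
    target_kind: str
    target_start: int
    target_end: int
    strand: str
    score: float
    read_length: int

    def __post_init__(self) -> None:
        if self.target_kind not in TARGET_KINDS:
            raise ValueError(f"unknown target kind {self.target_kind!r}")
        if not 1 <= self.read_start <= self.read_end <= self.read_length:
            raise ValueError(
                f"{self.read_id}: read interval {self.read_start}.."
                f"{self.read_end} outside [1, {self.read_length}]"
            )
        if self.score < 0:
            raise ValueError("negative alignment score")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start + 1

    def read_overlap(self, other: "ReadAlignment") -> int:
        """Signed overlap of the two read intervals.

        Positive values are shared bases, zero means the intervals are
        adjacent, negative values the size of the gap between them.
        """
        return min(self.read_end, other.read_end) - max(
            self.read_start, other.read_start
        ) + 1


@dataclass
class SVCluster:
    """A group of SV calls merged into one consensus variant.

    Produced by the meta-clustering stage; a cluster that survives every
    filter is the pipeline's unit of reporting ("robust SV").  Consensus
    coordinates are rounded means over members and therefore always lie
    inside the members' coordinate hull.
    """

    members: list[SVCall]
    sv_type: SVType | None
    consensus_start: int
    consensus_end: int
    consensus_length: int
    retained: bool = False
    provenance: set = field(default_factory=set)
    frequency: float | None = None

    @classmethod
    def from_members(cls, members: Sequence[SVCall]) -> "SVCluster":
        if not members:
            raise ValueError("cluster needs at least one member")
        types = {m.sv_type for m in members}
        sv_type = types.pop() if len(types) == 1 else None
        return cls(
            members=list(members),
            sv_type=sv_type,
            consensus_start=round_half_up(
                sum(m.start for m in members) / len(members)
            ),
            consensus_end=round_half_up(
                sum(m.end for m in members) / len(members)
            ),
            consensus_length=round_half_up(
                sum(m.length for m in members) / len(members)
            ),
        )

    @property
    def callers(self) -> set[str]:
        return {m.caller for m in self.members}

    @property
    def technologies(self) -> set[Technology]:
        return {m.technology for m in self.members}

    @property
    def total_read_support(self) -> int:
        return sum(m.read_support for m in self.members)

    @property
    def long_read_support(self) -> int:
        return sum(
            m.read_support
            for m in self.members
            if m.technology is Technology.LONG
        )

    @property
    def n_callers(self) -> int:
        return len(self.callers)

    @property
    def support_for_frequency(self) -> int:
        """Read support used in frequency estimation.

        The mean of member supports, not the sum: members are redundant
        measurements of the same variant by different callers, so summing
        would count the same molecules several times.
        """
        if not self.members:
            return 0
        return round_half_up(
            sum(m.read_support for m in self.members) / len(self.members)
        )

    @property
    def read_ids(self) -> list[str]:
        out: list[str] = []
        for m in self.members:
            if m.read_ids:
                out.extend(m.read_ids)
        return out

    def identity_key(self) -> tuple[str, int, int, int]:
        """Exact-identity key used for deduplication across grid points."""
        t = self.sv_type.value if self.sv_type is not None else "MIXED"
        return (t, self.consensus_start, self.consensus_end, self.consensus_length)


#: Alias used where a cluster has survived all filters.
RobustSV = SVCluster
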