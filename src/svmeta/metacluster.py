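"""Meta-calling by multi-threshold hierarchical clustering of SV calls.

Calls from several independent callers describing the same biological
variant rarely agree exactly on breakpoints — error-prone long reads in
particular map approximately — so merging them needs a distance scale.
No single scale works: a tight threshold leaves one variant split across
single-caller clusters (which downstream support filters would discard),
a loose one lumps distinct nearby variants together (which the same-type
filter would discard).  The pipeline therefore clusters at every
threshold of a fixed grid — 14 distance cutoffs crossed with 22 minimum
read-support levels — keeps the clusters that pass the filters at each
grid point, takes the union, and removes exact duplicates.

Clusters survive only when all members share one SV type and the variant
has independent support: either both sequencing technologies
(``cross_technology``, possible when short and long reads are available —
library-construction chimeras do not reproduce across technologies) or at
least two distinct callers (``min_two_callers``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .models import RobustSV, SVCall, SVCluster, SVType, Technology

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_THRESHOLDS = (
    5, 10, 30, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
)
DEFAULT_MIN_READ_THRESHOLDS = (
    4, 5, 6, 7, 8, 9, 10, 20, 30, 40, 50, 100, 200, 300, 400, 500, 600,
    700, 800, 900, 1000, 1500,
)

SUPPORT_MODES = ("cross_technology", "min_two_callers")


@dataclass
class ClusteringGrid:
    """The distance x min-read-support threshold grid."""

    distance_thresholds: tuple = DEFAULT_DISTANCE_THRESHOLDS
    min_read_thresholds: tuple = DEFAULT_MIN_READ_THRESHOLDS

    def __post_init__(self) -> None:
        for name in ("distance_thresholds", "min_read_thresholds"):
            values = tuple(getattr(self, name))
            setattr(self, name, values)
            if any(b <= a for a, b in zip(values, values[1:])):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class ClusterPolicy:
    """Filtering constants applied around the clustering grid."""

    support_mode: str = "cross_technology"
    base_min_reads: int = 3
    min_sv_length: int = 50
    max_sv_length: int | None = None  # defaults to half the genome
    circular_min_long_reads: int = 20
    circular_min_callers: int = 3

    def __post_init__(self) -> None:
        if self.support_mode not in SUPPORT_MODES:
            raise ValueError(f"unknown support mode {self.support_mode!r}")
        if self.base_min_reads < 1 or self.min_sv_length < 1:
            raise ValueError("base_min_reads and min_sv_length must be >= 1")


def harmonize(calls: Sequence[SVCall], policy: ClusterPolicy) -> list[SVCall]:
    """Keep calls meeting the base read-support and minimum-length cutoffs."""
    return [
        c
        for c in calls
        if c.read_support >= policy.base_min_reads
        and c.length >= policy.min_sv_length
    ]


def cluster_at(calls: Sequence[SVCall], t: float) -> list[SVCluster]:
    """Flat clusters of calls at distance threshold ``t``.

    Each call is the 2-D point (start, end) — INS degenerates to
    (start, start) — clustered with Euclidean distances and Ward linkage;
    the dendrogram is cut at height ``t``.  Length and type are not
    distance features: type homogeneity is enforced by the filter stage
    instead.
    """
    if not calls:
        return []
    if t <= 0:
        raise ValueError("distance threshold must be positive")
    if len(calls) == 1:
        return [SVCluster.from_members(list(calls))]
    points = np.array([c.point for c in calls], dtype=float)
    link = linkage(points, method="ward")
    labels = fcluster(link, t=t, criterion="distance")
    by_label: dict[int, list[SVCall]] = {}
    for call, lab in zip(calls, labels):
        by_label.setdefault(int(lab), []).append(call)
    return [
        SVCluster.from_members(members)
        for _, members in sorted(by_label.items())
    ]


def filter_clusters(
    clusters: Sequence[SVCluster], policy: ClusterPolicy
) -> list[SVCluster]:
    """Retain clusters that are type-homogeneous and independently supported."""
    kept: list[SVCluster] = []
    for cluster in clusters:
        if cluster.sv_type is None:  # mixed types
            continue
        if policy.support_mode == "cross_technology":
            ok = {Technology.SHORT, Technology.LONG} <= cluster.technologies
        else:
            ok = cluster.n_callers >= 2
        if ok:
            cluster.retained = True
            kept.append(cluster)
    return kept


def run_grid(
    calls: Sequence[SVCall],
    grid: ClusteringGrid | None = None,
    policy: ClusterPolicy | None = None,
) -> list[RobustSV]:
    """Cluster-and-filter at every grid point and return the union.

    Support levels are the base cutoff plus the grid's 22 thresholds (the
    base round is itself one clustering round; the grid repeats it at
    stricter support).  Each surviving cluster records the (min-reads,
    distance) grid point that produced it; the union is deduplicated
    afterwards by :func:`dedupe`.
    """
    grid = grid or ClusteringGrid()
    policy = policy or ClusterPolicy()
    support_levels = sorted({policy.base_min_reads, *grid.min_read_thresholds})
    out: list[RobustSV] = []
    for r in support_levels:
        subset = [c for c in calls if c.read_support >= r]
        if not subset:
            continue
        for t in grid.distance_thresholds:
            for cluster in filter_clusters(cluster_at(subset, t), policy):
                cluster.provenance = {(r, t)}
                out.append(cluster)
    if not out:
        logger.info("no cluster survived any grid point")
    return out


def dedupe(svs: Sequence[RobustSV]) -> list[RobustSV]:
    """Collapse SVs with identical consensus (type, start, end, length).

    Identity is exact equality of the rounded consensus fields —
    coordinate-distinct near-duplicates are intentionally kept.  The
    representative at each identity is the one with the largest total
    support; provenance is merged.  Idempotent.
    """
    by_key: dict[tuple, RobustSV] = {}
    for sv in svs:
        key = sv.identity_key()
        best = by_key.get(key)
        if best is None:
            kept = SVCluster(
                members=list(sv.members),
                sv_type=sv.sv_type,
                consensus_start=sv.consensus_start,
                consensus_end=sv.consensus_end,
                consensus_length=sv.consensus_length,
                retained=sv.retained,
                provenance=set(sv.provenance),
                frequency=sv.frequency,
            )
            by_key[key] = kept
        else:
            if sv.total_read_support > best.total_read_support:
                best.members = list(sv.members)
            best.provenance |= sv.provenance
    return sorted(
        by_key.values(),
        key=lambda s: (
            s.consensus_start,
            s.consensus_end,
            s.sv_type.value if s.sv_type else "",
        ),
    )


def circular_filter(
    svs: Sequence[RobustSV],
    genome_length: int,
    policy: ClusterPolicy | None = None,
) -> list[RobustSV]:
    """Remove likely artifacts of genome circularity.

    Reads spanning the arbitrary linearization point of a circular genome
    masquerade as enormous SVs.  SVs longer than half the genome are kept
    only when both heavily supported by long reads and seen by several
    callers.
    """
    policy = policy or ClusterPolicy()
    half = genome_length / 2
    kept = []
    for sv in svs:
        if sv.consensus_length > half and (
            sv.long_read_support < policy.circular_min_long_reads
            or sv.n_callers < policy.circular_min_callers
        ):
            continue
        kept.append(sv)
    return kept


def near_linear_ends(
    sv: RobustSV, genome_length: int, read_length: int = 151
) -> bool:
    """Flag SVs with an endpoint within one read length of position 1 or L."""
    for pos in (sv.consensus_start, sv.consensus_end):
        if pos <= read_length or pos > genome_length - read_length:
            return True
    return False


def select_robust_subset(
    svs: Sequence[RobustSV], fraction: float = 0.0498
) -> list[RobustSV]:
    """The most robust ~4.98% of SVs, for short-read-only datasets.

    When long reads are unavailable the cross-technology filter cannot
    run; instead the analysis is restricted to the fraction of SVs,
    calibrated on a dataset with both technologies, that two callers
    support.  Target size is ``ceil(fraction * len(svs))``: if enough SVs
    have >= 2 callers, the k highest-frequency among them are returned;
    otherwise all two-caller SVs are topped up with the most frequent
    remaining SVs.  Ties break on higher support, then lower start.
    """
    if not svs:
        return []
    k = math.ceil(fraction * len(svs))

    def rank(sv: RobustSV):
        freq = sv.frequency if sv.frequency is not None else 0.0
        return (-freq, -sv.total_read_support, sv.consensus_start)

    two_caller = sorted((s for s in svs if s.n_callers >= 2), key=rank)
    if len(two_caller) >= k:
        return two_caller[:k]
    rest = sorted((s for s in svs if s.n_callers < 2), key=rank)
    return two_caller + rest[: k - len(two_caller)]
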