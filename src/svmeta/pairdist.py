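"""Read-pair distance deletion caller.

Large deletions leave a footprint in paired-end data: the two mates of a
pair straddling the deleted interval map farther apart on the reference
than the library insert size allows.  This module infers single-pair
deletion events from that excess distance and merges pairs supporting the
same event into consensus deletion calls.

Only inter-read distances longer than a conservative threshold (default
700 bp, far above the spread expected from a ~260-bp-insert library) are
treated as evidence; smaller deletions are left to other callers.  The
deleted interval is taken as ``[left inner end + 1, right inner start - 1]``,
the unique convention under which the event length equals the observed
excess gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .models import SVCall, SVType, Technology, round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mate:
    """One aligned mate of a read pair (1-based inclusive coordinates)."""

    ref_start: int
    ref_end: int
    strand: str = "+"
    reference: str = "genome"


@dataclass
class ReadPairObservation:
    """A mapped read pair, candidate evidence for a deletion."""

    pair_id: str
    left_mate: Mate
    right_mate: Mate


@dataclass
class LibraryModel:
    """Paired-end library geometry and the deletion-evidence threshold."""

    insert_mean: int = 260
    read_length: int = 151
    min_gap: int = 700
    insert_sd: float = 30.0

    def __post_init__(self) -> None:
        expected_inner = max(self.insert_mean - 2 * self.read_length, 0)
        if self.min_gap <= expected_inner:
            raise ValueError(
                "min_gap must exceed the inner gap expected from the insert size"
            )


class GapResult(NamedTuple):
    gap: int
    overlapping: bool


@dataclass
class DeletionEvent:
    """One inferred deletion interval with its supporting pairs."""

    start: int
    end: int
    length: int
    supporting_pairs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("deletion event with end < start")
        if self.length != self.end - self.start + 1:
            raise ValueError("deletion length must equal its span")


def infer_gap(pair: ReadPairObservation) -> GapResult | None:
    """Inner distance between the two mates of a pair.

    Returns ``None`` when the mates map to different references (not a
    deletion candidate).  Overlapping mates — the norm for a 260-bp insert
    with 151-bp reads — clamp to gap 0 with the overlap flag set.
    """
    if pair.left_mate.reference != pair.right_mate.reference:
        return None
    gap = pair.right_mate.ref_start - pair.left_mate.ref_end - 1
    if gap < 0:
        return GapResult(0, True)
    return GapResult(gap, False)


def _is_fr(pair: ReadPairObservation) -> bool:
    return pair.left_mate.strand == "+" and pair.right_mate.strand == "-"


def call_pair_deletions(
    pairs: Sequence[ReadPairObservation],
    model: LibraryModel,
    collapse_duplicates: bool = False,
) -> list[DeletionEvent]:
    """One single-pair deletion event per pair with gap above the threshold.

    Non-FR pairs are excluded (other orientations signal SV types this
    caller does not handle).  ``collapse_duplicates`` keeps only one
    event per distinct inner-coordinate pair; it is off by default
    because in an overlapping-mate library genuinely distinct fragments
    spanning the same junction routinely share inner coordinates, so the
    collapse systematically undercounts support.  The collapse is logged
    when enabled.
    """
    events: list[DeletionEvent] = []
    seen: set[tuple[int, int]] = set()
    n_dupes = 0
    for pair in pairs:
        if not _is_fr(pair):
            continue
        result = infer_gap(pair)
        if result is None or result.gap <= model.min_gap:
            continue
        start = pair.left_mate.ref_end + 1
        end = pair.right_mate.ref_start - 1
        if collapse_duplicates:
            key = (start, end)
            if key in seen:
                n_dupes += 1
                continue
            seen.add(key)
        events.append(
            DeletionEvent(
                start=start, end=end, length=end - start + 1,
                supporting_pairs=[pair.pair_id],
            )
        )
    if n_dupes:
        logger.info("collapsed %d duplicate pair coordinates", n_dupes)
    return events


def _split_by_spread(
    indices: list[int], events: Sequence[DeletionEvent], max_spread: int
) -> list[list[int]]:
    """Split a group so start and end ranges both stay within max_spread."""
    ordered = sorted(indices, key=lambda i: (events[i].start, events[i].end))
    groups: list[list[int]] = []
    for i in ordered:
        if groups:
            g = groups[-1]
            starts = [events[j].start for j in g] + [events[i].start]
            ends = [events[j].end for j in g] + [events[i].end]
            if (
                max(starts) - min(starts) <= max_spread
                and max(ends) - min(ends) <= max_spread
            ):
                g.append(i)
                continue
        groups.append([i])
    return groups


def _merge_within_spread(
    groups: list[list[int]], events: Sequence[DeletionEvent], max_spread: int
) -> list[list[int]]:
    """Greedily merge groups while start and end ranges stay within bounds.

    The spread window is the defining constraint of a deletion event; the
    hierarchical step provides structure, but a tree cut can leave a
    genuine event split across flat clusters, so the final partition is
    the maximal merging compatible with the window (tightest pairs first).
    """

    def union_spread(a: list[int], b: list[int]) -> tuple[int, int]:
        starts = [events[i].start for i in a + b]
        ends = [events[i].end for i in a + b]
        return (max(starts) - min(starts), max(ends) - min(ends))

    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ds, de = union_spread(groups[i], groups[j])
                if ds <= max_spread and de <= max_spread:
                    cand = (max(ds, de), ds + de, i, j)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            break
        _, _, i, j = best
        groups[i] = groups[i] + groups[j]
        del groups[j]
    return groups


def cluster_deletion_events(
    events: Sequence[DeletionEvent],
    max_spread: int = 7,
    inconsistency_depth: int = 2,
    inconsistency_threshold: float = 1.15,
) -> list[SVCall]:
    """Merge single-pair events into consensus deletion calls.

    Events are points ``(start, end)``; agglomerative clustering with
    Euclidean distances and Ward linkage builds the tree, which is cut by
    the inconsistency criterion (depth and coefficient threshold
    configurable since no universal default exists).  Groups are then
    split further so that neither the start nor the end range exceeds
    ``max_spread`` (default 7 bp).  Each group becomes one DEL call with
    mean coordinates and the number of supporting pairs as read support.
    """
    if not events:
        return []
    if len(events) == 1:
        groups = [[0]]
    else:
        points = np.array([(e.start, e.end) for e in events], dtype=float)
        link = linkage(points, method="ward")
        labels = fcluster(
            link,
            t=inconsistency_threshold,
            criterion="inconsistent",
            depth=inconsistency_depth,
        )
        by_label: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            by_label.setdefault(int(lab), []).append(i)
        groups = []
        for indices in by_label.values():
            groups.extend(_split_by_spread(indices, events, max_spread))
        groups = _merge_within_spread(groups, events, max_spread)

    calls: list[SVCall] = []
    groups.sort(key=lambda g: min(events[i].start for i in g))
    for k, group in enumerate(groups, start=1):
        members = [events[i] for i in group]
        pair_ids = [p for e in members for p in e.supporting_pairs]
        calls.append(
            SVCall(
                id=f"pairdist_del_{k}",
                caller="pairdist",
                technology=Technology.SHORT,
                sv_type=SVType.DEL,
                start=round_half_up(sum(e.start for e in members) / len(members)),
                end=round_half_up(sum(e.end for e in members) / len(members)),
                length=round_half_up(sum(e.length for e in members) / len(members)),
                read_support=len(pair_ids),
                read_ids=pair_ids,
            )
        )
    return calls
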