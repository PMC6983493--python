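"""Detection of host transposable-element sequences in viral reads.

Short 151-bp reads reveal TE insertions as virus-host chimeric junctions:
a read aligning partly (and exclusively) to the viral genome and partly
(and exclusively) to a host TE.  Long reads can contain a whole TE copy,
so overlapping database hits are resolved to the best-scoring one and the
covered fraction of the TE consensus classifies each copy as full-length
or truncated.  Truncated copies that begin or terminate their read are of
special interest — an excess of them over the proportion expected from
sequence content alone (tested with an exact binomial test) suggests
linearized viral genomes ending in aborted-transposition scars.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom

from .models import ReadAlignment


@dataclass
class ChimericJunction:
    """A virus-host junction located within one short read."""

    read_id: str
    virus_segment: ReadAlignment
    host_segment: ReadAlignment
    overlap: int
    superfamily: str | None = None

    @property
    def duplicate_key(self) -> tuple:
        """Key identifying PCR duplicates: genome-side breakpoints + orientation.

        Reads amplified from one ligation molecule share the virus
        breakpoint, the host element breakpoint and the orientation, even
        if trimming shifted the read window.
        """
        v, h = self.virus_segment, self.host_segment
        virus_first = v.read_start <= h.read_start
        if virus_first:
            vbp = v.target_end if v.strand == "+" else v.target_start
            hbp = h.target_start if h.strand == "+" else h.target_end
        else:
            vbp = v.target_start if v.strand == "+" else v.target_end
            hbp = h.target_end if h.strand == "+" else h.target_start
        return (vbp, h.target_id, hbp, virus_first, v.strand, h.strand)


@dataclass
class TEInsertion:
    """A TE segment located in one (long) read."""

    read_id: str
    superfamily: str
    te_class: str  # "I" (retro) or "II" (DNA)
    read_start: int
    read_end: int
    read_length: int
    consensus_fraction: float | None = None
    completeness: str | None = None

    def __post_init__(self) -> None:
        if self.consensus_fraction is not None:
            if not 0 < self.consensus_fraction:
                raise ValueError("consensus_fraction must be positive")
            self.consensus_fraction = min(self.consensus_fraction, 1.0)

    @property
    def at_read_end(self) -> bool:
        """True when the TE interval touches read position 1 or the last base."""
        return self.read_start == 1 or self.read_end == self.read_length


@dataclass
class EnrichmentTest:
    """Exact binomial test of TE-at-read-end enrichment."""

    k: int
    n: int
    p0: float
    p_value: float


def detect_junctions(
    alignments: Sequence[ReadAlignment],
    min_seg: int = 16,
    min_total: int = 130,
    overlap_window: tuple[int, int] = (-5, 20),
    superfamily_map: Mapping[str, str] | None = None,
) -> list[ChimericJunction]:
    """Find virus-host junctions in short-read alignments.

    A read yields a junction when it has a virus-exclusive stretch of at
    least ``min_seg`` bp and a host-exclusive stretch of at least
    ``min_seg`` bp, its combined aligned length reaches ``min_total`` bp,
    and the signed overlap between the two read intervals (positive =
    shared bases, negative = unaligned micro-gap) lies inside
    ``overlap_window``.  At most one junction — the one with the largest
    aligned span, ties broken by score then coordinates — is emitted per
    read, so output is independent of alignment order.
    """
    superfamily_map = superfamily_map or {}
    lo, hi = overlap_window
    by_read: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)

    junctions: list[ChimericJunction] = []
    for read_id in sorted(by_read):
        hits = by_read[read_id]
        virus = [a for a in hits if a.target_kind == "virus"]
        host = [a for a in hits if a.target_kind != "virus"]
        best: tuple | None = None
        for v in virus:
            for h in host:
                ov = v.read_overlap(h)
                shared = max(ov, 0)
                virus_only = v.read_span - shared
                host_only = h.read_span - shared
                total = v.read_span + h.read_span - shared
                if (
                    virus_only >= min_seg
                    and host_only >= min_seg
                    and total >= min_total
                    and lo <= ov <= hi
                ):
                    rank = (
                        total,
                        v.score + h.score,
                        -v.read_start,
                        -h.read_start,
                        h.target_id,
                    )
                    if best is None or rank > best[0]:
                        best = (rank, v, h, ov)
        if best is not None:
            _, v, h, ov = best
            junctions.append(
                ChimericJunction(
                    read_id=read_id,
                    virus_segment=v,
                    host_segment=h,
                    overlap=ov,
                    superfamily=superfamily_map.get(h.target_id),
                )
            )
    return junctions


def dedupe_pcr(
    junctions: Sequence[ChimericJunction],
) -> tuple[list[ChimericJunction], int]:
    """Collapse PCR duplicates; returns (unique junctions, total count)."""
    seen: set[tuple] = set()
    unique: list[ChimericJunction] = []
    for j in junctions:
        key = j.duplicate_key
        if key not in seen:
            seen.add(key)
            unique.append(j)
    return unique, len(junctions)


def build_te_table(
    unique_counts: Mapping[str, int],
    total_counts: Mapping[str, int],
    frequencies: Mapping[str, float],
) -> pd.DataFrame:
    """Per-superfamily junction counts and insertion frequencies, with totals.

    Rows are sorted by unique-read count descending; the Total row holds
    column sums (the total insertion frequency is the sum of per-family
    frequencies, each family being an independent contribution).
    """
    rows = [
        {
            "superfamily": sf,
            "unique_reads": int(unique_counts[sf]),
            "reads_with_duplicates": int(total_counts.get(sf, unique_counts[sf])),
            "insertion_frequency_pct": float(frequencies.get(sf, 0.0)),
        }
        for sf in unique_counts
    ]
    rows.sort(key=lambda r: (-r["unique_reads"], r["superfamily"]))
    rows.append(
        {
            "superfamily": "Total",
            "unique_reads": sum(r["unique_reads"] for r in rows),
            "reads_with_duplicates": sum(r["reads_with_duplicates"] for r in rows),
            "insertion_frequency_pct": sum(
                r["insertion_frequency_pct"] for r in rows
            ),
        }
    )
    return pd.DataFrame(rows)


def te_insertion_frequency(unique_reads: int, mean_depth: float) -> float:
    """Default per-superfamily insertion frequency, as a percentage.

    Unique junction reads over (unique junction reads + mean genome
    depth) — the same reads-vs-reference logic as SV frequencies.  This
    is an explicit stand-in: published tables of this kind do not state
    their formula, so it is exposed for replacement.
    """
    if mean_depth < 0:
        raise ValueError("negative depth")
    if unique_reads == 0:
        return 0.0
    return 100.0 * unique_reads / (unique_reads + mean_depth)


def resolve_long_read_hits(
    hits: Sequence[ReadAlignment],
) -> list[ReadAlignment]:
    """Resolve overlapping database hits of one long read.

    Among mutually overlapping read intervals only the best-score hit
    survives (ties: lower read start, then lexicographic target id);
    non-overlapping hits all survive.  Output intervals are pairwise
    non-overlapping, sorted by read start.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, h.read_start, h.target_id))
    kept: list[ReadAlignment] = []
    for h in ordered:
        if all(
            h.read_end < k.read_start or k.read_end < h.read_start
            for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.read_start)
    return kept


def validate_chimera_flanks(
    kept_hits: Sequence[ReadAlignment],
    virus_hits: Sequence[ReadAlignment],
    min_seg: int = 16,
) -> bool:
    """True when read regions outside the host hits align to the virus.

    Confirms the host/virus chimeric nature of a long read: at least one
    virus alignment must contribute ``min_seg`` bp not covered by any
    retained host hit.
    """
    for v in virus_hits:
        exclusive = v.read_span
        for h in kept_hits:
            ov = v.read_overlap(h)
            if ov > 0:
                exclusive -= ov
        if exclusive >= min_seg:
            return True
    return False


def classify_completeness(
    insertion: TEInsertion, min_fraction: float = 0.95
) -> str | None:
    """Classify a TE copy as full-length or truncated.

    Full when the covered fraction of the TE consensus reaches
    ``min_fraction`` (boundary inclusive).  Returns ``None`` when the
    consensus length is unknown, leaving the classification withheld.
    """
    if insertion.consensus_fraction is None:
        insertion.completeness = None
        return None
    cls = "full" if insertion.consensus_fraction >= min_fraction else "truncated"
    insertion.completeness = cls
    return cls


def end_enrichment_test(
    insertions: Sequence[TEInsertion],
    total_read_bp: int,
    total_te_bp: int,
) -> EnrichmentTest:
    """Exact upper-tail binomial test for TE enrichment at read ends.

    The expected at-end proportion ``p0`` is total TE bases over total
    read bases; the p-value is P(X >= k) for X ~ Binomial(n, p0), where k
    counts TE segments touching a read end among the n segments found.
    """
    n = len(insertions)
    if n < 1:
        raise ValueError("need at least one TE segment")
    p0 = total_te_bp / total_read_bp
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"expected proportion {p0} outside (0, 1)")
    k = sum(1 for ins in insertions if ins.at_read_end)
    p_value = float(binom.sf(k - 1, n, p0))
    return EnrichmentTest(k=k, n=n, p0=p0, p_value=p_value)
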