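"""Per-SV frequency, Poisson genome burden, and population summaries.

The frequency of an SV in a virus population is estimated the way SNP
frequencies are: supporting reads over (supporting reads + reference
reads) at the variant position, with reference depth taken from a
per-base coverage track at the breakpoints.

With per-SV frequencies in hand, the fraction of genomes carrying at
least one variant follows from a Poisson model of the per-genome SV
count: with rate lambda equal to the sum of SV frequencies, the burdened
fraction is ``1 - exp(-lambda)``.  Per-type fractions combine to the
total burden as ``1 - prod(1 - f_type)``, which is algebraically the same
quantity — an identity exploited both as a self-check and to reconstruct
total burdens from published per-type values.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    CoverageTrack,
    Feature,
    GenomeAnnotation,
    RobustSV,
    SVCall,
    SVCluster,
    SVType,
)


@dataclass
class FrequencyEstimate:
    """Estimated proportion of genomes carrying one SV."""

    sv_id: str
    f: float
    sv_support: int
    ref_coverage: float
    undefined: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("frequency outside [0, 1]")


def sv_frequency(
    sv: RobustSV | SVCall,
    coverage: CoverageTrack,
    sv_id: str | None = None,
) -> FrequencyEstimate:
    """Estimate an SV's population frequency from breakpoint coverage.

    Reference coverage is the mean per-base depth at the two breakpoint
    positions (the single insertion point for INS) — the quantity directly
    comparable to breakpoint-supporting reads.  Frequency is
    ``support / (support + ref)``; zero support gives frequency 0, and
    zero support with zero coverage is reported as 0 with the undefined
    flag set.
    """
    if isinstance(sv, SVCluster):
        support = sv.support_for_frequency
        start, end = sv.consensus_start, sv.consensus_end
        svtype = sv.sv_type
        ident = sv_id or f"{svtype.value if svtype else 'SV'}_{start}_{end}"
    else:
        support = sv.read_support
        start, end = sv.start, sv.end
        ident = sv_id or sv.id
        svtype = sv.sv_type
    positions = [start] if (svtype is SVType.INS or start == end) else [start, end]
    ref = float(np.mean([coverage.depth_at(p) for p in positions]))
    if support == 0:
        return FrequencyEstimate(ident, 0.0, 0, ref, undefined=(ref == 0))
    return FrequencyEstimate(ident, support / (support + ref), support, ref)


def burden_fraction(frequencies: Iterable[float]) -> float:
    """Fraction of genomes carrying >= 1 SV under the Poisson model.

    ``lambda`` is the sum of per-SV frequencies; the result is
    ``1 - exp(-lambda)``.  Frequencies must lie in [0, 1): a frequency of
    one makes the Poisson rate for that variant undefined.
    """
    lam = 0.0
    for f in frequencies:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"frequency {f} outside [0, 1)")
        lam += f
    return 1.0 - math.exp(-lam)


def combine_type_fractions(fractions: Iterable[float]) -> float:
    """Combine per-type burdened fractions into the total burden.

    Returns ``1 - prod(1 - f)``, identical to :func:`burden_fraction`
    applied to the pooled Poisson rates.  A fraction of exactly 1 gives 1.
    """
    out = 1.0
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
        out *= 1.0 - f
    return 1.0 - out


@dataclass(frozen=True)
class GeneImpact:
    """Classification of one (SV, overlapped gene) pair."""

    sv_id: str
    feature_id: str
    classification: str  # "inactivating" | "non_inactivating"


def classify_gene_impact(sv: RobustSV | SVCall, gene: Feature) -> GeneImpact:
    """Classify an SV overlapping a gene as inactivating or not.

    A deletion removing any part of the gene truncates it, as does any SV
    placing a breakpoint strictly inside the gene body.  Only SVs that
    span the gene completely (both breakpoints outside) leave its coding
    capacity intact.
    """
    if isinstance(sv, SVCluster):
        start, end = sv.consensus_start, sv.consensus_end
        svtype = sv.sv_type
        ident = f"{svtype.value if svtype else 'SV'}_{start}_{end}"
    else:
        start, end, svtype, ident = sv.start, sv.end, sv.sv_type, sv.id
    if not (start <= gene.end and gene.start <= end):
        raise ValueError(f"SV {ident} does not overlap gene {gene.feature_id}")
    if svtype is SVType.DEL:
        cls = "inactivating"
    else:
        inside = {
            p for p in {start, end} if gene.start < p < gene.end
        }
        cls = "inactivating" if inside else "non_inactivating"
    return GeneImpact(ident, gene.feature_id, cls)


@dataclass
class SummaryRow:
    count: int
    lam: float
    fraction: float
    min_length: int
    mean_length: float
    max_length: int


@dataclass
class PopulationSummary:
    """Per-type and total SV counts, burdens and length statistics."""

    per_type: dict[str, SummaryRow]
    total: SummaryRow
    feature_burden: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in [t.value for t in SVType] + ["Total"]:
            row = self.total if name == "Total" else self.per_type[name]
            rows.append(
                {
                    "sv_type": name,
                    "n_svs": row.count,
                    "frequency_pct": round(100 * row.fraction, 2),
                    "min_length_bp": row.min_length,
                    "mean_length_bp": round(row.mean_length),
                    "max_length_bp": row.max_length,
                }
            )
        return pd.DataFrame(rows)


def _row(svs: Sequence[RobustSV], freqs: Sequence[float]) -> SummaryRow:
    lengths = [sv.consensus_length for sv in svs]
    lam = float(sum(freqs))
    return SummaryRow(
        count=len(svs),
        lam=lam,
        fraction=1.0 - math.exp(-lam),
        min_length=min(lengths) if lengths else 0,
        mean_length=float(np.mean(lengths)) if lengths else 0.0,
        max_length=max(lengths) if lengths else 0,
    )


def summarize(
    svs: Sequence[RobustSV],
    freqs: Sequence[FrequencyEstimate],
    annotation: GenomeAnnotation | None = None,
) -> PopulationSummary:
    """Build the per-type/total summary table and per-feature-kind burdens."""
    if len(svs) != len(freqs):
        raise ValueError("one frequency per SV required")
    per_type: dict[str, SummaryRow] = {}
    for t in SVType:
        sel = [
            (sv, fe.f) for sv, fe in zip(svs, freqs) if sv.sv_type is t
        ]
        per_type[t.value] = _row([s for s, _ in sel], [f for _, f in sel])
    total = _row(list(svs), [fe.f for fe in freqs])

    feature_burden: dict[str, float] = {}
    if annotation is not None:
        for kind in ("gene", "hr", "intergenic"):
            kind_features = annotation.features_of(kind)
            lam = 0.0
            for sv, fe in zip(svs, freqs):
                if any(
                    f.overlaps(sv.consensus_start, sv.consensus_end)
                    for f in kind_features
                ):
                    lam += fe.f
            feature_burden[kind] = 1.0 - math.exp(-lam)
    return PopulationSummary(per_type=per_type, total=total, feature_burden=feature_burden)


def multi_sv_reads(
    read_to_svs: Mapping[str, Sequence[tuple[str, int, int]]],
) -> tuple[dict[int, int], list[tuple[str, str, str]]]:
    """SVs-per-read histogram and nested-SV flags.

    ``read_to_svs`` maps a read id to the (sv_id, start, end) triples it
    supports.  Returns the histogram ``{n_svs: n_reads}`` and the list of
    (read_id, sv_a, sv_b) pairs whose intervals overlap on one read —
    evidence of nested SVs on a single genome molecule.
    """
    histogram: Counter = Counter()
    nested: list[tuple[str, str, str]] = []
    for read_id, svs in read_to_svs.items():
        histogram[len(svs)] += 1
        for i in range(len(svs)):
            for j in range(i + 1, len(svs)):
                a, b = svs[i], svs[j]
                if a[1] <= b[2] and b[1] <= a[2]:
                    nested.append((read_id, a[0], b[0]))
    return dict(histogram), nested


def shared_svs(
    a: Sequence[RobustSV], b: Sequence[RobustSV], tol: int = 10
) -> list[tuple[RobustSV, RobustSV]]:
    """SVs common to two populations, by greedy nearest-first matching.

    Two SVs match when they share a type and both breakpoints differ by
    at most ``tol`` bp; each SV matches at most once.  The tolerance is an
    explicit parameter because cross-population SV identity has no
    canonical definition.
    """
    candidates = []
    for i, sa in enumerate(a):
        for j, sb in enumerate(b):
            if sa.sv_type is not sb.sv_type:
                continue
            ds = abs(sa.consensus_start - sb.consensus_start)
            de = abs(sa.consensus_end - sb.consensus_end)
            if ds <= tol and de <= tol:
                candidates.append((math.hypot(ds, de), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((a[i], b[j]))
    return matched
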