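"""Synthetic inputs with known truth for every pipeline stage.

The generator emulates the study conditions the pipeline was built for —
a circular ~50-134 kb dsDNA virus genome sequenced very deep with a
short-read paired library plus long reads, SVs segregating mostly at very
low per-genome frequency, per-caller call sets with caller-specific
breakpoint jitter and sensitivity, library-chimera artifacts confined to
one technology, and host TE segments in reads — at desk scale, so that
recovery of planted truth is testable in seconds.

Everything is driven by :class:`numpy.random.Generator` seeds and is
fully deterministic; each generated object is auditable through the
returned truth structures and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .models import (
    CoverageTrack,
    Feature,
    GenomeAnnotation,
    ReadAlignment,
    SVCall,
    SVType,
    Technology,
    intergenic_complement,
    round_half_up,
)
from .pairdist import LibraryModel, Mate, ReadPairObservation

#: Planted SV counts per type; deletions dominate, as they do in defective
#: viral genome populations.
DEFAULT_SV_COUNTS: dict[str, int] = {"DEL": 40, "INV": 30, "DUP": 20, "INS": 10}

#: Log-uniform per-genome frequency range.  Most variants land below 1e-2,
#: mirroring the very-low-frequency regime of real virus populations.
DEFAULT_FREQ_RANGE: tuple[float, float] = (1e-4, 0.05)


@dataclass(frozen=True)
class CallerProfile:
    """Behavioural profile of one emulated SV caller.

    ``jitter_sd`` is the standard deviation (bp) of reported breakpoints
    around truth; long-read callers jitter more because error-prone long
    reads map only approximately.  ``sensitivity`` is the per-SV detection
    probability on top of read-support sampling; at the very deep coverage
    emulated here, callers miss variants mainly through support sampling,
    so the residual dropout is small.  ``fp_rate`` is the expected number
    of false calls per unit of depth.
    """

    name: str
    technology: Technology
    sensitivity: float = 0.95
    jitter_sd: float = 2.0
    fp_rate: float = 0.002
    supported_types: tuple = ("DEL", "DUP", "INS", "INV")

    def __post_init__(self) -> None:
        if not 0 < self.sensitivity <= 1:
            raise ValueError("sensitivity must be in (0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def default_profiles() -> list[CallerProfile]:
    """Four short-read and two long-read caller profiles."""
    short = Technology.SHORT
    long_ = Technology.LONG
    return [
        CallerProfile("pindel", short, jitter_sd=2.0),
        CallerProfile("lumpy", short, jitter_sd=2.0,
                      supported_types=("DEL", "DUP", "INV")),
        CallerProfile("fermikit", short, jitter_sd=2.0),
        CallerProfile("pairdist", short, jitter_sd=2.0,
                      supported_types=("DEL",)),
        CallerProfile("sniffles", long_, jitter_sd=15.0),
        CallerProfile("pbhoney", long_, jitter_sd=15.0),
    ]


@dataclass(frozen=True)
class PlantedSV:
    sv_type: SVType
    start: int
    end: int
    length: int
    frequency: float


@dataclass(frozen=True)
class PlantedTE:
    element_id: str
    superfamily: str
    te_class: str
    consensus_length: int
    completeness: str  # "full" | "truncated"
    at_read_end: bool = False
    truncated_fraction: float = 1.0
    rule_violating: bool = False


@dataclass
class TruthSet:
    """Everything planted into one synthetic dataset."""

    genome_length: int
    annotation: GenomeAnnotation
    planted_svs: list[PlantedSV] = field(default_factory=list)
    planted_tes: list[PlantedTE] = field(default_factory=list)
    depth: int = 2000
    seed: int = 0
    sequence: str | None = None


def make_genome(
    length: int = 50_000, seed: int = 0
) -> tuple[str, GenomeAnnotation]:
    """Random circular genome with tiled ~1-kb genes and hr-like repeats.

    Genes alternate with short intergenic gaps; every eighth feature slot
    holds a 300-bp repeat region standing in for a homologous region (hr).
    Gene, hr and intergenic features partition every base exactly once.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    sequence = "".join(alphabet[rng.integers(0, 4, size=length)])

    features: list[Feature] = []
    pos = 1
    slot = 0
    gene_n = 0
    hr_n = 0
    while True:
        gap = int(rng.integers(100, 200))
        pos += gap
        slot += 1
        if slot % 8 == 0:
            span = 300
        else:
            span = int(rng.integers(800, 1200))
        if pos + span - 1 > length - 100:
            break
        if slot % 8 == 0:
            hr_n += 1
            features.append(Feature(f"hr{hr_n}", "hr", pos, pos + span - 1))
        else:
            gene_n += 1
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(f"gene{gene_n:03d}", "gene", pos, pos + span - 1, strand)
            )
        pos += span
    features.extend(intergenic_complement(features, length))
    features.sort(key=lambda f: (f.start, f.end))
    return sequence, GenomeAnnotation(genome_length=length, features=features)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def plant_svs(
    annotation: GenomeAnnotation,
    counts: Mapping[str, int] | None = None,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    depth: int = 2000,
    seed: int = 0,
    sequence: str | None = None,
) -> TruthSet:
    """Plant SVs with log-uniform lengths and frequencies.

    Interval lengths run from 50 bp (the pipeline's minimum size cutoff)
    up to half the genome; insertions get 50-3000 bp of inserted sequence.
    Coordinates are drawn uniformly, pairwise non-identical.
    """
    counts = dict(DEFAULT_SV_COUNTS if counts is None else counts)
    lo, hi = freq_range
    if not (0 < lo < hi <= 0.1):
        raise ValueError("freq_range must satisfy 0 < lo < hi <= 0.1")
    rng = np.random.default_rng(seed)
    L = annotation.genome_length
    max_len = L // 2
    planted: list[PlantedSV] = []
    seen: set[tuple] = set()
    for type_name in sorted(counts):
        n = counts[type_name]
        if n < 0:
            raise ValueError("counts must be >= 0")
        svtype = SVType(type_name)
        for _ in range(n):
            for _attempt in range(1000):
                if svtype is SVType.INS:
                    length = round_half_up(_log_uniform(rng, 50, 3000))
                    start = int(rng.integers(1, L + 1))
                    end = start
                else:
                    length = round_half_up(_log_uniform(rng, 50, max_len))
                    length = min(max(length, 50), max_len)
                    start = int(rng.integers(1, L - length + 2))
                    end = start + length - 1
                key = (type_name, start, end)
                if key not in seen:
                    seen.add(key)
                    break
            else:
                raise ValueError("could not place planted SVs without collision")
            planted.append(
                PlantedSV(
                    sv_type=svtype,
                    start=start,
                    end=end,
                    length=length,
                    frequency=_log_uniform(rng, lo, hi),
                )
            )
    return TruthSet(
        genome_length=L,
        annotation=annotation,
        planted_svs=planted,
        depth=depth,
        seed=seed,
        sequence=sequence,
    )


def _jitter_call(
    sv: PlantedSV, profile: CallerProfile, L: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    js = profile.jitter_sd
    if js == 0:
        return sv.start, sv.end, sv.length
    ds = round_half_up(float(rng.normal(0, js)))
    start = min(max(sv.start + ds, 1), L)
    if sv.sv_type is SVType.INS:
        dl = round_half_up(float(rng.normal(0, js)))
        return start, start, max(sv.length + dl, 1)
    de = round_half_up(float(rng.normal(0, js)))
    end = min(max(sv.end + de, start), L)
    return start, end, end - start + 1


def simulate_caller_outputs(
    truth: TruthSet,
    profiles: Sequence[CallerProfile] | None = None,
    depth: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[SVCall]], CoverageTrack]:
    """Emulate per-caller call sets and the per-base coverage track.

    Each caller detects each planted SV of a supported type with its
    profile sensitivity, provided the binomially sampled read support
    (``Binomial(depth, frequency)``) is at least 1.  Reported breakpoints
    are truth plus rounded Gaussian jitter.  False calls arrive at
    ``fp_rate * depth`` per caller with random coordinates and low
    support.  The coverage track is flat at ``depth`` with binomially
    reduced depth inside planted deletions.
    """
    profiles = list(profiles) if profiles is not None else default_profiles()
    depth = depth if depth is not None else truth.depth
    rng = np.random.default_rng(seed)
    L = truth.genome_length

    calls: dict[str, list[SVCall]] = {p.name: [] for p in profiles}
    for profile in profiles:
        n = 0
        for i, sv in enumerate(truth.planted_svs):
            if sv.sv_type.value not in profile.supported_types:
                continue
            detected = rng.random() < profile.sensitivity
            support = int(rng.binomial(depth, sv.frequency))
            if not detected or support < 1:
                continue
            n += 1
            start, end, length = _jitter_call(sv, profile, L, rng)
            read_ids = None
            if profile.technology is Technology.LONG:
                read_ids = [f"{profile.name}_sv{i}_r{k}" for k in range(support)]
            calls[profile.name].append(
                SVCall(
                    id=f"{profile.name}_{n}",
                    caller=profile.name,
                    technology=profile.technology,
                    sv_type=sv.sv_type,
                    start=start,
                    end=end,
                    length=length,
                    read_support=support,
                    read_ids=read_ids,
                )
            )
        n_fp = int(rng.poisson(profile.fp_rate * depth))
        for k in range(n_fp):
            svtype = SVType(
                profile.supported_types[rng.integers(0, len(profile.supported_types))]
            )
            if svtype is SVType.INS:
                start = int(rng.integers(1, L + 1))
                end = start
                length = int(rng.integers(50, 500))
            else:
                length = int(rng.integers(50, L // 2))
                start = int(rng.integers(1, L - length + 2))
                end = start + length - 1
            calls[profile.name].append(
                SVCall(
                    id=f"{profile.name}_fp_{k}",
                    caller=profile.name,
                    technology=profile.technology,
                    sv_type=svtype,
                    start=start,
                    end=end,
                    length=length,
                    read_support=int(rng.integers(1, 4)),
                )
            )

    cov = np.full(L, depth, dtype=np.int64)
    for sv in truth.planted_svs:
        if sv.sv_type is SVType.DEL:
            lost = int(rng.binomial(depth, sv.frequency))
            cov[sv.start - 1 : sv.end] = np.maximum(
                cov[sv.start - 1 : sv.end] - lost, 0
            )
    return calls, CoverageTrack(genome_length=L, depth=cov)


def simulate_read_pairs(
    truth: TruthSet,
    library: LibraryModel | None = None,
    depth: int | None = None,
    n_background: int = 2000,
    seed: int = 0,
) -> list[ReadPairObservation]:
    """Paired-end reads from the planted genome population.

    Background pairs follow the insert model (no pair exceeds the
    deletion-evidence threshold except a vanishing Gaussian tail).  Each
    planted deletion contributes ``Binomial(depth, frequency)`` spanning
    pairs whose inner gap is inflated by the deletion length.
    """
    library = library or LibraryModel()
    depth = depth if depth is not None else truth.depth
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    rl = library.read_length
    pairs: list[ReadPairObservation] = []

    def draw_insert() -> int:
        return max(int(round(rng.normal(library.insert_mean, library.insert_sd))), rl + 1)

    for j in range(n_background):
        insert = draw_insert()
        left_start = int(rng.integers(1, max(L - insert, 2)))
        right_start = left_start + insert - rl
        pairs.append(
            ReadPairObservation(
                pair_id=f"bg_{j}",
                left_mate=Mate(left_start, left_start + rl - 1, "+"),
                right_mate=Mate(right_start, right_start + rl - 1, "-"),
            )
        )

    for i, sv in enumerate(truth.planted_svs):
        if sv.sv_type is not SVType.DEL:
            continue
        n_span = int(rng.binomial(depth, sv.frequency))
        for j in range(n_span):
            # Only fragments longer than two read lengths can place the
            # junction between the mates; condition on that tail.
            insert = draw_insert()
            while insert <= 2 * rl:
                insert = draw_insert()
            inner = insert - 2 * rl
            e1 = int(rng.integers(0, inner + 1))
            e2 = inner - e1
            left_end = sv.start - 1 - e1
            right_start = sv.end + 1 + e2
            left_start = left_end - rl + 1
            if left_start < 1 or right_start + rl - 1 > L:
                continue
            pairs.append(
                ReadPairObservation(
                    pair_id=f"del{i}_p{j}",
                    left_mate=Mate(left_start, left_end, "+"),
                    right_mate=Mate(right_start, right_start + rl - 1, "-"),
                )
            )
    return pairs


def inject_chimeras(
    calls_by_caller: Mapping[str, list[SVCall]],
    profiles: Sequence[CallerProfile],
    genome_length: int,
    rate: float = 0.05,
    n_fragments: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[SVCall]], list[dict]]:
    """Add library-chimera artifact calls, independently per technology.

    Chimeras arise during library construction, so a given artifact is
    confined to one technology but may be reported by every caller that
    consumed that library.  Per technology, ``Binomial(basis, rate)``
    artifacts are drawn (basis = ``n_fragments`` or that technology's
    call count), each with random breakpoints and modest read support.
    Returns the augmented call sets (inputs are not mutated) and a
    manifest describing every injected artifact.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = {name: list(calls) for name, calls in calls_by_caller.items()}
    manifest: list[dict] = []
    by_tech: dict[Technology, list[CallerProfile]] = {}
    for p in profiles:
        by_tech.setdefault(p.technology, []).append(p)

    for tech in sorted(by_tech, key=lambda t: t.value):
        tech_profiles = by_tech[tech]
        basis = (
            n_fragments
            if n_fragments is not None
            else sum(
                len(calls_by_caller.get(p.name, [])) for p in tech_profiles
            )
        )
        n_art = int(rng.binomial(basis, rate)) if basis else 0
        for k in range(n_art):
            svtype = SVType(("DEL", "DUP", "INV")[rng.integers(0, 3)])
            # A chimera joins two random breakpoints: draw both uniformly.
            while True:
                a, b = sorted(int(x) for x in rng.integers(1, genome_length + 1, 2))
                if b - a + 1 >= 50:
                    break
            start, end = a, b
            length = end - start + 1
            support = int(rng.integers(3, 31))
            callers = [tech_profiles[int(rng.integers(0, len(tech_profiles)))].name]
            for p in tech_profiles:
                if p.name not in callers and rng.random() < 0.8:
                    callers.append(p.name)
            for caller in callers:
                out.setdefault(caller, []).append(
                    SVCall(
                        id=f"chimera_{tech.value}_{k}_{caller}",
                        caller=caller,
                        technology=tech,
                        sv_type=svtype,
                        start=start,
                        end=end,
                        length=length,
                        read_support=support,
                    )
                )
            manifest.append(
                {
                    "technology": tech.value,
                    "sv_type": svtype.value,
                    "start": start,
                    "end": end,
                    "length": length,
                    "read_support": support,
                    "callers": sorted(callers),
                }
            )
    return out, manifest


DEFAULT_TE_LIBRARY: dict[str, tuple[str, str, int]] = {
    # element id -> (superfamily, TE class, consensus length in bp)
    "piggyBac-1": ("piggyBac", "II", 2472),
    "mariner-1": ("Mariner", "II", 1286),
    "sola-1": ("Sola", "II", 3014),
    "harbinger-1": ("Harbinger", "II", 2400),
    "gypsy-1": ("Gypsy", "I", 5100),
    "copia-1": ("Copia", "I", 4800),
}


def plant_tes(
    te_library: Mapping[str, tuple[str, str, int]] | None = None,
    n_full: int = 5,
    n_truncated: int = 8,
    end_truncated_fraction: float = 0.7,
    n_violating: int = 2,
    seed: int = 0,
) -> list[PlantedTE]:
    """Plant full-length and truncated TE copies, plus rule-violating decoys."""
    te_library = dict(te_library or DEFAULT_TE_LIBRARY)
    rng = np.random.default_rng(seed)
    ids = sorted(te_library)
    planted: list[PlantedTE] = []
    for i in range(n_full):
        eid = ids[int(rng.integers(0, len(ids)))]
        sf, cls, clen = te_library[eid]
        planted.append(PlantedTE(eid, sf, cls, clen, "full"))
    for i in range(n_truncated):
        eid = ids[int(rng.integers(0, len(ids)))]
        sf, cls, clen = te_library[eid]
        planted.append(
            PlantedTE(
                eid,
                sf,
                cls,
                clen,
                "truncated",
                at_read_end=bool(rng.random() < end_truncated_fraction),
                truncated_fraction=float(rng.uniform(0.2, 0.8)),
            )
        )
    for i in range(n_violating):
        eid = ids[int(rng.integers(0, len(ids)))]
        sf, cls, clen = te_library[eid]
        planted.append(
            PlantedTE(eid, sf, cls, clen, "truncated",
                      truncated_fraction=0.5, rule_violating=True)
        )
    return planted


def simulate_te_reads(
    planted_tes: Sequence[PlantedTE],
    te_library: Mapping[str, tuple[str, str, int]] | None = None,
    genome_length: int = 50_000,
    long_read_length: int = 20_000,
    short_read_length: int = 151,
    seed: int = 0,
) -> tuple[dict[str, list[ReadAlignment]], list[ReadAlignment]]:
    """Reads containing the planted TE segments.

    Long reads carry one TE segment each (full-length, or truncated — at
    a read end when so flagged) plus virus alignments covering the rest
    of the read; a lower-scoring overlapping decoy hit is added to a
    third of the reads to exercise hit resolution.  Short reads carry
    virus/host split alignments that satisfy the junction rules, except
    for decoys flagged ``rule_violating`` whose host segment is 15 bp.
    """
    te_library = dict(te_library or DEFAULT_TE_LIBRARY)
    rng = np.random.default_rng(seed)
    long_hits: dict[str, list[ReadAlignment]] = {}
    short_hits: list[ReadAlignment] = []

    for i, te in enumerate(planted_tes):
        _, _, clen = te_library[te.element_id]
        seg = clen if te.completeness == "full" else max(
            round_half_up(te.truncated_fraction * clen), 30
        )
        seg = min(seg, long_read_length - 200)
        read_id = f"long_te_{i}"
        if te.at_read_end:
            if rng.random() < 0.5:
                rs, re = 1, seg
            else:
                rs, re = long_read_length - seg + 1, long_read_length
        else:
            rs = int(rng.integers(2, long_read_length - seg))
            re = rs + seg - 1
        hits = [
            ReadAlignment(
                read_id, rs, re, te.element_id, "host_te", 1, seg, "+",
                score=2.0 * seg, read_length=long_read_length,
            )
        ]
        if rng.random() < 0.33 and re - rs > 100:
            hits.append(
                ReadAlignment(
                    read_id, rs + 20, re - 20, "decoy-element", "host_te",
                    1, re - rs - 39, "+",
                    score=1.0 * (re - rs - 39), read_length=long_read_length,
                )
            )
        vstart = int(rng.integers(1, genome_length // 2))
        if rs > 1:
            span = rs - 1
            hits.append(
                ReadAlignment(
                    read_id, 1, rs - 1, "virus", "virus",
                    vstart, vstart + span - 1, "+",
                    score=2.0 * span, read_length=long_read_length,
                )
            )
        if re < long_read_length:
            span = long_read_length - re
            hits.append(
                ReadAlignment(
                    read_id, re + 1, long_read_length, "virus", "virus",
                    vstart + rs, vstart + rs + span - 1, "+",
                    score=2.0 * span, read_length=long_read_length,
                )
            )
        long_hits[read_id] = hits

        # short-read chimeric junction for the same element
        read_id_s = f"short_te_{i}"
        host_len = 15 if te.rule_violating else int(rng.integers(40, 72))
        virus_len = short_read_length - host_len
        gstart = int(rng.integers(1, genome_length - virus_len))
        short_hits.append(
            ReadAlignment(
                read_id_s, 1, virus_len, "virus", "virus",
                gstart, gstart + virus_len - 1, "+",
                score=2.0 * virus_len, read_length=short_read_length,
            )
        )
        short_hits.append(
            ReadAlignment(
                read_id_s, virus_len + 1, short_read_length,
                te.element_id, "host_te",
                1, host_len, "+",
                score=2.0 * host_len, read_length=short_read_length,
            )
        )
    return long_hits, short_hits
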