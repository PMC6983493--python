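"""Readers and writers for the on-disk formats the pipeline touches.

VCF handling goes through :mod:`pysam`; GFF3 ingestion through
:mod:`gffutils`.  Per-base coverage is the two/three-column text produced
by genome-coverage tools with the per-base option, and pairwise alignments
are consumed as the 12-column blast tabular dialect.

Caller *dialects* map a caller name to the VCF INFO key that holds its
read support; the shipped defaults cover the callers the pipeline is
normally fed but every entry can be overridden.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .models import (
    CoverageTrack,
    Feature,
    GenomeAnnotation,
    ReadAlignment,
    SVCall,
    SVCluster,
    SVType,
    Technology,
    intergenic_complement,
)

#: INFO key holding read support, per caller.  Which field each caller
#: writes differs between programs, so this is configuration with defaults
#: rather than a hard-coded rule.
DEFAULT_DIALECTS: dict[str, str] = {
    "pindel": "SUPPORT",
    "lumpy": "SU",
    "fermikit": "SUPPORT",
    "pairdist": "SUPPORT",
    "sniffles": "RE",
    "pbhoney": "SUPPORT",
}

#: Keys tried, in order, when the dialect key is absent from a record.
FALLBACK_SUPPORT_KEYS = ("SUPPORT", "SU", "RE", "PE", "DV")

_SV_TYPES = {t.value for t in SVType}


@dataclass
class ParsedCalls:
    """Calls parsed from one caller's VCF plus a report of skipped records."""

    calls: list[SVCall]
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _support_from_record(rec, caller: str, dialect: Mapping[str, str]) -> int | None:
    keys = []
    if caller in dialect:
        keys.append(dialect[caller])
    keys.extend(k for k in FALLBACK_SUPPORT_KEYS if k not in keys)
    for key in keys:
        if key in rec.info:
            value = rec.info[key]
            if isinstance(value, (tuple, list)):
                return int(sum(int(v) for v in value))
            return int(value)
    return None


def read_caller_calls(
    path: str | Path,
    caller: str,
    technology: Technology | str,
    genome_length: int,
    dialect: Mapping[str, str] | None = None,
) -> ParsedCalls:
    """Parse one caller's VCF into :class:`SVCall` records.

    Records whose SVTYPE is not one of DEL/DUP/INS/INV (breakends in
    particular) are skipped and counted in the skip report, as are records
    with coordinates outside ``[1, genome_length]`` or without a usable
    support field.  Nothing is ever silently dropped.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    technology = Technology(technology)
    dialect = dict(DEFAULT_DIALECTS, **(dialect or {}))
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: not a parseable VCF (missing header?): {exc}")

    calls: list[SVCall] = []
    skipped: Counter = Counter()
    with vcf:
        for i, rec in enumerate(vcf):
            svtype = _scalar(rec.info.get("SVTYPE"))
            if svtype not in _SV_TYPES:
                skipped[f"svtype:{svtype}"] += 1
                continue
            start = rec.pos
            if svtype == "INS":
                end = start
                svlen = _scalar(rec.info.get("SVLEN"))
                if svlen is None:
                    skipped["ins_without_svlen"] += 1
                    continue
                length = abs(int(svlen))
            else:
                end = rec.stop
                if end < start:
                    skipped["end_before_start"] += 1
                    continue
                length = end - start + 1
            if not (1 <= start <= genome_length and 1 <= end <= genome_length):
                warnings.warn(
                    f"{path}: record {rec.id or i} at {start}..{end} outside "
                    f"[1, {genome_length}]; skipped"
                )
                skipped["out_of_range"] += 1
                continue
            support = _support_from_record(rec, caller, dialect)
            if support is None or support < 1:
                skipped["no_support_field"] += 1
                continue
            try:
                read_ids = rec.info.get("RNAMES")
            except ValueError:  # key not declared in this header
                read_ids = None
            if read_ids is not None:
                read_ids = [str(r) for r in (
                    read_ids if isinstance(read_ids, (tuple, list)) else [read_ids]
                )]
            calls.append(
                SVCall(
                    id=rec.id or f"{caller}_{i}",
                    caller=caller,
                    technology=technology,
                    sv_type=SVType(svtype),
                    start=start,
                    end=end,
                    length=length,
                    read_support=support,
                    read_ids=read_ids,
                )
            )
    return ParsedCalls(calls, dict(skipped))


def _vcf_header(genome_length: int, contig: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={genome_length}>")
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">'
    )
    header.add_line(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">'
    )
    header.add_line(
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">'
    )
    header.add_line(
        '##INFO=<ID=TECHS,Number=.,Type=String,Description="Supporting technologies">'
    )
    header.add_line(
        '##INFO=<ID=GRIDPOINTS,Number=1,Type=Integer,'
        'Description="Number of (min-reads, distance) grid points emitting this SV">'
    )
    return header


def write_sv_vcf(
    svs: Sequence[SVCall | SVCluster],
    path: str | Path,
    genome_length: int,
    contig: str = "genome",
) -> Path:
    """Write calls or consensus clusters as an uncompressed VCF 4.x file.

    DEL records carry a negative SVLEN following convention; lengths are
    recovered from END on re-read (and from |SVLEN| for INS).
    """
    path = Path(path)
    header = _vcf_header(genome_length, contig)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        def fields(sv):
            if isinstance(sv, SVCluster):
                return (
                    sv.sv_type.value,
                    sv.consensus_start,
                    sv.consensus_end,
                    sv.consensus_length,
                    sv.support_for_frequency,
                    sv,
                )
            return (sv.sv_type.value, sv.start, sv.end, sv.length, sv.read_support, None)

        for i, sv in enumerate(
            sorted(svs, key=lambda s: fields(s)[1:3])
        ):
            svtype, start, end, length, support, cluster = fields(sv)
            rec = out.new_record(
                contig=contig, start=start - 1, stop=end,
                alleles=("N", f"<{svtype}>"),
            )
            rec.id = f"sv_{i + 1}"
            rec.info["SVTYPE"] = svtype
            # For interval types the span in END already carries the length;
            # writing SVLEN too would make htslib re-derive the end from it
            # under the off-by-one REF-allele convention.
            if svtype == "INS":
                rec.info["SVLEN"] = length
            rec.info["SUPPORT"] = int(support)
            if cluster is not None:
                rec.info["CALLERS"] = sorted(cluster.callers)
                rec.info["TECHS"] = sorted(t.value for t in cluster.technologies)
                rec.info["GRIDPOINTS"] = len(cluster.provenance)
            out.write(rec)
    return path


def read_coverage(path: str | Path, genome_length: int) -> CoverageTrack:
    """Parse a per-base coverage file into a :class:`CoverageTrack`.

    Accepts two columns (position, depth) or three (name, position, depth).
    Positions missing from the file are filled with depth 0 and reported
    through a warning; duplicated positions or negative depths are format
    errors.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty coverage file")
    if df.shape[1] == 3:
        df = df.iloc[:, 1:]
    elif df.shape[1] != 2:
        raise ValueError(
            f"{path}: expected 2 or 3 columns, found {df.shape[1]}"
        )
    pos = df.iloc[:, 0].astype(int).to_numpy()
    depth = df.iloc[:, 1].astype(int).to_numpy()
    if len(np.unique(pos)) != len(pos):
        raise ValueError(f"{path}: duplicate positions")
    if (depth < 0).any():
        raise ValueError(f"{path}: negative depth")
    if (pos < 1).any() or (pos > genome_length).any():
        raise ValueError(f"{path}: positions outside [1, {genome_length}]")
    arr = np.zeros(genome_length, dtype=np.int64)
    arr[pos - 1] = depth
    n_missing = genome_length - len(pos)
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} positions missing from coverage file; "
            "filled with depth 0"
        )
    return CoverageTrack(genome_length=genome_length, depth=arr)


def write_coverage(
    track: CoverageTrack, path: str | Path, name: str = "genome"
) -> Path:
    """Write per-base coverage in the three-column (name, position, depth) form."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, d in enumerate(track.depth, start=1):
            fh.write(f"{name}\t{i}\t{int(d)}\n")
    return path


_GFF_KIND = {"gene": "gene", "repeat_region": "hr"}


def read_annotation(
    path: str | Path, genome_length: int | None = None
) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    ``gene`` rows map to gene features and ``repeat_region`` rows to
    homologous regions (hr); intergenic features are synthesized as the
    complement.  The genome length is taken from the ``##sequence-region``
    directive unless given explicitly.
    """
    path = Path(path)
    body = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4 and genome_length is None:
                    genome_length = int(parts[3])
            elif line and not line.startswith("#"):
                body = True
    if genome_length is None:
        raise ValueError(
            f"{path}: no ##sequence-region directive; pass genome_length"
        )

    features: list[Feature] = []
    if body:
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
        seen: set[str] = set()
        for ftype, kind in _GFF_KIND.items():
            for f in db.features_of_type(ftype):
                if f.end < f.start:
                    raise ValueError(
                        f"{path}: feature {f.id} has end < start"
                    )
                if f.id in seen:
                    raise ValueError(f"{path}: duplicate feature id {f.id}")
                seen.add(f.id)
                features.append(
                    Feature(f.id, kind, f.start, f.end, f.strand or "+")
                )
    features.sort(key=lambda f: (f.start, f.end))
    features.extend(intergenic_complement(features, genome_length))
    features.sort(key=lambda f: (f.start, f.end))
    return GenomeAnnotation(genome_length=genome_length, features=features)


def write_annotation(
    annotation: GenomeAnnotation, path: str | Path, seqid: str = "genome"
) -> Path:
    """Write gene and hr features as GFF3 (intergenic rows are implicit)."""
    path = Path(path)
    rev = {"gene": "gene", "hr": "repeat_region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.genome_length}\n")
        for f in annotation.features:
            if f.kind == "intergenic":
                continue
            fh.write(
                f"{seqid}\tsvmeta\t{rev[f.kind]}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.feature_id}\n"
            )
    return path


def read_alignment_table(
    path: str | Path,
    target_kind_map: Mapping[str, str] | None = None,
    read_length: int | Mapping[str, int] = 151,
) -> list[ReadAlignment]:
    """Parse a 12-column blast tabular file into :class:`ReadAlignment` records.

    Subject intervals are normalized so start <= end, with the strand
    inferred from the original orientation.  ``target_kind_map`` maps a
    subject id to virus/host_te/host_other; unmapped subjects default to
    ``host_other``.
    """
    target_kind_map = target_kind_map or {}
    out: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, found {len(cols)}"
                )
            qid, sid = cols[0], cols[1]
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            if qstart > qend:
                qstart, qend = qend, qstart
            strand = "+" if sstart <= send else "-"
            if sstart > send:
                sstart, send = send, sstart
            rl = (
                read_length[qid]
                if isinstance(read_length, Mapping)
                else int(read_length)
            )
            out.append(
                ReadAlignment(
                    read_id=qid,
                    read_start=qstart,
                    read_end=qend,
                    target_id=sid,
                    target_kind=target_kind_map.get(sid, "host_other"),
                    target_start=sstart,
                    target_end=send,
                    strand=strand,
                    score=float(cols[11]),
                    read_length=rl,
                )
            )
    return out


def write_alignment_table(
    alignments: Iterable[ReadAlignment], path: str | Path
) -> Path:
    """Write alignments in the 12-column blast tabular dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        for a in alignments:
            sstart, send = (
                (a.target_start, a.target_end)
                if a.strand == "+"
                else (a.target_end, a.target_start)
            )
            span = a.read_span
            fh.write(
                f"{a.read_id}\t{a.target_id}\t100.00\t{span}\t0\t0\t"
                f"{a.read_start}\t{a.read_end}\t{sstart}\t{send}\t"
                f"0.0\t{a.score:.1f}\n"
            )
    return path


def write_fasta(sequence: str, path: str | Path, name: str = "genome") -> Path:
    """Write one genome sequence as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")
    return path
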