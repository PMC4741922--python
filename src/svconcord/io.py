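"""Readers and writers for the flat-file formats the pipeline touches.

BEDPE and BED are parsed by hand (line-number-accurate errors matter more
here than speed); SEG-like tables and manifests go through pandas.  All
genomic records are 0-based, intervals half-open — the BED/BEDPE native
convention — so no coordinate shifting happens outside this module.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    Breakpoint,
    CnProfile,
    CnSegment,
    EvidenceIndex,
    GeneRecord,
    GenomeModel,
    Interval,
    Rearrangement,
    SampleMeta,
    canonicalize,
)

log = logging.getLogger("svconcord")

BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore"
    "\tstrand1\tstrand2\tsv_type\torigin\tsample_id"
)


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_genome(path: str | Path) -> GenomeModel:
    """Read chromosome names and lengths from a two-column TSV; the file
    order defines the canonical chromosome order."""
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>length'")
            try:
                items.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: bad chromosome length {fields[1]!r}") from exc
    return GenomeModel(items)


def write_genome(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def _infer_sv_type(chrom1: str, chrom2: str, label: str | None) -> str:
    if chrom1 != chrom2:
        return "CTX"
    if label in ("ITX", "DEL", "INV"):
        return label
    return "ITX"


def read_rearrangements(
    path: str | Path,
    dialect: str,
    genome: GenomeModel,
    sample_id: str = "",
) -> list[Rearrangement]:
    """Read an SV call table into canonicalized :class:`Rearrangement`s.

    dialect ``bedpe``: 10+ column BEDPE with score = read-pair support
    and optional sv_type/origin/sample_id trailing columns.
    dialect ``breakdancer_tsv``: the canonical 12-column caller output
    (Chr1 Pos1 Ori1 Chr2 Pos2 Ori2 Type Size Score num_Reads ...);
    trailing columns beyond num_Reads are ignored.

    Rows on chromosomes absent from the genome are dropped (count
    logged); malformed rows raise with the offending line number.
    """
    if dialect not in ("bedpe", "breakdancer_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    events: list[Rearrangement] = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            try:
                if dialect == "bedpe":
                    if len(f) < 8:
                        raise ValueError("BEDPE needs >= 8 columns")
                    chrom1, pos1 = f[0], int(f[1])
                    chrom2, pos2 = f[3], int(f[4])
                    support = int(round(float(f[7])))
                    sv_type = f[10] if len(f) > 10 and f[10] else None
                    origin = f[11] if len(f) > 11 and f[11] else "called"
                    sid = f[12] if len(f) > 12 and f[12] else sample_id
                else:
                    if len(f) < 10:
                        raise ValueError("breakdancer_tsv needs >= 10 columns")
                    chrom1, pos1 = f[0], int(f[1])
                    chrom2, pos2 = f[3], int(f[4])
                    sv_type = f[6]
                    support = int(round(float(f[9])))
                    origin = "called"
                    sid = sample_id
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed {dialect} record: {exc}") from exc
            if chrom1 not in genome or chrom2 not in genome:
                dropped += 1
                continue
            rearr = Rearrangement(
                left=Breakpoint(chrom1, pos1),
                right=Breakpoint(chrom2, pos2),
                sv_type=_infer_sv_type(chrom1, chrom2, sv_type),
                support=support,
                sample_id=sid,
                origin=origin,
            )
            events.append(canonicalize(rearr, genome))
    if dropped:
        log.warning("%s: dropped %d record(s) on chromosomes absent from the genome", path, dropped)
    return events


def write_rearrangements(events: Iterable[Rearrangement], path: str | Path) -> None:
    """Write events as 13-column BEDPE (score = support; sv_type, origin
    and sample_id in trailing columns so a round-trip is lossless)."""
    with open(path, "w") as fh:
        fh.write(BEDPE_HEADER + "\n")
        for i, r in enumerate(events):
            fh.write(
                f"{r.left.chrom}\t{r.left.pos}\t{r.left.pos + 1}"
                f"\t{r.right.chrom}\t{r.right.pos}\t{r.right.pos + 1}"
                f"\tr{i}\t{r.support}\t.\t.\t{r.sv_type}\t{r.origin}\t{r.sample_id}\n"
            )


def read_cn_segments(path: str | Path, genome: GenomeModel) -> dict[str, CnProfile]:
    """Read a SEG-like TSV (sample, chrom, start, end, cn) into per-sample
    profiles; overlapping segments within a sample are an error."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "chrom", "start", "end", "cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SEG columns {sorted(missing)}")
    profiles: dict[str, CnProfile] = {}
    dropped = 0
    for row in df.itertuples(index=False):
        if row.chrom not in genome:
            dropped += 1
            continue
        prof = profiles.setdefault(str(row.sample), CnProfile(str(row.sample)))
        prof.add(CnSegment(row.chrom, int(row.start), int(row.end), float(row.cn)))
    for prof in profiles.values():
        prof.validate()
    if dropped:
        log.warning("%s: dropped %d CN segment(s) on unknown chromosomes", path, dropped)
    return profiles


def write_cn_segments(profiles: Iterable[CnProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for chrom, segs in prof.segments.items():
            for seg in segs:
                rows.append((prof.sample_id, chrom, seg.start, seg.end, seg.cn))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "cn"]).to_csv(
        path, sep="\t", index=False
    )


def read_intervals(path: str | Path, genome: GenomeModel) -> list[Interval]:
    """Read BED3 intervals; records outside the genome are dropped with a
    logged count, end <= start is an error."""
    out: list[Interval] = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split(line)
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed BED record") from exc
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            if chrom not in genome or end > genome.chrom_lengths[chrom]:
                dropped += 1
                continue
            out.append(Interval(chrom, start, end))
    if dropped:
        log.warning("%s: dropped %d interval(s) outside the genome", path, dropped)
    return out


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes(path: str | Path, genome: GenomeModel) -> list[GeneRecord]:
    """Read a BED6 gene annotation (chrom start end name score strand)."""
    out: list[GeneRecord] = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split(line)
            try:
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5] if len(f) > 5 else "+"
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed gene BED record") from exc
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            if chrom not in genome or end > genome.chrom_lengths[chrom]:
                dropped += 1
                continue
            out.append(GeneRecord(chrom, start, end, name, strand))
    if dropped:
        log.warning("%s: dropped %d gene(s) outside the genome", path, dropped)
    return out


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(names):
            fh.write(name + "\n")


def read_evidence(path: str | Path, genome: GenomeModel) -> EvidenceIndex:
    """Read a discordant read-pair table
    (readname, chrom1, pos1, chrom2, pos2) into an :class:`EvidenceIndex`."""
    idx = EvidenceIndex(genome)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            try:
                idx.add(f[1], int(f[2]), f[3], int(f[4]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed evidence record: {exc}") from exc
    return idx


def write_evidence(idx: EvidenceIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#readname\tchrom1\tpos1\tchrom2\tpos2\n")
        for i, (c1, p1, c2, p2) in enumerate(idx.records()):
            fh.write(f"rp{i}\t{c1}\t{p1}\t{c2}\t{p2}\n")


def read_manifest(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "patient_id", "role", "physical_coverage", "sequence_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            patient_id=str(r.patient_id),
            role=str(r.role),
            physical_coverage=float(r.physical_coverage),
            sequence_coverage=float(r.sequence_coverage),
        )
        for r in df.itertuples(index=False)
    ]


def write_manifest(metas: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.sample_id, m.patient_id, m.role, m.physical_coverage, m.sequence_coverage)
            for m in metas
        ],
        columns=["sample_id", "patient_id", "role", "physical_coverage", "sequence_coverage"],
    ).to_csv(path, sep="\t", index=False)
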