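"""Core domain types for rearrangement concordance analysis.

A structural rearrangement is modelled as an unordered pair of genomic
breakpoints plus a caller class label (CTX for interchromosomal fusions,
ITX/DEL/INV for intrachromosomal events) and its read-pair support.  All
coordinates are 0-based; intervals are half-open, breakpoints are points.
Chromosome order is defined by the active :class:`GenomeModel`, never
lexicographically, so canonicalization is reproducible across inputs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

SV_TYPES = ("CTX", "ITX", "DEL", "INV")
ORIGINS = ("called", "rescued", "looked_up", "synthetic")


@dataclass(frozen=True, order=True)
class Breakpoint:
    """One end of a rearrangement: a 0-based point on a chromosome."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative breakpoint position {self.pos} on {self.chrom}")


@dataclass(frozen=True)
class Rearrangement:
    """A two-breakpoint structural rearrangement.

    ``left <= right`` under the genome's canonical chromosome order; use
    :func:`canonicalize` after construction from untrusted coordinates.
    ``sv_type`` must be CTX exactly when the two breakpoints sit on
    different chromosomes.
    """

    left: Breakpoint
    right: Breakpoint
    sv_type: str
    support: int = 0
    sample_id: str = ""
    origin: str = "called"

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.support < 0:
            raise ValueError("support must be non-negative")
        interchrom = self.left.chrom != self.right.chrom
        if interchrom != (self.sv_type == "CTX"):
            raise ValueError(
                f"sv_type {self.sv_type} inconsistent with chromosomes "
                f"{self.left.chrom}/{self.right.chrom}"
            )

    @property
    def intrachromosomal(self) -> bool:
        return self.left.chrom == self.right.chrom

    @property
    def span(self) -> int | None:
        """Distance between breakpoints; None for interchromosomal events."""
        if not self.intrachromosomal:
            return None
        return self.right.pos - self.left.pos

    def key(self) -> tuple[str, int, str, int]:
        return (self.left.chrom, self.left.pos, self.right.chrom, self.right.pos)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneRecord:
    """A gene span with strand; the genic area extends 2 kb upstream of
    the transcription start (strand-aware) through the 3' end."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gene span for {self.name}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")

    def extended_span(self, promoter: int = 2000) -> Interval:
        """Genic area: gene body plus ``promoter`` bp upstream of the TSS.

        Upstream is before ``start`` on the + strand and after ``end`` on
        the - strand.  The promoter boundary is inclusive at exactly
        ``promoter`` bp upstream.
        """
        if self.strand == "+":
            return Interval(self.chrom, max(0, self.start - promoter), self.end)
        return Interval(self.chrom, self.start, self.end + promoter)


@dataclass(frozen=True)
class CnSegment:
    """Piecewise-constant copy-number segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    cn: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty CN segment {self.chrom}:{self.start}-{self.end}")
        if self.cn < 0:
            raise ValueError("copy number must be non-negative")


@dataclass
class CnProfile:
    """Per-sample copy-number segmentation: sorted, non-overlapping
    segments per chromosome.  Gaps are interpreted downstream as normal
    ploidy (some segmentation dialects omit unremarkable regions)."""

    sample_id: str
    segments: dict[str, list[CnSegment]] = field(default_factory=dict)

    def add(self, seg: CnSegment) -> None:
        self.segments.setdefault(seg.chrom, []).append(seg)

    def validate(self) -> None:
        for chrom, segs in self.segments.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping CN segments in {self.sample_id} on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    def breaks(self, chrom: str) -> list[int]:
        out: set[int] = set()
        for seg in self.segments.get(chrom, []):
            out.add(seg.start)
            out.add(seg.end)
        return sorted(out)


@dataclass(frozen=True)
class SampleMeta:
    """Sample identity, role in the patient, and coverage depths.

    ``physical_coverage`` counts whole DNA fragments (mate-pair spans),
    ``sequence_coverage`` counts sequenced bases; the support-threshold
    rule uses sequence coverage, the support model uses physical.
    """

    sample_id: str
    patient_id: str
    role: str  # primary | metastasis | normal_pool
    physical_coverage: float = 22.3
    sequence_coverage: float = 9.3

    def __post_init__(self) -> None:
        if self.role not in ("primary", "metastasis", "normal_pool"):
            raise ValueError(f"unknown sample role {self.role!r}")
        if self.role != "normal_pool" and (
            self.physical_coverage <= 0 or self.sequence_coverage <= 0
        ):
            raise ValueError(f"non-positive coverage for tumor sample {self.sample_id}")


class GenomeModel:
    """Chromosome names/lengths plus masks, gene annotation and the
    cancer-gene subset.

    Chromosome order is the order given at construction; it defines the
    canonical ordering of breakpoints within a rearrangement.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int] | Sequence[tuple[str, int]],
        masks: Mapping[str, Sequence[Interval]] | None = None,
        genes: Sequence[GeneRecord] = (),
        cancer_genes: Iterable[str] = (),
    ):
        items = list(chrom_lengths.items()) if isinstance(chrom_lengths, Mapping) else list(chrom_lengths)
        if not items:
            raise ValueError("genome must define at least one chromosome")
        self.chrom_lengths: dict[str, int] = {}
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            self.chrom_lengths[name] = int(length)
        self._index = {name: i for i, name in enumerate(self.chrom_lengths)}
        self.masks: dict[str, list[Interval]] = {}
        for mask_name, ivals in (masks or {}).items():
            for iv in ivals:
                self._check_interval(iv, f"mask {mask_name}")
            self.masks[mask_name] = sorted(ivals, key=lambda iv: (self._index[iv.chrom], iv.start))
        for g in genes:
            self._check_interval(Interval(g.chrom, g.start, g.end), f"gene {g.name}")
        self.genes: list[GeneRecord] = sorted(genes, key=lambda g: (self._index[g.chrom], g.start))
        gene_names = {g.name for g in self.genes}
        self.cancer_genes: set[str] = set(cancer_genes)
        self.external_cancer_genes: set[str] = self.cancer_genes - gene_names

    def _check_interval(self, iv: Interval, what: str) -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"{what} on unknown chromosome {iv.chrom}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(f"{what} extends past end of {iv.chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def chrom_index(self, chrom: str) -> int:
        return self._index[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def check_breakpoint(self, bp: Breakpoint) -> None:
        if bp.chrom not in self.chrom_lengths:
            raise ValueError(f"breakpoint on unknown chromosome {bp.chrom}")
        if bp.pos >= self.chrom_lengths[bp.chrom]:
            raise ValueError(f"breakpoint {bp.chrom}:{bp.pos} past chromosome end")

    def in_mask(self, bp: Breakpoint, mask_names: Iterable[str] | None = None) -> bool:
        """True if the breakpoint position falls inside any named mask
        interval (point test; masks are already broad regions)."""
        names = list(mask_names) if mask_names is not None else list(self.masks)
        for name in names:
            for iv in self.masks.get(name, ()):
                if iv.chrom == bp.chrom and iv.contains(bp.pos):
                    return True
        return False


def breakpoint_sort_key(bp: Breakpoint, genome: GenomeModel) -> tuple[int, int]:
    return (genome.chrom_index(bp.chrom), bp.pos)


def canonicalize(rearr: Rearrangement, genome: GenomeModel) -> Rearrangement:
    """Order breakpoints by (chromosome index, position); idempotent."""
    genome.check_breakpoint(rearr.left)
    genome.check_breakpoint(rearr.right)
    if breakpoint_sort_key(rearr.left, genome) <= breakpoint_sort_key(rearr.right, genome):
        return rearr
    return replace(rearr, left=rearr.right, right=rearr.left)


def rearrangement_sort_key(r: Rearrangement, genome: GenomeModel) -> tuple[int, int, int, int]:
    return (*breakpoint_sort_key(r.left, genome), *breakpoint_sort_key(r.right, genome))


class EvidenceIndex:
    """Queryable store of discordant read pairs.

    Each record is one read pair whose two mates map near the two ends of
    a putative rearrangement, stored canonically by chromosome pair.  The
    look-up step asks how many pairs support both ends of an event within
    a window.
    """

    def __init__(self, genome: GenomeModel):
        self.genome = genome
        # (chrom1, chrom2) -> list of (pos1, pos2), pos1-side chromosome <= pos2-side
        self._pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
        self._sorted = True

    def add(self, chrom1: str, pos1: int, chrom2: str, pos2: int) -> None:
        b1, b2 = Breakpoint(chrom1, pos1), Breakpoint(chrom2, pos2)
        self.genome.check_breakpoint(b1)
        self.genome.check_breakpoint(b2)
        if breakpoint_sort_key(b1, self.genome) > breakpoint_sort_key(b2, self.genome):
            b1, b2 = b2, b1
        self._pairs.setdefault((b1.chrom, b2.chrom), []).append((b1.pos, b2.pos))
        self._sorted = False

    def _ensure_sorted(self) -> None:
        if not self._sorted:
            for recs in self._pairs.values():
                recs.sort()
            self._sorted = True

    def __len__(self) -> int:
        return sum(len(v) for v in self._pairs.values())

    def records(self):
        for (c1, c2), recs in self._pairs.items():
            for p1, p2 in recs:
                yield (c1, p1, c2, p2)

    def count_support(self, rearr: Rearrangement, half_width: int) -> int:
        """Number of read pairs whose mates both fall within ±half_width
        of the event's two breakpoints (correct chromosome pair)."""
        self._ensure_sorted()
        recs = self._pairs.get((rearr.left.chrom, rearr.right.chrom))
        if not recs:
            return 0
        lo = bisect.bisect_left(recs, (rearr.left.pos - half_width, -1))
        hi = bisect.bisect_right(recs, (rearr.left.pos + half_width, 1 << 62))
        return sum(
            1
            for p1, p2 in recs[lo:hi]
            if abs(p2 - rearr.right.pos) <= half_width
        )
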