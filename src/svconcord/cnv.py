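"""Copy-number profile similarity over union-break windows.

Two segmentations are compared on the windows delineated by the union of
their segmentation breaks; within each window both samples have a
constant copy number.  States are compared categorically (loss / normal /
gain relative to ploidy, default 2) rather than as exact CN levels,
which is robust to caller level noise; an exact mode is available.

Two metrics:

* event similarity — fraction of windows with identical aberrant states
  among windows where at least one sample is aberrant (both-normal
  windows excluded); windows are counted, not length-weighted.
* length similarity — length-weighted fraction of the genome where the
  two states agree, both-normal stretches included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .model import CnProfile, GenomeModel

log = logging.getLogger("svconcord")


@dataclass(frozen=True)
class CnWindow:
    chrom: str
    start: int
    end: int
    state_a: str  # loss | normal | gain (or exact CN as str in exact mode)
    state_b: str

    @property
    def length(self) -> int:
        return self.end - self.start


def categorize(cn: float, ploidy: float = 2.0) -> str:
    if cn < ploidy:
        return "loss"
    if cn > ploidy:
        return "gain"
    return "normal"


def _states_on_grid(
    profile: CnProfile, chrom: str, grid: Sequence[int], ploidy: float, exact: bool
) -> list[str]:
    """Per-window state of one sample on a break grid; windows not
    covered by any segment are normal (segmentation dialects may omit
    unremarkable regions)."""
    states = []
    segs = sorted(profile.segments.get(chrom, []), key=lambda s: s.start)
    si = 0
    for start, end in zip(grid, grid[1:]):
        while si < len(segs) and segs[si].end <= start:
            si += 1
        if si < len(segs) and segs[si].start <= start and segs[si].end >= end:
            cn = segs[si].cn
            states.append(str(cn) if exact else categorize(cn, ploidy))
        else:
            states.append(str(float(ploidy)) if exact else "normal")
    return states


def union_windows(
    profile_a: CnProfile,
    profile_b: CnProfile,
    genome: GenomeModel,
    ploidy: float = 2.0,
    exact: bool = False,
) -> list[CnWindow]:
    """Partition each chromosome at the union of both samples' segment
    boundaries and assign each sample's state per window."""
    windows: list[CnWindow] = []
    for chrom, length in genome.chrom_lengths.items():
        breaks = sorted(
            {0, length, *profile_a.breaks(chrom), *profile_b.breaks(chrom)}
        )
        breaks = [b for b in breaks if 0 <= b <= length]
        sa = _states_on_grid(profile_a, chrom, breaks, ploidy, exact)
        sb = _states_on_grid(profile_b, chrom, breaks, ploidy, exact)
        for (start, end), a, b in zip(zip(breaks, breaks[1:]), sa, sb):
            windows.append(CnWindow(chrom, start, end, a, b))
    return windows


def _is_normal(state: str, ploidy: float, exact: bool) -> bool:
    if exact:
        return float(state) == float(ploidy)
    return state == "normal"


def cn_event_similarity(
    windows: Sequence[CnWindow], ploidy: float = 2.0, exact: bool = False
) -> float | None:
    """Percent of aberrant windows with concordant states.

    Windows normal in both samples are excluded; a window counts as
    shared when both states are equal and aberrant.  Returns None
    (undefined) when no window is aberrant in either sample.
    """
    aberrant = [
        w
        for w in windows
        if not (_is_normal(w.state_a, ploidy, exact) and _is_normal(w.state_b, ploidy, exact))
    ]
    if not aberrant:
        log.warning("CN event similarity undefined: no aberrant window in either sample")
        return None
    shared = sum(1 for w in aberrant if w.state_a == w.state_b)
    return 100.0 * shared / len(aberrant)


def cn_length_similarity(windows: Sequence[CnWindow]) -> float:
    """Length-weighted percent of the compared genome where the two
    samples' states agree, shared-normal stretches included."""
    total = sum(w.length for w in windows)
    if total == 0:
        return 0.0
    agree = sum(w.length for w in windows if w.state_a == w.state_b)
    return 100.0 * agree / total


def compare_profiles(
    profile_a: CnProfile,
    profile_b: CnProfile,
    genome: GenomeModel,
    ploidy: float = 2.0,
    exact: bool = False,
) -> tuple[float | None, float]:
    """(event similarity, length similarity) for a pair of profiles."""
    windows = union_windows(profile_a, profile_b, genome, ploidy, exact)
    return cn_event_similarity(windows, ploidy, exact), cn_length_similarity(windows)
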