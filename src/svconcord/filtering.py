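"""Tumor catalogue filtering.

Raw caller output is reduced to a per-tumor catalogue by, in order:

1. read-pair support >= one third of the sample's average sequence
   coverage (floored at 2);
2. removal of events matching the normal-pool catalogue (likely
   germline), using the same two-sided +/-500 bp window as pair matching;
3. removal of intrachromosomal events with span < 7 kb (small-event
   noise; CTX exempt);
4. removal of events with a breakpoint in a centromere mask;
5. removal of events with a breakpoint in a segmental-duplication mask.

Removal is attributed to the first matching filter; the output set is
independent of the order, only the report attribution depends on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .compare import MatchWindow, breakpoints_match
from .model import GenomeModel, Rearrangement, SampleMeta

log = logging.getLogger("svconcord")

FILTER_ORDER = ("below_support", "normal_pool", "small_itx", "centromere", "segdup")


@dataclass
class FilterReport:
    """Accounting of catalogue filtering; input = sum(removed) + output."""

    input_count: int = 0
    removed_by: dict[str, int] = field(default_factory=lambda: {k: 0 for k in FILTER_ORDER})
    output_count: int = 0

    def check(self) -> None:
        if self.input_count - sum(self.removed_by.values()) != self.output_count:
            raise AssertionError("filter report does not balance")


def support_threshold(sequence_coverage: float) -> int:
    """Minimum read-pair support: ceil(coverage / 3), floored at 2.

    At 9x sequence coverage the threshold is 3 read pairs.
    """
    if sequence_coverage <= 0:
        raise ValueError("sequence coverage must be positive")
    return max(2, math.ceil(sequence_coverage / 3))


def filter_catalogue(
    raw_calls: Sequence[Rearrangement],
    meta: SampleMeta,
    normal_pool_calls: Sequence[Rearrangement] | None,
    genome: GenomeModel,
    min_itx_span: int = 7000,
    window: MatchWindow = MatchWindow(500),
) -> tuple[list[Rearrangement], FilterReport]:
    """Apply the support, germline, size and region filters to raw calls.

    A missing normal pool (None) skips the germline filter with a logged
    warning; an empty pool list is a present-but-empty pool.
    """
    report = FilterReport(input_count=len(raw_calls))
    threshold = support_threshold(meta.sequence_coverage)

    surviving: list[Rearrangement] = []
    for r in raw_calls:
        if r.support < threshold:
            report.removed_by["below_support"] += 1
        else:
            surviving.append(r)

    if normal_pool_calls is None:
        log.warning(
            "sample %s: no normal pool available; germline filter skipped", meta.sample_id
        )
    elif surviving:
        # any pool match removes (not one-to-one: several tumor events may
        # hit one pool event and all are germline-suspect)
        kept: list[Rearrangement] = []
        for r in surviving:
            if any(breakpoints_match(r, p, window) for p in normal_pool_calls):
                report.removed_by["normal_pool"] += 1
            else:
                kept.append(r)
        surviving = kept

    kept = []
    for r in surviving:
        if r.intrachromosomal and (r.span or 0) < min_itx_span:
            report.removed_by["small_itx"] += 1
        else:
            kept.append(r)
    surviving = kept

    for mask_name, key in (("centromere", "centromere"), ("segdup", "segdup")):
        kept = []
        for r in surviving:
            if genome.in_mask(r.left, [mask_name]) or genome.in_mask(r.right, [mask_name]):
                report.removed_by[key] += 1
            else:
                kept.append(r)
        surviving = kept

    report.output_count = len(surviving)
    report.check()
    return surviving, report
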