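"""Shared/specific classification of rearrangements between two tumors.

Two events match when their chromosome pairs are identical and both
breakpoints agree within a +/- 500 bp window (inclusive).  Classification
proceeds in three passes, mirroring how paired tumor catalogues are
curated in practice:

1. *direct* — greedy one-to-one matching of the two filtered catalogues
   by ascending summed two-side distance;
2. *rescue* — a still-specific event is reclassified as shared if the
   partner sample's raw (unfiltered, sub-threshold) call list contains a
   windowed match;
3. *look-up* — a still-specific event is reclassified as shared if at
   least one discordant read pair in the partner sample supports both of
   its ends within the window.

Rescue and look-up only ever move events from specific to shared.  Each
tumor's total is the number of events classified for it (shared +
specific), so a rescued event counts toward both totals even though it
entered through only one catalogue — this is what makes the two
directional percentages of a pair differ while the shared count is one
number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import EvidenceIndex, Rearrangement


@dataclass(frozen=True)
class MatchWindow:
    """Half-width of the breakpoint matching window, in bp."""

    half_width: int = 500

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("window half-width must be >= 0")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def breakpoints_match(r1: Rearrangement, r2: Rearrangement, w: MatchWindow) -> bool:
    """True iff chromosome pairs are identical and both breakpoint
    distances are within the window (boundary inclusive).  The caller's
    sv_type labels are deliberately not compared: the same junction may
    be labelled DEL in one sample and ITX in the other."""
    return (
        r1.left.chrom == r2.left.chrom
        and r1.right.chrom == r2.right.chrom
        and abs(r1.left.pos - r2.left.pos) <= w.half_width
        and abs(r1.right.pos - r2.right.pos) <= w.half_width
    )


def match_catalogues(
    cat_a: Sequence[Rearrangement],
    cat_b: Sequence[Rearrangement],
    w: MatchWindow,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching between two catalogues.

    Candidate pairs (same chromosome pair, both sides within the window)
    are taken in ascending order of summed two-side distance; ties break
    toward the b-side candidate with the lower (left, right) coordinates.
    Returns index pairs (i, j) into cat_a / cat_b.
    """
    by_chrom: dict[tuple[str, str], list[int]] = {}
    for j, r in enumerate(cat_b):
        by_chrom.setdefault((r.left.chrom, r.right.chrom), []).append(j)
    candidates: list[tuple[int, int, int, int, int, int, int]] = []
    for i, a in enumerate(cat_a):
        for j in by_chrom.get((a.left.chrom, a.right.chrom), ()):
            b = cat_b[j]
            dl = abs(a.left.pos - b.left.pos)
            dr = abs(a.right.pos - b.right.pos)
            if dl <= w.half_width and dr <= w.half_width:
                candidates.append(
                    (dl + dr, b.left.pos, b.right.pos, a.left.pos, a.right.pos, i, j)
                )
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matching: list[tuple[int, int]] = []
    for _, _, _, _, _, i, j in candidates:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matching.append((i, j))
    return matching


@dataclass(frozen=True)
class MatchedPair:
    """One shared rearrangement of a pair.

    Exactly one of event_a/event_b may be None: the side whose presence
    was established only through the partner's raw calls (rescued) or
    read-pair evidence (looked_up) rather than its filtered catalogue.
    """

    event_a: Rearrangement | None
    event_b: Rearrangement | None
    support_a: int
    support_b: int
    provenance: str  # direct | rescued | looked_up
    dist_left: int = 0
    dist_right: int = 0

    def representative(self) -> Rearrangement:
        ev = self.event_a if self.event_a is not None else self.event_b
        assert ev is not None
        return ev


@dataclass
class PairComparison:
    """Ledger of the shared/specific classification for one tumor pair."""

    sample_a: str
    sample_b: str
    shared_pairs: list[MatchedPair] = field(default_factory=list)
    specific_a: list[Rearrangement] = field(default_factory=list)
    specific_b: list[Rearrangement] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.shared_pairs)

    @property
    def total_a(self) -> int:
        return self.n_shared + len(self.specific_a)

    @property
    def total_b(self) -> int:
        return self.n_shared + len(self.specific_b)

    def swapped(self) -> "PairComparison":
        return PairComparison(
            sample_a=self.sample_b,
            sample_b=self.sample_a,
            shared_pairs=[
                MatchedPair(
                    event_a=p.event_b,
                    event_b=p.event_a,
                    support_a=p.support_b,
                    support_b=p.support_a,
                    provenance=p.provenance,
                    dist_left=p.dist_left,
                    dist_right=p.dist_right,
                )
                for p in self.shared_pairs
            ],
            specific_a=list(self.specific_b),
            specific_b=list(self.specific_a),
        )


def rescue(
    specific_events: Sequence[Rearrangement],
    raw_calls_other: Sequence[Rearrangement],
    w: MatchWindow,
) -> tuple[list[tuple[Rearrangement, Rearrangement]], list[Rearrangement]]:
    """Match still-specific events against the partner's raw call list.

    Returns (rescued, still_specific); rescued entries carry the matching
    raw call, whose support (>= 1) becomes the partner-side support.
    """
    rescued: list[tuple[Rearrangement, Rearrangement]] = []
    remaining: list[Rearrangement] = []
    matching = match_catalogues(specific_events, raw_calls_other, w)
    matched = {i: j for i, j in matching}
    for i, ev in enumerate(specific_events):
        if i in matched:
            rescued.append((ev, raw_calls_other[matched[i]]))
        else:
            remaining.append(ev)
    return rescued, remaining


def lookup(
    specific_events: Sequence[Rearrangement],
    evidence_other: EvidenceIndex,
    w: MatchWindow,
) -> tuple[list[tuple[Rearrangement, int]], list[Rearrangement]]:
    """Look still-specific events up in the partner's read-pair evidence.

    An event becomes shared if at least one read pair supports both of
    its ends within the window; the read-pair count is returned with it.
    """
    found: list[tuple[Rearrangement, int]] = []
    remaining: list[Rearrangement] = []
    for ev in specific_events:
        n = evidence_other.count_support(ev, w.half_width)
        if n >= 1:
            found.append((ev, n))
        else:
            remaining.append(ev)
    return found, remaining


def classify_pair(
    cat_a: Sequence[Rearrangement],
    cat_b: Sequence[Rearrangement],
    raw_a: Sequence[Rearrangement] = (),
    raw_b: Sequence[Rearrangement] = (),
    ev_a: EvidenceIndex | None = None,
    ev_b: EvidenceIndex | None = None,
    w: MatchWindow = MatchWindow(),
    sample_a: str = "a",
    sample_b: str = "b",
) -> PairComparison:
    """Full shared/specific classification: direct matching, then rescue
    (both directions), then look-up (both directions)."""
    pc = PairComparison(sample_a=sample_a, sample_b=sample_b)
    matching = match_catalogues(cat_a, cat_b, w)
    matched_a = {i for i, _ in matching}
    matched_b = {j for _, j in matching}
    for i, j in matching:
        a, b = cat_a[i], cat_b[j]
        pc.shared_pairs.append(
            MatchedPair(
                event_a=a,
                event_b=b,
                support_a=a.support,
                support_b=b.support,
                provenance="direct",
                dist_left=abs(a.left.pos - b.left.pos),
                dist_right=abs(a.right.pos - b.right.pos),
            )
        )
    spec_a = [r for i, r in enumerate(cat_a) if i not in matched_a]
    spec_b = [r for j, r in enumerate(cat_b) if j not in matched_b]

    rescued_a, spec_a = rescue(spec_a, raw_b, w)
    for ev, raw in rescued_a:
        pc.shared_pairs.append(
            MatchedPair(
                event_a=ev, event_b=None,
                support_a=ev.support, support_b=raw.support,
                provenance="rescued",
                dist_left=abs(ev.left.pos - raw.left.pos),
                dist_right=abs(ev.right.pos - raw.right.pos),
            )
        )
    rescued_b, spec_b = rescue(spec_b, raw_a, w)
    for ev, raw in rescued_b:
        pc.shared_pairs.append(
            MatchedPair(
                event_a=None, event_b=ev,
                support_a=raw.support, support_b=ev.support,
                provenance="rescued",
                dist_left=abs(ev.left.pos - raw.left.pos),
                dist_right=abs(ev.right.pos - raw.right.pos),
            )
        )
    if ev_b is not None:
        found, spec_a = lookup(spec_a, ev_b, w)
        for ev, n in found:
            pc.shared_pairs.append(
                MatchedPair(
                    event_a=ev, event_b=None,
                    support_a=ev.support, support_b=n,
                    provenance="looked_up",
                )
            )
    if ev_a is not None:
        found, spec_b = lookup(spec_b, ev_a, w)
        for ev, n in found:
            pc.shared_pairs.append(
                MatchedPair(
                    event_a=None, event_b=ev,
                    support_a=n, support_b=ev.support,
                    provenance="looked_up",
                )
            )
    pc.specific_a = spec_a
    pc.specific_b = spec_b
    return pc


@dataclass(frozen=True)
class SimilarityStats:
    """Directional and combined similarity of a pair, in percent.

    Unrounded values are kept; ``*_rounded`` apply the reporting rule
    (nearest integer, half away from zero).  A direction with total 0 is
    undefined and carried as None, never as 0 %.
    """

    pct_shared_a: float | None
    pct_shared_b: float | None
    pct_combined: float
    gained: int | None = None
    lost: int | None = None

    @property
    def pct_shared_a_rounded(self) -> int | None:
        return None if self.pct_shared_a is None else round_half_away(self.pct_shared_a)

    @property
    def pct_shared_b_rounded(self) -> int | None:
        return None if self.pct_shared_b is None else round_half_away(self.pct_shared_b)

    @property
    def pct_combined_rounded(self) -> int:
        return round_half_away(self.pct_combined)


def directional_similarity(pc: PairComparison) -> tuple[float | None, float | None]:
    """Percent of each tumor's events shared with the partner:
    100 * shared / total, per direction."""
    pa = 100.0 * pc.n_shared / pc.total_a if pc.total_a > 0 else None
    pb = 100.0 * pc.n_shared / pc.total_b if pc.total_b > 0 else None
    return pa, pb


def combined_similarity(pc: PairComparison) -> float:
    """Percent shared over the union of both tumors' events."""
    union = pc.total_a + pc.total_b - pc.n_shared
    return 100.0 * pc.n_shared / union if union > 0 else 0.0


def gained_lost(pc: PairComparison, role_a: str, role_b: str) -> tuple[int, int]:
    """(gained, lost) for a primary-metastasis comparison: events the
    metastasis acquired vs events of the primary it no longer carries."""
    roles = {role_a, role_b}
    if roles != {"primary", "metastasis"}:
        raise ValueError("gained/lost requires one primary and one metastasis")
    if role_a == "metastasis":
        return len(pc.specific_a), len(pc.specific_b)
    return len(pc.specific_b), len(pc.specific_a)


def similarity_stats(
    pc: PairComparison, role_a: str | None = None, role_b: str | None = None
) -> SimilarityStats:
    pa, pb = directional_similarity(pc)
    gained = lost = None
    if role_a and role_b and {role_a, role_b} == {"primary", "metastasis"}:
        gained, lost = gained_lost(pc, role_a, role_b)
    return SimilarityStats(
        pct_shared_a=pa,
        pct_shared_b=pb,
        pct_combined=combined_similarity(pc),
        gained=gained,
        lost=lost,
    )


def comparison_rows(
    pc: PairComparison,
    patient: str,
    role_a: str,
    role_b: str,
    matched: bool = True,
    cn_pct: float | None = None,
) -> list[dict]:
    """Two directional report rows (one per tumor) for a comparison, in
    the shape of the cohort concordance table."""
    rows = []
    for this, other, role, prole, total, specific in (
        (pc.sample_a, pc.sample_b, role_a, role_b, pc.total_a, len(pc.specific_a)),
        (pc.sample_b, pc.sample_a, role_b, role_a, pc.total_b, len(pc.specific_b)),
    ):
        rows.append(
            {
                "patient": patient,
                "sample": this,
                "paired_sample": other,
                "role": role,
                "paired_role": prole,
                "total": total,
                "shared": pc.n_shared,
                "specific": specific,
                "matched": matched,
                "cn_shared_pct": cn_pct,
            }
        )
        cn_pct = None  # CN similarity is one number per comparison
    return rows


def summarize_rows(rows: pd.DataFrame) -> dict:
    """Cohort summary over directional comparison rows.

    Expects columns patient, sample, paired_sample, role, paired_role,
    total, shared, specific, matched and optionally cn_shared_pct (one
    non-null value per comparison).  Percentages are computed unrounded
    and medians reported with half-away-from-zero rounding, matching how
    the per-row percentages themselves are reported.

    Two aggregations of the conditional likelihood P(shared-in-metastasis
    given present-in-primary) are emitted: pooled over all events and the
    per-pair mean; they answer subtly different questions and neither is
    preferred here.
    """
    df = rows.copy()
    df["pct_shared"] = 100.0 * df["shared"] / df["total"]

    def block(sub: pd.DataFrame) -> dict:
        out = {}
        for col in ("total", "shared", "specific"):
            out[f"median_{col}"] = round_half_away(float(np.median(sub[col])))
            out[f"min_{col}"] = int(sub[col].min())
            out[f"max_{col}"] = int(sub[col].max())
        pct = sub["pct_shared"]
        out["median_pct_shared"] = round_half_away(float(np.median(pct)))
        out["min_pct_shared"] = round_half_away(float(pct.min()))
        out["max_pct_shared"] = round_half_away(float(pct.max()))
        if "cn_shared_pct" in sub and sub["cn_shared_pct"].notna().any():
            cn = sub["cn_shared_pct"].dropna().astype(float)
            out["median_cn_pct"] = round_half_away(float(np.median(cn)))
            out["min_cn_pct"] = round_half_away(float(cn.min()))
            out["max_cn_pct"] = round_half_away(float(cn.max()))
        return out

    summary: dict = {}
    matched = df[df["matched"]]
    if len(matched):
        summary["paired"] = block(matched)
        pm = matched[(matched["role"] == "primary") & (matched["paired_role"] == "metastasis")]
        mp = matched[(matched["role"] == "metastasis") & (matched["paired_role"] == "primary")]
        if len(pm) and len(mp):
            # gained = metastasis-specific, lost = primary-specific, per
            # primary-metastasis comparison
            summary["gained"] = {
                "median": round_half_away(float(np.median(mp["specific"]))),
                "min": int(mp["specific"].min()),
                "max": int(mp["specific"].max()),
            }
            summary["lost"] = {
                "median": round_half_away(float(np.median(pm["specific"]))),
                "min": int(pm["specific"].min()),
                "max": int(pm["specific"].max()),
            }
            summary["p_met_given_prim_pooled"] = float(pm["shared"].sum() / pm["total"].sum())
            summary["p_met_given_prim_mean"] = float((pm["shared"] / pm["total"]).mean())
    unmatched = df[~df["matched"]]
    if len(unmatched):
        summary["random_pairs"] = block(unmatched)
    return summary
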