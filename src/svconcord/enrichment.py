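"""Genic-breakpoint and cancer-gene enrichment via simulation nulls.

Two questions, two empirical nulls:

* do breakpoints fall in genic areas (gene body plus 2 kb upstream of
  the TSS, strand-aware) more often than uniform random positions over
  the unmasked genome?  Null: redraw the same number of breakpoints
  uniformly, many times.
* among the genes hit, are known cancer genes over-represented?  Null:
  random draws, without replacement, of equally many genes from the
  annotated universe (hypergeometric-shaped by construction).

Empirical two-sided p-values are 2 x tail count / n_sims (capped at 1);
a zero tail is reported as the bound 2 / n_sims rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import GeneRecord, GenomeModel, Rearrangement


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    n_total: int
    null_median: float
    null_min: int
    null_max: int
    n_sims: int
    p_two_sided: float
    p_is_bound: bool  # True when the tail count was 0 and p is an upper bound
    fold: float  # observed / null_median, 1 decimal

    def __post_init__(self) -> None:
        if not (self.null_min <= self.null_median <= self.null_max):
            raise ValueError("null summary out of order")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError("p must be in (0, 1]")


def fold_enrichment(observed: float, null_median: float) -> float:
    """Fold over the null median, rounded to one decimal."""
    if null_median <= 0:
        raise ValueError("null median must be positive for a fold change")
    return round(observed / null_median, 1)


def empirical_two_sided_p(null_counts: np.ndarray, observed: float) -> tuple[float, bool]:
    """Two-sided empirical p: twice the tail count beyond the observed
    value (upper tail if observed exceeds the null median, lower
    otherwise), over n_sims; a zero tail returns the bound 2/n_sims."""
    null_counts = np.asarray(null_counts)
    n = len(null_counts)
    med = float(np.median(null_counts))
    if observed > med:
        tail = int((null_counts >= observed).sum())
    elif observed < med:
        tail = int((null_counts <= observed).sum())
    else:
        return 1.0, False
    if tail == 0:
        return 2.0 / n, True
    return min(1.0, 2.0 * tail / n), False


def _result(observed: int, n_total: int, null_counts: np.ndarray) -> EnrichmentResult:
    p, bound = empirical_two_sided_p(null_counts, observed)
    med = float(np.median(null_counts))
    return EnrichmentResult(
        observed=observed,
        n_total=n_total,
        null_median=med,
        null_min=int(null_counts.min()),
        null_max=int(null_counts.max()),
        n_sims=len(null_counts),
        p_two_sided=p,
        p_is_bound=bound,
        fold=fold_enrichment(observed, med) if med > 0 else float("inf"),
    )


class GenicIndex:
    """Point-in-genic-area queries over an annotation."""

    def __init__(self, genes: Sequence[GeneRecord], promoter: int = 2000):
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            span = g.extended_span(promoter)
            self.trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, g.name)

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def is_genic(self, chrom: str, pos: int) -> bool:
        tree = self.trees.get(chrom)
        return tree is not None and bool(tree.at(pos))


@dataclass
class GenicBreakpoints:
    n_breakpoints: int
    n_genic: int
    n_rearrangements: int
    n_rearr_with_genic: int
    affected_genes: set[str]

    @property
    def pct_genic(self) -> float:
        return 100.0 * self.n_genic / self.n_breakpoints if self.n_breakpoints else 0.0


def genic_breakpoints(
    events: Iterable[Rearrangement],
    genes: Sequence[GeneRecord],
    promoter: int = 2000,
) -> GenicBreakpoints:
    """Count breakpoints in genic areas and collect the affected genes.

    A breakpoint is genic iff it lies in some gene's strand-aware
    extended span (inclusive at exactly ``promoter`` bp upstream of the
    TSS); a rearrangement counts as genic when at least one of its two
    breakpoints is.
    """
    index = GenicIndex(genes, promoter)
    n_bp = n_genic = n_re = n_re_genic = 0
    affected: set[str] = set()
    for r in events:
        n_re += 1
        hit_any = False
        for bp in (r.left, r.right):
            n_bp += 1
            names = index.genes_at(bp.chrom, bp.pos)
            if names:
                n_genic += 1
                hit_any = True
                affected.update(names)
        if hit_any:
            n_re_genic += 1
    return GenicBreakpoints(n_bp, n_genic, n_re, n_re_genic, affected)


def _flattened_unmasked(genome: GenomeModel, avoid_masks: bool) -> tuple[np.ndarray, list[tuple[str, int, int, int]]]:
    """Unmasked genome as a flat coordinate space: returns segment table
    (chrom, start, end, cumulative offset) and the total length."""
    segs: list[tuple[str, int, int, int]] = []
    offset = 0
    for chrom, length in genome.chrom_lengths.items():
        if avoid_masks:
            masked = sorted(
                (iv.start, iv.end)
                for ivs in genome.masks.values()
                for iv in ivs
                if iv.chrom == chrom
            )
        else:
            masked = []
        cursor = 0
        for s, e in masked:
            if s > cursor:
                segs.append((chrom, cursor, s, offset))
                offset += s - cursor
            cursor = max(cursor, e)
        if cursor < length:
            segs.append((chrom, cursor, length, offset))
            offset += length - cursor
    return np.array([offset]), segs


def simulate_genic_null(
    n_breakpoints: int,
    genome: GenomeModel,
    genes: Sequence[GeneRecord],
    n_sims: int,
    seed: int,
    observed: int | None = None,
    promoter: int = 2000,
    avoid_masks: bool = True,
) -> EnrichmentResult:
    """Null distribution of genic breakpoint counts: ``n_sims`` draws of
    ``n_breakpoints`` uniform positions over the (unmasked) genome,
    summarized against ``observed`` (defaulting to the null's own median,
    i.e. p = 1)."""
    counts = simulate_genic_null_counts(
        n_breakpoints, genome, genes, n_sims, seed, promoter, avoid_masks
    )
    obs = int(np.median(counts)) if observed is None else observed
    return _result(obs, n_breakpoints, counts)


def simulate_genic_null_counts(
    n_breakpoints: int,
    genome: GenomeModel,
    genes: Sequence[GeneRecord],
    n_sims: int,
    seed: int,
    promoter: int = 2000,
    avoid_masks: bool = True,
) -> np.ndarray:
    """Vectorized genic-hit counts per simulation, deterministic given
    the seed."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    total_arr, segs = _flattened_unmasked(genome, avoid_masks)
    total = int(total_arr[0])
    if total <= 0:
        raise ValueError("no unmasked genome to draw from")
    # merged genic intervals mapped into flattened coordinates
    merged: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        span = g.extended_span(promoter)
        merged.setdefault(span.chrom, []).append(
            (max(0, span.start), min(span.end, genome.chrom_lengths[span.chrom]))
        )
    boundaries: list[int] = []
    for chrom, ivals in merged.items():
        ivals.sort()
        flat: list[tuple[int, int]] = []
        cs, ce = ivals[0]
        for s, e in ivals[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                flat.append((cs, ce))
                cs, ce = s, e
        flat.append((cs, ce))
        for s, e in flat:
            for seg_chrom, seg_s, seg_e, off in segs:
                if seg_chrom != chrom:
                    continue
                lo, hi = max(s, seg_s), min(e, seg_e)
                if lo < hi:
                    boundaries.append(off + lo - seg_s)
                    boundaries.append(off + hi - seg_s)
    bnd = np.sort(np.array(boundaries, dtype=np.int64)) if boundaries else np.array([], dtype=np.int64)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        draws = rng.integers(0, total, size=n_breakpoints)
        if len(bnd):
            counts[i] = int((np.searchsorted(bnd, draws, side="right") % 2 == 1).sum())
        else:
            counts[i] = 0
    return counts


def simulate_cancer_null_counts(
    draw_size: int, universe_size: int, n_cancer: int, n_sims: int, seed: int
) -> np.ndarray:
    """Cancer-gene hits per random draw of ``draw_size`` genes, without
    replacement, from a universe containing ``n_cancer`` cancer genes."""
    indicator = np.zeros(universe_size, dtype=np.int8)
    indicator[:n_cancer] = 1
    rng = np.random.default_rng(seed)
    counts = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        draw = rng.choice(universe_size, size=draw_size, replace=False)
        counts[i] = int(indicator[draw].sum())
    return counts


def cancer_gene_enrichment(
    affected_genes: Iterable[str],
    universe: Sequence[str],
    cancer_genes: Iterable[str],
    n_sims: int,
    seed: int,
) -> EnrichmentResult:
    """Cancer-gene over-representation among the affected genes.

    Simulates ``n_sims`` random draws, without replacement, of
    ``len(affected_genes)`` genes from the universe and counts cancer
    genes per draw; the null is hypergeometric-shaped.
    """
    affected = set(affected_genes)
    universe = list(universe)
    if not affected <= set(universe):
        raise ValueError("affected genes must be a subset of the universe")
    cancer = set(cancer_genes) & set(universe)
    observed = len(affected & cancer)
    counts = simulate_cancer_null_counts(
        len(affected), len(universe), len(cancer), n_sims, seed
    )
    return _result(observed, len(affected), counts)


def affected_gene_table(
    catalogues: dict[str, list[Rearrangement]],
    patient_of: dict[str, str],
    genes: Sequence[GeneRecord],
    genome: GenomeModel,
    w=None,
    promoter: int = 2000,
):
    """Per-gene counts of unique rearrangements and patients.

    Events are deduplicated across samples through the non-redundant
    barcode clustering first, so one shared event hitting a gene in two
    samples of a patient counts once.  Sorted by unique-rearrangement
    count descending, ties by gene name.
    """
    import pandas as pd

    from .barcode import build_nonredundant
    from .compare import MatchWindow

    w = w or MatchWindow()
    bm = build_nonredundant(catalogues, w, genome)
    index = GenicIndex(genes, promoter)
    per_gene: dict[str, dict] = {}
    for col, (rep, members) in enumerate(zip(bm.representatives, bm.clusters)):
        names = set(index.genes_at(rep.left.chrom, rep.left.pos)) | set(
            index.genes_at(rep.right.chrom, rep.right.pos)
        )
        if not names:
            continue
        patients = {patient_of[m.sample_id] for m in members if m.sample_id in patient_of}
        for name in names:
            rec = per_gene.setdefault(name, {"rearrangements": set(), "patients": set()})
            rec["rearrangements"].add(col)
            rec["patients"].update(patients)
    cancer = getattr(genome, "cancer_genes", set())
    rows = [
        {
            "gene": name,
            "n_rearrangements": len(rec["rearrangements"]),
            "n_patients": len(rec["patients"]),
            "cancer_gene": name in cancer,
        }
        for name, rec in per_gene.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_rearrangements", "n_patients", "cancer_gene"])
    if len(df):
        df = df.sort_values(
            ["n_rearrangements", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def validation_summary(
    shared_tested: int,
    shared_confirmed: int,
    shared_germline: int,
    specific_tested: int,
    specific_confirmed: int,
) -> dict:
    """PCR-style validation arithmetic.

    Per-category percentages (integer-rounded); categories with zero
    tested assays are omitted rather than reported as 0 %.  Two overall
    accuracies are emitted because "excluding germline" admits two
    readings: subtracting confirmed-germline assays from both numerator
    and denominator (``overall_pct_excl_germline``) or ignoring the
    germline annotation entirely (``overall_pct_all_informative``).
    """
    from .compare import round_half_away

    out: dict = {}
    if shared_tested > 0:
        out["shared_pct"] = round_half_away(100.0 * shared_confirmed / shared_tested)
    if specific_tested > 0:
        out["specific_pct"] = round_half_away(100.0 * specific_confirmed / specific_tested)
    total = shared_tested + specific_tested
    if total > 0:
        out["overall_pct_all_informative"] = round_half_away(
            100.0 * (shared_confirmed + specific_confirmed) / total
        )
        denom = total - shared_germline
        if denom > 0:
            out["overall_pct_excl_germline"] = round_half_away(
                100.0 * (shared_confirmed - shared_germline + specific_confirmed) / denom
            )
    return out
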