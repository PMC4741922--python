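"""Rearrangement hotspot analysis: chromosome-pair heatmaps, a
genome-wide breakpoint density track, and hotspot region calls.

The density track is a Gaussian kernel density over breakpoint
positions, computed per chromosome and weighted by each chromosome's
share of total breakpoints, so the track is one genome-wide density
(integral ~ 1) with no kernel mass leaking across chromosome boundaries.
Every rearrangement contributes both of its breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GeneRecord, GenomeModel, Interval, Rearrangement


def _breakpoints_by_chrom(events: Iterable[Rearrangement]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for r in events:
        out.setdefault(r.left.chrom, []).append(r.left.pos)
        out.setdefault(r.right.chrom, []).append(r.right.pos)
    return out


def pair_heatmap(
    events: Sequence[Rearrangement],
    genome: GenomeModel,
    bin_size: int = 50_000_000,
) -> pd.DataFrame:
    """Rearrangement counts per chromosome pair, normalized per
    ``bin_size`` of combined chromosome length.

    Off-diagonal cell (i, j): interchromosomal events joining i and j
    divided by (L_i + L_j) / bin_size.  Diagonal cell (i, i):
    intrachromosomal events on i divided by L_i / bin_size.  Call once
    per sample group (primaries / metastases, all or specific-only
    events) to build the split views.
    """
    chroms = genome.chromosomes
    idx = {c: k for k, c in enumerate(chroms)}
    counts = np.zeros((len(chroms), len(chroms)))
    for r in events:
        i, j = idx[r.left.chrom], idx[r.right.chrom]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    norm = (lengths[:, None] + lengths[None, :]) / bin_size
    np.fill_diagonal(norm, lengths / bin_size)
    return pd.DataFrame(counts / norm, index=chroms, columns=chroms)


@dataclass
class DensityTrack:
    """Per-chromosome breakpoint density grids (density per bp)."""

    grids: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (positions, density)
    bandwidth: float
    grid_step: int

    def integral(self) -> float:
        return float(
            sum(np.trapezoid(dens, pos) for pos, dens in self.grids.values())
        )

    def max_density(self) -> float:
        return float(max((dens.max() for _, dens in self.grids.values()), default=0.0))


def breakpoint_density(
    events: Sequence[Rearrangement],
    genome: GenomeModel,
    bandwidth: float = 10_000.0,
    grid_step: int = 10_000,
) -> DensityTrack:
    """Genome-wide Gaussian kernel breakpoint density (sigma =
    ``bandwidth``), both breakpoints of every event contributing.

    Each chromosome's curve is a per-chromosome KDE weighted by that
    chromosome's share of all breakpoints, so the genome-wide integral
    is ~1 (up to kernel tails truncated at chromosome ends).
    """
    bps = _breakpoints_by_chrom(events)
    n_total = sum(len(v) for v in bps.values())
    if n_total == 0:
        raise ValueError("density requires at least one breakpoint")
    sigma = float(bandwidth)
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    grids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in genome.chrom_lengths.items():
        pos = np.arange(0, length + 1, grid_step, dtype=float)
        if pos[-1] != length:
            pos = np.append(pos, float(length))
        points = np.asarray(bps.get(chrom, ()), dtype=float)
        if len(points) == 0:
            grids[chrom] = (pos, np.zeros_like(pos))
            continue
        dens = np.zeros_like(pos)
        # chunk over breakpoints to bound memory on dense chromosomes
        for start in range(0, len(points), 512):
            chunk = points[start : start + 512]
            z = (pos[None, :] - chunk[:, None]) / sigma
            dens += np.exp(-0.5 * z * z).sum(axis=0)
        dens *= norm / n_total
        grids[chrom] = (pos, dens)
    return DensityTrack(grids=grids, bandwidth=sigma, grid_step=grid_step)


def call_hotspots(track: DensityTrack, threshold: float = 3e-6) -> list[Interval]:
    """Maximal grid runs with density strictly above the threshold,
    snapped to the grid as half-open intervals.  Runs separated by even a
    single sub-threshold grid point stay separate."""
    regions: list[Interval] = []
    step = track.grid_step
    for chrom, (pos, dens) in track.grids.items():
        above = dens > threshold
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                start = int(pos[i])
                end = int(pos[j]) + step
                regions.append(Interval(chrom, start, min(end, int(pos[-1]) + step)))
                i = j + 1
            else:
                i += 1
    return regions


def annotate_regions(
    regions: Sequence[Interval],
    genes: Sequence[GeneRecord],
    promoter: int = 2000,
) -> dict[Interval, list[str]]:
    """Genes whose extended (promoter-included, strand-aware) span
    intersects each region."""
    out: dict[Interval, list[str]] = {}
    spans = [(g, g.extended_span(promoter)) for g in genes]
    for region in regions:
        hits = [g.name for g, span in spans if span.overlaps(region)]
        out[region] = sorted(hits)
    return out


def write_bedgraph(track: DensityTrack, path: str) -> None:
    """Serialize the density track as bedGraph (one value per grid
    cell, the density at the cell's left edge)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="breakpoint_density"\n')
        for chrom, (pos, dens) in track.grids.items():
            for k in range(len(pos) - 1):
                fh.write(f"{chrom}\t{int(pos[k])}\t{int(pos[k + 1])}\t{dens[k]:.6e}\n")
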