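"""Synthetic clonally related tumor pairs.

The generator emulates the data a low-coverage paired-end WGS study of
primary/metastasis tumor pairs produces, at the level this pipeline
consumes it: per-sample rearrangement call catalogues with read-pair
support, the unfiltered raw call lists, a discordant read-pair evidence
store, piecewise-constant copy-number segmentations, and a genome model
with masks, gene annotation and a cancer-gene subset.

Generative model, per patient:

* a set of somatic rearrangements is placed uniformly over the unmasked
  genome (types drawn at the frequencies seen in breast tumors: roughly
  even CTX/ITX/DEL/INV);
* a ``shared_fraction`` of the primary's events is retained in the
  metastasis; the metastasis additionally carries ``n_met_private`` new
  events;
* germline structural polymorphisms are present in both tumors and in
  the normal-pool catalogue;
* each sample observes an event's breakpoints with independent Gaussian
  jitter (sd ``jitter_sd``), and with read-pair support drawn
  Poisson(physical coverage x clonal fraction).  Clonal fractions follow
  Beta(5, 2); a configurable fraction of shared events is made subclonal
  in one sample (support below the catalogue threshold, exercising the
  rescue path), and a further subset is visible only as raw read-pair
  evidence (exercising the look-up path).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .filtering import support_threshold
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

SV_TYPE_FREQS = {"CTX": 0.28, "ITX": 0.23, "DEL": 0.22, "INV": 0.27}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the structure of an 11-patient breast cancer
    primary/metastasis WGS cohort: ~100 events per tumor, 89 % of the
    primary's events retained in the metastasis, 14 metastasis-private
    events, 22.3x physical / 9.3x sequence coverage.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (50_000_000,) * 5
    n_primary_events: int = 100
    shared_fraction: float = 0.89
    n_met_private: int = 14
    n_germline: int = 5
    coverage_primary: float = 22.3  # physical, fold
    coverage_met: float = 22.3
    seq_coverage_primary: float = 9.3
    seq_coverage_met: float = 9.3
    jitter_sd: float = 100.0  # bp, per sample per breakpoint
    subclonal_fraction: float = 0.1  # of shared events, sub-threshold in one sample
    lookup_only_fraction: float = 0.05  # of shared events, evidence-only in one sample
    clonal_beta: tuple[float, float] = (5.0, 2.0)
    cn_n_segments: int = 40
    cn_states: tuple[int, ...] = (0, 1, 3, 4)
    shared_cn_fraction: float = 0.35
    genic_fraction_target: float = 0.433
    gene_body_length: int = 23_000
    n_cancer_genes: int = 50
    min_intra_span: int = 20_000
    max_intra_span: int = 5_000_000
    centromere_half_width: int = 500_000
    evidence_offset: int = 150  # read-pair mates land within +/- this of a breakpoint

    def __post_init__(self) -> None:
        for name in ("shared_fraction", "subclonal_fraction", "lookup_only_fraction",
                     "shared_cn_fraction", "genic_fraction_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def build_genome(config: SimConfig, with_annotation: bool = True) -> GenomeModel:
    """Genome model for the configuration: chr1..chrN with a centromere
    mask in the middle of each chromosome, plus synthetic annotation."""
    chroms = [(f"chr{i + 1}", l) for i, l in enumerate(config.chrom_lengths)]
    masks: dict[str, list[Interval]] = {"centromere": [], "segdup": []}
    if config.centromere_half_width > 0:
        for name, length in chroms:
            mid = length // 2
            lo = max(0, mid - config.centromere_half_width)
            hi = min(length, mid + config.centromere_half_width)
            if lo < hi:
                masks["centromere"].append(Interval(name, lo, hi))
    genome = GenomeModel(chroms, masks=masks)
    if with_annotation:
        genes, cancer = simulate_annotation(config, genome)
        genome = GenomeModel(chroms, masks=masks, genes=genes, cancer_genes=cancer)
    return genome


def simulate_annotation(
    config: SimConfig, genome: GenomeModel
) -> tuple[list[GeneRecord], set[str]]:
    """Non-overlapping synthetic genes whose extended (promoter-included)
    footprint covers ~``genic_fraction_target`` of the genome, with a
    cancer-labelled subset of ``n_cancer_genes`` names."""
    rng = np.random.default_rng([config.seed, 11])
    total = genome.total_length()
    ext_len = config.gene_body_length + 2000
    n_genes = int(round(config.genic_fraction_target * total / ext_len))
    genes: list[GeneRecord] = []
    if n_genes > 0:
        per_chrom = {
            chrom: int(round(n_genes * length / total))
            for chrom, length in genome.chrom_lengths.items()
        }
        gi = 0
        for chrom, k in per_chrom.items():
            if k == 0:
                continue
            length = genome.chrom_lengths[chrom]
            spacing = length / k
            if spacing < ext_len + 2000:
                raise ValueError("genic_fraction_target too high to tile non-overlapping genes")
            for slot in range(k):
                # keep the full extended span inside the slot
                lo = int(slot * spacing) + 2000
                start = lo + int(rng.integers(0, max(1, int(spacing) - ext_len - 4000)))
                strand = "+" if gi % 2 == 0 else "-"
                genes.append(
                    GeneRecord(chrom, start, start + config.gene_body_length, f"G{gi:05d}", strand)
                )
                gi += 1
    names = [g.name for g in genes]
    k = min(config.n_cancer_genes, len(names))
    cancer = set(rng.choice(names, size=k, replace=False)) if k else set()
    return genes, cancer


@dataclass
class TruthEvent:
    """One true rearrangement with its per-sample observation."""

    primary: Rearrangement | None
    met: Rearrangement | None
    shared: bool
    germline: bool = False
    cf_primary: float = 0.0
    cf_met: float = 0.0
    subclonal_in: str | None = None  # 'primary' | 'met'
    lookup_only_in: str | None = None


@dataclass
class PatientTruth:
    patient_id: str
    genome: GenomeModel
    config: SimConfig
    events: list[TruthEvent] = field(default_factory=list)

    @property
    def primary_events(self) -> list[Rearrangement]:
        return [e.primary for e in self.events if e.primary is not None]

    @property
    def met_events(self) -> list[Rearrangement]:
        return [e.met for e in self.events if e.met is not None]

    @property
    def germline_events(self) -> list[TruthEvent]:
        return [e for e in self.events if e.germline]


def _draw_breakpoint(rng: np.random.Generator, genome: GenomeModel) -> Breakpoint:
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    for _ in range(1000):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        pos = int(rng.integers(0, int(lengths[ci])))
        bp = Breakpoint(chroms[ci], pos)
        if not genome.in_mask(bp):
            return bp
    raise RuntimeError("could not place a breakpoint outside the masks")


def _draw_event(
    rng: np.random.Generator,
    genome: GenomeModel,
    config: SimConfig,
    used: set[tuple[str, int]],
    sample_id: str = "",
) -> Rearrangement:
    types = list(SV_TYPE_FREQS)
    probs = np.array([SV_TYPE_FREQS[t] for t in types])
    for _ in range(1000):
        sv_type = types[int(rng.choice(len(types), p=probs))]
        left = _draw_breakpoint(rng, genome)
        if sv_type == "CTX":
            right = _draw_breakpoint(rng, genome)
            if right.chrom == left.chrom:
                continue
        else:
            span = int(
                math.exp(
                    rng.uniform(math.log(config.min_intra_span), math.log(config.max_intra_span))
                )
            )
            pos2 = left.pos + span
            if pos2 >= genome.chrom_lengths[left.chrom]:
                continue
            right = Breakpoint(left.chrom, pos2)
            if genome.in_mask(right):
                continue
        keys = {(left.chrom, left.pos), (right.chrom, right.pos)}
        if keys & used:
            continue
        used |= keys
        return canonicalize(
            Rearrangement(left, right, sv_type, support=0, sample_id=sample_id, origin="synthetic"),
            genome,
        )
    raise RuntimeError(
        "could not place a non-duplicate event; genome capacity exceeded for the configuration"
    )


def _jitter(
    rearr: Rearrangement, rng: np.random.Generator, sd: float, genome: GenomeModel, sample_id: str
) -> Rearrangement:
    """One sample's observation of an event: independent Gaussian offsets
    per breakpoint, truncated to chromosome bounds."""
    if sd == 0:
        return replace(rearr, sample_id=sample_id)

    def move(bp: Breakpoint) -> Breakpoint:
        pos = int(round(bp.pos + rng.normal(0.0, sd)))
        pos = min(max(pos, 0), genome.chrom_lengths[bp.chrom] - 1)
        return Breakpoint(bp.chrom, pos)

    return canonicalize(
        replace(rearr, left=move(rearr.left), right=move(rearr.right), sample_id=sample_id),
        genome,
    )


def simulate_patient(
    config: SimConfig,
    patient_id: str = "P1",
    genome: GenomeModel | None = None,
    germline_events: Sequence[Rearrangement] | None = None,
    rng: np.random.Generator | None = None,
) -> PatientTruth:
    """Draw the true somatic and germline event sets of one patient.

    Exactly ``round(shared_fraction * n_primary_events)`` of the
    primary's somatic events are retained in the metastasis.  Shared
    events appear in both samples' lists with coordinates differing only
    by the realized per-sample jitter.
    """
    genome = genome or build_genome(config)
    rng = rng if rng is not None else np.random.default_rng([config.seed, 1])
    a, b = config.clonal_beta
    truth = PatientTruth(patient_id=patient_id, genome=genome, config=config)
    used: set[tuple[str, int]] = set()
    sid_p, sid_m = f"{patient_id}_P", f"{patient_id}_M"

    if germline_events is None:
        germline_events = [
            _draw_event(rng, genome, config, used) for _ in range(config.n_germline)
        ]
    for g in germline_events:
        truth.events.append(
            TruthEvent(
                primary=_jitter(g, rng, config.jitter_sd, genome, sid_p),
                met=_jitter(g, rng, config.jitter_sd, genome, sid_m),
                shared=True,
                germline=True,
                cf_primary=1.0,
                cf_met=1.0,
            )
        )

    n_shared = int(round(config.shared_fraction * config.n_primary_events))
    shared_idx = set(rng.choice(config.n_primary_events, size=n_shared, replace=False).tolist())
    shared_events: list[TruthEvent] = []
    for i in range(config.n_primary_events):
        ev = _draw_event(rng, genome, config, used)
        if i in shared_idx:
            te = TruthEvent(
                primary=_jitter(ev, rng, config.jitter_sd, genome, sid_p),
                met=_jitter(ev, rng, config.jitter_sd, genome, sid_m),
                shared=True,
                cf_primary=float(rng.beta(a, b)),
                cf_met=float(rng.beta(a, b)),
            )
            shared_events.append(te)
        else:
            te = TruthEvent(
                primary=_jitter(ev, rng, config.jitter_sd, genome, sid_p),
                met=None,
                shared=False,
                cf_primary=float(rng.beta(a, b)),
            )
        truth.events.append(te)
    for _ in range(config.n_met_private):
        ev = _draw_event(rng, genome, config, used)
        truth.events.append(
            TruthEvent(
                primary=None,
                met=_jitter(ev, rng, config.jitter_sd, genome, sid_m),
                shared=False,
                cf_met=float(rng.beta(a, b)),
            )
        )

    # make some shared events subclonal (sub-threshold support) in one
    # sample, and a subset of those visible only as read-pair evidence
    n_sub = int(round(config.subclonal_fraction * len(shared_events)))
    n_lookup = min(int(round(config.lookup_only_fraction * len(shared_events))), n_sub)
    order = rng.permutation(len(shared_events))
    thr_p = support_threshold(config.seq_coverage_primary)
    thr_m = support_threshold(config.seq_coverage_met)
    for k in range(n_sub):
        te = shared_events[int(order[k])]
        side = "primary" if rng.random() < 0.5 else "met"
        te.subclonal_in = side
        thr = thr_p if side == "primary" else thr_m
        cov = config.coverage_primary if side == "primary" else config.coverage_met
        cf = max(0.02, (thr - 1.5) / cov)  # mean support just below threshold
        if side == "primary":
            te.cf_primary = cf
        else:
            te.cf_met = cf
        if k < n_lookup:
            te.lookup_only_in = side
    return truth


SampleKind = Literal["primary", "met"]


@dataclass
class ObservedSample:
    meta: SampleMeta
    catalogue: list[Rearrangement]
    raw_calls: list[Rearrangement]
    evidence: EvidenceIndex


def render_observed(
    truth: PatientTruth, meta: SampleMeta, config: SimConfig, which: SampleKind
) -> ObservedSample:
    """One sample's observed data: support drawn Poisson(physical
    coverage x clonal fraction) per event; events at or above the
    sequence-coverage threshold enter the catalogue, events with >= 1
    supporting pair enter the raw call list, and every supporting read
    pair enters the evidence index (with mates landing within
    ``evidence_offset`` bp of the breakpoints).  Look-up-only events are
    withheld from both call lists and live only in the evidence."""
    rng = np.random.default_rng([config.seed, 2 if which == "primary" else 3])
    coverage = config.coverage_primary if which == "primary" else config.coverage_met
    threshold = support_threshold(meta.sequence_coverage)
    catalogue: list[Rearrangement] = []
    raw_calls: list[Rearrangement] = []
    evidence = EvidenceIndex(truth.genome)
    for te in truth.events:
        rearr = te.primary if which == "primary" else te.met
        cf = te.cf_primary if which == "primary" else te.cf_met
        if rearr is None or cf <= 0:
            continue
        support = int(rng.poisson(coverage * cf))
        if support < 1:
            continue
        for _ in range(support):
            evidence.add(
                rearr.left.chrom,
                _clip(rearr.left.pos + int(rng.integers(-config.evidence_offset,
                                                        config.evidence_offset + 1)),
                      truth.genome.chrom_lengths[rearr.left.chrom]),
                rearr.right.chrom,
                _clip(rearr.right.pos + int(rng.integers(-config.evidence_offset,
                                                         config.evidence_offset + 1)),
                      truth.genome.chrom_lengths[rearr.right.chrom]),
            )
        if te.lookup_only_in == which:
            continue
        observed = replace(rearr, support=support, sample_id=meta.sample_id)
        raw_calls.append(observed)
        if support >= threshold:
            catalogue.append(observed)
    return ObservedSample(meta=meta, catalogue=catalogue, raw_calls=raw_calls, evidence=evidence)


def _clip(pos: int, length: int) -> int:
    return min(max(pos, 0), length - 1)


def render_pool(
    truth: PatientTruth, config: SimConfig, pool_id: str = "pool"
) -> list[Rearrangement]:
    """Normal-pool catalogue: the germline events at full clonal
    fraction (pool coverage taken as the primary's)."""
    rng = np.random.default_rng([config.seed, 4])
    out = []
    for te in truth.germline_events:
        base = te.primary if te.primary is not None else te.met
        assert base is not None
        support = max(1, int(rng.poisson(config.coverage_primary)))
        out.append(replace(base, support=support, sample_id=pool_id))
    return out


def simulate_cn_profiles(
    truth: PatientTruth, config: SimConfig
) -> tuple[CnProfile, CnProfile]:
    """Piecewise-constant integer CN for primary and metastasis.

    Aberrant segments are placed without overlap; each is shared (same
    interval and state in both samples) with probability
    ``shared_cn_fraction``, otherwise private to one sample.  Profiles
    list only aberrant segments; gaps are normal ploidy.
    """
    rng = np.random.default_rng([config.seed, 5])
    genome = truth.genome
    prim = CnProfile(f"{truth.patient_id}_P")
    met = CnProfile(f"{truth.patient_id}_M")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    placed = 0
    attempts = 0
    while placed < config.cn_n_segments and attempts < config.cn_n_segments * 200:
        attempts += 1
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        seg_len = int(math.exp(rng.uniform(math.log(500_000), math.log(10_000_000))))
        if seg_len >= genome.chrom_lengths[chrom]:
            continue
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - seg_len))
        end = start + seg_len
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        state = float(rng.choice(config.cn_states))
        seg = CnSegment(chrom, start, end, state)
        if rng.random() < config.shared_cn_fraction:
            prim.add(seg)
            met.add(seg)
        elif rng.random() < 0.5:
            prim.add(seg)
        else:
            met.add(seg)
        placed += 1
    prim.validate()
    met.validate()
    return prim, met


@dataclass
class PatientData:
    """Everything observed for one synthetic patient."""

    patient_id: str
    truth: PatientTruth
    primary: ObservedSample
    met: ObservedSample
    cn_primary: CnProfile
    cn_met: CnProfile


@dataclass
class Cohort:
    config: SimConfig
    genome: GenomeModel
    patients: list[PatientData]
    pool_catalogue: list[Rearrangement]
    pool_meta: SampleMeta


def simulate_cohort(config: SimConfig, n_patients: int = 6) -> Cohort:
    """A cohort of independent patients on one genome, sharing a single
    set of germline polymorphisms that also forms the normal pool."""
    genome = build_genome(config)
    germ_rng = np.random.default_rng([config.seed, 6])
    used: set[tuple[str, int]] = set()
    germline = [_draw_event(germ_rng, genome, config, used) for _ in range(config.n_germline)]

    patients: list[PatientData] = []
    pool: list[Rearrangement] = []
    for i in range(n_patients):
        pid = f"P{i + 1}"
        pconf = replace_seed(config, derive_seed(config.seed, i + 1))
        truth = simulate_patient(
            pconf, patient_id=pid, genome=genome, germline_events=germline
        )
        meta_p = SampleMeta(f"{pid}_P", pid, "primary", config.coverage_primary,
                            config.seq_coverage_primary)
        meta_m = SampleMeta(f"{pid}_M", pid, "metastasis", config.coverage_met,
                            config.seq_coverage_met)
        obs_p = render_observed(truth, meta_p, pconf, "primary")
        obs_m = render_observed(truth, meta_m, pconf, "met")
        cn_p, cn_m = simulate_cn_profiles(truth, pconf)
        patients.append(PatientData(pid, truth, obs_p, obs_m, cn_p, cn_m))
        if not pool:
            pool = render_pool(truth, pconf)
    pool_meta = SampleMeta("pool", "pool", "normal_pool", config.coverage_primary,
                           config.seq_coverage_primary)
    return Cohort(config=config, genome=genome, patients=patients,
                  pool_catalogue=pool, pool_meta=pool_meta)


def derive_seed(seed: int, stream: int) -> int:
    """Stable sub-seed below 2^31 for an independent stream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def replace_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
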