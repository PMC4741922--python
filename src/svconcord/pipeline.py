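"""End-to-end orchestration: simulate -> filter -> compare -> summarize
-> barcode -> clonality -> hotspots -> enrich, driven by one YAML config.

Each stage reads its inputs from the files the previous stage wrote, so
every intermediate is inspectable and the run can resume: a stage is
skipped when its recorded parameter hash matches and all its output
files still checksum to what the state file recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import barcode as barcode_mod
from . import cnv, enrichment, io
from .clonality import clonality_table
from .compare import MatchWindow, classify_pair, comparison_rows, round_half_away, summarize_rows
from .filtering import filter_catalogue
from .hotspots import annotate_regions, breakpoint_density, call_hotspots, pair_heatmap, write_bedgraph
from .model import GenomeModel, SampleMeta
from .simulate import Cohort, SimConfig, simulate_cohort

log = logging.getLogger("svconcord")

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_ALLOWED_TOP = {"seed", "window", "n_patients", "simulate", "filter", "hotspots", "enrichment"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check; raises before any computation on violation."""
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = cfg.get("simulate", {})
    bad = set(sim) - _SIM_FIELDS
    if bad:
        raise ValueError(f"unknown simulate keys: {sorted(bad)}")
    for section, allowed in (
        ("filter", {"min_itx_span"}),
        ("hotspots", {"bandwidth", "grid_step", "threshold", "bin_size"}),
        ("enrichment", {"n_sims"}),
    ):
        bad = set(cfg.get(section, {})) - allowed
        if bad:
            raise ValueError(f"unknown {section} keys: {sorted(bad)}")


def default_config(seed: int = 0) -> dict:
    """The bundled fully synthetic demo configuration."""
    return {
        "seed": seed,
        "window": 500,
        "n_patients": 6,
        "simulate": {"n_primary_events": 100, "shared_fraction": 0.89, "n_met_private": 14},
        "filter": {"min_itx_span": 7000},
        "hotspots": {"bandwidth": 10000.0, "grid_step": 10000, "threshold": 3e-6},
        "enrichment": {"n_sims": 2000},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: Any) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


class _State:
    """Checksummed stage ledger enabling partial reruns."""

    def __init__(self, outdir: Path):
        self.path = outdir / "pipeline_state.json"
        self.state: dict = {}
        if self.path.exists():
            self.state = json.loads(self.path.read_text())

    def fresh(self, stage: str, params_hash: str, outputs: list[Path]) -> bool:
        rec = self.state.get(stage)
        if not rec or rec["params"] != params_hash:
            return False
        for p, digest in rec["outputs"].items():
            fp = Path(p)
            if not fp.exists() or _sha256(fp) != digest:
                return False
        if set(rec["outputs"]) != {str(p) for p in outputs}:
            return False
        return True

    def record(self, stage: str, params_hash: str, outputs: list[Path]) -> None:
        self.state[stage] = {
            "params": params_hash,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.state, indent=1, sort_keys=True))


def _sample_paths(outdir: Path, sid: str) -> dict[str, Path]:
    d = outdir / "samples"
    return {
        "catalogue": d / f"{sid}.catalogue.bedpe",
        "raw": d / f"{sid}.raw.bedpe",
        "evidence": d / f"{sid}.evidence.tsv",
        "filtered": d / f"{sid}.filtered.bedpe",
        "report": d / f"{sid}.filter_report.tsv",
    }


def write_cohort_files(cohort: Cohort, outdir: Path) -> list[Path]:
    """Serialize a simulated cohort to the on-disk formats downstream
    stages consume."""
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, writer, *args) -> None:
        writer(*args, path)
        written.append(path)

    emit(outdir / "genome.tsv", io.write_genome, cohort.genome)
    for mask_name, ivals in cohort.genome.masks.items():
        emit(outdir / f"mask_{mask_name}.bed", io.write_intervals, ivals)
    emit(outdir / "genes.bed", io.write_genes, cohort.genome.genes)
    emit(outdir / "cancer_genes.txt", io.write_gene_list, cohort.genome.cancer_genes)
    emit(outdir / "samples" / "pool.catalogue.bedpe", io.write_rearrangements,
         cohort.pool_catalogue)

    metas: list[SampleMeta] = [cohort.pool_meta]
    segs = []
    for pat in cohort.patients:
        for obs, cn in ((pat.primary, pat.cn_primary), (pat.met, pat.cn_met)):
            metas.append(obs.meta)
            paths = _sample_paths(outdir, obs.meta.sample_id)
            emit(paths["catalogue"], io.write_rearrangements, obs.catalogue)
            emit(paths["raw"], io.write_rearrangements, obs.raw_calls)
            emit(paths["evidence"], io.write_evidence, obs.evidence)
            segs.append(cn)
    emit(outdir / "cn_profiles.seg", io.write_cn_segments, segs)
    emit(outdir / "manifest.tsv", io.write_manifest, metas)
    return written


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None) -> Path:
    """Run the full analysis into ``outdir``; deterministic given the
    seed.  Returns the output directory."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _State(outdir)
    if seed is not None:
        cfg = {**cfg, "seed": seed}
    seed = int(cfg.get("seed", 0))
    window = MatchWindow(int(cfg.get("window", 500)))
    n_patients = int(cfg.get("n_patients", 6))
    sim_cfg = SimConfig(seed=seed, **cfg.get("simulate", {}))

    # ---- simulate -------------------------------------------------
    sim_hash = _params_hash({"sim": dataclasses.asdict(sim_cfg), "n_patients": n_patients})
    manifest_path = outdir / "manifest.tsv"
    if state.state.get("simulate", {}).get("params") == sim_hash and manifest_path.exists():
        log.info("simulate: outputs up to date, skipping")
    else:
        log.info("simulate: %d patients, seed %d", n_patients, seed)
        cohort = simulate_cohort(sim_cfg, n_patients=n_patients)
        written = write_cohort_files(cohort, outdir)
        state.record("simulate", sim_hash, written)

    genome = io.read_genome(outdir / "genome.tsv")
    masks = {
        name: io.read_intervals(outdir / f"mask_{name}.bed", genome)
        for name in ("centromere", "segdup")
        if (outdir / f"mask_{name}.bed").exists()
    }
    genes = io.read_genes(outdir / "genes.bed", genome)
    cancer = io.read_gene_list(outdir / "cancer_genes.txt")
    genome = GenomeModel(genome.chrom_lengths, masks=masks, genes=genes, cancer_genes=cancer)
    metas = {m.sample_id: m for m in io.read_manifest(manifest_path)}
    tumor_metas = [m for m in metas.values() if m.role != "normal_pool"]
    pool = io.read_rearrangements(outdir / "samples" / "pool.catalogue.bedpe", "bedpe", genome)

    # ---- filter ---------------------------------------------------
    min_itx = int(cfg.get("filter", {}).get("min_itx_span", 7000))
    filt_hash = _params_hash({"sim": sim_hash, "min_itx": min_itx, "w": window.half_width})
    filt_out = [p for m in tumor_metas for p in
                (_sample_paths(outdir, m.sample_id)["filtered"],
                 _sample_paths(outdir, m.sample_id)["report"])]
    if state.fresh("filter", filt_hash, filt_out):
        log.info("filter: outputs up to date, skipping")
    else:
        for m in tumor_metas:
            paths = _sample_paths(outdir, m.sample_id)
            raw = io.read_rearrangements(paths["raw"], "bedpe", genome, m.sample_id)
            filtered, report = filter_catalogue(raw, m, pool, genome, min_itx_span=min_itx,
                                                window=window)
            io.write_rearrangements(filtered, paths["filtered"])
            pd.DataFrame(
                [{"filter": k, "removed": v} for k, v in report.removed_by.items()]
                + [{"filter": "input", "removed": report.input_count},
                   {"filter": "output", "removed": report.output_count}]
            ).to_csv(paths["report"], sep="\t", index=False)
        state.record("filter", filt_hash, filt_out)

    filtered = {
        m.sample_id: io.read_rearrangements(
            _sample_paths(outdir, m.sample_id)["filtered"], "bedpe", genome, m.sample_id
        )
        for m in tumor_metas
    }
    raw = {
        m.sample_id: io.read_rearrangements(
            _sample_paths(outdir, m.sample_id)["raw"], "bedpe", genome, m.sample_id
        )
        for m in tumor_metas
    }
    evidence = {
        m.sample_id: io.read_evidence(_sample_paths(outdir, m.sample_id)["evidence"], genome)
        for m in tumor_metas
    }
    cn_profiles = io.read_cn_segments(outdir / "cn_profiles.seg", genome)

    # ---- compare + summarize -------------------------------------
    rows: list[dict] = []
    clon_dir = outdir / "clonality"
    clon_dir.mkdir(exist_ok=True)
    sids = [m.sample_id for m in tumor_metas]
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            ma, mb = metas[a], metas[b]
            matched = ma.patient_id == mb.patient_id
            pc = classify_pair(
                filtered[a], filtered[b], raw[a], raw[b], evidence[a], evidence[b],
                w=window, sample_a=a, sample_b=b,
            )
            cn_pct = None
            if a in cn_profiles and b in cn_profiles:
                ev_sim, _ = cnv.compare_profiles(cn_profiles[a], cn_profiles[b], genome)
                cn_pct = ev_sim
            rows.extend(comparison_rows(pc, ma.patient_id if matched else f"{ma.patient_id}|{mb.patient_id}",
                                        ma.role, mb.role, matched=matched, cn_pct=cn_pct))
            if matched:
                table = clonality_table(pc, ma, mb)
                table.to_csv(clon_dir / f"{ma.patient_id}.clonality.tsv", sep="\t", index=False)
    report = pd.DataFrame(rows)
    report["pct_shared"] = (100.0 * report["shared"] / report["total"]).map(round_half_away)
    report.to_csv(outdir / "cohort_report.tsv", sep="\t", index=False)
    summary = summarize_rows(report)
    (outdir / "cohort_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    # ---- barcode --------------------------------------------------
    bm = barcode_mod.build_nonredundant(filtered, window, genome)
    bm.matrix.to_csv(outdir / "barcode_matrix.tsv", sep="\t")
    dist = barcode_mod.binary_distance(bm)
    linkage = barcode_mod.ward_cluster(dist)
    (outdir / "dendrogram.newick").write_text(
        barcode_mod.to_newick(linkage, list(bm.matrix.index)) + "\n"
    )

    # ---- hotspots -------------------------------------------------
    hcfg = cfg.get("hotspots", {})
    all_events = [r for evs in filtered.values() for r in evs]
    bin_size = int(hcfg.get("bin_size", 50_000_000))
    for role in ("primary", "metastasis"):
        events = [r for m in tumor_metas if m.role == role for r in filtered[m.sample_id]]
        pair_heatmap(events, genome, bin_size).to_csv(
            outdir / f"heatmap_{role}.tsv", sep="\t"
        )
    track = breakpoint_density(
        all_events, genome,
        bandwidth=float(hcfg.get("bandwidth", 10_000.0)),
        grid_step=int(hcfg.get("grid_step", 10_000)),
    )
    write_bedgraph(track, str(outdir / "density.bedgraph"))
    regions = call_hotspots(track, threshold=float(hcfg.get("threshold", 3e-6)))
    ann = annotate_regions(regions, genome.genes)
    with open(outdir / "hotspots.bed", "w") as fh:
        for region in regions:
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{','.join(ann[region]) or '.'}\n"
            )

    # ---- enrichment ----------------------------------------------
    n_sims = int(cfg.get("enrichment", {}).get("n_sims", 2000))
    gb = enrichment.genic_breakpoints(all_events, genome.genes)
    genic_null = enrichment.simulate_genic_null(
        gb.n_breakpoints, genome, genome.genes, n_sims, seed=seed + 101,
        observed=gb.n_genic,
    )
    universe = [g.name for g in genome.genes]
    cg = (
        enrichment.cancer_gene_enrichment(
            gb.affected_genes, universe, genome.cancer_genes, n_sims, seed=seed + 102
        )
        if gb.affected_genes
        else None
    )
    patient_of = {m.sample_id: m.patient_id for m in tumor_metas}
    gene_table = enrichment.affected_gene_table(filtered, patient_of, genome.genes, genome, window)
    gene_table.to_csv(outdir / "affected_genes.tsv", sep="\t", index=False)
    enr = {
        "genic": {
            "observed": gb.n_genic,
            "n_breakpoints": gb.n_breakpoints,
            "pct_genic": gb.pct_genic,
            "null_median": genic_null.null_median,
            "p_two_sided": genic_null.p_two_sided,
            "p_is_bound": genic_null.p_is_bound,
            "fold": genic_null.fold,
        },
        "cancer_genes": None
        if cg is None
        else {
            "observed": cg.observed,
            "draw_size": cg.n_total,
            "null_median": cg.null_median,
            "p_two_sided": cg.p_two_sided,
            "p_is_bound": cg.p_is_bound,
            "fold": cg.fold,
        },
    }
    (outdir / "enrichment.json").write_text(json.dumps(enr, indent=1, sort_keys=True))

    # ---- artifact manifest ---------------------------------------
    arts = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "artifacts.sha256")
    with open(outdir / "artifacts.sha256", "w") as fh:
        for p in arts:
            if p.name == "pipeline_state.json":
                continue
            fh.write(f"{_sha256(p)}  {p.relative_to(outdir)}\n")
    log.info("pipeline complete: %s", outdir)
    return outdir
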