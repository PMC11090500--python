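"""Configuration-driven orchestration of the synthetic analysis pipeline.

Stages run in dependency order: ``simulate`` writes a genome (FASTA), truth
footprints (BED), and per-sample alignments (SAM); ``count`` converts
alignments to per-nucleotide cut profiles (bedGraph); ``bias`` estimates the
hexamer table from a naked-DNA library; ``correct`` applies the chosen
correction to the pooled profile; ``footprint`` calls protected regions on
the raw pooled counts; ``dynamics`` bins library-size-normalized profiles
over the region and summarizes site-adjacent change.  Every output lands in
a manifest with content hashes, so a fixed seed gives hash-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bias as bias_mod
from . import cuts as cuts_mod
from . import footprints as fp_mod
from . import simulate as sim_mod

log = logging.getLogger("tn5foot.pipeline")

STAGES = ("simulate", "count", "bias", "correct", "footprint", "dynamics")


class ConfigError(ValueError):
    """Aggregated configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"- {v}" for v in violations))


@dataclass
class RunConfig:
    """Validated pipeline parameters (see ``validate_config``)."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    genome_length: int = 20_000
    gc_fraction: float = 0.5
    contig: str = sim_mod.DEFAULT_CONTIG
    footprints: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    bias_hexamer: str | None = None
    bias_preference: float = 1.0
    samples: list[dict] = field(default_factory=lambda: [{"id": "s1", "n_events": 50_000}])
    naked_n_events: int = 200_000
    region_name: str = "region"
    region_start: int = 0
    region_end: int | None = None
    footprint_threshold: float = 100.0
    min_len: int = 5
    max_len: int = 50
    n_bins: int = 9
    flank: int = 5
    correction_method: str = "poisson"
    alpha: float = 0.01
    genome_size: float | None = None  # default: the synthetic genome length
    normalization_scale: float = cuts_mod.CPM_SCALE


def validate_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON config file, reporting every violation at once."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config_dict(raw)


def validate_config_dict(raw: dict) -> RunConfig:
    violations: list[str] = []
    cfg = RunConfig()
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            violations.append(f"unknown field {key!r}")
    for key, value in raw.items():
        if key in known:
            setattr(cfg, key, value)
    cfg.footprints = [((int(s), int(e)), float(d)) for s, e, d in (raw.get("footprints") or [])]
    if cfg.region_end is None:
        cfg.region_end = cfg.genome_length
    if cfg.genome_size is None:
        cfg.genome_size = float(cfg.genome_length)
    for stage in cfg.stages:
        if stage not in STAGES:
            violations.append(f"unknown stage {stage!r}")
    if cfg.genome_length < 6:
        violations.append("genome_length must be >= 6")
    if not 0 <= cfg.gc_fraction <= 1:
        violations.append("gc_fraction must lie in [0, 1]")
    if cfg.footprint_threshold <= 0:
        violations.append("footprint_threshold must be positive")
    if not 0 <= cfg.region_start < cfg.region_end <= cfg.genome_length:
        violations.append("region must be a non-empty interval within the genome")
    if cfg.n_bins < 1:
        violations.append("n_bins must be >= 1")
    if cfg.correction_method not in ("hint", "bagfoot", "poisson"):
        violations.append(f"unknown correction method {cfg.correction_method!r}")
    if not cfg.samples:
        violations.append("at least one sample is required")
    for i, s in enumerate(cfg.samples):
        if "id" not in s or "n_events" not in s:
            violations.append(f"sample {i} must declare 'id' and 'n_events'")
        elif int(s["n_events"]) < 0:
            violations.append(f"sample {s['id']!r} has negative n_events")
    spans = sorted((s, e) for (s, e), _ in cfg.footprints)
    for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
        if e1 > s2:
            violations.append(f"footprints [{s1},{e1}) and [{s2},{e2}) overlap")
    for (s, e), d in cfg.footprints:
        if not (0 <= s < e <= cfg.genome_length):
            violations.append(f"footprint [{s},{e}) out of genome bounds")
        if not 0 <= d <= 1:
            violations.append(f"footprint [{s},{e}) depletion {d} not in [0, 1]")
    if violations:
        raise ConfigError(violations)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the selected stages; return the output manifest.

    The manifest maps each output file to its sha256 and echoes the full
    parameter set; it is also written to ``manifest.json`` in ``outdir``.
    Deterministic stages are hash-identical for identical config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.stages]
    outputs: list[Path] = []

    genome = sim_mod.generate_genome(config.genome_length, config.gc_fraction, config.seed)
    landscape = sim_mod.plant_landscape(genome, config.footprints)
    if config.bias_hexamer:
        bias_model = sim_mod.BiasModel.with_preference(config.bias_hexamer, config.bias_preference)
    else:
        bias_model = sim_mod.BiasModel.uniform()

    sample_paths: dict[str, Path] = {}
    if "simulate" in stages:
        log.info("simulate: genome %d bp, %d samples", genome.length, len(config.samples))
        fasta = outdir / "genome.fa"
        sim_mod.write_fasta(genome, fasta, config.contig)
        outputs.append(fasta)
        truth = outdir / "truth_footprints.bed"
        sim_mod.write_truth_bed(landscape, truth, config.contig)
        outputs.append(truth)
        for i, s in enumerate(config.samples):
            frags = sim_mod.simulate_fragments(
                genome,
                landscape,
                bias_model,
                n_events=int(s["n_events"]),
                seed=config.seed + 1 + i,
                sample_id=str(s["id"]),
                contig=config.contig,
            )
            sam = outdir / f"sample_{s['id']}.sam"
            sim_mod.write_alignments(frags, genome, sam)
            sample_paths[str(s["id"])] = sam
            outputs.append(sam)
        naked_frags = sim_mod.simulate_fragments(
            genome,
            sim_mod.plant_landscape(genome),  # naked DNA: no footprints
            bias_model,
            n_events=config.naked_n_events,
            seed=config.seed + 1000,
            sample_id="naked",
            contig=config.contig,
        )
        naked_sam = outdir / "naked.sam"
        sim_mod.write_alignments(naked_frags, genome, naked_sam)
        outputs.append(naked_sam)
        params_json = outdir / "simulation_params.json"
        sim_mod.write_run_config(
            {
                "seed": config.seed,
                "genome_length": config.genome_length,
                "gc_fraction": config.gc_fraction,
                "footprints": config.footprints,
                "bias_hexamer": config.bias_hexamer,
                "bias_preference": config.bias_preference,
                "samples": config.samples,
                "naked_n_events": config.naked_n_events,
            },
            params_json,
        )
        outputs.append(params_json)
    else:
        for s in config.samples:
            sample_paths[str(s["id"])] = outdir / f"sample_{s['id']}.sam"

    profiles = {}
    pooled = None
    if {"count", "correct", "footprint", "dynamics"} & set(stages):
        for sid, sam in sample_paths.items():
            if not sam.is_file():
                raise RuntimeError(f"stage 'count' failed: missing alignments {sam}")
            profiles[sid] = cuts_mod.count_cuts(
                sam, config.contig, config.region_start, config.region_end, sample_id=sid
            )
        pooled = cuts_mod.pool_profiles(list(profiles.values())) if profiles else None
    if "count" in stages:
        log.info("count: region [%d, %d)", config.region_start, config.region_end)
        for sid, prof in profiles.items():
            bg = outdir / f"cuts_{sid}.bedGraph"
            cuts_mod.write_bedgraph(prof, bg)
            outputs.append(bg)
        pooled_bg = outdir / "cuts_pooled.bedGraph"
        cuts_mod.write_bedgraph(pooled, pooled_bg)
        outputs.append(pooled_bg)

    bias_table = None
    if {"bias", "correct"} & set(stages):
        naked_sam = outdir / "naked.sam"
        if not naked_sam.is_file():
            raise RuntimeError("stage 'bias' failed: missing naked-DNA alignments")
        naked_profile = cuts_mod.count_cuts(naked_sam, config.contig, 0, genome.length, sample_id="naked")
        bias_table = bias_mod.estimate_bias(naked_profile, genome.sequence)
    if "bias" in stages:
        log.info("bias: estimated from %s cuts", bias_table.metadata["total_cuts"])
        bias_tsv = outdir / "bias_table.tsv"
        bias_table.to_tsv(bias_tsv)
        outputs.append(bias_tsv)

    if "correct" in stages:
        log.info("correct: method=%s alpha=%g G=%g", config.correction_method, config.alpha, config.genome_size)
        gate = None
        if config.correction_method == "poisson":
            gate = bias_mod.PoissonGate.from_profile(pooled, config.genome_size, config.alpha)
        corrected = bias_mod.correct(pooled, bias_table, genome.sequence, config.correction_method, gate=gate)
        corr_bg = outdir / f"cuts_corrected_{config.correction_method}.bedGraph"
        cuts_mod.write_bedgraph(corrected, corr_bg)
        outputs.append(corr_bg)

    regions = []
    if "footprint" in stages:
        params = fp_mod.FootprintParams(config.footprint_threshold, config.min_len, config.max_len)
        regions = fp_mod.call_protected_regions(pooled, params)
        log.info("footprint: %d protected regions at T=%g", len(regions), params.threshold)
        bed = outdir / "footprints.bed"
        fp_mod.write_bed(regions, bed)
        outputs.append(bed)

    if "dynamics" in stages:
        normalized = [
            cuts_mod.normalize_library(p, config.normalization_scale) for p in profiles.values()
        ]
        series = fp_mod.bin_region(normalized, config.region_start, config.region_end, config.n_bins)
        bins_tsv = outdir / "bin_series.tsv"
        series.means.to_csv(bins_tsv, sep="\t", index_label="sample")
        outputs.append(bins_tsv)
        sites = [(s, e) for (s, e), _ in config.footprints
                 if config.region_start <= s < e <= config.region_end]
        if sites and len(normalized) >= 2:
            report = fp_mod.site_adjacent_change(normalized, sites, flank=config.flank)
            ratio_tsv = outdir / "site_adjacent_change.tsv"
            report.to_csv(ratio_tsv, sep="\t", index=False)
            outputs.append(ratio_tsv)

    manifest = {
        "stages": stages,
        "parameters": {
            k: getattr(config, k) for k in RunConfig.__dataclass_fields__
        },
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
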