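"""End-to-end orchestration: build -> align -> count -> null -> test -> L1.

A run is described by a single config (YAML-serializable dataclass).  Each
stage writes its outputs under the run directory; a manifest records seeds,
input checksums and stage timings so that a persisted config reruns to
identical outputs.  With caching enabled a stage whose outputs already exist
is skipped, so deleting an intermediate file recomputes only downstream
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import (AlignerConfig, SeedIndex, align_batch, read_fastq,
                    write_alignment_table, write_fastq)
from .l1 import Scoring, load_panel, profile_table, start_profile
from .nullsim import NullConfig, null_counts
from .quantify import (FamilyCountMatrix, assemble_matrix, count_by_family,
                       frequency_summary, pool_samples)
from .reference import (FamilyTaxonomy, RepeatDB, build_coding_db,
                        build_repeat_db, parse_repeat_annotations, read_genome)
from .stats import run_table1, write_results
from .synth import (ExpressionConfig, SyntheticGenomeConfig, make_genome,
                    make_reads)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "retex_run"
    rng_seed: int = 0
    # inputs: either real files ...
    genome: str | None = None
    repeats: str | None = None          # RepeatMasker .out or BED6
    ccds: str | None = None
    reads: list[str] = field(default_factory=list)   # FASTQ per technical replicate
    pool_map: dict[str, str] = field(default_factory=dict)
    # ... or a synthetic scenario
    synth_genome: dict | None = None     # SyntheticGenomeConfig kwargs
    synth_reads: dict | None = None      # ExpressionConfig kwargs
    n_samples: int = 10
    # analysis parameters
    flank_bp: int = 50
    aligner: dict = field(default_factory=dict)       # AlignerConfig kwargs
    null: dict = field(default_factory=dict)          # NullConfig kwargs
    run_ccds_null: bool = False
    l1_panel: str | None = None
    l1_bin: int = 100
    l1_max_reads: int = 2000
    cache: bool = False

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stages:
    """Tracks stage execution, timings and output caching."""

    def __init__(self, out_dir: Path, cache: bool):
        self.out_dir = out_dir
        self.cache = cache
        self.timings: dict[str, float] = {}
        self._cached: set[str] = set()

    def fresh(self, name: str, *outputs: Path) -> bool:
        """True when the stage must run (cache off or an output is missing)."""
        if self.cache and outputs and all(p.exists() for p in outputs):
            logger.info("stage %s: cached, skipping", name)
            self.timings[name] = 0.0
            self._cached.add(name)
            return False
        return True

    def done(self, name: str, t0: float):
        if name in self._cached:
            return
        self.timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: %.2f s", name, self.timings[name])


def run_all(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stages(out, cfg.cache)
    aligner_cfg = AlignerConfig(**cfg.aligner)

    # --- stage: inputs (synthesize or load) --------------------------------
    t0 = time.perf_counter()
    synth_dir = out / "synth"
    if cfg.synth_genome is not None:
        syn_cfg = SyntheticGenomeConfig(
            **{**cfg.synth_genome, "rng_seed": cfg.synth_genome.get("rng_seed", cfg.rng_seed)})
        syn = make_genome(syn_cfg)
        if stages.fresh("synth_genome", synth_dir / "genome.fa"):
            syn.write(synth_dir)
        genome = syn.genome
        taxonomy = syn.taxonomy
        annotations = syn.annotations
        coding = syn.coding_db()
    else:
        if not (cfg.genome and cfg.repeats):
            raise ValueError("either synth_genome or genome+repeats inputs are required")
        syn = None
        genome = read_genome(cfg.genome)
        taxonomy = FamilyTaxonomy()
        annotations = parse_repeat_annotations(cfg.repeats, taxonomy)
        coding = build_coding_db(cfg.ccds) if cfg.ccds else None
    stages.done("inputs", t0)

    # --- stage: repeat database -------------------------------------------
    t0 = time.perf_counter()
    db_dir = out / "db"
    db = build_repeat_db(genome, annotations, flank_bp=cfg.flank_bp)
    if stages.fresh("build_db", db_dir / "repeats.fa"):
        db.write(db_dir)
    if coding is not None:
        coding.write(db_dir / "ccds.fa") if stages.fresh("build_ccds", db_dir / "ccds.fa") else None
    index = SeedIndex(db, seed_len=aligner_cfg.seed_len)
    stages.done("build_db", t0)

    families = list(taxonomy)

    # --- stage: observed reads + alignment + counts ------------------------
    t0 = time.perf_counter()
    counts_path = out / "counts_observed.tsv"
    if stages.fresh("observed_counts", counts_path):
        columns = []
        if syn is not None:
            expr = ExpressionConfig(
                **{**(cfg.synth_reads or {}),
                   "rng_seed": (cfg.synth_reads or {}).get("rng_seed", cfg.rng_seed)})
            reads_dir = out / "reads"
            reads_dir.mkdir(exist_ok=True)
            for s in range(cfg.n_samples):
                sample_id = f"sample_{s}"
                reads, _ = make_reads(syn, expr, sample_seed=expr.rng_seed * 1000 + s + 1,
                                      id_prefix=sample_id)
                write_fastq(reads_dir / f"{sample_id}.fq", reads)
                table, _ = align_batch(reads, index, aligner_cfg)
                write_alignment_table(table, out / f"align_{sample_id}.tsv")
                columns.append(count_by_family(table, families, sample_id))
        else:
            for path in cfg.reads:
                sample_id = Path(path).stem
                table, _ = align_batch(read_fastq(path), index, aligner_cfg)
                write_alignment_table(table, out / f"align_{sample_id}.tsv")
                columns.append(count_by_family(table, families, sample_id))
        observed = assemble_matrix(columns, "observed")
        if cfg.pool_map:
            observed = pool_samples(observed, cfg.pool_map)
        observed.write(counts_path)
    observed = FamilyCountMatrix.read(counts_path)
    stages.done("observed_counts", t0)

    # --- stage: null simulation -------------------------------------------
    t0 = time.perf_counter()
    null_path = out / "counts_null.tsv"
    null_cfg = NullConfig(**{**cfg.null,
                             "rng_seed": cfg.null.get("rng_seed", cfg.rng_seed + 1)})
    if stages.fresh("null_counts", null_path):
        null_matrix = null_counts(db, null_cfg, index, aligner_cfg, families)
        null_matrix.write(null_path)
    null_matrix = FamilyCountMatrix.read(null_path)
    stages.done("null_counts", t0)

    if cfg.run_ccds_null and coding is not None:
        t0 = time.perf_counter()
        ccds_path = out / "counts_null_ccds.tsv"
        if stages.fresh("ccds_null", ccds_path):
            ccds_cfg = NullConfig(**{**cfg.null, "source": "ccds",
                                     "rng_seed": cfg.null.get("rng_seed", cfg.rng_seed + 2)})
            null_counts(coding, ccds_cfg, index, aligner_cfg, families).write(ccds_path)
        stages.done("ccds_null", t0)

    # --- stage: differential test + frequency summary ----------------------
    t0 = time.perf_counter()
    results_path = out / "family_tests.tsv"
    if stages.fresh("nb_test", results_path):
        results = run_table1(observed, null_matrix)
        write_results(results, results_path)
        joint = observed.hstack(null_matrix)
        frequency_summary(joint).to_csv(out / "family_frequencies.tsv", sep="\t")
    stages.done("nb_test", t0)

    # --- stage: L1 5' profile ----------------------------------------------
    t0 = time.perf_counter()
    l1_path = out / "l1_profile.tsv"
    panel = None
    if cfg.l1_panel:
        panel = load_panel(cfg.l1_panel)
    elif syn is not None and "L1" in syn.consensus:
        panel = [("L1_consensus", syn.consensus["L1"])]
    if panel is not None and stages.fresh("l1_profile", l1_path):
        obs_l1 = _l1_reads_from_run(out, cfg)
        from .nullsim import NullConfig as _NC, simulate_uniform_reads
        sim_cfg = _NC(n_datasets=1, reads_per_dataset=max(len(obs_l1), 1),
                      read_len=aligner_cfg.read_len, rng_seed=cfg.rng_seed + 3)
        l1_db = RepeatDB([e for e in db.entries if e.family == "L1"], db.flank_bp)
        sim_l1 = []
        if l1_db.entries:
            _, sim_reads, _ = next(iter(simulate_uniform_reads(l1_db, sim_cfg)))
            sim_l1 = sim_reads
        prof_obs = start_profile(obs_l1, panel, "observed", cfg.l1_bin)
        prof_sim = start_profile(sim_l1, panel, "simulated", cfg.l1_bin)
        profile_table(prof_obs, prof_sim).to_csv(l1_path, sep="\t", index=False)
    stages.done("l1_profile", t0)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "retex_version": __version__,
        "rng_seed": cfg.rng_seed,
        "null_seed": null_cfg.rng_seed,
        "config": asdict(cfg),
        "stage_seconds": stages.timings,
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    cfg.to_yaml(out / "run_config.yaml")
    return out


def _l1_reads_from_run(out: Path, cfg: RunConfig):
    """Collect sequences of reads whose best repeat-DB hit is family L1."""
    reads = []
    seqs = {}
    fastqs = list(cfg.reads)
    if (out / "reads").exists():
        fastqs += sorted(str(p) for p in (out / "reads").glob("*.fq"))
    for fq in fastqs:
        for rid, seq in read_fastq(fq):
            seqs[rid] = seq
    for path in sorted(out.glob("align_*.tsv")):
        table = pd.read_csv(path, sep="\t")
        for rid in table.loc[table["family"] == "L1", "read_id"]:
            if rid in seqs:
                reads.append((rid, seqs[rid]))
        if len(reads) >= cfg.l1_max_reads:
            break
    return reads[: cfg.l1_max_reads]
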