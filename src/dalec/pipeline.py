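"""End-to-end orchestration: simulate/ingest -> tag database -> counts ->
gene indices -> dyad profile.

A run is driven by a YAML config (see RunConfig).  Every stage writes its
tables plus a JSON manifest naming the stage, parameters and input hashes;
re-running with an identical config, inputs and seed is byte-identical.
A stage failure halts the run with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from . import metaprofile as mp
from . import quantify as qt
from .reads import count_hits
from .simulate import DatasetConfig, NucleosomeModel, generate_synthetic_dataset
from .tagdb import FilterConfig, build_tag_database

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("dalec")


@dataclass
class RunConfig:
    """Declarative description of a full run.

    With ``simulate`` set, inputs are generated; otherwise genome/reads/
    genes/anchors/expression paths must point at existing files.
    """

    outdir: str = "dalec_out"
    seed: int = 0
    simulate: dict | None = None          # DatasetConfig overrides
    genome: str | None = None
    reads: dict[str, str] = field(default_factory=dict)  # label -> fastq
    control_sample: str = "control"
    genes: str | None = None
    anchors: str | None = None
    expression: str | None = None
    proximal_threshold: int = 20
    exclusion_fasta: str | None = None
    min_sites: int = 4
    profile_halfwidth: int = 1000
    smoothing_window: int = 400


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(doc) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**doc)


def _dataset_config(cfg: RunConfig) -> DatasetConfig:
    over = dict(cfg.simulate or {})
    if "nucleosomes" in over:
        over["nucleosomes"] = NucleosomeModel(**over["nucleosomes"])
    over.setdefault("seed", cfg.seed)
    return DatasetConfig(**over)


def run_pipeline(cfg: RunConfig, dry_run: bool = False) -> dict[str, object]:
    """Execute tagdb -> (simulate|count) -> quantify -> profile."""
    stages = ["simulate" if cfg.simulate is not None else "ingest",
              "tagdb", "count", "quantify", "profile"]
    if dry_run:
        for s in stages:
            print(f"plan: {s}")
        return {"plan": stages}

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}
    stage = "setup"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            log.info("stage %s", stage)
            ds = generate_synthetic_dataset(_dataset_config(cfg), out / "sim")
            genome_path = ds.paths["genome"]
            genes = ds.genes
            anchors = ds.anchors
            expression = ds.expression
            reads = {k: str(v) for k, v in ds.fastq_paths.items()}
            artifacts["dataset"] = ds
        else:
            stage = "ingest"
            if not (cfg.genome and cfg.reads):
                raise ValueError("need genome and reads (or a simulate block)")
            genome_path = Path(cfg.genome)
            genes = dio.read_genes_bed(cfg.genes) if cfg.genes else None
            anchors = None
            if cfg.anchors:
                bed = dio.read_bed(cfg.anchors)
                anchors = bed.rename(columns={"start": "pos"})[
                    ["contig", "pos", "strand"]
                ]
            expression = (
                dio.read_expression(cfg.expression) if cfg.expression else None
            )
            reads = dict(cfg.reads)

        stage = "tagdb"
        log.info("stage %s", stage)
        contigs = dio.read_fasta(genome_path)
        exclusion = ()
        if cfg.exclusion_fasta:
            exclusion = tuple(
                c.sequence for c in dio.read_fasta(cfg.exclusion_fasta)
            )
        db = build_tag_database(
            contigs,
            FilterConfig(
                proximal_threshold=cfg.proximal_threshold,
                exclusion_sequences=exclusion,
            ),
        )
        dio.write_tag_database(db, out / "tagdb")
        dio.write_manifest(
            out / "tagdb.manifest.json", "tagdb",
            {"proximal_threshold": cfg.proximal_threshold,
             **db.stage_counts},
            {"genome": genome_path},
        )
        artifacts["db"] = db

        stage = "count"
        log.info("stage %s", stage)
        tables = {}
        for label, fq in reads.items():
            t = count_hits(fq, db, sample=label)
            dio.write_hit_table(t, db, out / f"hits_{label}")
            dio.write_manifest(
                out / f"hits_{label}.manifest.json", "count",
                dict(t.totals), {"fastq": fq},
            )
            tables[label] = t
        artifacts["hit_tables"] = tables

        control = tables.get(cfg.control_sample)
        if genes is not None and control is not None:
            stage = "quantify"
            log.info("stage %s", stage)
            for label, t in tables.items():
                if label == cfg.control_sample:
                    continue
                idx = qt.accessibility_index(
                    t, control, genes, db, min_sites=cfg.min_sites
                )
                idx.to_csv(out / f"index_{label}.tsv", sep="\t", index=False)
                div = qt.gene_divergence(t, control, genes, db)
                div.to_csv(out / f"divergence_{label}.tsv", sep="\t",
                           index=False)
                if expression is not None:
                    bins = qt.sage_bin_averages(idx, expression)
                    bins.to_csv(out / f"sagebins_{label}.tsv", sep="\t",
                                index=False)
                artifacts[f"index_{label}"] = idx

        if anchors is not None:
            stage = "profile"
            log.info("stage %s", stage)
            offmap = mp.map_halfsites_to_offsets(
                anchors, db, halfwidth=cfg.profile_halfwidth
            )
            for label, t in tables.items():
                prof = mp.dyad_profile(t, offmap, control=control)
                prof["smoothed"] = mp.moving_average(
                    prof["value"], cfg.smoothing_window
                )
                prof.to_csv(out / f"profile_{label}.tsv", sep="\t",
                            index=False)
                artifacts[f"profile_{label}"] = prof
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
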