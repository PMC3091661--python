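"""Shared fixtures: toy genomes and seeded synthetic datasets.

The two simulated bundles are session-scoped because they are reused by
many tests: ``demo`` is a small end-to-end dataset; ``deep`` runs 10,000
molecules per sample for the depth-dependent checks (parameter recovery,
control flatness, phasing); ``cohort`` has many genes for calibration and
expression-trend checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
import scipy.stats  # noqa: F401  (imported early; cheap)

from dalec.reads import count_hits
from dalec.simulate import DatasetConfig, generate_synthetic_dataset
from dalec.tagdb import build_tag_database


@dataclasses.dataclass
class Bundle:
    ds: object
    db: object
    tables: dict


def _build(cfg: DatasetConfig, outdir) -> Bundle:
    ds = generate_synthetic_dataset(cfg, outdir)
    db = build_tag_database(ds.genome)
    tables = {
        label: count_hits(path, db, sample=label)
        for label, path in ds.fastq_paths.items()
    }
    return Bundle(ds=ds, db=db, tables=tables)


@pytest.fixture(scope="session")
def demo(tmp_path_factory) -> Bundle:
    cfg = DatasetConfig(
        genome_length=50_000,
        n_genes=12,
        gene_spacing=1300,
        n_molecules=800,
        n_reads=60_000,
        seed=5,
    )
    return _build(cfg, tmp_path_factory.mktemp("demo"))


@pytest.fixture(scope="session")
def deep(tmp_path_factory) -> Bundle:
    cfg = DatasetConfig(
        genome_length=150_000,
        n_genes=50,
        gene_spacing=1300,
        n_molecules=10_000,
        n_reads=400_000,
        seed=11,
    )
    return _build(cfg, tmp_path_factory.mktemp("deep"))


@pytest.fixture(scope="session")
def cohort(tmp_path_factory) -> Bundle:
    cfg = DatasetConfig(
        genome_length=300_000,
        n_genes=150,
        gene_length=1200,
        gene_spacing=700,
        n_molecules=1200,
        n_reads=250_000,
        tissue_samples=("tissue",),
        control_samples=("control", "control2"),
        seed=23,
    )
    return _build(cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def random_genome_50kb() -> str:
    rng = np.random.default_rng(424242)
    return "".join(rng.choice(list("ACGT"), size=50_000))
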