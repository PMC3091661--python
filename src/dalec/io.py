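"""File formats: FASTA, FASTQ (Phred+33), BED, TSV tables, manifests.

Coordinates are 0-based half-open throughout (BED convention).  TSV tables
carry a header row; stage manifests are machine-readable JSON written next
to the tables.  Gzip-suffixed FASTQ paths are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .tagdb import ContigSequence, TagDatabase

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "read_genes_bed",
    "read_expression",
    "write_tag_database",
    "read_tag_database_frame",
    "write_hit_table",
    "write_manifest",
    "file_sha256",
]


def read_fasta(path: str | Path) -> list[ContigSequence]:
    """Read a (multi-)FASTA; order preserved, sequences uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ContigSequence(r.id, str(r.seq)) for r in records]


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _open_maybe_gz(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, bases, qualities); lengths validated by the parser."""
    with _open_maybe_gz(path, "r") as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield rid, seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    n = 0
    with _open_maybe_gz(path, "w") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"length mismatch in record {rid!r}")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """BED6 of gene bodies -> gene model table (txStart/txEnd half-open)."""
    bed = read_bed(path)
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "contig": bed["contig"],
            "txStart": bed["start"],
            "txEnd": bed["end"],
            "strand": bed["strand"],
        }
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, sage_score (non-negative integers)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "sage_score"} <= set(df.columns):
        raise ValueError("expression table needs gene_id and sage_score")
    if (df["sage_score"] < 0).any():
        raise ValueError("sage_score must be non-negative")
    return df


def write_tag_database(db: TagDatabase, prefix: str | Path) -> dict[str, Path]:
    """TSV of all tags with flags, BED of retained half-sites, JSON counts."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "tags": prefix.with_suffix(".tags.tsv"),
        "retained_bed": prefix.with_suffix(".retained.bed"),
        "counts": prefix.with_suffix(".counts.json"),
    }
    db.all_tags.to_csv(paths["tags"], sep="\t", index=False)
    ret = db.retained_tags
    bed = pd.DataFrame(
        {
            "contig": ret["contig"],
            "start": ret["site_pos"],
            "end": ret["site_pos"] + 4,
            "name": ret["id"],
            "score": 0,
            "strand": ret["strand"],
        }
    )
    write_bed(bed, paths["retained_bed"])
    with open(paths["counts"], "w") as fh:
        json.dump(db.stage_counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_tag_database_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_hit_table(table, db: TagDatabase, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "hits": prefix.with_suffix(".hits.tsv"),
        "stats": prefix.with_suffix(".stats.json"),
    }
    table.to_frame(db).to_csv(paths["hits"], sep="\t", index=False)
    with open(paths["stats"], "w") as fh:
        json.dump({"sample": table.sample, **table.totals}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    params: Mapping[str, object],
    inputs: Mapping[str, str | Path] = (),
) -> None:
    """JSON manifest naming the producing stage, parameters and input hashes."""
    doc = {
        "stage": stage,
        "params": dict(params),
        "inputs": {
            k: {"path": str(v), "sha256": file_sha256(v)}
            for k, v in dict(inputs).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
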