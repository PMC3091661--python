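"""Read parsing and exact-match tag alignment.

A valid read has the structure ``5'-N16-19 GA-3'`` followed by the reverse
complement of the linker A top oligo: the genomic portion ends in the GA
left by Dpn I cleavage of the methylated GATC.  Parsing locates the linker
by an exact 15-mer seed; the prefix is accepted if its length is 18-21 nt,
it ends in GA and contains no ambiguous base.  The alignable unit is the
16 nt immediately upstream of the terminal GA, looked up by exact match in
the retained tag database (no mismatches; uniqueness is guaranteed by the
database, so a hit identifies one half-site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import LinkerSet
from .tagdb import TagDatabase

__all__ = ["ParsedTag", "HitTable", "parse_read", "align_tag", "count_hits"]

MIN_PORTION = 18  # N16 + GA
MAX_PORTION = 21  # N19 + GA

PARSE_STATUSES = (
    "parsed",
    "no_linker",
    "bad_length",
    "no_GA_terminus",
    "ambiguous_base",
)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ParsedTag:
    read_id: str
    status: str
    tag16: str = ""
    parsed_length: int = 0


@dataclass
class HitTable:
    """Per-half-site read counts for one sample, with stage totals."""

    sample: str
    counts: dict[int, int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    @property
    def aligned(self) -> int:
        return self.totals.get("aligned", 0)

    def count(self, half_site_id: int) -> int:
        return self.counts.get(half_site_id, 0)

    def to_frame(self, db: TagDatabase) -> pd.DataFrame:
        tags = db.retained_tags
        out = tags[["id", "contig", "site_pos", "strand"]].copy()
        out["count"] = [self.counts.get(int(i), 0) for i in tags["id"]]
        return out.reset_index(drop=True)

    def count_array(self, db: TagDatabase) -> np.ndarray:
        """Counts aligned with db.all_tags row order (zeros elsewhere)."""
        arr = np.zeros(len(db.all_tags), dtype=np.int64)
        for tid, c in self.counts.items():
            arr[tid] = c
        return arr


def parse_read(
    read_id: str,
    bases: str,
    linkers: LinkerSet | None = None,
) -> ParsedTag:
    """Parse one read into a 16-nt tag, or a failure status.

    The earliest exact occurrence of the first 15 linker bases delimits the
    genomic portion.  All failures are statuses, never exceptions.
    """
    linkers = linkers or LinkerSet()
    bases = bases.upper()
    at = bases.find(linkers.parse_probe)
    if at < 0:
        return ParsedTag(read_id, "no_linker")
    portion = bases[:at]
    if not MIN_PORTION <= len(portion) <= MAX_PORTION:
        return ParsedTag(read_id, "bad_length", parsed_length=len(portion))
    if not portion.endswith("GA"):
        return ParsedTag(read_id, "no_GA_terminus", parsed_length=len(portion))
    if set(portion) - _ACGT:
        return ParsedTag(read_id, "ambiguous_base", parsed_length=len(portion))
    return ParsedTag(read_id, "parsed", tag16=portion[-18:-2],
                     parsed_length=len(portion))


def align_tag(tag: ParsedTag, db: TagDatabase) -> int | None:
    """Exact lookup of tag16 among retained tags; no mismatches tolerated."""
    if tag.status != "parsed":
        return None
    return db.lookup(tag.tag16)


def _iter_fastq(source) -> Iterator[tuple[str, str]]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            for rid, seq, _qual in FastqGeneralIterator(fh):
                yield rid, seq
    else:
        for rec in source:  # (id, bases) pairs
            yield rec[0], rec[1]


def count_hits(
    reads: str | Path | Iterable[tuple[str, str]],
    db: TagDatabase,
    sample: str = "sample",
    linkers: LinkerSet | None = None,
) -> HitTable:
    """Stream reads through parse and align, counting hits per half-site.

    No deduplication: the assay's signal is per-molecule capture frequency,
    so every aligned read increments its half-site.  Totals record the raw,
    per-failure-status, parsed and aligned counts (raw = parsed + failures;
    aligned <= parsed).
    """
    linkers = linkers or LinkerSet()
    probe = linkers.parse_probe
    retained = db.retained
    counts: dict[int, int] = {}
    totals = {k: 0 for k in ("raw", "parsed", "aligned")}
    for status in PARSE_STATUSES[1:]:
        totals[status] = 0
    for rid, bases in _iter_fastq(reads):
        totals["raw"] += 1
        at = bases.find(probe)
        if at < 0:
            totals["no_linker"] += 1
            continue
        portion = bases[:at]
        n = len(portion)
        if not MIN_PORTION <= n <= MAX_PORTION:
            totals["bad_length"] += 1
            continue
        if not portion.endswith("GA"):
            totals["no_GA_terminus"] += 1
            continue
        if set(portion) - _ACGT:
            totals["ambiguous_base"] += 1
            continue
        totals["parsed"] += 1
        tid = retained.get(portion[-18:-2])
        if tid is not None:
            totals["aligned"] += 1
            counts[tid] = counts.get(tid, 0) + 1
    return HitTable(sample=sample, counts=counts, totals=totals)
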