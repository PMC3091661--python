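"""In-silico DAM tag database.

A DAM (GATC) half-site tag is the 16-nt genomic context on one side of a
GATC tetramer: the 16 bases immediately upstream on the plus strand, or the
reverse complement of the 16 bases immediately downstream for the minus
strand.  Because the assay captures a ~20-bp fragment ending at the Dpn I
blunt cut inside GATC, a 16-nt tag match constrained to be followed by GATC
is effectively a 20-nt perfect genomic match.

The database is built by scanning every contig for GATC, emitting up to two
oriented tags per site, then flagging tags that are (i) truncated by a
contig edge or an ambiguous base, (ii) non-unique genome-wide, (iii) present
on an exclusion list (vector/ribosomal sequences), or (iv) "proximal":
belonging to two adjacent GATC sites closer than a threshold (default
20 bp), where capture of one end competes with the other.  Only tags with
no flags are retained for alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContigSequence",
    "FilterConfig",
    "TagDatabase",
    "revcomp",
    "scan_gatc_sites",
    "extract_half_site_tags",
    "mark_nonunique",
    "mark_proximal",
    "mark_excluded",
    "build_tag_database",
]

TAG_LEN = 16
SITE = "GATC"
SITE_LEN = len(SITE)
#: full alignable context: 16-nt tag plus the GATC tetramer
MATCH_LEN = TAG_LEN + SITE_LEN

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"^[ACGTN]*$")

FLAG_COLUMNS = (
    "edge_truncated",
    "nonunique",
    "on_exclusion_list",
    "proximal_excluded",
)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContigSequence:
    """A named contig; sequence is uppercased on construction."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not _VALID.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"contig {self.name!r}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterConfig:
    """Filtering parameters for the tag database.

    proximal_threshold
        Two adjacent GATC sites whose gap (end of the first tetramer to the
        start of the second) is strictly less than this are "proximal"; the
        inward-facing tag pair is excluded.
    exclusion_sequences
        Sequences (e.g. cloning vector, rDNA repeat) whose 20-mers, on
        either strand, disqualify a tag.
    """

    proximal_threshold: int = 20
    exclusion_sequences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.proximal_threshold < 0:
            raise ValueError("proximal_threshold must be >= 0")


def scan_gatc_sites(contig: ContigSequence | str) -> np.ndarray:
    """Return 0-based start positions of every GATC occurrence, sorted.

    GATC cannot overlap itself, so a single left-to-right scan is exhaustive.
    """
    seq = contig.sequence if isinstance(contig, ContigSequence) else contig.upper()
    return np.fromiter(
        (m.start() for m in re.finditer(SITE, seq)), dtype=np.int64
    )


def extract_half_site_tags(
    contig: ContigSequence, sites: np.ndarray | Sequence[int]
) -> pd.DataFrame:
    """Emit the plus and minus half-site tag for every GATC site.

    Plus tag:  genome[pos-16, pos), read on the top strand.
    Minus tag: reverse complement of genome[pos+4, pos+20).

    Tags whose 16-nt context runs off the contig, or contains an ambiguous
    base, are emitted with ``edge_truncated`` set (tag16 left empty); such
    tags are never retained and do not enter the uniqueness census.
    """
    seq = contig.sequence
    n = len(seq)
    rows: list[tuple[str, int, str, str, bool]] = []
    for pos in np.asarray(sites, dtype=np.int64):
        pos = int(pos)
        if seq[pos : pos + SITE_LEN] != SITE:
            raise ValueError(f"no GATC at {contig.name}:{pos}")
        up = seq[pos - TAG_LEN : pos] if pos >= TAG_LEN else ""
        trunc_p = pos < TAG_LEN or "N" in up
        rows.append((contig.name, pos, "+", "" if trunc_p else up, trunc_p))
        down = seq[pos + SITE_LEN : pos + SITE_LEN + TAG_LEN]
        trunc_m = pos + SITE_LEN + TAG_LEN > n or "N" in down
        rows.append(
            (contig.name, pos, "-", "" if trunc_m else revcomp(down), trunc_m)
        )
    df = pd.DataFrame(
        rows, columns=["contig", "site_pos", "strand", "tag16", "edge_truncated"]
    )
    for col in FLAG_COLUMNS[1:]:
        df[col] = False
    return df


def mark_nonunique(tags: pd.DataFrame) -> pd.DataFrame:
    """Flag every tag whose 16-mer occurs more than once genome-wide.

    The census runs over the union of all plus and minus tags of all
    contigs; edge-truncated tags (no full 16-mer) do not participate.
    """
    full = ~tags["edge_truncated"]
    counts = tags.loc[full, "tag16"].value_counts()
    dup = set(counts.index[counts > 1])
    tags.loc[full & tags["tag16"].isin(dup), "nonunique"] = True
    return tags


def mark_excluded(tags: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Flag tags whose tag16+GATC 20-mer occurs in any exclusion sequence
    (either strand)."""
    if not cfg.exclusion_sequences:
        return tags
    kmers: set[str] = set()
    for ex in cfg.exclusion_sequences:
        for s in (ex.upper(), revcomp(ex.upper())):
            kmers.update(
                s[i : i + MATCH_LEN] for i in range(len(s) - MATCH_LEN + 1)
            )
    full = ~tags["edge_truncated"]
    hit = (tags["tag16"] + SITE).isin(kmers)
    tags.loc[full & hit, "on_exclusion_list"] = True
    return tags


def mark_proximal(tags: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Flag the inward-facing tag pair of adjacent sites closer than the
    threshold.

    For consecutive sites s1 < s2 on a contig with
    ``gap = s2.pos - (s1.pos + 4) < proximal_threshold`` the short
    inter-site fragment can only be captured from one end, so the minus tag
    of s1 and the plus tag of s2 are excluded.
    """
    for _, grp in tags.groupby("contig", sort=False):
        pos = np.sort(grp["site_pos"].unique())
        gaps = pos[1:] - (pos[:-1] + SITE_LEN)
        close = gaps < cfg.proximal_threshold
        left = set(pos[:-1][close])   # minus tag faces into the short gap
        right = set(pos[1:][close])   # plus tag faces into the short gap
        idx = grp.index
        sel_m = grp["site_pos"].isin(left) & (grp["strand"] == "-")
        sel_p = grp["site_pos"].isin(right) & (grp["strand"] == "+")
        tags.loc[idx[sel_m | sel_p], "proximal_excluded"] = True
    return tags


@dataclass
class TagDatabase:
    """All extracted half-site tags plus the retained exact-match index."""

    all_tags: pd.DataFrame
    retained: dict[str, int]          # tag16 -> row index into all_tags
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def retained_mask(self) -> pd.Series:
        return ~self.all_tags[list(FLAG_COLUMNS)].any(axis=1)

    @property
    def retained_tags(self) -> pd.DataFrame:
        return self.all_tags[self.retained_mask]

    def midpoints(self) -> pd.Series:
        """GATC midpoint (site_pos + 2) per tag, the positional convention
        used for gene assignment and dyad offsets."""
        return self.all_tags["site_pos"] + SITE_LEN // 2

    def lookup(self, tag16: str) -> int | None:
        return self.retained.get(tag16)


def build_tag_database(
    genome: Iterable[ContigSequence] | Mapping[str, str],
    cfg: FilterConfig | None = None,
) -> TagDatabase:
    """Scan, extract and filter: uniqueness -> exclusion list -> proximal.

    Deterministic for fixed inputs; per-stage counts are recorded for
    auditability.  A duplicate retained 16-mer is impossible after the
    uniqueness filter and raises if ever observed.
    """
    cfg = cfg or FilterConfig()
    if isinstance(genome, Mapping):
        contigs = [ContigSequence(k, v) for k, v in genome.items()]
    else:
        contigs = list(genome)
    if not contigs:
        raise ValueError("empty genome")

    frames = []
    n_sites = 0
    for contig in contigs:
        sites = scan_gatc_sites(contig)
        n_sites += sites.size
        frames.append(extract_half_site_tags(contig, sites))
    tags = pd.concat(frames, ignore_index=True)
    tags.insert(0, "id", tags.index.to_numpy())

    mark_nonunique(tags)
    mark_excluded(tags, cfg)
    mark_proximal(tags, cfg)

    retained_mask = ~tags[list(FLAG_COLUMNS)].any(axis=1)
    retained_df = tags[retained_mask]
    if retained_df["tag16"].duplicated().any():
        raise AssertionError("duplicate retained tag16 after uniqueness filter")
    retained = dict(zip(retained_df["tag16"], retained_df.index))

    counts = {
        "n_sites": int(n_sites),
        "n_tags": int(len(tags)),
        "n_edge_truncated": int(tags["edge_truncated"].sum()),
        "n_nonunique": int(tags["nonunique"].sum()),
        "n_on_exclusion_list": int(tags["on_exclusion_list"].sum()),
        "n_proximal_excluded": int(tags["proximal_excluded"].sum()),
        "n_retained": int(retained_mask.sum()),
    }
    return TagDatabase(all_tags=tags, retained=retained, stage_counts=counts)
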