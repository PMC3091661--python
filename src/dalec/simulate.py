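"""Forward simulation of the DALEC molecular protocol.

The assay probes chromatin accessibility with bacterial DAM
methyltransferase: accessible GATC sites acquire N6-methyl-adenine on each
strand, Dpn I cleaves only doubly-methylated GATC (blunt, between GA and
TC), and the blunt fragment ends are captured by ligation to a branched
linker A carrying an Mme I site.  Mme I liberates ~20 bp of genomic DNA
with a 2-nt 3' overhang, a second branched linker B is ligated, and the
116-nt top strand of the doubly-linkered molecule is amplified and
sequenced.  The read therefore starts with the genomic tag (ending in the
GA of the cleaved GATC) followed by the reverse complement of the linker A
top oligo.

This module simulates every stage on a synthetic genome: a
nucleosome-phased accessibility track, per-molecule per-strand Bernoulli
methylation, Dpn I digestion, end capture with Mme I length slop and a
short-fragment collision rule, library assembly, and FASTQ emission.  The
dataset generator bundles genome, gene models, SAGE-like expression scores,
dyad anchors, tissue and in-vitro-control libraries, and ground-truth
tables.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .tagdb import SITE_LEN, ContigSequence, revcomp

__all__ = [
    "LinkerSet",
    "NucleosomeModel",
    "MethylationConfig",
    "SimConfig",
    "MoleculeState",
    "FragmentRecord",
    "Readout",
    "DatasetConfig",
    "SyntheticDataset",
    "nucleosome_track",
    "simulate_molecules",
    "dpnI_digest",
    "mboI_cuts",
    "sau3aI_cuts",
    "capture_fragment_ends",
    "assemble_library_molecule",
    "read_sequence",
    "emit_reads",
    "simulate_sample_readouts",
    "generate_synthetic_dataset",
    "sample_rng",
]

CUT_OFFSET = 2  # Dpn I cuts GA^TC: blunt boundary at site_pos + 2


# --------------------------------------------------------------------------
# library chemistry


@dataclass(frozen=True)
class LinkerSet:
    """Linker/primer oligos of the capture chemistry (printed defaults).

    Both linkers are branched: only part of each bottom oligo is
    complementary to its top oligo.  ``mme_offset`` is the top-strand
    distance from the linker A junction to the Mme I cut, with +/-1 slop;
    the cut leaves a 2-nt 3' overhang (hence the NN pool in linker B).
    """

    linkerA_top: str = "CAAGCAGAAGACGGCATACGATCCTGAGTACACTATGTTCCGAC"
    linkerA_bottom: str = "GTCGGAACATAGTGTAGCA"
    linkerB_top: str = "TCATCTTTCCCTACACGACGCTCTTCCGATCTNN"
    linkerB_bottom: str = (
        "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTCGGTGGTCGCCGTATCATT"
    )
    bridge_primer_1: str = "AATGATACGGCGACCACCGA"
    bridge_primer_2: str = "CAAGCAGAAGACGGCATACGA"
    mme_offset: int = 20
    #: distribution of the top-strand genomic tag length
    mme_slop: tuple[tuple[int, float], ...] = ((19, 0.15), (20, 0.70), (21, 0.15))

    @property
    def read_linker(self) -> str:
        """Linker sequence that follows the genomic tag in a read."""
        return revcomp(self.linkerA_top)

    @property
    def parse_probe(self) -> str:
        """First 15 nt of the read-side linker, used to locate it."""
        return self.read_linker[:15]

    def slop_lengths(self) -> np.ndarray:
        return np.array([l for l, _ in self.mme_slop], dtype=np.int64)

    def slop_weights(self) -> np.ndarray:
        w = np.array([p for _, p in self.mme_slop], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class NucleosomeModel:
    """Phased nucleosomes downstream of each TSS plus an upstream NDR.

    Dyads are placed at fixed offsets from the TSS (strand-aware).
    Occupancy under each nucleosome follows a cos^2 bump of the given depth
    within +/- half_width of the dyad; accessibility is 1 - occupancy.
    The nucleosome-depleted region upstream of the first dyad is modelled
    as protected by non-histone factors at ``ndr_depth`` (the assay sees a
    methylation valley there despite low nucleosome coverage).
    """

    dyads_rel: tuple[int, ...] = (80, 260, 440, 620)
    half_width: int = 73
    depth: float = 0.75
    ndr_window: tuple[int, int] = (-150, -30)  # relative to TSS, half-open
    ndr_depth: float = 0.5


@dataclass(frozen=True)
class MethylationConfig:
    """Per-strand Bernoulli methylation: p = p_max * accessibility."""

    p_max: float = 0.8
    strand_independent: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Per-sample simulation knobs."""

    n_molecules: int = 2000
    read_length: int = 36
    error_rate: float = 0.0
    min_capture_duplex: int = 24
    n_reads: int | None = None  # subsample emitted reads (sequencing depth)
    hemi_leak: float = 0.0      # Dpn I activity on hemimethylated sites


@dataclass
class MoleculeState:
    """Per-site (top, bottom) methylation booleans on one genome copy."""

    contig: str
    molecule_id: int
    meth: np.ndarray  # (n_sites, 2) bool


@dataclass
class FragmentRecord:
    """A Dpn I fragment with its flanking cut sites.

    ``left_cut``/``right_cut`` are indices into the site array, or None at
    a molecule end.  Internal sites are never doubly methylated.
    """

    contig: str
    start: int
    end: int
    left_cut: int | None
    right_cut: int | None
    internal: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Readout:
    """One captured fragment end: a half-site tag observation.

    ``avail`` is the genomic duplex length available from the blunt end;
    when the sampled Mme I length exceeds it the tag runs into the linker
    ligated at the fragment's other end (contaminated, unalignable).
    """

    site_index: int
    strand: str  # '+' (upstream tag) or '-' (downstream tag)
    avail: int
    length: int = 20


# --------------------------------------------------------------------------
# accessibility track


def nucleosome_track(
    model: NucleosomeModel,
    genes: pd.DataFrame,
    contig_len: int,
) -> np.ndarray:
    """Accessibility in [0, 1] per base: 1 - occupancy.

    ``genes`` needs columns txStart, txEnd, strand; the TSS is txStart for
    plus-strand genes and txEnd - 1 for minus-strand genes.  Occupancy from
    overlapping features combines by maximum.
    """
    occ = np.zeros(contig_len, dtype=np.float64)
    hw = model.half_width
    bump_x = np.arange(-hw, hw + 1)
    bump = model.depth * np.cos(np.pi * bump_x / (2 * hw)) ** 2
    for row in genes.itertuples():
        sign = 1 if row.strand == "+" else -1
        tss = row.txStart if row.strand == "+" else row.txEnd - 1
        for rel in model.dyads_rel:
            d = tss + sign * rel
            lo, hi = d - hw, d + hw + 1
            s, e = max(lo, 0), min(hi, contig_len)
            if s < e:
                seg = bump[s - lo : e - lo]
                np.maximum(occ[s:e], seg, out=occ[s:e])
        a, b = model.ndr_window
        w0, w1 = tss + sign * a, tss + sign * b
        if sign < 0:
            w0, w1 = w1 + 1, w0 + 1
        s, e = max(w0, 0), min(w1, contig_len)
        if s < e:
            np.maximum(occ[s:e], model.ndr_depth, out=occ[s:e])
    return 1.0 - occ


def site_methylation_probs(
    track: np.ndarray, site_pos: np.ndarray, meth: MethylationConfig
) -> np.ndarray:
    """Per-site, per-strand methylation probability:
    p_max * mean(track over the 4 bases of the site)."""
    if site_pos.size == 0:
        return np.zeros(0)
    windows = np.stack(
        [track[site_pos + k] for k in range(SITE_LEN)], axis=1
    )
    return meth.p_max * windows.mean(axis=1)


# --------------------------------------------------------------------------
# methylation, digestion, capture


def simulate_molecules(
    site_probs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    contig: str = "",
) -> Iterator[MoleculeState]:
    """Yield n molecules; each strand of each site methylated independently
    with its site probability.  Deterministic given the generator state."""
    n_sites = site_probs.size
    for m in range(n):
        meth = rng.random((n_sites, 2)) < site_probs[:, None]
        yield MoleculeState(contig=contig, molecule_id=m, meth=meth)


def dpnI_cuts(meth: np.ndarray) -> np.ndarray:
    """Dpn I cuts only GATC methylated on both strands."""
    return meth[:, 0] & meth[:, 1]


def mboI_cuts(meth: np.ndarray) -> np.ndarray:
    """Mbo I cuts only non-methylated GATC."""
    return ~meth[:, 0] & ~meth[:, 1]


def sau3aI_cuts(meth: np.ndarray) -> np.ndarray:
    """Sau3A I cuts regardless of methylation."""
    return np.ones(meth.shape[0], dtype=bool)


def dpnI_digest(
    molecule: MoleculeState,
    site_pos: np.ndarray,
    contig_len: int,
    hemi_leak: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[FragmentRecord]:
    """Blunt cut at site_pos + 2 of every doubly-methylated site.

    Hemimethylated sites are uncut by default (Dpn I is ~60-fold slower on
    them); ``hemi_leak`` optionally cuts them with that probability.
    Fragments are returned in order with their internal (protected) sites.
    """
    cut = dpnI_cuts(molecule.meth)
    if hemi_leak > 0.0:
        hemi = molecule.meth[:, 0] ^ molecule.meth[:, 1]
        if rng is None:
            raise ValueError("hemi_leak > 0 requires an rng")
        cut = cut | (hemi & (rng.random(hemi.size) < hemi_leak))
    idx = np.flatnonzero(cut)
    bounds = [0, *(site_pos[idx] + CUT_OFFSET), contig_len]
    cuts: list[int | None] = [None, *idx.tolist(), None]
    frags = []
    for i in range(len(bounds) - 1):
        frag = FragmentRecord(
            contig=molecule.contig,
            start=int(bounds[i]),
            end=int(bounds[i + 1]),
            left_cut=cuts[i],
            right_cut=cuts[i + 1],
        )
        inside = np.flatnonzero(
            (site_pos + CUT_OFFSET > frag.start)
            & (site_pos + CUT_OFFSET < frag.end)
        )
        frag.internal = [int(j) for j in inside if not cut[j]]
        frags.append(frag)
    return frags


def capture_fragment_ends(
    fragment: FragmentRecord,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[Readout]:
    """Capture each Dpn I-generated blunt end of a fragment.

    The left cut end yields the minus half-site tag of its site; the right
    cut end the plus tag.  Molecule-terminal ends are not capturable.  If
    the fragment duplex is shorter than ``min_capture_duplex`` and both
    ends are cut sites, exactly one end is captured, chosen uniformly -
    the undercount mechanism at proximal sites.
    """
    ends: list[Readout] = []
    if fragment.left_cut is not None:
        ends.append(Readout(fragment.left_cut, "-", fragment.length))
    if fragment.right_cut is not None:
        ends.append(Readout(fragment.right_cut, "+", fragment.length))
    if len(ends) == 2 and fragment.length < cfg.min_capture_duplex:
        ends = [ends[0] if rng.random() < 0.5 else ends[1]]
    return ends


def _capture_molecule(
    cut_idx: np.ndarray,
    site_pos: np.ndarray,
    contig_len: int,
    min_duplex: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized digestion + capture for one molecule.

    Equivalent to composing dpnI_digest with capture_fragment_ends over all
    fragments; returns (site index, strand code 0=+ / 1=-, avail length).
    """
    p = site_pos[cut_idx] + CUT_OFFSET
    k = cut_idx.size
    f = np.empty(k + 1, dtype=np.int64)
    f[0] = p[0]
    if k > 1:
        f[1:k] = np.diff(p)
    f[k] = contig_len - p[-1]
    # plus tag of cut j captured from fragment j; minus tag from fragment j+1
    plus_keep = np.ones(k, dtype=bool)
    minus_keep = np.ones(k, dtype=bool)
    if k > 1:
        short = np.flatnonzero(f[1:k] < min_duplex)  # interior fragment ii+1
        if short.size:
            pick_minus = rng.random(short.size) < 0.5
            minus_keep[short] = pick_minus
            plus_keep[short + 1] = ~pick_minus
    sites = np.concatenate([cut_idx[plus_keep], cut_idx[minus_keep]])
    strands = np.concatenate(
        [
            np.zeros(int(plus_keep.sum()), dtype=np.int8),
            np.ones(int(minus_keep.sum()), dtype=np.int8),
        ]
    )
    avail = np.concatenate([f[:k][plus_keep], f[1 : k + 1][minus_keep]])
    return sites, strands, avail


def simulate_sample_readouts(
    site_probs: np.ndarray,
    site_pos: np.ndarray,
    contig_len: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Methylate, digest and capture cfg.n_molecules molecules.

    Returns one row per readout: site_index, strand ('+'/'-'), avail and
    the sampled Mme I top-strand tag length.
    """
    sites_l, strands_l, avail_l = [], [], []
    for mol in simulate_molecules(site_probs, cfg.n_molecules, rng):
        cuts = np.flatnonzero(dpnI_cuts(mol.meth))
        if cuts.size == 0:
            continue
        s, st, av = _capture_molecule(
            cuts, site_pos, contig_len, cfg.min_capture_duplex, rng
        )
        sites_l.append(s)
        strands_l.append(st)
        avail_l.append(av)
    if not sites_l:
        return pd.DataFrame(
            columns=["site_index", "strand", "avail", "length"]
        ).astype({"site_index": np.int64, "avail": np.int64, "length": np.int64})
    site = np.concatenate(sites_l)
    strand = np.concatenate(strands_l)
    avail = np.concatenate(avail_l)
    lengths = rng.choice(
        _slop_lengths(cfg), size=site.size, p=_slop_weights(cfg)
    )
    if cfg.n_reads is not None and cfg.n_reads < site.size:
        keep = np.sort(rng.choice(site.size, cfg.n_reads, replace=False))
        site, strand, avail, lengths = (
            site[keep], strand[keep], avail[keep], lengths[keep]
        )
    return pd.DataFrame(
        {
            "site_index": site.astype(np.int64),
            "strand": np.where(strand == 0, "+", "-"),
            "avail": avail.astype(np.int64),
            "length": lengths.astype(np.int64),
        }
    )


# slop distribution comes from the linker set; SimConfig carries a LinkerSet
# only implicitly (defaults). Helper indirection keeps the hot loop simple.
_DEFAULT_LINKERS = LinkerSet()


def _slop_lengths(cfg: SimConfig) -> np.ndarray:
    return _DEFAULT_LINKERS.slop_lengths()


def _slop_weights(cfg: SimConfig) -> np.ndarray:
    return _DEFAULT_LINKERS.slop_weights()


# --------------------------------------------------------------------------
# library assembly and reads


def read_genomic_portion(
    seq: str,
    site_pos: int,
    strand: str,
    length: int,
    avail: int | None = None,
    linkers: LinkerSet | None = None,
) -> str:
    """Genomic portion of a read for one captured half-site.

    Read orientation: the portion ends in the GA left at the Dpn I cut, so
    a plus tag reads genome[cut - length, cut) and a minus tag reads the
    reverse complement of genome[cut, cut + length).  When fewer than
    ``length`` duplex bases were available, the missing 5' bases are the
    linker A top-oligo suffix ligated at the fragment's other end.
    """
    linkers = linkers or _DEFAULT_LINKERS
    cut = site_pos + CUT_OFFSET
    eff = length if avail is None else min(length, avail)
    if strand == "+":
        gen = seq[max(cut - eff, 0) : cut]
    else:
        gen = revcomp(seq[cut : cut + eff])
    fill = length - len(gen)
    return (linkers.linkerA_top[-fill:] if fill else "") + gen


def assemble_library_molecule(
    genomic_portion: str, linkers: LinkerSet | None = None
) -> tuple[str, str, int, bool]:
    """Assemble the doubly-linkered molecule around one captured tag.

    ``genomic_portion`` is in read orientation (ends in GA); the amplicon
    top strand carries its reverse complement between linker A and the
    reverse complement of the linker B bottom oligo:

        top    = linkerA_top + rc(portion) + rc(linkerB_bottom)
        bottom = linkerB_top(NN resolved)  + insert bottom 18-mer
                 + linkerA_bottom

    Returns (top, bottom, amplicon length, amplifiable).  With the printed
    oligos and a 20-mer insert the strands are 116 and 71 nt and both
    bridge primers anneal; non-default linkers that break primer annealing
    are flagged non-amplifiable.
    """
    linkers = linkers or _DEFAULT_LINKERS
    insert = revcomp(genomic_portion)
    top = linkers.linkerA_top + insert + revcomp(linkers.linkerB_bottom)
    overhang = insert[-2:]  # 2-nt 3' overhang at the Mme I cut end
    b_top = linkers.linkerB_top
    if b_top.endswith("NN"):
        b_top = b_top[:-2] + revcomp(overhang)
    bottom = b_top + revcomp(insert[:-2]) + linkers.linkerA_bottom
    amplifiable = top.startswith(linkers.bridge_primer_2) and (
        linkers.bridge_primer_1 in top
    )
    return top, bottom, len(top), amplifiable


def read_sequence(
    genomic_portion: str, linkers: LinkerSet, read_length: int
) -> str:
    """Sequencer output: genomic portion then rc(linker A top), truncated."""
    return (genomic_portion + linkers.read_linker)[:read_length]


def emit_reads(
    readouts: pd.DataFrame,
    seq: str,
    site_pos: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    handle,
    sample: str = "sample",
    linkers: LinkerSet | None = None,
    contig: str = "chrS",
) -> int:
    """Write one Phred+33 FASTQ record per readout.

    Read ids encode the true source half-site
    (``<sample>:<n> src=<contig>:<pos>:<strand>``) so simulated libraries
    carry their own ground truth.  Optional uniform substitution errors.
    """
    linkers = linkers or _DEFAULT_LINKERS
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    n = 0
    for row in readouts.itertuples():
        portion = read_genomic_portion(
            seq, int(site_pos[row.site_index]), row.strand,
            int(row.length), int(row.avail), linkers,
        )
        read = read_sequence(portion, linkers, cfg.read_length)
        if cfg.error_rate > 0.0:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            hit = np.flatnonzero(rng.random(arr.size) < cfg.error_rate)
            if hit.size:
                arr[hit] = bases[rng.integers(0, 4, hit.size)]
                read = arr.tobytes().decode()
        rid = (
            f"{sample}:{n} src={contig}:{int(site_pos[row.site_index])}:"
            f"{row.strand}"
        )
        handle.write(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")
        n += 1
    return n


# --------------------------------------------------------------------------
# synthetic dataset generator


@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for a complete synthetic dataset.

    Defaults emulate the assay's design regime: a GATC site every ~190 bp
    (the C. elegans genome averages one per ~370 bp; the denser planting
    keeps per-gene site counts useful on a small genome), genes with
    phased +1..+4 nucleosomes and an upstream protected NDR, per-gene
    accessibility multipliers spanning a two-fold range (matching the
    observed bound on between-sample divergence), and a SAGE-like
    expression score coupled to accessibility through a monotone link.
    """

    genome_length: int = 200_000
    contig_name: str = "chrS"
    n_genes: int = 50
    gene_length: int = 1500
    gene_spacing: int = 1200
    gatc_spacing: int = 190
    gatc_jitter: int = 50
    n_molecules: int = 2000
    n_reads: int | None = None
    read_length: int = 36
    error_rate: float = 0.0
    min_capture_duplex: int = 24
    p_max_tissue: float = 0.8
    p_max_control: float = 0.9
    multiplier_low: float = 0.5
    multiplier_high: float = 1.0
    sage_lambda_max: float = 12.0
    nucleosomes: NucleosomeModel = NucleosomeModel()
    tissue_samples: tuple[str, ...] = ("tissue",)
    control_samples: tuple[str, ...] = ("control",)
    seed: int = 0


@dataclass
class SyntheticDataset:
    """In-memory bundle plus the paths written by the generator."""

    config: DatasetConfig
    genome: dict[str, str]
    genes: pd.DataFrame
    expression: pd.DataFrame
    anchors: pd.DataFrame
    site_pos: np.ndarray
    truth_halfsites: pd.DataFrame
    truth_genes: pd.DataFrame
    fastq_paths: dict[str, Path]
    paths: dict[str, Path]


def sample_rng(master_seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream per sample label."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed % 2**31, zlib.crc32(label.encode())])
    )


def _make_genome(cfg: DatasetConfig, rng: np.random.Generator) -> str:
    seq = rng.choice(list("ACGT"), size=cfg.genome_length)
    pos = cfg.gatc_spacing
    planted = []
    while pos < cfg.genome_length - SITE_LEN - 20:
        planted.append(pos)
        pos += cfg.gatc_spacing + int(
            rng.integers(-cfg.gatc_jitter, cfg.gatc_jitter + 1)
        )
    for p in planted:
        seq[p : p + SITE_LEN] = list("GATC")
    return "".join(seq)


def _make_genes(cfg: DatasetConfig, rng: np.random.Generator) -> pd.DataFrame:
    pitch = cfg.gene_length + cfg.gene_spacing
    usable = cfg.genome_length - 2000
    if cfg.n_genes * pitch > usable:
        raise ValueError("genes do not fit in the genome with the given spacing")
    rows = []
    start = 1000
    for g in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene{g:04d}", cfg.contig_name, start,
                     start + cfg.gene_length, strand))
        start += pitch
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "txStart", "txEnd", "strand"]
    )


def _expression_and_multiplier(
    cfg: DatasetConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent activity u ~ U(0,1) drives both quantities monotonically:
    accessibility multiplier = low + (high-low)*u, SAGE score ~
    Poisson(lambda_max * u^2)."""
    u = rng.random(len(genes))
    mult = cfg.multiplier_low + (cfg.multiplier_high - cfg.multiplier_low) * u
    score = rng.poisson(cfg.sage_lambda_max * u**2)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "latent": u,
            "multiplier": mult,
            "sage_score": score.astype(np.int64),
        }
    )


def _tissue_track(
    cfg: DatasetConfig, genes: pd.DataFrame, truth: pd.DataFrame
) -> np.ndarray:
    track = nucleosome_track(cfg.nucleosomes, genes, cfg.genome_length)
    for row in genes.merge(truth, on="gene_id").itertuples():
        track[row.txStart : row.txEnd] *= row.multiplier
    return np.clip(track, 0.0, 1.0)


def generate_synthetic_dataset(
    cfg: DatasetConfig, outdir: str | Path
) -> SyntheticDataset:
    """Generate and write a complete, seeded dataset bundle.

    Writes genome FASTA, gene BED, expression TSV, dyad-anchor BED, one
    FASTQ per sample, per-half-site and per-gene truth TSVs and a JSON
    manifest.  Re-running with the same config is byte-identical.
    """
    from . import io as dio  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = sample_rng(cfg.seed, "genome")
    seq = _make_genome(cfg, rng)
    genes = _make_genes(cfg, rng)
    if (genes["txEnd"] > cfg.genome_length).any():
        raise ValueError("gene outside contig")
    truth_genes = _expression_and_multiplier(cfg, genes, rng)

    site_pos = np.fromiter(
        (m.start() for m in __import__("re").finditer("GATC", seq)),
        dtype=np.int64,
    )
    tissue_track = _tissue_track(cfg, genes, truth_genes)
    meth_t = MethylationConfig(p_max=cfg.p_max_tissue)
    meth_c = MethylationConfig(p_max=cfg.p_max_control)
    probs_tissue = site_methylation_probs(tissue_track, site_pos, meth_t)
    probs_control = np.full(site_pos.size, cfg.p_max_control)

    th = pd.DataFrame(
        {
            "contig": cfg.contig_name,
            "site_pos": np.repeat(site_pos, 2),
            "strand": np.tile(["+", "-"], site_pos.size),
            "p_meth_tissue": np.repeat(probs_tissue, 2),
            "p_meth_control": np.repeat(probs_control, 2),
        }
    )
    # expected readouts per molecule, ignoring short-fragment collisions
    th["expected_capture_tissue"] = th["p_meth_tissue"] ** 2
    th["expected_capture_control"] = th["p_meth_control"] ** 2

    # anchors: the peak (+1) dyad of every gene, strand-aware
    d0 = cfg.nucleosomes.dyads_rel[0]
    sign = np.where(genes["strand"] == "+", 1, -1)
    tss = np.where(genes["strand"] == "+", genes["txStart"], genes["txEnd"] - 1)
    anchors = pd.DataFrame(
        {
            "contig": cfg.contig_name,
            "pos": tss + sign * d0,
            "gene_id": genes["gene_id"],
            "strand": genes["strand"],
        }
    )

    sim = SimConfig(
        n_molecules=cfg.n_molecules,
        read_length=cfg.read_length,
        error_rate=cfg.error_rate,
        min_capture_duplex=cfg.min_capture_duplex,
        n_reads=cfg.n_reads,
    )
    fastq_paths: dict[str, Path] = {}
    for label in (*cfg.tissue_samples, *cfg.control_samples):
        is_control = label in cfg.control_samples
        probs = probs_control if is_control else probs_tissue
        srng = sample_rng(cfg.seed, label)
        readouts = simulate_sample_readouts(
            probs, site_pos, cfg.genome_length, sim, srng
        )
        path = outdir / f"reads_{label}.fastq"
        with open(path, "w") as fh:
            emit_reads(
                readouts, seq, site_pos, sim, srng, fh,
                sample=label, contig=cfg.contig_name,
            )
        fastq_paths[label] = path

    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.bed",
        "expression": outdir / "expression.tsv",
        "anchors": outdir / "anchors.bed",
        "truth_halfsites": outdir / "truth_halfsites.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "manifest": outdir / "manifest.json",
    }
    dio.write_fasta({cfg.contig_name: seq}, paths["genome"])
    dio.write_bed(
        genes[["contig", "txStart", "txEnd", "gene_id", "strand"]]
        .assign(score=0)[["contig", "txStart", "txEnd", "gene_id", "score", "strand"]],
        paths["genes"],
    )
    truth_genes.merge(genes, on="gene_id")[["gene_id", "sage_score"]].to_csv(
        paths["expression"], sep="\t", index=False
    )
    dio.write_bed(
        anchors.assign(end=anchors["pos"] + 1, score=0)[
            ["contig", "pos", "end", "gene_id", "score", "strand"]
        ],
        paths["anchors"],
    )
    th.to_csv(paths["truth_halfsites"], sep="\t", index=False)
    truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "genome_length": cfg.genome_length,
                "n_genes": cfg.n_genes,
                "n_gatc_sites": int(site_pos.size),
                "n_molecules": cfg.n_molecules,
                "samples": sorted(fastq_paths),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return SyntheticDataset(
        config=cfg,
        genome={cfg.contig_name: seq},
        genes=genes,
        expression=truth_genes[["gene_id", "sage_score"]].copy(),
        anchors=anchors,
        site_pos=site_pos,
        truth_halfsites=th,
        truth_genes=truth_genes,
        fastq_paths=fastq_paths,
        paths=paths,
    )
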