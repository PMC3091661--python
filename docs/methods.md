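# Methods

## The assay model

DAM methyltransferase expressed in a tissue methylates the adenine of
GATC on each strand independently, at a rate assumed proportional to
local chromatin accessibility.  The model used throughout is a
per-molecule, per-site, per-strand Bernoulli draw with

    p(site, strand) = p_max × mean(accessibility over the 4 site bases)

with `p_max = 0.8` for in-vivo tissue exposure and `p_max = 0.9` for the
in-vitro naked-DNA control (applied with accessibility ≡ 1).  This is the
simplest model consistent with partial-digestion patterns — restriction
gels of DAM-exposed DNA show incomplete Dpn I digestion, i.e. a subset of
sites methylated per molecule — and no kinetic information is available
to justify anything richer.  Hemimethylated sites are uncut by default
(Dpn I is reported ~60-fold slower on them); `dpnI_digest` exposes a
`hemi_leak` probability for sensitivity analyses.

Dpn I cleaves doubly-methylated GATC blunt between GA and TC, so all
fragment boundaries sit at `site_pos + 2` (coordinates are 0-based,
half-open everywhere).  A direct consequence, preserved by the simulator
and asserted in tests, is that no fragment ever contains a
doubly-methylated internal site, and internal sites of cloned fragments
are protected (unmethylated or hemimethylated).

## Capture chemistry

Linker A (branched; only the first 15 nt of its bottom oligo pair with
the top oligo) ligates to each blunt Dpn I end and carries an Mme I site
at the junction.  Mme I cuts ~20/18 nt into the genomic DNA, leaving a
2-nt 3' overhang; the top-strand genomic length is drawn from
{19: 0.15, 20: 0.70, 21: 0.15}.  The weights are a design choice — the
enzyme's ±1 heterogeneity is well known but unquantified here — chosen to
populate the parser's full N16–19 acceptance range.  Linker B (a 16-fold
NN pool) ligates to the overhang.  Assembly of the doubly-linkered
molecule from the printed oligos gives a 116-nt top strand and a 71-nt
bottom strand for a 20-mer insert, and both bridge PCR primers anneal;
these are verified by string identities, not stored constants.

Capture rules: only Dpn I-generated ends are capturable (molecule ends
are not).  When a fragment's duplex is shorter than
`min_capture_duplex = 24` nt (20-nt Mme I reach plus the 4-nt site),
exactly one of its two ends is captured, uniformly at random — this
reproduces the undercount at closely spaced sites that motivates the
database's proximal filter.  If the sampled tag length exceeds the
available duplex, the missing 5' bases are taken from the linker ligated
at the fragment's other end; such chimeric tags parse but cannot align,
which is the realistic failure mode.

Reads are the genomic portion (ending in the GA of the cut site) followed
by the reverse complement of the linker A top oligo, truncated to 36 nt
(fixed-length early-Illumina regime), Phred+33 with uniform-substitution
errors off by default.

## Tag database decisions

- Tags are 16 nt; with the obligatory following GATC, alignment is
  effectively a 20-nt perfect match.  Matching is exact (hash lookup); no
  mismatch tolerance, matching the original exact-parsing design.
- Edge handling: a site whose 16-nt context runs off the contig or
  contains N yields an `edge_truncated` tag that never enters the
  uniqueness census and is never retained.
- The proximal rule excludes the *inward-facing* pair (minus tag of the
  left site, plus tag of the right site) when the inter-site gap — end of
  the first tetramer to start of the second — is strictly below 20 bp.
  The capture-competition argument concerns only the short inter-site
  fragment, so the outward-facing tags are kept.  The threshold is
  configurable.
- Filter order is fixed (uniqueness → exclusion list → proximal) and
  per-stage counts are recorded; flags can co-occur, and conservation
  (retained + union-flagged = all) is a tested invariant.

## Quantification decisions

- Counts are normalized to hits per million aligned reads before any
  ratio or fold, making indices invariant to library size.
- The ≥4-half-site gene filter is interpreted as: at least four
  half-sites inside [txStart, txEnd) each hit ≥1 time in at least one of
  the samples being compared.  Genes with zero control coverage are
  excluded rather than pseudocounted, avoiding unbounded indices.
- The divergence test is the exact conditional binomial: given
  t = x + y, x ~ Binomial(t, N1/(N1+N2)) under the null; p is the doubled
  smaller tail capped at 1.  The original analysis names only "P < 0.05";
  the binomial choice is this package's decision and alternative tests
  can be slotted behind the same (fold, p) interface.  Both raw counts
  and normalized folds are reported because figure axes and the
  equivalence line use different scales.
- Half-site position is the GATC midpoint (`site_pos + 2`) for both gene
  assignment and dyad offsets, a symmetric convention the source material
  leaves unstated.

## Metaprofiles

Offsets run dyad-relative, flipped for minus-strand anchors, default
half-width 1,000 nt.  The profile value at an offset is total hits
divided by the number of retained half-sites at that offset; offsets with
no half-site are undefined (NaN), never zero.  The control-normalized
variant divides by the same statistic from the control table.  Smoothing
is a centered moving average (default 400 nt) that skips undefined
offsets and truncates at the edges.  Anchors closer than twice the
half-width both receive shared hits; multiplicity is documented rather
than deduplicated.

## The synthetic-data generator

The generator emulates the assay's design regime, not any particular
genome:

- Random ACGT background with GATC planted every ~190 ± 50 bp (denser
  than the ~370 bp genome-wide average of the target organism, keeping
  per-gene site counts informative on small test genomes; natural random
  GATC occurrences are kept as sites too).
- Non-overlapping genes on alternating random strands; phased nucleosome
  dyads at +80, +260, +440, +620 nt from the TSS (cos² occupancy bumps,
  half-width 73 nt, depth 0.75) and a protected NDR at −150..−30
  (depth 0.5) — the upstream valley observed in the real profiles is
  attributed to non-histone protection, so the generator protects it too.
  Beyond the phased array the track returns to 1; real gene bodies carry
  delocalized nucleosomes, which the generator deliberately omits, so
  absolute index levels are not comparable to real data (rank structure
  is).
- A latent activity u ~ U(0,1) per gene drives both the accessibility
  multiplier (0.5 + 0.5u, a two-fold range matching the observed bound on
  between-sample divergence) and a SAGE-like expression score
  ~ Poisson(12 u²).  The continuous multiplier makes rank-recovery
  statistics well defined; the monotone link makes the expression trend
  recoverable.
- One RNG stream per sample, seeded from the master seed plus a CRC of
  the sample label, so samples are independently reproducible and the
  whole bundle is byte-identical under re-runs.

What passing tests show: the pipeline recovers planted structure (ranks,
phasing, calibration) from its own generative model at realistic depths.
What they do not show: robustness to PCR bias, duplicates, quality decay,
sequence-composition bias of the enzymes, transgene mosaicism or mixed
tissues — none of which the generator models.

## Problem sizes

Simulation studies use a 150 kb genome / 50 genes / 10,000 molecules per
sample (depth-dependent checks: control flatness CV < 0.1, phasing,
Spearman rank recovery > 0.9) and a 300 kb genome / 150 genes / 1,200
molecules (calibration and trend checks, where gene count matters more
than depth), each subsampled to a few hundred thousand reads — the
package's chosen balance between statistical resolution and quick,
repeatable runs.  The genome-wide GATC census check needs the real WS170
assembly and therefore a download; it cannot run from packaged data.

## Numerical notes

- Probabilities, occupancies and tracks are clipped to [0, 1];
  degenerate inputs (empty genomes, zero molecules, zero-coverage genes,
  x = y = 0 divergence points) return empty/NaN/flagged results rather
  than raising, except where the contract demands an error (invalid
  alphabet, negative scores, inconsistent configs).
- Ties in the short-fragment collision are broken by a single uniform
  draw per fragment; Mme I slop is sampled per readout after capture, so
  capture decisions are independent of tag length.
- The exact binomial uses scipy's survival functions; no normal
  approximation anywhere.
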