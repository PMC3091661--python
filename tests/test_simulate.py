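"""Protocol simulator: chemistry geometry, digestion, capture, datasets."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dalec.simulate import (
    DatasetConfig,
    FragmentRecord,
    LinkerSet,
    MethylationConfig,
    MoleculeState,
    NucleosomeModel,
    SimConfig,
    _capture_molecule,
    assemble_library_molecule,
    capture_fragment_ends,
    dpnI_digest,
    generate_synthetic_dataset,
    mboI_cuts,
    nucleosome_track,
    read_genomic_portion,
    read_sequence,
    sau3aI_cuts,
    simulate_molecules,
    simulate_sample_readouts,
    site_methylation_probs,
)
from dalec.tagdb import revcomp

L = LinkerSet()


class TestChemistry:
    def test_printed_oligo_invariants(self):
        assert L.linkerA_top.startswith(L.bridge_primer_2)
        assert revcomp(L.linkerB_bottom)[:20] == L.bridge_primer_1
        assert L.linkerA_top.endswith("TCCGAC")  # Mme I site at the junction

    def test_doubly_linkered_molecule_is_116_and_71(self):
        portion = "AAACGTACGTACGTACGTGA"  # 20-mer in read orientation
        top, bottom, amp, ok = assemble_library_molecule(portion)
        assert (len(top), len(bottom), amp) == (116, 71, 116)
        assert ok

    def test_slop_changes_lengths_additively(self):
        top, bottom, _, _ = assemble_library_molecule("A" * 19 + "GA")  # 21-mer
        assert (len(top), len(bottom)) == (117, 72)

    def test_bridge_primers_anneal_to_default_assembly(self):
        top, _, _, ok = assemble_library_molecule("AAACGTACGTACGTACGTGA")
        assert ok
        assert top.startswith(L.bridge_primer_2)
        assert L.bridge_primer_1 in top

    def test_broken_linker_flagged_non_amplifiable(self):
        bad = LinkerSet(linkerA_top="T" * 44)
        *_, ok = assemble_library_molecule("AAACGTACGTACGTACGTGA", bad)
        assert not ok

    def test_read_structure(self):
        genome = "ACGTACGTACGTACGTGATC" + "T" * 30
        portion = read_genomic_portion(genome, 16, "+", 18)
        read = read_sequence(portion, L, 36)
        assert read.startswith("ACGTACGTACGTACGTGA")
        assert read[18:] == "GTCGGAACATAGTGTACT"  # rc(linker A top) prefix
        assert len(read) == 36


class TestTrack:
    def test_no_nucleosomes_is_fully_accessible(self):
        genes = pd.DataFrame(columns=["txStart", "txEnd", "strand"])
        track = nucleosome_track(NucleosomeModel(), genes, 1000)
        assert np.all(track == 1.0)

    def test_single_dyad_valley(self):
        model = NucleosomeModel(dyads_rel=(500,), depth=0.9, ndr_depth=0.0)
        genes = pd.DataFrame(
            [{"txStart": 0, "txEnd": 1000, "strand": "+"}]
        )
        track = nucleosome_track(model, genes, 1000)
        assert track[500] == pytest.approx(0.1)
        assert np.argmin(track) == 500
        assert track[500 - 80] == 1.0 and track[500 + 80] == 1.0

    def test_phased_array_autocorrelation_peak(self):
        model = NucleosomeModel(
            dyads_rel=(100, 280, 460, 640, 820), ndr_depth=0.0
        )
        genes = pd.DataFrame([{"txStart": 0, "txEnd": 1000, "strand": "+"}])
        occ = 1 - nucleosome_track(model, genes, 1000)
        x = occ - occ.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
        lag = 100 + int(np.argmax(ac[100:260]))
        assert abs(lag - 180) <= 5

    def test_minus_strand_gene_is_mirrored(self):
        model = NucleosomeModel(dyads_rel=(100,), ndr_depth=0.0)
        plus = pd.DataFrame([{"txStart": 500, "txEnd": 900, "strand": "+"}])
        minus = pd.DataFrame([{"txStart": 100, "txEnd": 500, "strand": "-"}])
        tp = nucleosome_track(model, plus, 1000)
        tm = nucleosome_track(model, minus, 1000)
        assert np.argmin(tp) == 600  # TSS 500, dyad +100
        assert np.argmin(tm) == 399  # TSS 499, dyad -100


class TestMethylationAndDigestion:
    def test_zero_accessibility_never_methylates(self):
        rng = np.random.default_rng(0)
        probs = site_methylation_probs(
            np.zeros(100), np.array([10, 50]), MethylationConfig(p_max=0.9)
        )
        for mol in simulate_molecules(probs, 50, rng):
            assert not mol.meth.any()

    def test_double_methylation_rate_is_p_squared(self):
        rng = np.random.default_rng(1)
        probs = np.array([0.9])
        frac = np.mean(
            [m.meth[0, 0] & m.meth[0, 1]
             for m in simulate_molecules(probs, 10_000, rng)]
        )
        assert frac == pytest.approx(0.81, abs=3 * np.sqrt(0.81 * 0.19 / 10_000))

    def test_digest_cuts_only_double_and_protects_internal(self):
        site_pos = np.array([100, 200, 300])
        meth = np.array([[1, 1], [1, 0], [1, 1]], dtype=bool)
        mol = MoleculeState("c", 0, meth)
        frags = dpnI_digest(mol, site_pos, 400)
        assert [(f.start, f.end) for f in frags] == [(0, 102), (102, 302), (302, 400)]
        assert frags[1].internal == [1]  # the hemimethylated protected site

    def test_digest_degenerate_cases(self):
        site_pos = np.array([100, 200])
        none = MoleculeState("c", 0, np.zeros((2, 2), dtype=bool))
        assert len(dpnI_digest(none, site_pos, 400)) == 1
        allm = MoleculeState("c", 0, np.ones((2, 2), dtype=bool))
        assert len(dpnI_digest(allm, site_pos, 400)) == 3

    def test_fragment_lengths_conserve_contig(self):
        rng = np.random.default_rng(2)
        site_pos = np.sort(rng.choice(10_000, 30, replace=False))
        meth = rng.random((30, 2)) < 0.6
        frags = dpnI_digest(MoleculeState("c", 0, meth), site_pos, 10_000)
        assert sum(f.length for f in frags) == 10_000
        double = meth[:, 0] & meth[:, 1]
        for f in frags:
            assert not any(double[i] for i in f.internal)

    def test_isoschizomer_predicates(self):
        meth = np.array([[0, 0], [1, 0], [1, 1]], dtype=bool)
        assert mboI_cuts(meth).tolist() == [True, False, False]
        assert sau3aI_cuts(meth).tolist() == [True, True, True]


class TestCapture:
    CFG = SimConfig(min_capture_duplex=24)

    def test_long_fragment_yields_both_ends(self):
        rng = np.random.default_rng(0)
        frag = FragmentRecord("c", 100, 300, left_cut=3, right_cut=7)
        outs = capture_fragment_ends(frag, self.CFG, rng)
        assert {(o.site_index, o.strand) for o in outs} == {(3, "-"), (7, "+")}

    def test_short_fragment_yields_exactly_one_end(self):
        rng = np.random.default_rng(0)
        frag = FragmentRecord("c", 100, 112, left_cut=3, right_cut=7)
        for _ in range(20):
            assert len(capture_fragment_ends(frag, self.CFG, rng)) == 1

    def test_terminal_ends_not_captured(self):
        rng = np.random.default_rng(0)
        frag = FragmentRecord("c", 0, 150, left_cut=None, right_cut=2)
        outs = capture_fragment_ends(frag, self.CFG, rng)
        assert [(o.site_index, o.strand) for o in outs] == [(2, "+")]

    def test_fast_path_matches_fragmentwise_capture(self):
        """Vectorized capture equals digest+capture composition when no
        fragment is short (both paths then deterministic)."""
        rng = np.random.default_rng(5)
        site_pos = np.array([50, 120, 260, 400])
        meth = np.array([[1, 1], [0, 1], [1, 1], [1, 1]], dtype=bool)
        mol = MoleculeState("c", 0, meth)
        slow = [
            (o.site_index, o.strand, o.avail)
            for f in dpnI_digest(mol, site_pos, 500)
            for o in capture_fragment_ends(f, self.CFG, rng)
        ]
        cuts = np.flatnonzero(meth[:, 0] & meth[:, 1])
        s, st, av = _capture_molecule(cuts, site_pos, 500, 24, rng)
        fast = list(zip(s.tolist(),
                        ["+" if v == 0 else "-" for v in st],
                        av.tolist()))
        assert sorted(slow) == sorted(fast)

    def test_slop_length_histogram(self):
        rng = np.random.default_rng(9)
        probs = np.full(5, 0.95)
        site_pos = np.array([100, 300, 500, 700, 900])
        df = simulate_sample_readouts(
            probs, site_pos, 1100, SimConfig(n_molecules=2000), rng
        )
        frac = df["length"].value_counts(normalize=True)
        for length, weight in LinkerSet().mme_slop:
            se = 3 * np.sqrt(weight * (1 - weight) / len(df))
            assert frac[length] == pytest.approx(weight, abs=se)

    def test_readouts_bounded_by_two_per_cut(self):
        rng = np.random.default_rng(10)
        probs = np.full(10, 0.7)
        site_pos = np.arange(10) * 150 + 100
        cfg = SimConfig(n_molecules=200)
        df = simulate_sample_readouts(probs, site_pos, 2000, cfg, rng)
        # expected capture count per molecule <= 2 * number of cut sites
        assert len(df) <= 2 * 10 * 200


class TestDataset:
    def test_seeded_bundle_is_byte_identical(self, tmp_path):
        cfg = DatasetConfig(
            genome_length=20_000, n_genes=4, n_molecules=50, seed=99
        )
        a = generate_synthetic_dataset(cfg, tmp_path / "a")
        b = generate_synthetic_dataset(cfg, tmp_path / "b")
        for key in a.paths:
            assert filecmp.cmp(a.paths[key], b.paths[key], shallow=False), key
        for s in a.fastq_paths:
            assert filecmp.cmp(a.fastq_paths[s], b.fastq_paths[s], shallow=False)

    def test_zero_molecules_gives_empty_fastq_full_truth(self, tmp_path):
        cfg = DatasetConfig(
            genome_length=20_000, n_genes=4, n_molecules=0, seed=1
        )
        ds = generate_synthetic_dataset(cfg, tmp_path)
        for p in ds.fastq_paths.values():
            assert Path(p).stat().st_size == 0
        assert len(ds.truth_halfsites) == 2 * ds.site_pos.size
        assert len(ds.truth_genes) == 4

    def test_invalid_geometry_rejected(self, tmp_path):
        cfg = DatasetConfig(genome_length=10_000, n_genes=50, seed=1)
        with pytest.raises(ValueError):
            generate_synthetic_dataset(cfg, tmp_path)

    def test_capture_rate_monotone_in_accessibility(self, deep):
        """Per-half-site counts rise with the planted capture rate."""
        truth = deep.ds.truth_halfsites.copy()
        key = {
            (r.contig, int(r.site_pos), r.strand): r.id
            for r in deep.db.retained_tags.itertuples()
        }
        tissue = deep.tables["tissue"]
        rows = []
        for r in truth.itertuples():
            tid = key.get((r.contig, int(r.site_pos), r.strand))
            if tid is not None:
                rows.append((r.expected_capture_tissue, tissue.count(tid)))
        rate, count = np.array(rows).T
        order = np.argsort(rate)
        bins = np.array_split(count[order], 10)
        means = [b.mean() for b in bins]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_control_counts_homogeneous(self, deep):
        """In-vitro control: uniform counts across interior retained
        half-sites (chi-square goodness of fit not rejected at 0.01)."""
        from scipy import stats

        control = deep.tables["control"]
        ret = deep.db.retained_tags
        interior = ret[
            (ret.site_pos > 100)
            & (ret.site_pos < deep.ds.config.genome_length - 100)
        ]
        counts = np.array([control.count(int(i)) for i in interior["id"]])
        stat, p = stats.chisquare(counts)
        assert p > 0.01
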