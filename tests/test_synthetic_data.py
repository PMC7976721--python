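import filecmp
import math
from pathlib import Path

import numpy as np
import pytest

from bseeker import candidate_selection as sel
from bseeker import io_formats as iof
from bseeker import synthetic_data as synth


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.SimulationConfig(class_fractions={"single_copy": 0.5})

    def test_class_counts_total_n_genes(self):
        cfg = synth.SimulationConfig(n_genes=97)
        assert sum(cfg.class_counts().values()) == 97

    def test_b_copies_shift_expected_gfc(self):
        g1 = synth._gene_table(synth.SimulationConfig(b_copies=1))
        g3 = synth._gene_table(synth.SimulationConfig(b_copies=3))
        uc1 = g1[g1["gene_class"] == "b_linked_UC"]["expected_gfc"].unique()
        uc3 = g3[g3["gene_class"] == "b_linked_UC"]["expected_gfc"].unique()
        assert uc1 == pytest.approx([math.log2(1.5)])
        assert uc3 == pytest.approx([math.log2(2.5)])


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = synth.SimulationConfig(
            seed=5, n_genes=12,
            class_fractions={"single_copy": 8 / 12, "b_linked_UC": 2 / 12,
                             "b_linked_IC": 1 / 12, "repetitive": 1 / 12},
        )
        dirs = []
        for name in ("a", "b"):
            ds = synth.simulate_dataset(cfg)
            out = tmp_path / name
            synth.write_dataset(ds, out)
            dirs.append(out)
        files = sorted(p.relative_to(dirs[0]) for p in dirs[0].rglob("*") if p.is_file())
        assert files
        for f in files:
            assert (dirs[0] / f).read_bytes() == (dirs[1] / f).read_bytes(), f

    def test_different_seed_differs(self):
        a = synth.simulate_dataset(synth.SimulationConfig(seed=1, n_genes=10,
                                                          class_fractions={"single_copy": 1.0}))
        b = synth.simulate_dataset(synth.SimulationConfig(seed=2, n_genes=10,
                                                          class_fractions={"single_copy": 1.0}))
        assert a.sequences != b.sequences


class TestPlantedSignals:
    def test_depth_ratio_concentrates_at_high_depth(self):
        """b_copies=1 at depth factor 100: per-gene 1B/0B mean-depth ratio
        (library-size normalized) in [1.4, 1.6] for >= 95% of genes."""
        cfg = synth.SimulationConfig(
            seed=9, n_genes=100, class_fractions={"b_linked_UC": 1.0},
            b_copies=1, depth_factor=100.0, n_0B=1, n_1B=1,
        )
        ds = synth.simulate_dataset(cfg)
        lib0 = next(l for l in ds.libraries if l.molecule == "gDNA" and l.b_count == 0)
        lib1 = next(l for l in ds.libraries if l.molecule == "gDNA" and l.b_count == 1)
        in_band = 0
        for c in ds.contigs:
            d0 = ds.depth_tracks[(lib0.library_id, c.contig_id)].depth.mean()
            d1 = ds.depth_tracks[(lib1.library_id, c.contig_id)].depth.mean()
            ratio = (d1 / lib1.total_bases) / (d0 / lib0.total_bases)
            in_band += 1.4 <= ratio <= 1.6
        assert in_band >= 95

    def test_single_copy_genes_have_no_systematic_gfc(self, default_dataset):
        """Mean gFC of 200 neutral genes within +/-0.03 of 0."""
        from bseeker import copy_number as cn

        ds = default_dataset
        cfg = ds.config
        table = cn.copy_number_table(
            ds.depth_tracks.values(), ds.libraries, ds.contigs, cfg.genome_model()
        )
        genes = ds.manifest.genes
        neutral = set(genes.loc[genes["gene_class"] == "single_copy", "contig_id"])
        pivot = table.pivot(index="contig_id", columns="library_id",
                            values="copies_per_haploid")
        ids_0B = [l.library_id for l in ds.libraries
                  if l.molecule == "gDNA" and l.b_count == 0]
        ids_1B = [l.library_id for l in ds.libraries
                  if l.molecule == "gDNA" and l.b_count == 1]
        gfcs = []
        for contig in sorted(neutral):
            rec = sel.compute_gfc(contig, pivot.loc[contig, ids_1B].to_numpy(),
                                  pivot.loc[contig, ids_0B].to_numpy())
            gfcs.extend(rec.gfc)
        assert len(gfcs) >= 200
        assert abs(np.mean(gfcs)) <= 0.03

    def test_ic_breakpoint_recovered_by_segmentation(self, default_dataset):
        ds = default_dataset
        genes = ds.manifest.genes
        ic = genes[genes["gene_class"] == "b_linked_IC"]
        lib_by = {l.library_id: l for l in ds.libraries}
        t0, t1 = {}, {}
        for (lid, contig), track in ds.depth_tracks.items():
            (t1 if lib_by[lid].b_count else t0).setdefault(contig, []).append(track)
        hits = 0
        for row in ic.itertuples(index=False):
            ratio = sel.pooled_ratio(t1[row.contig_id], t0[row.contig_id], ds.libraries)
            segs, pattern = sel.segment_coverage(ratio, 100, 1.3)
            assert pattern == "IC"
            breakpoints = [e for _s, e, _m in segs[:-1]]
            assert any(abs(b - row.hc_end) <= 50 for b in breakpoints)
            hits += 1
        assert hits == len(ic)

    def test_alt_fraction_matches_b_dose(self, single_b_copy_dataset):
        """1B gDNA Alt fraction at planted sites near b/(2+b) = 1/3."""
        ds = single_b_copy_dataset
        fracs = []
        for r in ds.manifest.snps.itertuples(index=False):
            counts = ds.group_pileups[r.contig_id]["gDNA_1B"].counts[r.position - 1]
            alt = counts[iof.ALLELE_INDEX[r.alt]]
            total = counts.sum()
            fracs.append(alt / total)
        assert np.mean(fracs) == pytest.approx(1 / 3, abs=0.02)


class TestClosure:
    def test_written_files_parse_with_io_readers(self, tmp_path):
        cfg = synth.SimulationConfig(
            seed=21, n_genes=10,
            class_fractions={"single_copy": 6 / 10, "b_linked_UC": 3 / 10,
                             "b_linked_IC": 1 / 10},
        )
        ds = synth.simulate_dataset(cfg)
        out = tmp_path / "bundle"
        synth.write_dataset(ds, out)
        contigs = iof.read_contigs_tsv(out / "contigs.tsv")
        libs = iof.read_libraries_tsv(out / "libraries.tsv")
        lengths = {c.contig_id: c.length for c in contigs}
        assert len(contigs) == 10 and len(libs) == len(ds.libraries) + 2
        seqs = iof.read_fasta(out / "contigs.fasta")
        assert seqs == ds.sequences
        for lib in libs:
            if lib.species == "focal" and lib.molecule == "gDNA":
                tracks = iof.read_depth_tsv(out / "depth" / f"{lib.library_id}.depth.tsv",
                                            lengths, lib.library_id)
                for t in tracks:
                    orig = ds.depth_tracks[(lib.library_id, t.contig_id)]
                    assert np.array_equal(t.depth, orig.depth)
        for group in ("gDNA_0B", "gDNA_1B", "RNA_0B", "RNA_1B"):
            piles = iof.read_pileup_tsv(out / "pileup" / f"{group}.pileup.tsv",
                                        lengths, group)
            for p in piles:
                assert np.array_equal(p.counts, ds.group_pileups[p.contig_id][group].counts)


class TestScoreRecovery:
    def test_perfect_and_empty(self):
        truth = {"a", "b"}
        perfect = synth.score_recovery(truth, truth, universe={"a", "b", "c"})
        assert perfect["precision"] == perfect["recall"] == 1.0
        empty = synth.score_recovery(set(), truth)
        assert empty["recall"] == 0.0 and empty["fn"] == 2

    def test_hand_built_confusion_table(self):
        # 4 genes: predicted {a, c}, truth {a, b} over universe {a, b, c, d}
        out = synth.score_recovery({"a", "c"}, {"a", "b"}, universe=set("abcd"))
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (1, 1, 1, 1)
        assert out["precision"] == 0.5 and out["recall"] == 0.5
        assert out["specificity"] == 0.5

    def test_labels_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            synth.score_recovery({"z"}, {"a"}, universe={"a"})
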