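import numpy as np
import pytest

from bseeker import snp_calling as snp
from bseeker.io_formats import ALLELE_INDEX, ALLELES, PileupCounts


def _pileup(group, length=1, **per_pos):
    """Build a tiny pileup: per_pos maps 'p<idx>' -> {allele: count}."""
    counts = np.zeros((length, len(ALLELES)), dtype=np.int64)
    for key, alleles in per_pos.items():
        i = int(key[1:])
        for a, c in alleles.items():
            counts[i, ALLELE_INDEX[a]] = c
    return PileupCounts(group, "c1", counts)


def _call_site(c0, c1, cross=None, cfg=None):
    pileups = {
        "gDNA_0B": _pileup("gDNA_0B", 1, p0=c0),
        "gDNA_1B": _pileup("gDNA_1B", 1, p0=c1),
    }
    xs = [_pileup("xs", 1, p0=cross)] if cross else []
    return snp.call_b_snps(pileups, xs, cfg or snp.SnpCallConfig())


class TestFilterCascade:
    def test_clean_b_specific_snp_passes(self):
        (call,) = _call_site({"A": 40}, {"A": 30, "G": 14})
        assert (call.verdict, call.ref_allele, call.alt_allele) == ("PASS", "A", "G")
        assert call.group_counts["gDNA_0B"] == (40, 0)
        assert call.group_counts["gDNA_1B"] == (30, 14)

    def test_alt_reads_in_0B_break_fixation(self):
        (call,) = _call_site({"A": 38, "G": 2}, {"A": 30, "G": 14})
        assert call.verdict == "not_fixed_0B"

    def test_ref_below_alt_in_1B_fails_proportion_filter(self):
        (call,) = _call_site({"A": 40}, {"A": 10, "G": 25})
        assert call.verdict == "ref_lt_alt_1B"

    def test_proportion_filter_direction_is_configurable(self):
        cfg = snp.SnpCallConfig(proportion_filter="off")
        (call,) = _call_site({"A": 40}, {"A": 10, "G": 25}, cfg=cfg)
        assert call.verdict == "PASS"

    def test_two_cross_species_alt_reads_reject(self):
        (call,) = _call_site({"A": 40}, {"A": 30, "G": 14}, cross={"A": 30, "G": 2})
        assert call.verdict == "cross_species_alt"
        (call,) = _call_site({"A": 40}, {"A": 30, "G": 14}, cross={"A": 30, "G": 1})
        assert call.verdict == "PASS"

    def test_low_depth_rejected(self):
        (call,) = _call_site({"A": 5}, {"A": 30, "G": 14})
        assert call.verdict == "low_depth"

    def test_missing_gdna_group_is_an_error(self):
        with pytest.raises(ValueError, match="gDNA_1B"):
            snp.call_b_snps({"gDNA_0B": _pileup("gDNA_0B", 1, p0={"A": 40})})

    def test_position_without_alt_reads_is_not_a_candidate(self):
        calls = _call_site({"A": 40}, {"A": 35})
        assert calls == []

    def test_alt_tie_broken_by_fixed_allele_order(self):
        (call,) = _call_site({"A": 40}, {"A": 30, "C": 7, "G": 7})
        assert call.alt_allele == "C"

    def test_pass_set_is_a_conjunction_of_all_filters(self, rng):
        """Order-independence: PASS iff every filter holds, re-derived independently."""
        cfg = snp.SnpCallConfig()
        for _ in range(200):
            ref0 = int(rng.integers(0, 60))
            alt0 = int(rng.integers(0, 3))
            ref1 = int(rng.integers(0, 60))
            alt1 = int(rng.integers(0, 40))
            xs_alt = int(rng.integers(0, 4))
            calls = _call_site(
                {"A": ref0, "G": alt0}, {"A": ref1, "G": alt1}, cross={"G": xs_alt}
            )
            if ref0 == 0 or (alt0 > ref0) or alt1 < 1:
                # no fixed Ref base or Alt absent from 1B: no candidate either way
                continue
            (call,) = [c for c in calls if c.alt_allele == "G"] or [None]
            expected = (
                alt0 <= cfg.max_0B_alt
                and ref1 >= alt1
                and xs_alt <= cfg.cross_species_max_alt
                and ref0 + alt0 >= cfg.min_depth
                and ref1 + alt1 >= cfg.min_depth
            )
            assert (call.verdict == "PASS") is expected


class TestIndelEventMerging:
    def _indel_calls(self, specs):
        calls = []
        for pos, alt, verdict in specs:
            calls.append(
                snp.SnpCall("c1", pos, "A", alt, {"gDNA_0B": (40, 0), "gDNA_1B": (30, 14)},
                            0, verdict)
            )
        return snp.merge_indel_events(calls)

    def test_adjacent_deletions_share_one_event(self):
        calls = self._indel_calls([(10, "del", "PASS"), (11, "del", "PASS"),
                                   (12, "del", "PASS")])
        assert len({c.event_id for c in calls}) == 1

    def test_gap_separates_events(self):
        calls = self._indel_calls([(10, "del", "PASS"), (12, "del", "PASS")])
        assert len({c.event_id for c in calls}) == 2

    def test_type_change_separates_events(self):
        calls = self._indel_calls([(10, "G", "PASS"), (11, "del", "PASS")])
        assert len({c.event_id for c in calls}) == 2

    def test_non_pass_calls_do_not_merge(self):
        calls = self._indel_calls([(10, "del", "PASS"), (11, "del", "low_depth")])
        assert len({c.event_id for c in calls}) == 2


class TestSummary:
    def test_pass_substitutions_counted_per_gene(self):
        calls = [
            snp.SnpCall("c1", p, "A", "G", {}, 0, "PASS") for p in (5, 9, 20)
        ]
        s = snp.summarize_variants(calls, {"c1": "gene1"})
        assert s.per_gene_snps == {"gene1": 3}
        assert s.class_counts == {"s": 3, "d": 0, "i": 0}
        assert s.n_events == 3

    def test_empty_input_empty_summary(self):
        s = snp.summarize_variants([])
        assert s.per_gene_snps == {} and s.n_pass == 0 and s.n_events == 0

    def test_planted_114_variants_across_11_genes(self, rng):
        """Summary totals reproduce a planted 114-SNP / 11-gene ground truth."""
        calls = []
        genes = {}
        per_gene = rng.multinomial(114 - 11, np.full(11, 1 / 11)) + 1
        for g, n in enumerate(per_gene):
            contig = f"c{g}"
            genes[contig] = f"gene{g}"
            for j in range(n):
                calls.append(snp.SnpCall(contig, 10 + 2 * j, "A", "G", {}, 0, "PASS"))
        s = snp.summarize_variants(calls, genes)
        assert sum(s.per_gene_snps.values()) == 114
        assert len(s.per_gene_snps) == 11
        assert s.n_events <= s.n_pass


class TestOnSyntheticData:
    def test_no_false_positives_without_alt_reads(self):
        """With no Alt reads in 1B gDNA anywhere, nothing passes."""
        rng = np.random.default_rng(5)
        length = 2000
        counts0 = np.zeros((length, 6), dtype=np.int64)
        counts1 = np.zeros((length, 6), dtype=np.int64)
        ref = rng.integers(0, 4, size=length)
        counts0[np.arange(length), ref] = rng.poisson(120, size=length)
        counts1[np.arange(length), ref] = rng.poisson(180, size=length)
        calls = snp.call_b_snps(
            {
                "gDNA_0B": PileupCounts("gDNA_0B", "c1", counts0),
                "gDNA_1B": PileupCounts("gDNA_1B", "c1", counts1),
            }
        )
        assert all(c.verdict != "PASS" for c in calls)

    def test_sensitivity_and_specificity_on_planted_variants(self, single_b_copy_dataset):
        """>= 95% sensitivity, 100% specificity at Alt fraction 1/3, depth >= 30."""
        ds = single_b_copy_dataset
        truth = {
            (r.contig_id, r.position) for r in ds.manifest.snps.itertuples(index=False)
        }
        assert len(truth) >= 100
        called = set()
        any_called = set()
        for contig, groups in ds.group_pileups.items():
            for call in snp.call_b_snps(groups, ds.cross_pileups[contig]):
                any_called.add((call.contig_id, call.position))
                if call.verdict == "PASS":
                    called.add((call.contig_id, call.position))
        tp = len(called & truth)
        assert tp / len(truth) >= 0.95          # sensitivity
        assert len(called - truth) == 0          # specificity: no false PASS
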