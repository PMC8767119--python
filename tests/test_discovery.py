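import itertools

import numpy as np
import pytest

from conftest import make_expression
from lncnet.discovery import (
    classify_positional,
    coding_potential_surrogate,
    filter_candidates,
    longest_orf,
    summarize_features,
    build_records,
)
from lncnet.intervals import GenomicInterval, TranscriptModel
from lncnet.simulate.genome import random_seq
from oracles import brute_force_longest_orf, interval_relation


def tm(tid, start, end, strand="+", chrom="chr1", biotype="candidate", exons=None):
    return TranscriptModel(
        tid, tid.lower(), GenomicInterval(chrom, start, end, strand),
        exons=exons or [], biotype=biotype,
    )


def fpkm_of(values):
    samples = [f"s{i}" for i in range(len(next(iter(values.values()))))]
    return make_expression(values, samples, unit="FPKM")


class TestFilterCandidates:
    GENE = tm("G1", 1000, 2000, "+", biotype="protein_coding")

    def test_short_transcript_removed_at_step3(self):
        cand = tm("t1", 5000, 5199)  # 199 nt, no overlap
        fpkm = fpkm_of({"t1": [10.0, 10.0]})
        survivors, tally = filter_candidates([cand], fpkm, [self.GENE])
        assert survivors == [] and tally["removed_short"] == 1
        assert tally["removed_same_strand_exonic_overlap"] == 0

    def test_fpkm_exactly_half_retained(self):
        cand = tm("t1", 5000, 5200)  # exactly 200 nt
        fpkm = fpkm_of({"t1": [0.5, 0.1]})
        survivors, _ = filter_candidates([cand], fpkm, [self.GENE])
        assert [t.id for t in survivors] == ["t1"]

    def test_fpkm_below_half_removed(self):
        cand = tm("t1", 5000, 5200)
        fpkm = fpkm_of({"t1": [0.499, 0.2]})
        survivors, tally = filter_candidates([cand], fpkm, [self.GENE])
        assert survivors == [] and tally["removed_low_fpkm"] == 1

    def test_antisense_exonic_overlap_retained(self):
        cand = tm("t1", 1500, 1900, "-")  # opposite strand over gene exon
        fpkm = fpkm_of({"t1": [5.0, 5.0]})
        survivors, tally = filter_candidates([cand], fpkm, [self.GENE])
        assert [t.id for t in survivors] == ["t1"]
        assert tally["removed_same_strand_exonic_overlap"] == 0

    def test_same_strand_exonic_overlap_removed(self):
        cand = tm("t1", 1500, 1900, "+")
        fpkm = fpkm_of({"t1": [5.0, 5.0]})
        survivors, tally = filter_candidates([cand], fpkm, [self.GENE])
        assert survivors == [] and tally["removed_same_strand_exonic_overlap"] == 1

    def test_intronic_same_strand_survives(self):
        # gene with two exons; candidate inside the intron, same strand
        gene = tm(
            "G2", 1000, 3000, "+", biotype="protein_coding",
            exons=[GenomicInterval("chr1", 1000, 1200, "+"),
                   GenomicInterval("chr1", 2800, 3000, "+")],
        )
        cand = tm("t1", 1500, 2500, "+")
        fpkm = fpkm_of({"t1": [5.0, 5.0]})
        survivors, _ = filter_candidates([cand], fpkm, [gene])
        assert [t.id for t in survivors] == ["t1"]

    def test_missing_feature_raises(self):
        cand = tm("t1", 5000, 5400)
        with pytest.raises(KeyError, match="t1"):
            filter_candidates([cand], fpkm_of({"other": [1.0]}), [])

    def test_order_invariance_of_final_set(self, rng):
        """The three removal predicates are independent: any application
        order yields the same surviving set."""
        genes = [self.GENE]
        cands, fpkm_rows = [], {}
        for i in range(40):
            start = int(rng.integers(0, 9000))
            length = int(rng.integers(150, 600))
            strand = "+" if rng.random() < 0.5 else "-"
            cands.append(tm(f"c{i}", start, start + length, strand))
            fpkm_rows[f"c{i}"] = [float(rng.uniform(0, 3)), float(rng.uniform(0, 3))]
        fpkm = fpkm_of(fpkm_rows)
        max_fpkm = fpkm.values.max(axis=1)

        def p_overlap(t):
            return any(t.exonic_overlap(g, stranded=True) for g in genes)

        def p_low(t):
            return max_fpkm[t.id] < 0.5

        def p_short(t):
            return t.length < 200

        expected = {
            t.id for t in cands if not (p_overlap(t) or p_low(t) or p_short(t))
        }
        for order in itertools.permutations([p_overlap, p_low, p_short]):
            kept = [t for t in cands if not any(p(t) for p in order)]
            assert {t.id for t in kept} == expected
        survivors, _ = filter_candidates(cands, fpkm, genes)
        assert {t.id for t in survivors} == expected


class TestCodingSurrogate:
    def test_no_atg_is_noncoding(self):
        verdict, orf = coding_potential_surrogate("CCCGGGCCCGGG")
        assert verdict == "noncoding" and orf == 0

    def test_threshold_boundary_100_codons(self, rng):
        orf = "ATG" + "GCT" * 99 + "TAA"  # 100 coding codons + stop
        seq = random_seq(rng, 50) + orf + random_seq(rng, 47)
        # guard against the random flanks extending the frame
        verdict, length = coding_potential_surrogate(orf)
        assert verdict == "coding" and length == 100
        verdict99, length99 = coding_potential_surrogate("ATG" + "GCT" * 98 + "TAA")
        assert verdict99 == "noncoding" and length99 == 99

    def test_short_sequence(self):
        assert coding_potential_surrogate("AT") == ("noncoding", 0)

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        for _ in range(1000):
            seq = random_seq(rng, int(rng.integers(30, 320)))
            assert longest_orf(seq) == brute_force_longest_orf(seq)


class TestClassifyPositional:
    GENES = [
        tm("G1", 10_000, 12_000, "+", biotype="protein_coding"),
        tm("G2", 30_000, 31_000, "-", biotype="protein_coding"),
    ]

    def test_distant_is_lincrna(self):
        assert classify_positional(tm("t", 50_000, 51_000), self.GENES) == "lincRNA"

    def test_opposite_strand_overlap_is_antisense(self):
        assert (
            classify_positional(tm("t", 10_500, 11_000, "-"), self.GENES)
            == "antisense"
        )

    def test_containing_same_strand_gene_is_overlapping(self):
        # precedence: containment wins over sense
        assert (
            classify_positional(tm("t", 9_000, 13_000, "+"), self.GENES)
            == "overlapping"
        )

    def test_containing_opposite_strand_gene_is_overlapping(self):
        assert (
            classify_positional(tm("t", 29_000, 32_000, "+"), self.GENES)
            == "overlapping"
        )

    def test_same_strand_overlap_is_sense(self):
        assert classify_positional(tm("t", 11_500, 12_500, "+"), self.GENES) == "sense"

    def test_agrees_with_pairwise_relation_oracle(self, study):
        """Exhaustive interval-relation oracle on the synthetic genome."""
        genes = study.sim.genes
        for cand in study.sim.candidates:
            got = classify_positional(cand, genes)
            relations = [
                interval_relation(
                    cand.interval.start, cand.interval.end, cand.strand,
                    g.interval.start, g.interval.end, g.strand,
                )
                for g in genes
                if g.chrom == cand.chrom
            ]
            if "contains" in relations:
                expected = "overlapping"
            elif "antisense_overlap" in relations:
                expected = "antisense"
            elif "sense_overlap" in relations:
                expected = "sense"
            else:
                expected = "lincRNA"
            assert got == expected, cand.id


class TestSummaries:
    def _records(self, lengths):
        fpkm = fpkm_of({f"t{i}": [1.0] for i in range(len(lengths))})
        lncs = [tm(f"t{i}", 0, n) for i, n in enumerate(lengths)]
        return build_records(lncs, [], fpkm)

    def test_one_per_bin(self):
        tabs = summarize_features(self._records([250, 800, 1200, 2000]))
        assert list(tabs["length_bins"]["percent"]) == [25.0] * 4

    def test_degenerate_single_bin(self):
        tabs = summarize_features(self._records([300, 300, 300]))
        assert tabs["length_bins"]["percent"].iloc[0] == 100.0
        assert tabs["length_bins"]["count"].sum() == 3

    def test_percentages_sum_to_100(self, study, rng):
        lengths = [int(rng.integers(200, 3000)) for _ in range(57)]
        tabs = summarize_features(self._records(lengths))
        assert np.isclose(tabs["length_bins"]["percent"].sum(), 100.0)
        assert np.isclose(tabs["classes"]["percent"].sum(), 100.0)

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            tabs = summarize_features([])
        assert tabs["length_bins"].empty
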