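"""Three-letter alignment, candidate budgets, and anchored mate rescue."""

import numpy as np
import pytest

from acemethylome import ace_align as aa
from acemethylome import synthetic_data as sd
from acemethylome._seq import c2t, g2a, revcomp
from conftest import bare_genome, random_dna
from oracles import brute_align_pair

Q40 = "I" * 80
PARAMS = aa.AlignParams()


def cand(chrom, start, strand, phred=0, lead=0):
    return aa.AlignmentCandidate(chrom, start, strand, lead, phred)


class TestConversion:
    def test_genome_conversions(self):
        c2t_idx, g2a_idx = aa.build_index({"chr1": "ACGT" * 10}, seed_length=12)
        assert c2t_idx.sequences["chr1"].startswith("ATGT")
        assert "C" not in c2t_idx.sequences["chr1"]
        assert g2a_idx.sequences["chr1"].startswith("ACAT")
        assert "G" not in g2a_idx.sequences["chr1"]

    def test_read_conversions(self):
        r1, r2 = aa.convert_reads("TTCG", "TTCG")
        assert r1 == "TTTG"
        assert r2 == "TTCA"
        r1, _ = aa.convert_reads("TTAG", "AAAA")
        assert r1 == "TTAG"

    def test_short_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            c2t_idx, _ = aa.build_index({"tiny": "ACGT", "chr1": "A" * 100},
                                        seed_length=20)
        assert "tiny" not in c2t_idx.sequences


class TestIndexLookup:
    def test_duplicated_seed_returns_all_positions(self):
        base = random_dna(2000, seed=5)
        motif = random_dna(30, seed=6)
        seq = base[:500] + motif + base[500:1500] + motif + base[1500:]
        c2t_idx, _ = aa.build_index({"chr1": seq}, seed_length=20)
        kmer = c2t(motif)[:20]
        hits = sorted(p for _, p in c2t_idx.lookup(kmer))
        # brute-force substring scan of the converted genome
        conv = c2t(seq)
        expected = sorted(
            i for i in range(len(conv) - 19) if conv[i:i + 20] == kmer
        )
        assert hits == expected
        assert len(hits) >= 2


@pytest.fixture(scope="module")
def indexed(repeat_genome):
    return aa.build_index(repeat_genome, seed_length=20)


class TestAlignRead:
    def test_exact_read_single_unique_candidate(self, repeat_genome, indexed):
        read = repeat_genome["chr1"][25_000:25_080]  # single-copy region
        cands = aa.align_read(c2t(read), Q40, indexed, 1)
        assert len(cands) == 1
        assert cands[0].start == 25_000
        assert cands[0].strand == "+"
        assert cands[0].mismatches_leading == 0

    def test_duplicated_locus_yields_five_candidates(self, repeat_genome,
                                                     indexed):
        read = repeat_genome["chr1"][4500:4580]  # inside the repeated unit
        cands = aa.align_read(c2t(read), Q40, indexed, 1)
        assert len(cands) == 5
        starts = sorted(c.start for c in cands)
        assert starts == [4500, 9500, 15_500, 22_500, 31_500]
        assert all(c.strand == "+" for c in cands)

    def test_four_leading_mismatches_rejected(self, repeat_genome, indexed):
        read = list(repeat_genome["chr1"][25_000:25_080])
        for i in (2, 12, 22, 32):  # four mismatches in the leading 40 bases
            read[i] = "A" if read[i] != "A" else "G"
        # quality 20 keeps the summed phred at mismatches (80) within budget,
        # so rejection can only come from the leading-40 mismatch count
        cands = aa.align_read(c2t("".join(read)), "5" * 80, indexed, 1)
        assert cands == []

    def test_three_leading_mismatches_allowed(self, repeat_genome, indexed):
        read = list(repeat_genome["chr1"][25_000:25_080])
        for i in (2, 12, 22):
            read[i] = "A" if read[i] != "A" else "G"
        cands = aa.align_read(c2t("".join(read)), "5" * 80, indexed, 1)
        assert len(cands) == 1 and cands[0].start == 25_000

    def test_phred_budget_rejects_high_quality_mismatches(self, repeat_genome,
                                                          indexed):
        read = list(repeat_genome["chr1"][25_000:25_080])
        for i in (2, 12, 22, 50):  # 4 total, 3 in leading 40: 4*40=160 > 140
            read[i] = "A" if read[i] != "A" else "G"
        assert aa.align_read(c2t("".join(read)), Q40, indexed, 1) == []

    def test_read2_aligns_as_reverse_complement(self, repeat_genome, indexed):
        frag = repeat_genome["chr1"][25_000:25_400]
        read2 = revcomp(frag)[:80]
        cands = aa.align_read(g2a(read2), Q40, indexed, 2)
        assert len(cands) == 1
        assert cands[0].start == 25_320
        assert cands[0].strand == "-"


class TestResolvePair:
    def test_rescue_picks_the_window_consistent_candidate(self):
        c1 = [cand("chr1", 10_000, "+")]
        c2 = [cand("chr1", 10_350, "-"), cand("chr1", 42_000, "-")]
        pair = aa.resolve_pair(c1, c2, 80, 80, (300, 600))
        assert pair.resolution == "rescued"
        assert (pair.start1, pair.start2) == (10_000, 10_350)
        assert pair.fragment_strand == "+"

    def test_ambiguous_rescue_is_discarded(self):
        c1 = [cand("chr1", 10_000, "+")]
        c2 = [cand("chr1", 10_350, "-"), cand("chr1", 10_400, "-")]
        pair = aa.resolve_pair(c1, c2, 80, 80, (300, 600))
        assert pair.resolution == "unresolved"

    def test_both_unique_passthrough(self):
        pair = aa.resolve_pair([cand("chr1", 1000, "+")],
                               [cand("chr1", 1400, "-")], 80, 80, (300, 600))
        assert pair.resolution == "both_unique"
        assert (pair.start1, pair.end1, pair.start2, pair.end2) == \
            (1000, 1080, 1400, 1480)
        assert pair.fragment_strand == "+"

    def test_both_unique_discordant_is_unresolved(self):
        pair = aa.resolve_pair([cand("chr1", 1000, "+")],
                               [cand("chr1", 9000, "-")], 80, 80, (300, 600))
        assert pair.resolution == "unresolved"

    def test_neither_unique_is_unresolved(self):
        c = [cand("chr1", 1000, "+"), cand("chr1", 5000, "+")]
        assert aa.resolve_pair(c, c, 80, 80, (300, 600)).resolution == \
            "unresolved"

    def test_rescued_pairs_always_satisfy_window_and_orientation(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            c1 = [cand("chr1", int(rng.integers(0, 40_000)),
                       rng.choice(["+", "-"])) for _ in range(rng.integers(1, 4))]
            c2 = [cand("chr1", int(rng.integers(0, 40_000)),
                       rng.choice(["+", "-"])) for _ in range(rng.integers(1, 4))]
            pair = aa.resolve_pair(c1, c2, 80, 80, (300, 600))
            if pair.resolution == "unresolved":
                continue
            frag_len = max(pair.end1, pair.end2) - min(pair.start1, pair.start2)
            assert 300 <= frag_len <= 600
            if pair.fragment_strand == "+":
                assert pair.start1 <= pair.start2
            else:
                assert pair.start2 <= pair.start1


class TestEndToEnd:
    def test_oracle_equivalence_on_repeat_genome(self, repeat_genome):
        """Seeded search + rescue equals a full-scan brute-force aligner."""
        genome = bare_genome(repeat_genome)
        profile = sd.MethylomeProfile("WT", {"background": 0.5})
        probs = sd.assign_methylome(genome, profile, 1)
        lib = sd.LibraryParams(seed=13, depth=0.7)
        sim = sd.simulate_bsseq_reads(repeat_genome, probs, lib)
        indexes = aa.build_index(repeat_genome, 20)
        aln = aa.align_pairs(sim.reads1[:120], sim.reads2[:120], indexes)
        for row, (_, s1, q1), (_, s2, q2) in zip(
            aln.itertuples(), sim.reads1[:120], sim.reads2[:120]
        ):
            oracle = brute_align_pair(s1, q1, s2, q2, repeat_genome, PARAMS)
            assert row.resolution == oracle[0]
            if oracle[0] != "unresolved":
                assert (row.chrom, row.frag_start, row.frag_end,
                        row.fragment_strand) == oracle[1:]

    def test_resolved_pairs_map_to_true_origin(self, repeat_genome):
        """Nearly every resolved pair from unique sequence is placed at the
        fragment it was simulated from; rescued repeat-interior pairs whose
        anchor lies in unique flanks land on the true copy."""
        profile = sd.MethylomeProfile("WT", {"background": 0.5})
        probs = sd.assign_methylome(bare_genome(repeat_genome), profile, 1)
        lib = sd.LibraryParams(seed=17, depth=3)
        sim = sd.simulate_bsseq_reads(repeat_genome, probs, lib)
        indexes = aa.build_index(repeat_genome, 20)
        aln = aa.align_pairs(sim.reads1, sim.reads2, indexes)
        truth = sim.fragments.set_index("fragment_id")
        res = aln[aln.chrom.notna()].copy()
        assert len(res) > 400
        res["fid"] = res.read_id.str.split(":").str[0]
        merged = res.merge(truth, left_on="fid", right_index=True)
        correct = ((merged.frag_start == merged.start)
                   & (merged.frag_end == merged.end)
                   & (merged.fragment_strand == merged.strand))
        assert correct.mean() >= 0.99
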