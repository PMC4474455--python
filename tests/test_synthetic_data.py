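"""Generator behaviour: genome layout, methylome assignment, read simulation."""

import numpy as np
import pandas as pd
import pytest

from acemethylome import synthetic_data as sd
from acemethylome._seq import cg_start_positions, revcomp
from conftest import fig_s26_scenario


class TestGenerateToyGenome:
    def test_declared_layout_and_determinism(self):
        spec = sd.ToyGenomeSpec(
            chrom_length=50_000,
            feature_layout=[
                sd.FeatureSpec("LINE", length=6000),
                sd.FeatureSpec("LTR", length=500),
            ],
        )
        g1 = sd.generate_toy_genome(spec, seed=7)
        g2 = sd.generate_toy_genome(spec, seed=7)
        assert len(g1.sequences["chr1"]) == 50_000
        assert len(g1.repeats) == 2
        lengths = (g1.repeats.end - g1.repeats.start).tolist()
        assert sorted(lengths) == [500, 6000]
        assert g1.sequences == g2.sequences
        pd.testing.assert_frame_equal(g1.repeats, g2.repeats)
        g3 = sd.generate_toy_genome(spec, seed=8)
        assert g3.sequences != g1.sequences

    def test_zero_features_gives_empty_annotations(self):
        g = sd.generate_toy_genome(sd.ToyGenomeSpec(chrom_length=10_000), 1)
        assert g.repeats.empty and g.genes.empty and g.islands.empty
        assert len(g.sequences["chr1"]) == 10_000

    def test_island_density_within_tolerance(self):
        spec = sd.ToyGenomeSpec(chrom_length=20_000,
                                cg_island_spec=[(1000, 60.0)])
        g = sd.generate_toy_genome(spec, seed=3)
        isl = g.islands.iloc[0]
        cgs = cg_start_positions(g.sequences["chr1"])
        n = int(((cgs >= isl.start) & (cgs < isl.end)).sum())
        realized_per_600 = n * 600 / (isl.end - isl.start)
        assert 48 <= realized_per_600 <= 72

    def test_infeasible_layout_raises(self):
        spec = sd.ToyGenomeSpec(
            chrom_length=10_000,
            feature_layout=[sd.FeatureSpec("LINE", length=6000),
                            sd.FeatureSpec("LINE", length=6000)],
        )
        with pytest.raises(sd.LayoutError):
            sd.generate_toy_genome(spec, seed=1)

    def test_partial_overlap_raises(self):
        spec = sd.ToyGenomeSpec(
            chrom_length=20_000,
            feature_layout=[
                sd.FeatureSpec("LTR", length=1000, start=5000),
                sd.FeatureSpec("LTR", length=1000, start=5500),
            ],
        )
        with pytest.raises(sd.LayoutError):
            sd.generate_toy_genome(spec, seed=1)


class TestAssignMethylome:
    def test_tko_probabilities_capped(self, toy_genome):
        probs = sd.assign_methylome(toy_genome, sd.default_profile("TKO"), 1)
        assert (probs.prob <= 0.01).all()

    def test_tko_profile_rejects_high_probability(self):
        with pytest.raises(ValueError):
            sd.MethylomeProfile("TKO", {"background": 0.2})

    def test_dko_ltr_retention_exact_levels(self, toy_genome):
        profile = sd.MethylomeProfile(
            "DKO", {"background": 0.18, "LTR": 0.78, "cg_island": 0.18,
                    "LINE_promoter": 0.18, "LINE_body": 0.18}
        )
        probs = sd.assign_methylome(toy_genome, profile, 1)
        ltr = toy_genome.repeats[toy_genome.repeats["class"] == "LTR"].iloc[0]
        cg = probs[probs.context == "CG"]
        inside = cg[(cg.pos >= ltr.start) & (cg.pos < ltr.end)]
        assert not inside.empty
        assert (inside.prob == 0.78).all()
        # background well clear of features, their promoters, and the island
        last = max(int(toy_genome.repeats.end.max()),
                   int(toy_genome.islands.end.max()))
        outside = cg[cg.pos >= last + 1200]
        assert not outside.empty
        assert (outside.prob == 0.18).all()

    def test_symmetric_mode_equal_strand_probabilities(self, toy_genome):
        probs = sd.assign_methylome(toy_genome, sd.default_profile("WT"), 1)
        cg = probs[probs.context == "CG"]
        plus = cg[cg.strand == "+"].set_index("pos").prob
        minus = cg[cg.strand == "-"].copy()
        minus["pos"] = minus.pos - 1
        minus = minus.set_index("pos").prob
        common = plus.index.intersection(minus.index)
        assert len(common) > 100
        assert (plus.loc[common].to_numpy() == minus.loc[common].to_numpy()).all()

    def test_independent_mode_uses_two_levels(self, toy_genome):
        profile = sd.default_profile("WT", strand_mode="independent")
        probs = sd.assign_methylome(toy_genome, profile, 1)
        cg = probs[probs.context == "CG"]
        assert set(np.unique(cg.prob)) <= set(profile.independent_levels)

    def test_unknown_region_class_is_configuration_error(self, toy_genome):
        profile = sd.MethylomeProfile("WT", {"LTR": 0.5})
        with pytest.raises(KeyError):
            sd.assign_methylome(toy_genome, profile, 1)


class TestSimulateReads:
    def _flat_probs(self, genome, p):
        profile = sd.MethylomeProfile(
            "WT", {k: p for k in ("background", "cg_island", "LTR",
                                  "LINE_promoter", "LINE_body")},
            chh_rate=p,
        )
        return sd.assign_methylome(genome, profile, 1)

    def test_fully_methylated_limit(self, toy_genome):
        probs = self._flat_probs(toy_genome, 1.0)
        lib = sd.LibraryParams(seed=2, depth=1, conversion_rate=1.0)
        sim = sd.simulate_bsseq_reads(toy_genome, probs, lib)
        assert (sim.states.state == "C").all()

    def test_fully_unmethylated_limit(self, toy_genome):
        probs = self._flat_probs(toy_genome, 0.0)
        lib = sd.LibraryParams(seed=2, depth=1, conversion_rate=1.0)
        sim = sd.simulate_bsseq_reads(toy_genome, probs, lib)
        assert (sim.states.state == "T").all()
        # no cytosine survives on read 1 (original converted strand)
        assert all("C" not in seq for _, seq, _ in sim.reads1)

    def test_read_pair_count_equals_total_amplification(self):
        genome, p, sim = fig_s26_scenario()
        assert len(sim.reads1) == sim.fragments.copies.sum() == 73
        assert len(sim.reads2) == len(sim.reads1)

    def test_fig_s26_site_counts_at_tag_level(self):
        genome, p, sim = fig_s26_scenario()
        tags = sd.truth_pileup(sim, level="tag")
        top = tags[(tags.pos == p) & (tags.strand == "+")].iloc[0]
        assert (top.rC, top.rT) == (20, 50)
        bottom = tags[(tags.pos == p + 1) & (tags.strand == "-")].iloc[0]
        assert (bottom.rC, bottom.rT) == (2, 1)

    def test_fig_s26_clone_level_counts(self):
        genome, p, sim = fig_s26_scenario()
        clones = sd.truth_pileup(sim, level="clone")
        top = clones[(clones.pos == p) & (clones.strand == "+")].iloc[0]
        assert (top.rC, top.rT) == (2, 1)

    def test_read_length_must_fit_fragment(self):
        with pytest.raises(ValueError):
            sd.LibraryParams(fragment_min=100, fragment_max=300,
                             read_length=150)

    def test_empirical_mr_within_three_binomial_se(self, toy_genome):
        """At ~30x the truth-table MR tracks the assigned probability."""
        probs = self._flat_probs(toy_genome, 0.6)
        lib = sd.LibraryParams(seed=5, depth=30, conversion_rate=1.0)
        sim = sd.simulate_bsseq_reads(toy_genome, probs, lib)
        piled = sd.truth_pileup(sim)
        cov = piled.rC + piled.rT
        well = piled[cov >= 30]
        assert len(well) > 1000
        mr = well.rC / (well.rC + well.rT)
        se = np.sqrt(0.6 * 0.4 / (well.rC + well.rT))
        assert ((mr - 0.6).abs() <= 3 * se).mean() > 0.99

    def test_fragment_lengths_within_window(self, toy_genome):
        probs = self._flat_probs(toy_genome, 0.5)
        lib = sd.LibraryParams(seed=9, depth=2)
        sim = sd.simulate_bsseq_reads(toy_genome, probs, lib)
        lens = sim.fragments.end - sim.fragments.start
        assert lens.between(300, 600).all()

    def test_reads_match_reference_after_conversion(self, toy_genome):
        """Read 1 is the converted original strand; read 2 its reverse
        complement: with full methylation, read1 equals the reference."""
        probs = self._flat_probs(toy_genome, 1.0)
        lib = sd.LibraryParams(seed=2, depth=0.5, conversion_rate=1.0)
        sim = sd.simulate_bsseq_reads(toy_genome, probs, lib)
        seq = toy_genome.sequences["chr1"]
        for frag, (_, r1, _), (_, r2, _) in zip(
            sim.fragments.itertuples(), sim.reads1[:20], sim.reads2[:20]
        ):
            template = (seq[frag.start:frag.end] if frag.strand == "+"
                        else revcomp(seq[frag.start:frag.end]))
            assert r1 == template[:80]
            assert r2 == revcomp(template)[:80]


@pytest.fixture(scope="module")
def gene_study():
    feats = []
    for i in range(30):
        cls = "low" if i % 3 == 0 else "high"
        feats.append(sd.FeatureSpec("gene", length=1100,
                                    cg_density_class=cls,
                                    promoter_pad=500))
    spec = sd.ToyGenomeSpec(chrom_length=60_000, feature_layout=feats,
                            spacer=300)
    genome = sd.generate_toy_genome(spec, seed=4)
    probs = sd.assign_methylome(genome, sd.default_profile("WT"), 2,
                                contexts=("CG",))
    return genome, probs


class TestSimulateExpression:
    def test_deregulation_follows_promoter_state(self, gene_study):
        genome, probs = gene_study
        table = sd.simulate_expression(genome.genes, probs, seed=3)
        fc = np.log2(table.fpkm_tko / table.fpkm_wt)
        dereg = table.true_class == "deregulated"
        assert dereg.sum() == 10  # the low-density methylated genes
        assert (np.abs(fc[dereg]) > 2.5).all()
        assert (np.abs(fc[~dereg]) < 0.5).all()
        assert (table.fpkm_wt > 0).all() and (table.fpkm_tko > 0).all()
        # promoter features recovered from the probability table
        assert (table.promoter_meth[dereg] > 0.5).all()
        assert (table.promoter_cg_density[dereg] < 30).all()
        assert (table.promoter_meth[~dereg] < 0.1).all()
        assert (table.promoter_cg_density[~dereg] > 40).all()

    def test_deterministic_under_fixed_seed(self, gene_study):
        genome, probs = gene_study
        t1 = sd.simulate_expression(genome.genes, probs, seed=3)
        t2 = sd.simulate_expression(genome.genes, probs, seed=3)
        pd.testing.assert_frame_equal(t1, t2)
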