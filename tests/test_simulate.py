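"""Synthetic-data generator: determinism, conservation, contact model."""

import numpy as np
import pandas as pd
import pytest

from goldenpath import simulate as sim


class TestGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.simulate_genome(2, 100_000, seed=9)
        b = sim.simulate_genome(2, 100_000, seed=9)
        assert a == b
        c = sim.simulate_genome(2, 100_000, seed=10)
        assert a != c

    def test_requested_shape(self):
        g = sim.simulate_genome(2, [150_000, 250_000], seed=0)
        assert list(g) == ["chr1", "chr2"]
        assert len(g["chr1"]) == 150_000 and len(g["chr2"]) == 250_000

    def test_gc_fraction_near_half(self):
        g = sim.simulate_genome(1, 100_000, seed=3)["chr1"]
        gc = sum(b in "GC" for b in g) / len(g)
        sigma = 0.5 / np.sqrt(len(g))
        assert abs(gc - 0.5) < 3 * sigma


class TestFragmentGenome:
    def test_error_free_contigs_reconstruct_genome(self):
        g = sim.simulate_genome(2, 500_000, seed=4)
        seqs, truth = sim.fragment_genome(g, 10, seed=4)
        assert len(seqs) == 10
        for chrom in g:
            sub = truth.segments[truth.segments["chromosome"] == chrom]
            sub = sub.sort_values("genome_start")
            rebuilt = "".join(seqs[r["contig_id"]] for _, r in sub.iterrows())
            assert rebuilt == g[chrom]

    def test_total_length_conserved(self):
        g = sim.simulate_genome(2, 400_000, seed=5)
        seqs, truth = sim.fragment_genome(g, 8, seed=5, inversion_count=2)
        assert sum(map(len, seqs.values())) == 800_000
        assert truth.contig_lengths().sum() == 800_000

    def test_chimera_contig_lists_two_chromosomes(self):
        g = sim.simulate_genome(2, 2_000_000, seed=6)
        seqs, truth = sim.fragment_genome(
            g, 10, seed=6, chimera_count=1, min_chimera_arm=300_000
        )
        chimeras = [e for e in truth.errors if e["type"] == "chimera"]
        assert len(chimeras) == 1
        cid = chimeras[0]["contig_id"]
        seg = truth.segments[truth.segments["contig_id"] == cid]
        assert len(set(seg["chromosome"])) == 2
        arms = (seg["genome_end"] - seg["genome_start"]).to_numpy()
        assert (arms >= 300_000).all()

    def test_inverted_contig_sequence_is_reverse_complement(self):
        g = sim.simulate_genome(1, 300_000, seed=7)
        seqs, truth = sim.fragment_genome(g, 4, seed=7, inversion_count=1)
        inv = [e["contig_id"] for e in truth.errors if e["type"] == "inversion"]
        assert len(inv) == 1
        seg = truth.segments.set_index("contig_id").loc[inv[0]]
        original = g["chr1"][int(seg["genome_start"]) : int(seg["genome_end"])]
        assert seqs[inv[0]] == sim.reverse_complement(original)

    def test_infeasible_chimera_raises(self):
        g = sim.simulate_genome(2, 100_000, seed=8)
        with pytest.raises(ValueError, match="chimera"):
            sim.fragment_genome(g, 4, seed=8, chimera_count=1,
                                min_chimera_arm=2_000_000)


@pytest.fixture(scope="module")
def flat_truth():
    g = sim.simulate_genome(2, 2_000_000, seed=20)
    _, truth = sim.fragment_genome(g, 8, seed=20)
    return truth


class TestHiCPairs:
    def test_trans_zero_keeps_all_pairs_cis(self, flat_truth):
        pairs = sim.simulate_hic_pairs(flat_truth, 5000, trans_frac=0.0,
                                       noise_frac=0.0, seed=1)
        seg = flat_truth.segments.set_index("contig_id")
        ch1 = seg.loc[pairs["contig1"], "chromosome"].to_numpy()
        ch2 = seg.loc[pairs["contig2"], "chromosome"].to_numpy()
        assert (ch1 == ch2).all()

    def test_trans_fraction_within_binomial_bounds(self, flat_truth):
        n = 100_000
        frac = 0.05
        pairs = sim.simulate_hic_pairs(flat_truth, n, trans_frac=frac,
                                       noise_frac=0.0, seed=2)
        seg = flat_truth.segments.set_index("contig_id")
        ch1 = seg.loc[pairs["contig1"], "chromosome"].to_numpy()
        ch2 = seg.loc[pairs["contig2"], "chromosome"].to_numpy()
        observed = (ch1 != ch2).mean()
        # trans draws can land on the same chromosome by chance (2 chromosomes,
        # equal lengths: about half), so the cross-chromosome rate is ~frac/2
        expected = frac / 2
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * sigma

    def test_median_separation_decreases_with_decay_exponent(self, flat_truth):
        med = {}
        for alpha in (0.5, 1.5):
            pairs = sim.simulate_hic_pairs(flat_truth, 100_000, decay_alpha=alpha,
                                           trans_frac=0.0, noise_frac=0.0, seed=3)
            seg = flat_truth.segments.set_index("contig_id")
            g1 = (seg.loc[pairs["contig1"], "genome_start"].to_numpy()
                  + pairs["pos1"].to_numpy())
            g2 = (seg.loc[pairs["contig2"], "genome_start"].to_numpy()
                  + pairs["pos2"].to_numpy())
            med[alpha] = np.median(np.abs(g1 - g2))
        assert med[1.5] < med[0.5]

    def test_noise_pairs_fall_below_q10(self, flat_truth):
        pairs = sim.simulate_hic_pairs(flat_truth, 50_000, noise_frac=0.1, seed=4)
        mq = np.minimum(pairs["mapq1"], pairs["mapq2"])
        noisy = (mq < 10).mean()
        assert 0.07 < noisy < 0.13
        assert (pairs.loc[mq >= 10, ["mapq1", "mapq2"]].to_numpy() == 60).all()

    def test_deterministic_for_seed(self, flat_truth):
        a = sim.simulate_hic_pairs(flat_truth, 1000, seed=5)
        b = sim.simulate_hic_pairs(flat_truth, 1000, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestGuideMap:
    def test_marker_count_tracks_spacing(self, flat_truth):
        markers, _ = sim.simulate_guide_map(flat_truth, marker_spacing=100_000, seed=6)
        per_chrom = markers.groupby("chromosome").size()
        for chrom, L in flat_truth.chrom_lengths.items():
            assert abs(per_chrom[chrom] - L / 100_000) <= 2

    def test_noise_free_alignments_match_truth(self, flat_truth):
        _, aln = sim.simulate_guide_map(flat_truth, marker_spacing=50_000, seed=7)
        seg = flat_truth.segments.set_index("contig_id")
        homes = seg["chromosome"]
        assert (aln["guide_chr"].to_numpy()
                == homes.loc[aln["contig_id"]].to_numpy()).all()

    def test_inverted_contig_alignments_have_minus_orientation(self):
        g = sim.simulate_genome(1, 500_000, seed=21)
        _, truth = sim.fragment_genome(g, 4, seed=21, inversion_count=1)
        inv = [e["contig_id"] for e in truth.errors if e["type"] == "inversion"][0]
        _, aln = sim.simulate_guide_map(truth, marker_spacing=20_000, seed=8)
        on_inv = aln[aln["contig_id"] == inv]
        assert len(on_inv) > 0
        assert (on_inv["orientation"] == -1).all()

    def test_noise_markers_get_wrong_chromosome(self, flat_truth):
        _, aln = sim.simulate_guide_map(flat_truth, marker_spacing=50_000, seed=9,
                                        noise_markers=5)
        seg = flat_truth.segments.set_index("contig_id")
        wrong = (aln["guide_chr"].to_numpy()
                 != seg.loc[aln["contig_id"], "chromosome"].to_numpy()).sum()
        assert wrong == 5


class TestGroundTruthBreaks:
    def test_apply_breaks_matches_break_contigs_naming_and_coordinates(self):
        g = sim.simulate_genome(1, 400_000, seed=22)
        seqs, truth = sim.fragment_genome(g, 2, seed=22)
        cid = truth.segments["contig_id"].iloc[0]
        L = int(truth.contig_lengths()[cid])
        cut = L // 3
        t2 = truth.apply_breaks([(cid, cut)])
        lens = t2.contig_lengths()
        assert lens[f"{cid}.1"] == cut
        assert lens[f"{cid}.2"] == L - cut
        # the parts still tile the genome
        for chrom, Lc in t2.chrom_lengths.items():
            sub = t2.segments[t2.segments["chromosome"] == chrom]
            sub = sub.sort_values("genome_start")
            assert sub["genome_start"].iloc[0] == 0
            assert sub["genome_end"].iloc[-1] == Lc
            assert (sub["genome_start"].to_numpy()[1:]
                    == sub["genome_end"].to_numpy()[:-1]).all()
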