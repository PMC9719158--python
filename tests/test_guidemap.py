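"""Guide-map construction, alignment filtering, chromosome assignment."""

import numpy as np
import pandas as pd
import pytest

from goldenpath.guidemap import (
    assign_chromosomes,
    extract_single_copy_markers,
    genetic_map_tags,
    ingest_marker_paf,
)
from goldenpath.model import UNASSIGNED


def _random_seq(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), n))


class TestSingleCopyExtraction:
    def test_nonrepeating_sequence_gives_one_near_full_marker(self):
        seq = _random_seq(5000, 1)
        markers = extract_single_copy_markers({"chr1": seq}, min_len=100, k=31)
        assert len(markers) == 1
        assert len(markers.at[0, "tag_sequence"]) >= 4900

    def test_internal_duplicate_splits_markers_around_it(self):
        x = _random_seq(400, 2)
        d = _random_seq(300, 3)
        y = _random_seq(400, 4)
        markers = extract_single_copy_markers({"chr1": x + d + y + d}, k=31)
        # only X and Y are single-copy; D (and its second copy) is excluded
        assert len(markers) == 2
        for tag in markers["tag_sequence"]:
            assert d not in tag

    def test_interval_below_min_len_dropped(self):
        x = _random_seq(99, 5)
        d = _random_seq(500, 6)
        markers = extract_single_copy_markers({"chr1": x + d + d}, min_len=100, k=31)
        assert len(markers) == 0

    def test_doubled_genome_has_no_single_copy_markers(self):
        seq = _random_seq(3000, 7)
        markers = extract_single_copy_markers({"chr1": seq, "chr2": seq}, k=31)
        assert len(markers) == 0

    def test_k_larger_than_sequences_warns_and_returns_empty(self):
        markers = extract_single_copy_markers({"chr1": "ACGT"}, k=31)
        assert len(markers) == 0

    def test_reverse_complement_duplicate_is_not_single_copy(self):
        from goldenpath.simulate import reverse_complement

        x = _random_seq(400, 8)
        d = _random_seq(300, 9)
        seq = x + d + _random_seq(400, 10) + reverse_complement(d)
        markers = extract_single_copy_markers({"chr1": seq}, k=31)
        for tag in markers["tag_sequence"]:
            assert d not in tag


class TestGeneticMapTags:
    @pytest.fixture
    def reference(self):
        return {"ref1": _random_seq(5000, 11)}

    def _map_row(self, pos, marker="m1"):
        return pd.DataFrame(
            [{"marker_id": marker, "chromosome": "1", "cM": 10.5,
              "ref_chromosome": "ref1", "ref_position": pos}]
        )

    def test_full_flank_tag_is_101bp_centered(self, reference):
        tags = genetic_map_tags(self._map_row(1000), reference, flank=50)
        tag = tags.at[0, "tag_sequence"]
        assert len(tag) == 101
        assert tag == reference["ref1"][949:1050]  # [pos-1-50, pos+50]
        assert tags.at[0, "position"] == 10.5

    def test_tag_truncated_at_sequence_start(self, reference):
        tags = genetic_map_tags(self._map_row(10), reference, flank=50)
        assert len(tags.at[0, "tag_sequence"]) == 60  # 9 left + site + 50 right

    def test_position_beyond_end_skips_record(self, reference):
        tags = genetic_map_tags(self._map_row(9999), reference)
        assert len(tags) == 0

    def test_empty_map_table(self, reference):
        empty = pd.DataFrame(
            columns=["marker_id", "chromosome", "cM", "ref_chromosome", "ref_position"]
        )
        assert len(genetic_map_tags(empty, reference)) == 0

    def test_end100_style_tag_ends_at_marker(self, reference):
        tags = genetic_map_tags(self._map_row(1000), reference, tag_style="end100")
        assert tags.at[0, "tag_sequence"] == reference["ref1"][900:1000]


class TestPafIngestion:
    MARKERS = pd.DataFrame(
        {"marker_id": ["m1", "m2", "m3"], "chromosome": ["1", "1", "2"],
         "position": [5.0, 7.5, 1.0]}
    )

    @staticmethod
    def _paf(qname, nmatch, alnlen, qlen=101, qstart=0, qend=101, strand="+"):
        return {
            "qname": qname, "qlen": qlen, "qstart": qstart, "qend": qend,
            "strand": strand, "tname": "tigA", "tlen": 10_000, "tstart": 500,
            "tend": 500 + alnlen, "nmatch": nmatch, "alnlen": alnlen, "mapq": 60,
        }

    def test_clean_unique_alignment_kept(self):
        paf = pd.DataFrame([self._paf("m1", 100, 101)])
        out = ingest_marker_paf(paf, self.MARKERS)
        assert list(out["marker_id"]) == ["m1"]
        assert out.at[0, "guide_chr"] == "1"
        assert out.at[0, "contig_pos"] == 500
        assert out.at[0, "orientation"] == 1

    def test_near_equal_second_alignment_is_ambiguous(self):
        paf = pd.DataFrame([self._paf("m1", 100, 101), self._paf("m1", 91, 101)])
        assert len(ingest_marker_paf(paf, self.MARKERS)) == 0

    def test_weak_second_alignment_is_fine(self):
        paf = pd.DataFrame([self._paf("m1", 100, 101), self._paf("m1", 80, 101)])
        assert len(ingest_marker_paf(paf, self.MARKERS)) == 1

    def test_low_identity_dropped(self):
        paf = pd.DataFrame([self._paf("m1", 85, 100)])
        assert len(ingest_marker_paf(paf, self.MARKERS, min_identity=0.9)) == 0

    def test_short_alignment_fraction_dropped(self):
        paf = pd.DataFrame([self._paf("m1", 50, 50, qstart=0, qend=50)])
        assert len(ingest_marker_paf(paf, self.MARKERS, min_frac_aligned=0.8)) == 0

    def test_minus_strand_records_orientation(self):
        paf = pd.DataFrame([self._paf("m2", 101, 101, strand="-")])
        out = ingest_marker_paf(paf, self.MARKERS)
        assert out.at[0, "orientation"] == -1

    def test_malformed_paf_line_names_line_number(self, tmp_path):
        f = tmp_path / "aln.paf"
        f.write_text("m1\t101\t0\t101\t+\ttigA\t10000\t500\t601\tx\t101\t60\n")
        with pytest.raises(ValueError, match=":1"):
            ingest_marker_paf(f, self.MARKERS)


def _aln(contig, chroms, positions=None):
    n = len(chroms)
    positions = positions if positions is not None else np.arange(n) * 1000
    return pd.DataFrame(
        {
            "marker_id": [f"{contig}_m{i}" for i in range(n)],
            "guide_chr": chroms,
            "guide_pos": np.arange(n) * 100_000.0,
            "contig_id": contig,
            "contig_pos": positions,
            "aligned_len": 101,
            "identity": 1.0,
            "orientation": 1,
        }
    )


class TestAssignChromosomes:
    def test_unanimous_contig_assigned_with_purity_one(self):
        out = assign_chromosomes(_aln("c", ["chr1"] * 10))
        assert out.at[0, "chromosome"] == "chr1"
        assert out.at[0, "purity"] == 1.0
        assert out.at[0, "support"] == 10
        assert not out.at[0, "chimera_flag"]

    def test_mixed_contig_unassigned_and_flagged(self):
        out = assign_chromosomes(_aln("c", ["chr1"] * 6 + ["chr2"] * 4))
        assert out.at[0, "chromosome"] == UNASSIGNED
        assert out.at[0, "purity"] == pytest.approx(0.6)
        assert out.at[0, "chimera_flag"]

    def test_markerless_contig_reported_unassigned_with_zero_support(self):
        contigs = pd.DataFrame({"contig_id": ["c", "bare"], "length": [100, 100]})
        out = assign_chromosomes(_aln("c", ["chr1"] * 3), contigs).set_index("contig_id")
        assert out.at["bare", "chromosome"] == UNASSIGNED
        assert out.at["bare", "support"] == 0

    def test_single_marker_below_min_support(self):
        out = assign_chromosomes(_aln("c", ["chr1"]), min_support=2)
        assert out.at[0, "chromosome"] == UNASSIGNED
        assert out.at[0, "support"] == 1

    def test_guide_pos_is_median_of_winning_markers(self):
        out = assign_chromosomes(_aln("c", ["chr1"] * 5))
        assert out.at[0, "guide_pos"] == 200_000.0


def test_simulated_contigs_assigned_to_true_chromosome(small_bundle, small_assembly):
    # noise-free alignments: every contig with enough markers lands correctly
    from goldenpath.guidemap import assign_chromosomes

    truth = small_bundle["truth"]
    homes = truth.dominant_homes().set_index("contig_id")
    out = assign_chromosomes(small_assembly.alignments, small_assembly.contigs)
    for _, row in out.iterrows():
        if row["chromosome"] != UNASSIGNED:
            assert row["chromosome"] == homes.at[row["contig_id"], "chromosome"]
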