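"""Chimera detection heuristics and contig breaking."""

import numpy as np
import pandas as pd
import pytest

import goldenpath as gp
from goldenpath.chimera import (
    Breakpoint,
    break_contigs,
    detect_coverage_drops,
    detect_marker_discordance,
)
from goldenpath.digest_links import CoverageProfile


def _profile(values, window=1000, length=None):
    values = np.asarray(values, dtype=np.int64)
    length = length if length is not None else len(values) * window
    return CoverageProfile("c", window, length, values)


class TestCoverageDrops:
    def test_flat_profile_has_no_candidates(self):
        assert detect_coverage_drops(_profile([50] * 400)) == []

    def test_internal_eightfold_dip_yields_one_candidate_at_minimum(self):
        vals = np.full(400, 80)
        vals[200:203] = [12, 9, 11]  # mean ~ 79.5, 9 is > 8-fold below
        cands = detect_coverage_drops(_profile(vals))
        assert len(cands) == 1
        assert cands[0].position == pytest.approx(201_500, abs=1)

    def test_dip_within_end_margin_ignored(self):
        vals = np.full(400, 80)
        vals[50] = 0  # 50.5 kb from the start: inside the 100-kb margin
        assert detect_coverage_drops(_profile(vals)) == []

    def test_shallow_dip_below_threshold_ignored(self):
        vals = np.full(400, 80)
        vals[200] = 15  # 80/15 = 5.3-fold < 8-fold
        assert detect_coverage_drops(_profile(vals)) == []

    def test_contig_shorter_than_two_margins_has_no_interior(self):
        assert detect_coverage_drops(_profile([0] * 150)) == []

    def test_nearby_low_windows_merge_into_one_candidate(self):
        vals = np.full(400, 80)
        vals[200] = 2
        vals[203] = 1  # within 3 windows: same run
        vals[250] = 3  # separate run
        cands = detect_coverage_drops(_profile(vals))
        assert len(cands) == 2


def _discordant_alignments(blocks):
    """blocks: list of (chromosome, n_markers); markers laid consecutively."""
    rows = []
    pos = 0
    for chrom, n in blocks:
        for _ in range(n):
            rows.append(
                {"marker_id": f"m{pos}", "guide_chr": chrom,
                 "guide_pos": float(pos), "contig_id": "c", "contig_pos": pos,
                 "aligned_len": 101, "identity": 1.0, "orientation": 1}
            )
            pos += 1000
    return pd.DataFrame(rows)


class TestMarkerDiscordance:
    def test_two_chromosome_blocks_flagged_with_boundary(self):
        aln = _discordant_alignments([("chr1", 20), ("chr2", 20)])
        out = detect_marker_discordance(aln)
        assert list(out["contig_id"]) == ["c"]
        assert out.at[0, "boundary_start"] == 19_000
        assert out.at[0, "boundary_end"] == 20_000

    def test_single_chromosome_not_flagged(self):
        aln = _discordant_alignments([("chr1", 40)])
        assert len(detect_marker_discordance(aln)) == 0

    def test_stray_marker_block_below_minimum_not_flagged(self):
        aln = _discordant_alignments([("chr1", 20), ("chr2", 1), ("chr1", 20)])
        assert len(detect_marker_discordance(aln)) == 0


@pytest.fixture
def breakable_assembly():
    contigs = pd.DataFrame({"contig_id": ["C"], "length": [5_000_000]})
    fragments = pd.DataFrame(
        {"contig_id": ["C", "C"], "start": [0, 1_500_000],
         "end": [1_500_000, 5_000_000], "index": [0, 1]}
    )
    pairs = pd.DataFrame(
        {"contig1": ["C", "C"], "pos1": [1_999_999, 100],
         "mapq1": [60, 60], "contig2": ["C", "C"],
         "pos2": [2_000_000, 4_000_000], "mapq2": [60, 60]}
    )
    alignments = pd.DataFrame(
        {"marker_id": ["m1"], "guide_chr": ["chr1"], "guide_pos": [1.0],
         "contig_id": ["C"], "contig_pos": [3_500_000], "aligned_len": [101],
         "identity": [1.0], "orientation": [1]}
    )
    return gp.new_assembly(contigs, fragments, pairs, alignments)


class TestBreakContigs:
    def test_parts_cover_the_split_intervals(self, breakable_assembly):
        out = break_contigs(breakable_assembly, [("C", 2_000_000)])
        lens = out.contig_lengths()
        assert lens["C.1"] == 2_000_000 and lens["C.2"] == 3_000_000

    def test_marker_moves_to_second_part_with_shifted_position(self, breakable_assembly):
        out = break_contigs(breakable_assembly, [("C", 2_000_000)])
        aln = out.alignments.iloc[0]
        assert aln["contig_id"] == "C.2"
        assert aln["contig_pos"] == 1_500_000

    def test_boundary_position_stays_in_left_part(self, breakable_assembly):
        out = break_contigs(breakable_assembly, [("C", 2_000_000)])
        ends = out.pairs.iloc[0]
        # position 1,999,999 < 2,000,000 stays left; 2,000,000 goes right at 0
        assert {ends["contig1"], ends["contig2"]} == {"C.1", "C.2"}
        by_part = {ends["contig1"]: ends["pos1"], ends["contig2"]: ends["pos2"]}
        assert by_part["C.1"] == 1_999_999
        assert by_part["C.2"] == 0

    def test_fragments_recut_at_break(self, breakable_assembly):
        out = break_contigs(breakable_assembly, [("C", 2_000_000)])
        frag = out.fragments
        f1 = frag[frag["contig_id"] == "C.1"]
        assert list(zip(f1["start"], f1["end"])) == [(0, 1_500_000), (1_500_000, 2_000_000)]
        f2 = frag[frag["contig_id"] == "C.2"]
        assert list(zip(f2["start"], f2["end"])) == [(0, 3_000_000)]

    def test_conservation_of_pairs_markers_and_bp(self, small_assembly):
        lengths = small_assembly.contig_lengths()
        big = lengths.idxmax()
        cuts = [int(lengths[big] * f) for f in (0.3, 0.7)]
        out = break_contigs(small_assembly, [(big, c) for c in cuts])
        assert len(out.pairs) == len(small_assembly.pairs)
        assert len(out.alignments) == len(small_assembly.alignments)
        assert out.contigs["length"].sum() == small_assembly.contigs["length"].sum()
        out.validate()

    def test_sequences_split_consistently(self, small_assembly):
        lengths = small_assembly.contig_lengths()
        big = lengths.idxmax()
        cut = int(lengths[big] // 2)
        out = break_contigs(small_assembly, [(big, cut)])
        orig = small_assembly.sequences[big]
        assert out.sequences[f"{big}.1"] + out.sequences[f"{big}.2"] == orig

    @pytest.mark.parametrize("position", [0, 5_000_000, -1, 6_000_000])
    def test_out_of_range_breakpoint_rejected(self, breakable_assembly, position):
        with pytest.raises(ValueError):
            break_contigs(breakable_assembly, [("C", position)])

    def test_duplicate_breakpoint_rejected(self, breakable_assembly):
        with pytest.raises(ValueError, match="duplicate"):
            break_contigs(breakable_assembly, [("C", 1000), ("C", 1000)])

    def test_unknown_contig_rejected(self, breakable_assembly):
        with pytest.raises(KeyError):
            break_contigs(breakable_assembly, [(Breakpoint("nope", 10))])


def test_injected_chimeras_detected_near_true_junctions(chimera_bundle, chimera_assembly):
    """Every injected inter-chromosomal chimera shows a coverage trough within
    one window of the junction and discordant marker blocks."""
    from goldenpath.chimera import scan_assembly

    asm = chimera_assembly
    truth = chimera_bundle["truth"]
    junctions = {e["contig_id"]: e["junction"] for e in truth.errors
                 if e["type"] == "chimera"}
    assert len(junctions) == 3
    cands = scan_assembly(asm)
    for cid, junction in junctions.items():
        # within one coverage window: same or adjacent 1-kb window
        hits = [c for c in cands if c.contig_id == cid
                and abs(c.position // 1000 - junction // 1000) <= 1]
        assert hits, f"no candidate within one window of {cid} junction"
    flagged = set(detect_marker_discordance(asm.alignments)["contig_id"])
    assert set(junctions) <= flagged
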