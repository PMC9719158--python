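"""Synthetic test bed: genomes, fragmented contigs, Hi-C pairs, guide maps.

The generator emulates the inputs of a chromosome-scale scaffolding run on an
inbred diploid genome: a multi-chromosome genome of i.i.d. random sequence
(so k-mers are unique with high probability and every region is single-copy),
fragmented into contigs at uniform breakpoints, optionally with injected
inter-chromosomal chimeras and inversions; Hi-C read pairs with a truncated
power-law contact-distance decay and a configurable trans-contact fraction,
emitted as already-mapped positions; and a guide map of regularly spaced
markers whose assembly alignments are computed exactly from the ground truth.

Every function takes an integer seed and is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ALIGNMENT_COLUMNS, HiCMap

__all__ = [
    "GroundTruth",
    "simulate_genome",
    "fragment_genome",
    "simulate_hic_pairs",
    "simulate_guide_map",
    "simulate_all",
]

_SEG_COLUMNS = [
    "contig_id", "seg_index", "chromosome",
    "genome_start", "genome_end", "strand", "contig_start",
]


@dataclass
class GroundTruth:
    """True provenance of every contig: which genome slices compose it.

    ``segments`` has one row per (contig, source slice); ordinary contigs
    have one segment, injected chimeras two.  Segment rows of one chromosome
    tile it exactly.  ``errors`` records injected chimera junctions and
    inversions.
    """

    chrom_lengths: dict[str, int]
    segments: pd.DataFrame
    errors: list[dict] = field(default_factory=list)

    def contig_lengths(self) -> pd.Series:
        seg = self.segments
        ln = (seg["genome_end"] - seg["genome_start"]).groupby(seg["contig_id"]).sum()
        ln.name = "length"
        return ln

    def contig_catalog(self) -> pd.DataFrame:
        ln = self.contig_lengths()
        return pd.DataFrame({"contig_id": ln.index, "length": ln.to_numpy()})

    # -- truth layout ---------------------------------------------------

    def dominant_homes(self, min_purity: float = 0.95) -> pd.DataFrame:
        """Per contig: dominant chromosome, its bp share, position and strand.

        The dominant chromosome is the one contributing the most bp.  Contigs
        whose dominant share is below ``min_purity`` (unbroken chimeras) get
        chromosome None.  ``offset`` extrapolates the contig origin onto the
        dominant chromosome (genome_start - contig_start of the dominant
        segment), so midpoints of lightly contaminated parts stay honest.
        """
        seg = self.segments.assign(
            bp=lambda s: s["genome_end"] - s["genome_start"]
        )
        rows = []
        for cid, grp in seg.groupby("contig_id", sort=False):
            by_chrom = grp.groupby("chromosome")["bp"].sum()
            chrom = by_chrom.idxmax()
            purity = by_chrom[chrom] / by_chrom.sum()
            dom = grp[grp["chromosome"] == chrom].sort_values("bp").iloc[-1]
            rows.append(
                {
                    "contig_id": cid,
                    "chromosome": chrom if purity >= min_purity else None,
                    "purity": float(purity),
                    "offset": int(dom["genome_start"]) - int(dom["contig_start"]),
                    "strand": int(dom["strand"]),
                    "length": int(grp["bp"].sum()),
                }
            )
        return pd.DataFrame(rows)

    def to_map(self, gap: int = 0, min_purity: float = 0.95) -> HiCMap:
        """The true contig layout as a HiCMap (offsets = true genome starts).

        Contigs are placed on their dominant chromosome when it holds at
        least ``min_purity`` of their bp, which keeps parts of broken
        chimeras (carrying at most a sliver of foreign sequence when the
        break missed the junction by a little) in the layout; genuinely
        chimeric contigs have no single true position and stay unplaced.
        """
        homes = self.dominant_homes(min_purity=min_purity)
        rows = []
        for chrom in self.chrom_lengths:
            sub = homes[homes["chromosome"] == chrom].sort_values("offset")
            for rank, (_, r) in enumerate(sub.iterrows(), start=1):
                rows.append(
                    {
                        "chromosome": chrom,
                        "rank": rank,
                        "contig_id": r["contig_id"],
                        "orientation": int(r["strand"]),
                        "length": int(r["length"]),
                        "offset": int(r["offset"]),
                    }
                )
        table = pd.DataFrame(rows, columns=["chromosome", "rank", "contig_id",
                                            "orientation", "length", "offset"])
        unplaced = sorted(homes.loc[homes["chromosome"].isna(), "contig_id"])
        return HiCMap(table=table, unplaced=unplaced, gap=gap)

    # -- coordinate projection -------------------------------------------

    def project(self, chromosomes: np.ndarray, positions: np.ndarray):
        """Map genome coordinates to (contig_id, contig position) arrays."""
        seg = self.segments
        out_contig = np.empty(len(positions), dtype=object)
        out_pos = np.zeros(len(positions), dtype=np.int64)
        chromosomes = np.asarray(chromosomes, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        for chrom in self.chrom_lengths:
            mask = chromosomes == chrom
            if not mask.any():
                continue
            sub = seg[seg["chromosome"] == chrom].sort_values("genome_start")
            starts = sub["genome_start"].to_numpy()
            ends = sub["genome_end"].to_numpy()
            strands = sub["strand"].to_numpy()
            c_start = sub["contig_start"].to_numpy()
            cids = sub["contig_id"].to_numpy(dtype=object)
            p = positions[mask]
            i = np.searchsorted(starts, p, side="right") - 1
            if (i < 0).any() or (p >= ends[i]).any():
                raise ValueError("genome position outside truth tiling")
            fwd = c_start[i] + (p - starts[i])
            rev = c_start[i] + (ends[i] - 1 - p)
            out_contig[mask] = cids[i]
            out_pos[mask] = np.where(strands[i] == 1, fwd, rev)
        return out_contig, out_pos

    # -- updates and persistence ------------------------------------------

    def apply_breaks(self, breaks: list[tuple[str, int]]) -> "GroundTruth":
        """Truth after splitting contigs; part naming matches break_contigs."""
        by_contig: dict[str, list[int]] = {}
        for cid, pos in breaks:
            by_contig.setdefault(cid, []).append(int(pos))
        rows = []
        for cid, grp in self.segments.groupby("contig_id", sort=False):
            grp = grp.sort_values("seg_index")
            if cid not in by_contig:
                rows.extend(grp.to_dict("records"))
                continue
            total = int((grp["genome_end"] - grp["genome_start"]).sum())
            cuts = [0] + sorted(by_contig[cid]) + [total]
            for part_i, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:]), start=1):
                part_id = f"{cid}.{part_i}"
                seg_i = 0
                for _, s in grp.iterrows():
                    s_lo = int(s["contig_start"])
                    s_hi = s_lo + int(s["genome_end"] - s["genome_start"])
                    a, b = max(lo, s_lo), min(hi, s_hi)
                    if a >= b:
                        continue
                    if s["strand"] == 1:
                        g0 = int(s["genome_start"]) + (a - s_lo)
                        g1 = g0 + (b - a)
                    else:
                        g1 = int(s["genome_end"]) - (a - s_lo)
                        g0 = g1 - (b - a)
                    rows.append(
                        {
                            "contig_id": part_id,
                            "seg_index": seg_i,
                            "chromosome": s["chromosome"],
                            "genome_start": g0,
                            "genome_end": g1,
                            "strand": int(s["strand"]),
                            "contig_start": a - lo,
                        }
                    )
                    seg_i += 1
        return GroundTruth(
            chrom_lengths=dict(self.chrom_lengths),
            segments=pd.DataFrame(rows, columns=_SEG_COLUMNS),
            errors=list(self.errors),
        )

    def save(self, path) -> None:
        payload = {
            "chrom_lengths": self.chrom_lengths,
            "segments": self.segments.to_dict("records"),
            "errors": self.errors,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            chrom_lengths={k: int(v) for k, v in payload["chrom_lengths"].items()},
            segments=pd.DataFrame(payload["segments"], columns=_SEG_COLUMNS),
            errors=payload["errors"],
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(
    n_chrom: int = 2, chrom_lengths=20_000_000, seed: int = 0
) -> dict[str, str]:
    """Random genome: i.i.d. uniform A/C/G/T chromosomes named chr1, chr2, ...

    ``chrom_lengths`` is a single length or a sequence of per-chromosome
    lengths (>= 1 Mb recommended so the Hi-C decay model has range to act on).
    """
    if np.isscalar(chrom_lengths):
        chrom_lengths = [int(chrom_lengths)] * n_chrom
    if len(chrom_lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    rng = np.random.default_rng(seed)
    genome = {}
    for i, L in enumerate(chrom_lengths, start=1):
        idx = rng.integers(0, 4, size=int(L))
        genome[f"chr{i}"] = _BASES[idx].tobytes().decode("ascii")
    return genome


def fragment_genome(
    genome: dict[str, str],
    n_contigs: int,
    seed: int = 0,
    chimera_count: int = 0,
    inversion_count: int = 0,
    min_chimera_arm: int = 2_000_000,
) -> tuple[dict[str, str], GroundTruth]:
    """Fragment a genome into contigs, optionally injecting assembly errors.

    Breakpoints are drawn uniformly (contig count split across chromosomes in
    proportion to length).  Each injected chimera joins two runs of adjacent
    intervals from *different* chromosomes, each run at least
    ``min_chimera_arm`` long, so the junction sits >= that distance from both
    contig ends; merging runs means error injection can reduce the contig
    count below ``n_contigs``.  Inversions reverse-complement an ordinary
    contig in place (truth strand becomes -1).  Contig ids are assigned in a
    random permutation so identifiers carry no positional information.
    """
    chroms = list(genome)
    if n_contigs < len(chroms):
        raise ValueError("n_contigs must be >= number of chromosomes")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    extra = n_contigs - len(chroms)
    alloc = rng.multinomial(extra, lengths / lengths.sum())

    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, k in zip(chroms, alloc):
        L = len(genome[chrom])
        cuts = np.unique(rng.integers(1, L, size=int(k)))
        bounds = np.concatenate(([0], cuts, [L]))
        intervals[chrom] = list(zip(bounds[:-1], bounds[1:]))

    # chimeras: merge interval runs >= min_chimera_arm on two chromosomes
    chimera_pieces = []  # list of ((chromA, lo, hi), (chromB, lo, hi))
    errors: list[dict] = []
    for _ in range(chimera_count):
        picked = []
        order = rng.permutation(len(chroms))
        for ci in order:
            chrom = chroms[ci]
            iv = intervals[chrom]
            run = _find_run(iv, min_chimera_arm, rng)
            if run is not None:
                lo_i, hi_i = run
                lo, hi = iv[lo_i][0], iv[hi_i][1]
                picked.append((chrom, lo, hi, lo_i, hi_i))
            if len(picked) == 2:
                break
        if len(picked) < 2:
            raise ValueError("cannot inject chimera: fragments too short")
        for chrom, lo, hi, lo_i, hi_i in picked:
            del intervals[chrom][lo_i : hi_i + 1]
        chimera_pieces.append(tuple(p[:3] for p in picked))

    # assemble contig definitions: list of segment lists
    defs: list[list[tuple[str, int, int, int]]] = []  # (chrom, lo, hi, strand)
    for chrom in chroms:
        for lo, hi in intervals[chrom]:
            defs.append([(chrom, int(lo), int(hi), 1)])
    for (ca, la, ha), (cb, lb, hb) in chimera_pieces:
        defs.append([(ca, la, ha, 1), (cb, lb, hb, 1)])

    # inversions among ordinary contigs
    simple_idx = [i for i, d in enumerate(defs) if len(d) == 1]
    if inversion_count > len(simple_idx):
        raise ValueError("not enough ordinary contigs for requested inversions")
    inverted = set(rng.choice(simple_idx, size=inversion_count, replace=False).tolist())
    for i in inverted:
        chrom, lo, hi, _ = defs[i][0]
        defs[i][0] = (chrom, lo, hi, -1)

    # name in a random permutation
    width = max(5, len(str(len(defs))))
    names = [f"tig{j + 1:0{width}d}" for j in range(len(defs))]
    perm = rng.permutation(len(defs))
    seg_rows, sequences = [], {}
    for slot, di in enumerate(perm):
        cid = names[slot]
        parts, cpos = [], 0
        for seg_i, (chrom, lo, hi, strand) in enumerate(defs[di]):
            s = genome[chrom][lo:hi]
            parts.append(s if strand == 1 else reverse_complement(s))
            seg_rows.append(
                {
                    "contig_id": cid, "seg_index": seg_i, "chromosome": chrom,
                    "genome_start": lo, "genome_end": hi,
                    "strand": strand, "contig_start": cpos,
                }
            )
            cpos += hi - lo
        sequences[cid] = "".join(parts)
        if len(defs[di]) == 2:
            junction = defs[di][0][2] - defs[di][0][1]
            errors.append({"type": "chimera", "contig_id": cid, "junction": int(junction)})
        elif defs[di][0][3] == -1:
            errors.append({"type": "inversion", "contig_id": cid})

    truth = GroundTruth(
        chrom_lengths={c: len(genome[c]) for c in chroms},
        segments=pd.DataFrame(seg_rows, columns=_SEG_COLUMNS),
        errors=errors,
    )
    return sequences, truth


def _find_run(intervals, min_total: int, rng) -> tuple[int, int] | None:
    """A random run of adjacent intervals totaling >= min_total, or None."""
    n = len(intervals)
    candidates = []
    for i in range(n):
        total = 0
        for j in range(i, n):
            # runs must be genomically contiguous (earlier chimera carve-outs
            # leave gaps between list-adjacent intervals)
            if j > i and intervals[j][0] != intervals[j - 1][1]:
                break
            total += intervals[j][1] - intervals[j][0]
            if total >= min_total:
                candidates.append((i, j))
                break
    if not candidates:
        return None
    # leave at least one interval on the chromosome
    candidates = [c for c in candidates if not (c[0] == 0 and c[1] == n - 1)] or candidates
    return candidates[int(rng.integers(0, len(candidates)))]


def _power_law_separation(rng, n, alpha, lo, hi):
    """Draw separations with density proportional to d**-alpha on [lo, hi)."""
    u = rng.random(n)
    lo = float(lo)
    hi = np.asarray(hi, dtype=float)
    if abs(alpha - 1.0) < 1e-12:
        d = lo * np.exp(u * np.log(hi / lo))
    else:
        a = 1.0 - alpha
        d = (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)
    return np.minimum(d.astype(np.int64), (hi - 1).astype(np.int64))


def simulate_hic_pairs(
    truth: GroundTruth,
    n_pairs: int,
    decay_alpha: float = 1.0,
    trans_frac: float = 0.05,
    min_sep: int = 1000,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Hi-C read pairs as mapped positions in contig coordinates.

    Cis pairs (probability 1 - trans_frac) put one end uniformly on a
    chromosome chosen in proportion to length and the other at a separation
    drawn from a truncated power law d**-decay_alpha on [min_sep, chromosome
    length).  Trans pairs place both ends uniformly on independently chosen
    chromosomes.  Positions are projected onto contigs through the ground
    truth (respecting injected chimeras and inversions) and given mapping
    quality 60; a ``noise_frac`` fraction of pairs emulates mis-mapped reads —
    one end is moved to a uniformly random contig position with mapping
    quality below 10, so the default Q10 ingestion filter removes them.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(truth.chrom_lengths)
    lens = np.array([truth.chrom_lengths[c] for c in chroms], dtype=np.int64)
    probs = lens / lens.sum()

    is_trans = rng.random(n_pairs) < trans_frac
    ci1 = rng.choice(len(chroms), size=n_pairs, p=probs)
    ci2 = np.where(is_trans, rng.choice(len(chroms), size=n_pairs, p=probs), ci1)
    g1 = (rng.random(n_pairs) * lens[ci1]).astype(np.int64)
    g2 = np.empty(n_pairs, dtype=np.int64)
    # trans: uniform on the second chromosome
    g2[is_trans] = (rng.random(is_trans.sum()) * lens[ci2[is_trans]]).astype(np.int64)
    # cis: power-law separation, direction flipped when out of range
    cis = ~is_trans
    n_cis = int(cis.sum())
    if n_cis:
        x = g1[cis]
        L = lens[ci1[cis]]
        d = _power_law_separation(rng, n_cis, decay_alpha, min_sep, L)
        # resample separations that fit on neither side of x, so pairs never
        # clamp onto chromosome termini
        for _ in range(100):
            stuck = d > np.maximum(x, L - 1 - x)
            if not stuck.any():
                break
            d[stuck] = _power_law_separation(
                rng, int(stuck.sum()), decay_alpha, min_sep, L[stuck]
            )
        else:
            d = np.minimum(d, np.maximum(x, L - 1 - x))
        sign = np.where(rng.random(n_cis) < 0.5, 1, -1)
        cand = x + sign * d
        out = (cand < 0) | (cand >= L)
        cand = np.where(out, x - sign * d, cand)
        g2[cis] = cand

    chrom_arr = np.array(chroms, dtype=object)
    c1, p1 = truth.project(chrom_arr[ci1], g1)
    c2, p2 = truth.project(chrom_arr[ci2], g2)
    mq1 = np.full(n_pairs, 60, dtype=np.int64)
    mq2 = np.full(n_pairs, 60, dtype=np.int64)

    if noise_frac > 0:
        noisy = rng.random(n_pairs) < noise_frac
        idx = np.flatnonzero(noisy)
        if len(idx):
            lengths = truth.contig_lengths()
            cids = lengths.index.to_numpy(dtype=object)
            pick = rng.integers(0, len(cids), size=len(idx))
            rnd_pos = (rng.random(len(idx)) * lengths.to_numpy()[pick]).astype(np.int64)
            which = rng.random(len(idx)) < 0.5
            c1[idx[which]] = cids[pick[which]]
            p1[idx[which]] = rnd_pos[which]
            mq1[idx[which]] = rng.integers(0, 10, size=int(which.sum()))
            c2[idx[~which]] = cids[pick[~which]]
            p2[idx[~which]] = rnd_pos[~which]
            mq2[idx[~which]] = rng.integers(0, 10, size=int((~which).sum()))

    return pd.DataFrame(
        {"contig1": c1, "pos1": p1, "mapq1": mq1, "contig2": c2, "pos2": p2, "mapq2": mq2}
    )


def simulate_guide_map(
    truth: GroundTruth,
    marker_spacing: int = 100_000,
    seed: int = 0,
    noise_markers: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guide markers at regular spacing (with jitter) plus exact alignments.

    Marker positions are bp coordinates on the true chromosomes; alignments
    are computed from the ground truth, so no external aligner is involved.
    ``noise_markers`` randomly chosen markers get a wrong guide chromosome
    label, emulating marker misplacement in real maps.
    """
    if marker_spacing >= min(truth.chrom_lengths.values()):
        raise ValueError("marker_spacing must be below the shortest chromosome")
    rng = np.random.default_rng(seed)
    mk_rows = []
    for chrom, L in truth.chrom_lengths.items():
        grid = np.arange(marker_spacing // 2, L, marker_spacing, dtype=np.int64)
        jitter = rng.integers(-marker_spacing // 4, marker_spacing // 4 + 1, size=len(grid))
        pos = np.clip(grid + jitter, 0, L - 1)
        for i, p in enumerate(np.unique(pos)):
            mk_rows.append(
                {"marker_id": f"m_{chrom}_{i:05d}", "chromosome": chrom,
                 "position": int(p), "tag_sequence": ""}
            )
    markers = pd.DataFrame(mk_rows)

    guide_chr = markers["chromosome"].to_numpy(dtype=object).copy()
    if noise_markers > 0:
        chroms = list(truth.chrom_lengths)
        idx = rng.choice(len(markers), size=min(noise_markers, len(markers)), replace=False)
        for i in idx:
            others = [c for c in chroms if c != guide_chr[i]] or chroms
            guide_chr[i] = others[int(rng.integers(0, len(others)))]

    cids, cpos = truth.project(
        markers["chromosome"].to_numpy(dtype=object), markers["position"].to_numpy()
    )
    seg = truth.segments.set_index(["contig_id", "seg_index"])
    # orientation of the segment each marker landed in
    strands = _segment_strands(truth, markers)
    alignments = pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "guide_chr": guide_chr,
            "guide_pos": markers["position"].astype(float),
            "contig_id": cids,
            "contig_pos": cpos,
            "aligned_len": 101,
            "identity": 1.0,
            "orientation": strands,
        },
        columns=ALIGNMENT_COLUMNS,
    )
    return markers, alignments


def _segment_strands(truth: GroundTruth, markers: pd.DataFrame) -> np.ndarray:
    out = np.ones(len(markers), dtype=np.int64)
    seg = truth.segments
    for chrom in truth.chrom_lengths:
        mask = (markers["chromosome"] == chrom).to_numpy()
        if not mask.any():
            continue
        sub = seg[seg["chromosome"] == chrom].sort_values("genome_start")
        starts = sub["genome_start"].to_numpy()
        strands = sub["strand"].to_numpy()
        p = markers["position"].to_numpy()[mask]
        i = np.searchsorted(starts, p, side="right") - 1
        out[mask] = strands[i]
    return out


def simulate_all(
    seed: int = 1,
    n_chrom: int = 2,
    chrom_lengths=20_000_000,
    n_contigs: int = 60,
    n_pairs: int = 500_000,
    decay_alpha: float = 1.0,
    trans_frac: float = 0.05,
    marker_spacing: int = 100_000,
    chimera_count: int = 0,
    inversion_count: int = 0,
    noise_frac: float = 0.02,
    noise_markers: int = 0,
):
    """One-call study-scale dataset; returns a dict bundle.

    Defaults are the package's reference synthetic conditions: a 2 x 20 Mb
    genome in 60 contigs, 5e5 Hi-C pairs (decay exponent 1.0, 5% trans), and
    markers every 100 kb.  Sub-seeds are derived from ``seed`` so the stages
    are independently reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    genome = simulate_genome(n_chrom, chrom_lengths, seed=seeds[0])
    contigs, truth = fragment_genome(
        genome, n_contigs, seed=seeds[1],
        chimera_count=chimera_count, inversion_count=inversion_count,
    )
    pairs = simulate_hic_pairs(
        truth, n_pairs, decay_alpha=decay_alpha, trans_frac=trans_frac,
        noise_frac=noise_frac, seed=seeds[2],
    )
    markers, alignments = simulate_guide_map(
        truth, marker_spacing=marker_spacing, seed=seeds[3], noise_markers=noise_markers
    )
    return {
        "genome": genome,
        "contig_sequences": contigs,
        "truth": truth,
        "pairs": pairs,
        "markers": markers,
        "alignments": alignments,
    }


def emit_fastq(
    genome: dict[str, str], pairs_genomic: pd.DataFrame, read_len: int, path1, path2
) -> None:
    """Optional FASTQ emitter for integration with external mappers.

    ``pairs_genomic`` needs columns (chrom1, gpos1, chrom2, gpos2); reads are
    genome substrings of ``read_len`` starting at each end (truncated at
    chromosome ends), constant quality.  Not used on the main analysis path.
    """
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, row in pairs_genomic.iterrows():
            for fh, (ch, gp) in zip(
                (f1, f2),
                ((row["chrom1"], row["gpos1"]), (row["chrom2"], row["gpos2"])),
            ):
                seq = genome[ch][int(gp) : int(gp) + read_len]
                fh.write(f"@pair{i}\n{seq}\n+\n{'I' * len(seq)}\n")
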