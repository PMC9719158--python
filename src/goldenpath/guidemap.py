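"""Guide maps: ordered marker tags that assign contigs to chromosomes.

A guide map is a set of sequence-tag markers with a (chromosome, position)
coordinate — either intervals of a finished reference genome that occur
exactly once genome-wide (a "reference" guide map), or short flanking tags of
genetic-map markers positioned in centimorgans.  Markers are aligned to the
new assembly externally (PAF input); this module builds the marker sets,
filters the alignments, and votes contigs onto chromosomes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import ALIGNMENT_COLUMNS, ASSIGNMENT_COLUMNS, UNASSIGNED

logger = logging.getLogger(__name__)

__all__ = [
    "extract_single_copy_markers",
    "genetic_map_tags",
    "ingest_marker_paf",
    "assign_chromosomes",
]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(base: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit k-mer codes for every window start; invalid windows masked.

    Exact for k <= 32 (codes fit in 64 bits).
    """
    n = len(base)
    m = n - k + 1
    valid_pos = base >= 0
    b = np.where(valid_pos, base, 0).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        fwd += b[i : m + i] << np.uint64(2 * (k - 1 - i))
        rev += (np.uint64(3) - b[i : m + i]) << np.uint64(2 * i)
    # window valid iff all k positions are unambiguous bases
    cs = np.concatenate(([0], np.cumsum(valid_pos.astype(np.int64))))
    ok = (cs[k:] - cs[:-k]) == k
    return np.minimum(fwd, rev), ok


def extract_single_copy_markers(
    sequences: dict[str, str], min_len: int = 100, k: int = 31
) -> pd.DataFrame:
    """Extract single-copy regions of a reference as guide markers.

    A position is single-copy when every k-mer window covering it occurs
    exactly once genome-wide (canonical k-mers, so a region duplicated on the
    opposite strand is not single-copy).  Maximal single-copy runs of at
    least ``min_len`` bp become markers with id ``chr:start-end`` (0-based,
    half-open) and position at the interval midpoint.

    Returns a marker table: marker_id, chromosome, position, tag_sequence.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    encoded = {name: _encode(seq) for name, seq in sequences.items()}
    usable = {n: b for n, b in encoded.items() if len(b) >= k}
    if not usable:
        logger.warning("k=%d exceeds every sequence length; no markers extracted", k)
        return pd.DataFrame(
            columns=["marker_id", "chromosome", "position", "tag_sequence"]
        )
    all_codes, all_ok = [], []
    for name in usable:
        codes, ok = _kmer_codes(usable[name], k)
        all_codes.append(codes)
        all_ok.append(ok)
    cat_codes = np.concatenate(all_codes)
    cat_ok = np.concatenate(all_ok)
    uniq, inverse, counts = np.unique(
        cat_codes[cat_ok], return_inverse=True, return_counts=True
    )
    single = np.zeros(len(cat_codes), dtype=bool)
    single[np.flatnonzero(cat_ok)] = counts[inverse] == 1

    rows = []
    pos0 = 0
    for name in usable:
        m = len(usable[name]) - k + 1
        u = single[pos0 : pos0 + m]
        pos0 += m
        # position i single-copy <=> all covering windows j in [i-k+1, i] single
        pad = np.ones(k - 1, dtype=bool)
        up = np.concatenate([pad, u, pad])
        sw = np.lib.stride_tricks.sliding_window_view(up, k)
        pos_ok = sw.all(axis=1)[: len(usable[name])]
        # ambiguous bases are never single-copy
        pos_ok &= usable[name] >= 0
        for start, end in _runs(pos_ok):
            if end - start >= min_len:
                rows.append(
                    {
                        "marker_id": f"{name}:{start}-{end}",
                        "chromosome": name,
                        "position": (start + end) // 2,
                        "tag_sequence": sequences[name][start:end],
                    }
                )
    out = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "tag_sequence"])
    logger.info("extracted %d single-copy markers >= %d bp (k=%d)", len(out), min_len, k)
    return out


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs."""
    if len(mask) == 0:
        return
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    yield from zip(starts, ends)


def genetic_map_tags(
    map_table: pd.DataFrame,
    sequences: dict[str, str],
    flank: int = 50,
    min_tag_len: int = 20,
    tag_style: str = "flank",
) -> pd.DataFrame:
    """Build marker tags from a genetic map positioned on a reference.

    ``map_table`` columns: marker_id, chromosome, cM, ref_chromosome,
    ref_position (1-based, genetic-map convention).  With the default
    ``tag_style="flank"`` the tag covers ``flank`` bp up- and downstream of
    the marker site (101 bp at full flanks), truncated at sequence ends;
    ``tag_style="end100"`` emits exact 100-bp tags ending at the marker
    position (the convention of some published SNP-array maps).  Tags shorter
    than ``min_tag_len`` are dropped with a warning.  Marker position in the
    output is the cM value.
    """
    if tag_style not in ("flank", "end100"):
        raise ValueError(f"unknown tag_style {tag_style!r}")
    rows = []
    for _, rec in map_table.iterrows():
        ref_chr = str(rec["ref_chromosome"])
        if ref_chr not in sequences:
            logger.error("marker %s: unknown reference sequence %r; skipped",
                         rec["marker_id"], ref_chr)
            continue
        seq = sequences[ref_chr]
        pos1 = int(rec["ref_position"])
        if pos1 < 1 or pos1 > len(seq):
            logger.error("marker %s: position %d beyond %r end (%d bp); skipped",
                         rec["marker_id"], pos1, ref_chr, len(seq))
            continue
        p = pos1 - 1  # 0-based site
        if tag_style == "flank":
            start, end = max(0, p - flank), min(len(seq), p + flank + 1)
        else:
            start, end = max(0, pos1 - 100), pos1
        tag = seq[start:end]
        if len(tag) < min_tag_len:
            logger.warning("marker %s: tag of %d bp < %d; dropped",
                           rec["marker_id"], len(tag), min_tag_len)
            continue
        rows.append(
            {
                "marker_id": str(rec["marker_id"]),
                "chromosome": str(rec["chromosome"]),
                "position": float(rec["cM"]),
                "tag_sequence": tag,
            }
        )
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "tag_sequence"])


_PAF_COLS = [
    "qname", "qlen", "qstart", "qend", "strand",
    "tname", "tlen", "tstart", "tend", "nmatch", "alnlen", "mapq",
]


def read_paf(path) -> pd.DataFrame:
    """Parse the 12 standard PAF columns (extra SAM-style tags ignored)."""
    rows = {c: [] for c in _PAF_COLS}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has < 12 columns")
            try:
                for i, c in enumerate(_PAF_COLS):
                    v = fields[i]
                    rows[c].append(v if c in ("qname", "strand", "tname") else int(v))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed PAF field") from None
    return pd.DataFrame(rows)


def ingest_marker_paf(
    paf,
    markers: pd.DataFrame,
    min_identity: float = 0.9,
    min_frac_aligned: float = 0.8,
    ambiguity_ratio: float = 0.9,
) -> pd.DataFrame:
    """Filter marker-to-assembly PAF alignments into a marker-alignment table.

    Per marker the single best alignment by (matches, then alignment length)
    is kept; markers are dropped when the best alignment has identity below
    ``min_identity`` or aligns less than ``min_frac_aligned`` of the tag, or
    when a second alignment reaches ``ambiguity_ratio`` times the best match
    count (ambiguous placement).  Guide coordinates come from ``markers``
    (columns marker_id, chromosome, position).
    """
    aln = read_paf(paf) if not isinstance(paf, pd.DataFrame) else paf.copy()
    guide = markers.set_index("marker_id")
    rows = []
    for qname, grp in aln.groupby("qname", sort=True):
        grp = grp.sort_values(["nmatch", "alnlen"], ascending=False, kind="stable")
        best = grp.iloc[0]
        if len(grp) > 1 and grp.iloc[1]["nmatch"] >= ambiguity_ratio * best["nmatch"]:
            continue
        identity = best["nmatch"] / best["alnlen"] if best["alnlen"] else 0.0
        frac = (best["qend"] - best["qstart"]) / best["qlen"] if best["qlen"] else 0.0
        if identity < min_identity or frac < min_frac_aligned:
            continue
        if qname not in guide.index:
            logger.warning("alignment for unknown marker %r skipped", qname)
            continue
        g = guide.loc[qname]
        rows.append(
            {
                "marker_id": qname,
                "guide_chr": g["chromosome"],
                "guide_pos": g["position"],
                "contig_id": best["tname"],
                "contig_pos": int(best["tstart"]),
                "aligned_len": int(best["alnlen"]),
                "identity": float(identity),
                "orientation": 1 if best["strand"] == "+" else -1,
            }
        )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def assign_chromosomes(
    alignments: pd.DataFrame,
    contigs: pd.DataFrame | None = None,
    min_support: int = 2,
    min_purity: float = 0.75,
    chimera_purity: float = 0.95,
) -> pd.DataFrame:
    """Vote each contig onto a chromosome from its marker alignments.

    The winning chromosome is the mode of the markers' guide chromosomes
    (ties broken lexicographically); purity is the winner's share.  Contigs
    with fewer than ``min_support`` winning-chromosome markers or purity
    below ``min_purity`` are left UNASSIGNED.  Contigs whose markers span
    more than one chromosome with purity below ``chimera_purity`` are flagged
    as chimera candidates.  ``guide_pos`` is the median guide position of the
    winning-chromosome markers.  Passing the contig catalog adds rows
    (support 0, UNASSIGNED) for markerless contigs.
    """
    rows = []
    if len(alignments):
        for cid, grp in alignments.groupby("contig_id", sort=True):
            counts = grp["guide_chr"].value_counts()
            top = counts.max()
            winner = sorted(counts[counts == top].index)[0]
            support = int(counts[winner])
            purity = support / len(grp)
            guide_pos = float(grp.loc[grp["guide_chr"] == winner, "guide_pos"].median())
            chimera = len(counts) > 1 and purity < chimera_purity
            assigned = support >= min_support and purity >= min_purity
            rows.append(
                {
                    "contig_id": cid,
                    "chromosome": winner if assigned else UNASSIGNED,
                    "support": support,
                    "purity": purity,
                    "guide_pos": guide_pos,
                    "chimera_flag": bool(chimera),
                }
            )
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    if contigs is not None:
        missing = set(contigs["contig_id"]) - set(out["contig_id"])
        if missing:
            extra = pd.DataFrame(
                {
                    "contig_id": sorted(missing),
                    "chromosome": UNASSIGNED,
                    "support": 0,
                    "purity": np.nan,
                    "guide_pos": np.nan,
                    "chimera_flag": False,
                }
            )
            out = pd.concat([out, extra], ignore_index=True)
    return out
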