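"""In-silico restriction digestion and Hi-C link bookkeeping.

Hi-C pairs arrive as already-mapped positions produced by an external read
mapper; this module filters them by mapping quality (Q10 by default, keeping
only pairs mapped with some degree of uniqueness), aggregates them into
per-contig-pair link counts, computes physical-coverage profiles (the number
of pairs whose spanned interval overlaps a genomic window — troughs mark
candidate chimera junctions), and bins placed pairs into contact matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    PAIR_COLUMNS,
    ContactMatrix,
    HiCMap,
    canonicalize_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RESTRICTION_ENZYMES",
    "digest",
    "digest_assembly",
    "ingest_pairs",
    "aggregate_links",
    "physical_coverage",
    "contact_matrix",
    "CoverageProfile",
]

#: Recognition sequences of supported restriction enzymes.  Fragment
#: boundaries are placed at site starts (cut offset 0).
RESTRICTION_ENZYMES = {
    "MboI": "GATC",
    "DpnII": "GATC",
    "Sau3AI": "GATC",
    "HindIII": "AAGCTT",
}


def digest(sequence: str, site: str = "GATC") -> pd.DataFrame:
    """Cut a sequence at every occurrence of a restriction site.

    Cut positions are the occurrence starts; fragments tile ``[0, L)`` and
    zero-length fragments (a site at position 0) are dropped.  Ambiguity
    codes never match.  Overlapping occurrences all cut (irrelevant for
    palindromic sites like GATC).

    Returns a fragment table (contig-less): columns start, end, index.
    """
    if not site:
        raise ValueError("recognition site must be non-empty")
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        return pd.DataFrame({"start": [], "end": [], "index": []}, dtype=np.int64)
    cuts = [0]
    i = seq.find(site)
    while i != -1:
        if i != 0:
            cuts.append(i)
        i = seq.find(site, i + 1)
    cuts.append(L)
    starts = np.asarray(cuts[:-1], dtype=np.int64)
    ends = np.asarray(cuts[1:], dtype=np.int64)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    return pd.DataFrame(
        {"start": starts, "end": ends, "index": np.arange(len(starts), dtype=np.int64)}
    )


def digest_assembly(sequences: dict[str, str], enzyme: str = "MboI") -> pd.DataFrame:
    """Digest every contig; returns the full fragment map (contig_id column added)."""
    try:
        site = RESTRICTION_ENZYMES[enzyme]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {enzyme!r}; known: {sorted(RESTRICTION_ENZYMES)}"
        ) from None
    parts = []
    for cid, seq in sequences.items():
        frags = digest(seq, site)
        frags.insert(0, "contig_id", cid)
        parts.append(frags)
    if not parts:
        return pd.DataFrame(columns=["contig_id", "start", "end", "index"])
    return pd.concat(parts, ignore_index=True)


def ingest_pairs(
    source, mapq_min: int = 10, drop_duplicates: bool = False
) -> pd.DataFrame:
    """Read a Hi-C pair table, keep pairs with min(mapq1, mapq2) >= mapq_min.

    ``source`` is a path to a tab-separated file with columns
    (contig1, pos1, mapq1, contig2, pos2, mapq2) and optional '#' header
    lines, or an already-parsed DataFrame with those columns.  Retained pairs
    are canonically ordered.  ``drop_duplicates`` removes exact duplicate
    rows after canonical ordering (off by default: the upstream mapping
    protocol may or may not already deduplicate).
    """
    if isinstance(source, pd.DataFrame):
        pairs = source[PAIR_COLUMNS].copy()
    else:
        pairs = _read_pair_file(Path(source))
    n_in = len(pairs)
    if n_in:
        mq = np.minimum(pairs["mapq1"].to_numpy(), pairs["mapq2"].to_numpy())
        pairs = pairs[mq >= mapq_min]
    pairs = canonicalize_pairs(pairs)
    if drop_duplicates:
        pairs = pairs.drop_duplicates(ignore_index=True)
    logger.info(
        "ingest_pairs: %d read, %d retained (mapq >= %d), %d discarded",
        n_in, len(pairs), mapq_min, n_in - len(pairs),
    )
    return pairs


def _read_pair_file(path: Path) -> pd.DataFrame:
    rows = {c: [] for c in PAIR_COLUMNS}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
            try:
                rows["contig1"].append(fields[0])
                rows["pos1"].append(int(fields[1]))
                rows["mapq1"].append(int(fields[2]))
                rows["contig2"].append(fields[3])
                rows["pos2"].append(int(fields[4]))
                rows["mapq2"].append(int(fields[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    out = pd.DataFrame(rows)
    for c in ("pos1", "mapq1", "pos2", "mapq2"):
        out[c] = out[c].astype(np.int64)
    return out


def aggregate_links(pairs: pd.DataFrame) -> pd.DataFrame:
    """Count Hi-C pairs per unordered contig pair (self-pairs included).

    Returns columns (contig1, contig2, n_links); the total of n_links equals
    the number of input pairs.  The ``weight`` column is added later by
    :func:`goldenpath.scaffolder.normalize_links`.
    """
    if len(pairs) == 0:
        return pd.DataFrame({"contig1": [], "contig2": [], "n_links": []})
    canon = canonicalize_pairs(pairs)
    links = (
        canon.groupby(["contig1", "contig2"], sort=True)
        .size()
        .rename("n_links")
        .reset_index()
    )
    return links


@dataclass
class CoverageProfile:
    """Per-window count of spanning Hi-C pairs along one contig."""

    contig_id: str
    window: int
    length: int
    values: np.ndarray

    def window_center(self, index: int) -> float:
        return min((index + 0.5) * self.window, self.length)


def physical_coverage(
    pairs: pd.DataFrame,
    contig_id: str,
    length: int,
    window: int = 1000,
    max_span: int = 1_000_000,
) -> CoverageProfile:
    """Physical Hi-C coverage: pairs whose interval overlaps each window.

    Only intra-contig pairs with span <= ``max_span`` contribute; a pair
    covers the half-open interval [min(pos), max(pos)).  Defaults (1 kb
    windows, 1 Mb span cap) keep chimera troughs sharp on multi-megabase
    contigs.
    """
    n_win = int(np.ceil(length / window)) if length else 0
    values = np.zeros(n_win, dtype=np.int64)
    intra = pairs[(pairs["contig1"] == contig_id) & (pairs["contig2"] == contig_id)]
    if len(intra):
        lo = np.minimum(intra["pos1"].to_numpy(), intra["pos2"].to_numpy())
        hi = np.maximum(intra["pos1"].to_numpy(), intra["pos2"].to_numpy())
        keep = (hi - lo) <= max_span
        lo, hi = lo[keep], hi[keep]
        keep2 = hi > lo  # zero-span pairs cover nothing
        lo, hi = lo[keep2], hi[keep2]
        # difference-array trick over window indices
        first = lo // window
        last = (hi - 1) // window  # last window overlapped by [lo, hi)
        diff = np.zeros(n_win + 1, dtype=np.int64)
        np.add.at(diff, first, 1)
        np.add.at(diff, last + 1, -1)
        values = np.cumsum(diff[:-1])
    return CoverageProfile(contig_id=contig_id, window=window, length=length, values=values)


def lift_positions(
    hic_map: HiCMap, contig_ids: np.ndarray, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lift contig coordinates onto pseudomolecule coordinates.

    Returns (chromosome array, global position array, placed mask).  A contig
    placed with orientation -1 maps position p to offset + length - 1 - p.
    """
    t = hic_map.table.set_index("contig_id")
    placed = np.asarray(pd.Index(contig_ids).isin(t.index))
    chrom = np.full(len(contig_ids), "", dtype=object)
    gpos = np.zeros(len(contig_ids), dtype=np.int64)
    if placed.any():
        sub = t.reindex(np.asarray(contig_ids, dtype=object)[placed])
        off = sub["offset"].to_numpy(dtype=np.int64)
        ori = sub["orientation"].to_numpy(dtype=np.int64)
        ln = sub["length"].to_numpy(dtype=np.int64)
        p = np.asarray(positions)[placed]
        gpos[placed] = np.where(ori == 1, off + p, off + ln - 1 - p)
        chrom[placed] = sub["chromosome"].to_numpy(dtype=object)
    return chrom, gpos, placed


def map_bins(hic_map: HiCMap, bin_size: int) -> pd.DataFrame:
    """Axis labels (chromosome, bin, start) for a contact matrix over a map."""
    rows = []
    for chrom in hic_map.chromosomes():
        clen = hic_map.chromosome_length(chrom)
        n_bins = max(1, int(np.ceil(clen / bin_size)))
        for b in range(n_bins):
            rows.append((chrom, b, b * bin_size))
    return pd.DataFrame(rows, columns=["chromosome", "bin", "start"])


def contact_matrix(
    hic_map: HiCMap, pairs: pd.DataFrame, bin_size: int = 1_000_000
) -> ContactMatrix:
    """Bin placed Hi-C pairs into a symmetric contact matrix.

    Pair ends are lifted through (offset, orientation); pairs with either end
    on an unplaced contig are skipped.  Each pair is counted once — the
    mirrored storage means the matrix total (upper triangle + diagonal)
    equals the number of contributing pairs.
    """
    bins = map_bins(hic_map, bin_size)
    n = len(bins)
    counts = np.zeros((n, n), dtype=np.int64)
    if len(pairs):
        ch1, g1, ok1 = lift_positions(
            hic_map, pairs["contig1"].to_numpy(dtype=object), pairs["pos1"].to_numpy()
        )
        ch2, g2, ok2 = lift_positions(
            hic_map, pairs["contig2"].to_numpy(dtype=object), pairs["pos2"].to_numpy()
        )
        ok = ok1 & ok2
        if ok.any():
            key = {
                (c, b): i
                for i, (c, b) in enumerate(zip(bins["chromosome"], bins["bin"]))
            }

            def flat(ch, gp):
                bi = gp // bin_size
                return np.array(
                    [key[(c, b)] for c, b in zip(ch, bi)], dtype=np.int64
                )

            i1 = flat(ch1[ok], g1[ok])
            i2 = flat(ch2[ok], g2[ok])
            lo = np.minimum(i1, i2)
            hi = np.maximum(i1, i2)
            np.add.at(counts, (lo, hi), 1)
            mirror = counts.T.copy()
            np.fill_diagonal(mirror, 0)
            counts = counts + mirror
    return ContactMatrix(bin_size=bin_size, bins=bins, counts=counts)
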