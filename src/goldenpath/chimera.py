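"""Chimeric-contig detection and breaking.

A chimera wrongly joins sequences that are far apart (often on different
chromosomes) in the true genome.  Two independent signals flag candidates:

* troughs in physical Hi-C coverage — almost no pair spans the false
  junction, so coverage drops far below the contig-wide average there;
* guide-map discordance — markers from more than one chromosome arranged in
  blocks along the contig.

Detection only proposes candidates; breaking requires an explicit breakpoint
list, so the decision stays with the curator.  Breaking updates the whole
assembly object: pair and marker positions are remapped into the new parts
and restriction fragments are re-cut at the break positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest_links import CoverageProfile, physical_coverage
from .model import AssemblyObject

logger = logging.getLogger(__name__)

__all__ = [
    "Breakpoint",
    "detect_coverage_drops",
    "detect_marker_discordance",
    "scan_assembly",
    "break_contigs",
]


@dataclass(frozen=True)
class Breakpoint:
    """A split position: contig becomes [0, position) and [position, length)."""

    contig_id: str
    position: int


def detect_coverage_drops(
    profile: CoverageProfile,
    min_ratio: float = 8.0,
    end_margin: int = 100_000,
    merge_within: int = 3,
) -> list[Breakpoint]:
    """Candidate breakpoints where coverage collapses in a contig's interior.

    Windows whose coverage is at least ``min_ratio``-fold below the contig-
    wide mean and whose centers lie at least ``end_margin`` from both contig
    ends are merged into runs (gaps of up to ``merge_within`` windows join);
    each run yields one candidate at its minimum-coverage window center.
    Contigs shorter than twice ``end_margin`` have no interior and return
    nothing.
    """
    L = profile.length
    if L < 2 * end_margin or len(profile.values) == 0:
        return []
    mean = float(profile.values.mean())
    if mean <= 0:
        return []
    centers = (np.arange(len(profile.values)) + 0.5) * profile.window
    low = (profile.values < mean / min_ratio) & (
        (centers >= end_margin) & (centers <= L - end_margin)
    )
    idx = np.flatnonzero(low)
    if len(idx) == 0:
        return []
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][-1] <= merge_within:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    out = []
    for run in runs:
        vals = profile.values[run]
        wmin = run[int(np.argmin(vals))]
        pos = int(min(centers[wmin], L - 1))
        out.append(Breakpoint(profile.contig_id, pos))
    out.sort(key=lambda b: b.position)
    return out


def detect_marker_discordance(
    alignments: pd.DataFrame, min_block: int = 3
) -> pd.DataFrame:
    """Flag contigs carrying marker blocks from more than one chromosome.

    Markers are scanned in contig-position order and compressed into runs of
    the same guide chromosome; a contig is flagged when it has at least two
    runs of ``min_block`` or more consecutive markers from different
    chromosomes.  Isolated stray markers (runs shorter than ``min_block``)
    never flag a contig.  Returns one row per flagged contig with the
    boundary interval between the first two qualifying blocks.
    """
    rows = []
    for cid, grp in alignments.groupby("contig_id", sort=True):
        grp = grp.sort_values("contig_pos")
        chroms = grp["guide_chr"].to_numpy(dtype=object)
        pos = grp["contig_pos"].to_numpy()
        blocks = []  # (chromosome, first marker idx, last marker idx)
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                if i - start >= min_block:
                    blocks.append((chroms[start], start, i - 1))
                start = i
        seen = {b[0] for b in blocks}
        if len(blocks) >= 2 and len(seen) >= 2:
            for b1, b2 in zip(blocks[:-1], blocks[1:]):
                if b1[0] != b2[0]:
                    rows.append(
                        {
                            "contig_id": cid,
                            "chromosomes": sorted(seen),
                            "boundary_start": int(pos[b1[2]]),
                            "boundary_end": int(pos[b2[1]]),
                        }
                    )
                    break
    return pd.DataFrame(
        rows, columns=["contig_id", "chromosomes", "boundary_start", "boundary_end"]
    )


def scan_assembly(
    assembly: AssemblyObject,
    window: int = 1000,
    max_span: int = 1_000_000,
    min_ratio: float = 8.0,
    end_margin: int = 100_000,
    min_length: int | None = None,
) -> list[Breakpoint]:
    """Run coverage-drop detection over every contig long enough to matter."""
    if min_length is None:
        min_length = 2 * end_margin
    out: list[Breakpoint] = []
    lengths = assembly.contig_lengths()
    for cid in sorted(lengths.index):
        L = int(lengths[cid])
        if L < min_length:
            continue
        prof = physical_coverage(assembly.pairs, cid, L, window=window, max_span=max_span)
        out.extend(
            detect_coverage_drops(prof, min_ratio=min_ratio, end_margin=end_margin)
        )
    return out


def break_contigs(
    assembly: AssemblyObject, breaks: list[Breakpoint] | list[tuple[str, int]]
) -> AssemblyObject:
    """Split contigs at breakpoints and remap every coordinate.

    Contig C broken at b1 < ... < bn becomes parts ``C.1 ... C.{n+1}``
    covering the obvious intervals; pair ends and marker alignments at
    position p move to the part containing p at p - part_start.  Fragments
    are re-cut at the break positions (not re-digested).  Pair count, marker
    count and total bp are conserved.
    """
    norm: list[Breakpoint] = [
        b if isinstance(b, Breakpoint) else Breakpoint(b[0], int(b[1])) for b in breaks
    ]
    lengths = assembly.contig_lengths()
    by_contig: dict[str, list[int]] = {}
    for b in norm:
        if b.contig_id not in lengths.index:
            raise KeyError(f"breakpoint on unknown contig {b.contig_id!r}")
        L = int(lengths[b.contig_id])
        if not (0 < b.position < L):
            raise ValueError(
                f"breakpoint {b.position} out of range (0, {L}) on {b.contig_id!r}"
            )
        lst = by_contig.setdefault(b.contig_id, [])
        if b.position in lst:
            raise ValueError(f"duplicate breakpoint {b.position} on {b.contig_id!r}")
        lst.append(b.position)

    # part lookup: contig -> (sorted cut array, part ids, part starts)
    parts: dict[str, tuple[np.ndarray, list[str], np.ndarray]] = {}
    cat_rows = []
    for cid in assembly.contigs["contig_id"]:
        L = int(lengths[cid])
        if cid in by_contig:
            cuts = np.array(sorted(by_contig[cid]), dtype=np.int64)
            bounds = np.concatenate(([0], cuts, [L]))
            ids = [f"{cid}.{k}" for k in range(1, len(bounds))]
            parts[cid] = (bounds, ids, bounds[:-1])
            for pid, lo, hi in zip(ids, bounds[:-1], bounds[1:]):
                cat_rows.append({"contig_id": pid, "length": int(hi - lo)})
        else:
            for_row = {"contig_id": cid, "length": L}
            cat_rows.append(for_row)
    contigs = pd.DataFrame(cat_rows)

    def remap(table: pd.DataFrame, id_col: str, pos_cols: list[str]) -> pd.DataFrame:
        if len(table) == 0:
            return table.copy()
        out = table.copy()
        for cid, (bounds, ids, starts) in parts.items():
            mask = (out[id_col] == cid).to_numpy()
            if not mask.any():
                continue
            for pos_col in pos_cols:
                p = out.loc[mask, pos_col].to_numpy(dtype=np.int64)
                k = np.searchsorted(bounds, p, side="right") - 1
                out.loc[mask, pos_col] = p - starts[k]
                out.loc[mask, id_col + "__new"] = np.asarray(ids, dtype=object)[k]
            out.loc[mask, id_col] = out.loc[mask, id_col + "__new"]
        drop = [c for c in out.columns if c.endswith("__new")]
        return out.drop(columns=drop)

    pairs = assembly.pairs.copy()
    for id_col, pos_col in (("contig1", "pos1"), ("contig2", "pos2")):
        pairs = remap(pairs, id_col, [pos_col])
    alignments = remap(assembly.alignments, "contig_id", ["contig_pos"])

    # fragments: re-cut at break positions
    frag_rows = []
    for cid, grp in assembly.fragments.groupby("contig_id", sort=False):
        grp = grp.sort_values("index")
        if cid not in parts:
            frag_rows.extend(grp.to_dict("records"))
            continue
        bounds, ids, starts = parts[cid]
        counters = {pid: 0 for pid in ids}
        for _, fr in grp.iterrows():
            lo, hi = int(fr["start"]), int(fr["end"])
            inner = [c for c in bounds[1:-1] if lo < c < hi]
            pieces = list(zip([lo] + inner, inner + [hi]))
            for a, b_ in pieces:
                k = int(np.searchsorted(bounds, a, side="right") - 1)
                pid = ids[k]
                frag_rows.append(
                    {
                        "contig_id": pid,
                        "start": a - int(starts[k]),
                        "end": b_ - int(starts[k]),
                        "index": counters[pid],
                    }
                )
                counters[pid] += 1
    fragments = pd.DataFrame(frag_rows, columns=["contig_id", "start", "end", "index"])

    sequences = None
    if assembly.sequences is not None:
        sequences = {}
        for cid, seq in assembly.sequences.items():
            if cid in parts:
                bounds, ids, _ = parts[cid]
                for pid, lo, hi in zip(ids, bounds[:-1], bounds[1:]):
                    sequences[pid] = seq[lo:hi]
            else:
                sequences[cid] = seq

    from .model import canonicalize_pairs

    updated = AssemblyObject(
        contigs=contigs,
        fragments=fragments,
        pairs=canonicalize_pairs(pairs),
        alignments=alignments.reset_index(drop=True),
        sequences=sequences,
    )
    updated.validate()
    logger.info(
        "broke %d contig(s) at %d breakpoint(s)", len(by_contig), len(norm)
    )
    return updated
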