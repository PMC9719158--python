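"""Spreadsheet-based map curation: the correct-map-inspect cycle.

The Hi-C map is exported as a plain TSV of ordered contigs that a curator can
edit in any spreadsheet program (flip an orientation sign, swap two rows'
ranks, move a contig to "unplaced"), then re-imported under strict
validation: misformatted rows raise errors naming the offending line rather
than being silently repaired, a guard against spreadsheet autocorrection
mangling sequence identifiers.  Contact matrices computed before and after an
edit are compared bin-by-bin, and a scalar "off-diagonal mass" per chromosome
summarizes how much link weight sits away from the diagonal — corrective
edits should reduce it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MAP_COLUMNS, AssemblyObject, ContactMatrix, HiCMap

logger = logging.getLogger(__name__)

__all__ = [
    "export_map_table",
    "import_map_table",
    "diff_contact_matrices",
    "off_diagonal_mass",
]

_EXPORT_COLUMNS = [
    "chromosome", "rank", "contig_id", "orientation",
    "length_bp", "n_markers", "guide_pos",
]
_ORIENT_TOKENS = {"+": 1, "-": -1, "1": 1, "-1": -1}


def export_map_table(
    hic_map: HiCMap, path, alignments: pd.DataFrame | None = None
) -> None:
    """Write the map as a curator-editable TSV.

    Columns: chromosome, rank, contig_id, orientation (+/-), length_bp,
    n_markers, guide_pos; placed rows sorted by (chromosome, rank), then a
    trailing section of unplaced contigs with chromosome "unplaced".
    """
    t = hic_map.table.sort_values(["chromosome", "rank"], kind="stable")
    n_markers = pd.Series(0, index=t["contig_id"], dtype=int)
    guide_pos = pd.Series(np.nan, index=t["contig_id"])
    if alignments is not None and len(alignments):
        cnt = alignments.groupby("contig_id").size()
        med = alignments.groupby("contig_id")["guide_pos"].median()
        n_markers = cnt.reindex(n_markers.index).fillna(0).astype(int)
        guide_pos = med.reindex(guide_pos.index)
    rows = pd.DataFrame(
        {
            "chromosome": t["chromosome"].to_numpy(),
            "rank": t["rank"].to_numpy(),
            "contig_id": t["contig_id"].to_numpy(),
            "orientation": np.where(t["orientation"].to_numpy() == 1, "+", "-"),
            "length_bp": t["length"].to_numpy(),
            "n_markers": n_markers.to_numpy(),
            "guide_pos": guide_pos.to_numpy(),
        }
    )
    unp = pd.DataFrame(
        {
            "chromosome": "unplaced",
            "rank": np.arange(1, len(hic_map.unplaced) + 1),
            "contig_id": hic_map.unplaced,
            "orientation": "+",
            "length_bp": -1,
            "n_markers": 0,
            "guide_pos": np.nan,
        }
    )
    out = pd.concat([rows, unp], ignore_index=True)[_EXPORT_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def import_map_table(path, assembly: AssemblyObject, gap: int = 100) -> HiCMap:
    """Read an edited map table back under strict validation.

    Every error names the offending line: unknown contig ids, duplicate
    contigs, orientation tokens outside {+, -, 1, -1}, and non-integer ranks
    all raise.  Ranks may have gaps (sort order decides); contigs present in
    the assembly but missing from the table become unplaced with a warning.
    """
    path = Path(path)
    lengths = assembly.contig_lengths()
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chromosome", "rank", "contig_id", "orientation"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    seen: dict[str, int] = {}
    placed_rows = []
    unplaced: list[str] = []
    for i, rec in raw.iterrows():
        line = i + 2  # header is line 1
        cid = rec["contig_id"]
        if not isinstance(cid, str) or cid == "":
            raise ValueError(f"{path}:{line}: empty contig id")
        if cid not in lengths.index:
            raise KeyError(f"{path}:{line}: unknown contig id {cid!r}")
        if cid in seen:
            raise ValueError(
                f"{path}:{line}: contig {cid!r} already listed on line {seen[cid]}"
            )
        seen[cid] = line
        chrom = rec["chromosome"]
        if chrom == "unplaced":
            unplaced.append(cid)
            continue
        tok = str(rec["orientation"]).strip()
        if tok not in _ORIENT_TOKENS:
            raise ValueError(f"{path}:{line}: bad orientation token {tok!r}")
        try:
            rank = int(str(rec["rank"]).strip())
        except ValueError:
            raise ValueError(f"{path}:{line}: non-integer rank {rec['rank']!r}") from None
        if rank < 1:
            raise ValueError(f"{path}:{line}: rank must be positive, got {rank}")
        placed_rows.append(
            {
                "chromosome": chrom, "rank": rank, "contig_id": cid,
                "orientation": _ORIENT_TOKENS[tok], "length": int(lengths[cid]),
                "line": line,
            }
        )

    placed = pd.DataFrame(
        placed_rows, columns=["chromosome", "rank", "contig_id", "orientation",
                              "length", "line"]
    )
    for chrom, grp in placed.groupby("chromosome", sort=False):
        dup = grp[grp["rank"].duplicated()]
        if len(dup):
            r = dup.iloc[0]
            raise ValueError(
                f"{path}:{r['line']}: duplicate rank {r['rank']} on {chrom}"
            )
    # renumber ranks consecutively per chromosome, keep sort order
    placed = placed.sort_values(["chromosome", "rank"], kind="stable")
    placed["rank"] = placed.groupby("chromosome", sort=False).cumcount() + 1
    placed = placed.drop(columns=["line"]).reset_index(drop=True)
    placed["offset"] = 0

    omitted = sorted(set(lengths.index) - set(seen))
    if omitted:
        logger.warning(
            "%d contig(s) absent from %s moved to unplaced: %s%s",
            len(omitted), path, ", ".join(omitted[:5]), "..." if len(omitted) > 5 else "",
        )
    hic_map = HiCMap(
        table=placed[MAP_COLUMNS], unplaced=sorted(set(unplaced) | set(omitted)), gap=gap
    ).recompute_offsets()
    hic_map.validate()
    return hic_map


def off_diagonal_mass(matrix: ContactMatrix) -> pd.Series:
    """Per-chromosome sum of counts weighted by |bin1 - bin2|.

    A scalar curation metric: misplaced or flipped contigs push link counts
    away from the diagonal, so corrective edits reduce this mass.  Counts
    between different chromosomes are excluded.
    """
    out = {}
    for chrom in dict.fromkeys(matrix.bins["chromosome"]):
        sl = matrix.chromosome_slice(chrom)
        sub = matrix.counts[sl, sl]
        n = sub.shape[0]
        i, j = np.triu_indices(n)
        out[chrom] = float((sub[i, j] * np.abs(i - j)).sum())
    return pd.Series(out, name="off_diagonal_mass")


def diff_contact_matrices(
    before: ContactMatrix, after: ContactMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare two contact matrices over the same binning.

    Returns (changed-bin table, per-chromosome summary).  The changed-bin
    table lists upper-triangle cells whose counts differ; the summary gives
    before/after off-diagonal mass per chromosome.
    """
    if before.bin_size != after.bin_size:
        raise ValueError("contact matrices have different bin sizes")
    if not before.bins[["chromosome", "bin"]].equals(after.bins[["chromosome", "bin"]]):
        raise ValueError("contact matrices have incompatible axes")
    delta = after.counts - before.counts
    i, j = np.nonzero(np.triu(delta))
    bins = before.bins
    changed = pd.DataFrame(
        {
            "chromosome1": bins["chromosome"].to_numpy()[i],
            "bin1": bins["bin"].to_numpy()[i],
            "chromosome2": bins["chromosome"].to_numpy()[j],
            "bin2": bins["bin"].to_numpy()[j],
            "before": before.counts[i, j],
            "after": after.counts[i, j],
            "delta": delta[i, j],
        }
    )
    summary = pd.DataFrame(
        {
            "before": off_diagonal_mass(before),
            "after": off_diagonal_mass(after),
        }
    )
    summary["delta"] = summary["after"] - summary["before"]
    return changed, summary
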