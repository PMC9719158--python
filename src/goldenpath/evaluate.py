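"""Downsampling experiments and map-quality metrics.

How much Hi-C and how dense a guide map does a chromosome-scale map need?
These routines thin the link table or the marker set by a random fraction,
rebuild the map without curation, and report the Pearson correlation between
contig positions in the thinned and the reference map — the package's
quantitative analog of assessing contact matrices by eye.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .model import AssemblyObject, HiCMap

logger = logging.getLogger(__name__)

__all__ = [
    "downsample_links",
    "downsample_markers",
    "map_correlation",
    "collinearity_points",
    "run_downsampling_experiment",
]


def _thin(table: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1:
        return table.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(table)) < fraction
    return table[keep].reset_index(drop=True)


def downsample_links(pairs: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Retain each Hi-C pair independently with probability ``fraction``."""
    return _thin(pairs, fraction, seed)


def downsample_markers(markers: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Retain each guide marker independently with probability ``fraction``."""
    return _thin(markers, fraction, seed)


def map_correlation(
    map_a: HiCMap, map_b: HiCMap, per_chromosome: bool = True
) -> pd.DataFrame:
    """Pearson r between contig midpoint positions in two maps.

    Computed per chromosome of ``map_a`` over the contigs both maps place on
    that chromosome; contigs the maps put on *different* chromosomes are
    excluded from r and reported in ``n_mismatched``.  Chromosomes sharing
    fewer than two contigs get r = NaN (reported, not raised).  Columns:
    chromosome, r, r2, n, n_mismatched.
    """
    a = map_a.midpoints().set_index("contig_id")
    b = map_b.midpoints().set_index("contig_id")
    shared = a.index.intersection(b.index)
    rows = []
    for chrom in map_a.chromosomes():
        ca = a.loc[a["chromosome"] == chrom]
        ids = ca.index.intersection(shared)
        same = [i for i in ids if b.at[i, "chromosome"] == chrom]
        mismatched = len(ids) - len(same)
        if len(same) >= 2:
            x = ca.loc[same, "midpoint"].to_numpy(dtype=float)
            y = b.loc[same, "midpoint"].to_numpy(dtype=float)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r = float(stats.pearsonr(x, y).statistic)
            else:
                r = np.nan
        else:
            r = np.nan
        rows.append(
            {
                "chromosome": chrom, "r": r, "r2": r * r if not np.isnan(r) else np.nan,
                "n": len(same), "n_mismatched": mismatched,
            }
        )
    out = pd.DataFrame(rows, columns=["chromosome", "r", "r2", "n", "n_mismatched"])
    if not per_chromosome:
        return out.agg({"r": "median", "r2": "median", "n": "sum", "n_mismatched": "sum"})
    return out


def placement_accuracy(hic_map: HiCMap, truth) -> dict:
    """Score a map against simulator ground truth.

    Returns: ``bp_on_true_chromosome`` — fraction of total assembly bp whose
    true home is the chromosome it was placed on (unplaced contigs score 0);
    ``orientation_accuracy`` and ``orientation_n`` — agreement of placed
    orientations with the truth strand, over contigs with an unambiguous
    dominant home.
    """
    seg = truth.segments.assign(bp=lambda s: s["genome_end"] - s["genome_start"])
    total_bp = int(seg["bp"].sum())
    per = seg.groupby(["contig_id", "chromosome"])["bp"].sum()
    placed = hic_map.table.set_index("contig_id")
    ok_bp = 0
    for cid, row in placed.iterrows():
        ok_bp += int(per.get((cid, row["chromosome"]), 0))
    homes = truth.dominant_homes().set_index("contig_id")
    n_ok = n_tot = 0
    for cid, row in placed.iterrows():
        if cid in homes.index and homes.at[cid, "chromosome"] is not None:
            n_tot += 1
            if int(row["orientation"]) == int(homes.at[cid, "strand"]):
                n_ok += 1
    return {
        "bp_on_true_chromosome": ok_bp / total_bp if total_bp else np.nan,
        "orientation_accuracy": n_ok / n_tot if n_tot else np.nan,
        "orientation_n": n_tot,
    }


def collinearity_points(hic_map: HiCMap, alignments: pd.DataFrame) -> pd.DataFrame:
    """Dot-plot table: pseudomolecule position vs guide position per marker.

    One row per marker on a placed contig; the standard visual check of a
    compiled map against its guide map (monotone diagonals per chromosome,
    locally reversed segments for flipped contigs).
    """
    from .digest_links import lift_positions

    if len(alignments) == 0:
        return pd.DataFrame(
            columns=["marker_id", "chromosome", "pseudo_pos", "guide_chr", "guide_pos"]
        )
    chrom, gpos, placed = lift_positions(
        hic_map,
        alignments["contig_id"].to_numpy(dtype=object),
        alignments["contig_pos"].to_numpy(),
    )
    sub = alignments[placed]
    return pd.DataFrame(
        {
            "marker_id": sub["marker_id"].to_numpy(),
            "chromosome": chrom[placed],
            "pseudo_pos": gpos[placed],
            "guide_chr": sub["guide_chr"].to_numpy(),
            "guide_pos": sub["guide_pos"].to_numpy(),
        }
    )


def run_downsampling_experiment(
    assembly: AssemblyObject,
    baseline: HiCMap,
    fractions,
    n_reps: int = 30,
    seed: int = 0,
    thin: str = "links",
    scaffold_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Thin links or markers, rebuild the map without curation, correlate.

    For every fraction x replicate: draw a thinned table with a sub-seed,
    rebuild the Hi-C map from scratch, and record the per-chromosome Pearson
    r against ``baseline``.  Output rows: fraction, rep, chromosome, r, r2,
    n, n_mismatched, n_links, n_markers.  Deterministic given ``seed``.
    """
    from .scaffolder import scaffold_assembly

    if thin not in ("links", "markers"):
        raise ValueError(f"thin must be 'links' or 'markers', got {thin!r}")
    kwargs = scaffold_kwargs or {}
    rows = []
    for fi, fraction in enumerate(fractions):
        for rep in range(n_reps):
            sub_seed = (seed * 100_003 + fi * 1_009 + rep) % (2**31)
            if thin == "links":
                pairs = downsample_links(assembly.pairs, fraction, seed=sub_seed)
                alignments = assembly.alignments
            else:
                pairs = assembly.pairs
                alignments = downsample_markers(
                    assembly.alignments, fraction, seed=sub_seed
                )
            trial = AssemblyObject(
                contigs=assembly.contigs,
                fragments=assembly.fragments,
                pairs=pairs,
                alignments=alignments,
                sequences=assembly.sequences,
            )
            hic_map = scaffold_assembly(trial, **kwargs)
            corr = map_correlation(baseline, hic_map)
            for _, c in corr.iterrows():
                rows.append(
                    {
                        "fraction": fraction, "rep": rep,
                        "chromosome": c["chromosome"], "r": c["r"], "r2": c["r2"],
                        "n": c["n"], "n_mismatched": c["n_mismatched"],
                        "n_links": len(pairs), "n_markers": len(alignments),
                    }
                )
        logger.info("downsampling %s fraction %g done (%d reps)", thin, fraction, n_reps)
    return pd.DataFrame(rows)
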