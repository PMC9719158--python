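"""Compile a curated Hi-C map into AGP and pseudomolecule FASTA.

The AGP ("a golden path") file records, in 1-based inclusive coordinates, how
pseudomolecule spans map onto contigs (W components) and gaps (U components,
100 bp of unknown size by NCBI convention).  Pseudomolecule sequences are the
oriented contig sequences joined by N-runs; unplaced contigs go to a separate
multi-FASTA with one record each (never a concatenated "chrUn", which INSDC
archives refuse).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import HiCMap

__all__ = [
    "compile_agp",
    "write_agp",
    "read_agp",
    "write_pseudomolecules",
    "extract_by_agp",
    "assembly_stats",
    "read_fasta",
    "write_fasta",
]

AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "component_id", "component_beg", "component_end", "orientation",
]


def compile_agp(
    hic_map: HiCMap, gap_length: int = 100, chrom_prefix: str = "chr"
) -> pd.DataFrame:
    """AGP v2.1 rows for every chromosome of a map.

    W rows place each contig full-span in rank order; U rows of
    ``gap_length`` (gap_type "scaffold", linkage "yes", evidence
    "proximity_ligation") separate consecutive contigs; no trailing gap.
    Object names are ``chrom_prefix`` + the guide-map chromosome label
    (labels already starting with the prefix are not doubled).
    """
    rows = []
    chroms = hic_map.chromosomes()
    if not chroms:
        raise ValueError("map has no placed chromosomes")
    for chrom in chroms:
        grp = hic_map.table[hic_map.table["chromosome"] == chrom].sort_values("rank")
        if len(grp) == 0:
            raise ValueError(f"chromosome {chrom} has no contigs")
        label = str(chrom)
        obj = label if label.startswith(chrom_prefix) else chrom_prefix + label
        pos = 0  # 0-based cursor
        part = 0
        for k, (_, r) in enumerate(grp.iterrows()):
            if k > 0:
                part += 1
                rows.append(
                    {
                        "object": obj,
                        "object_beg": pos + 1,
                        "object_end": pos + gap_length,
                        "part_number": part,
                        "component_type": "U",
                        "component_id": str(gap_length),
                        "component_beg": "scaffold",
                        "component_end": "yes",
                        "orientation": "proximity_ligation",
                    }
                )
                pos += gap_length
            L = int(r["length"])
            part += 1
            rows.append(
                {
                    "object": obj,
                    "object_beg": pos + 1,
                    "object_end": pos + L,
                    "part_number": part,
                    "component_type": "W",
                    "component_id": str(r["contig_id"]),
                    "component_beg": 1,
                    "component_end": L,
                    "orientation": "+" if r["orientation"] == 1 else "-",
                }
            )
            pos += L
    return pd.DataFrame(rows, columns=AGP_COLUMNS)


def write_agp(agp: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            rows.append(dict(zip(AGP_COLUMNS, fields)))
    agp = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for c in ("object_beg", "object_end", "part_number"):
        agp[c] = agp[c].astype(np.int64)
    return agp


def _build_objects(agp: pd.DataFrame, sequences: dict[str, str]) -> dict[str, str]:
    objects: dict[str, list[str]] = {}
    for _, r in agp.iterrows():
        parts = objects.setdefault(r["object"], [])
        span = int(r["object_end"]) - int(r["object_beg"]) + 1
        if r["component_type"] == "U":
            parts.append("N" * span)
        elif r["component_type"] == "W":
            cid = r["component_id"]
            if cid not in sequences:
                raise KeyError(f"AGP component {cid!r} missing from contig FASTA")
            beg, end = int(r["component_beg"]), int(r["component_end"])
            seg = sequences[cid][beg - 1 : end]
            if len(seg) != span:
                raise ValueError(
                    f"AGP span mismatch for {cid!r}: object span {span}, "
                    f"component span {len(seg)}"
                )
            if r["orientation"] == "-":
                seg = str(Seq(seg).reverse_complement())
            parts.append(seg)
        else:
            raise ValueError(f"unsupported component type {r['component_type']!r}")
    return {obj: "".join(parts) for obj, parts in objects.items()}


def write_pseudomolecules(
    agp: pd.DataFrame,
    sequences: dict[str, str],
    pseudo_path,
    unplaced_path,
    unplaced: list[str] | None = None,
) -> dict[str, str]:
    """Write pseudomolecule FASTA from AGP + contig sequences, plus unplaced.

    Minus-oriented components are reverse-complemented; U gaps become runs of
    N.  ``unplaced`` defaults to every contig not referenced by the AGP; each
    is written as its own record.  Returns the pseudomolecule sequences.
    """
    objects = _build_objects(agp, sequences)
    write_fasta(objects, pseudo_path)
    used = set(agp.loc[agp["component_type"] == "W", "component_id"])
    if unplaced is None:
        unplaced = sorted(set(sequences) - used)
    write_fasta({cid: sequences[cid] for cid in unplaced}, unplaced_path)
    return objects


def extract_by_agp(agp: pd.DataFrame, pseudomolecules: dict[str, str]) -> dict[str, str]:
    """Recover contig sequences from pseudomolecules through the AGP.

    The inverse of :func:`write_pseudomolecules` for W components; used to
    verify the compilation round trip is bit-exact.
    """
    out = {}
    for _, r in agp.iterrows():
        if r["component_type"] != "W":
            continue
        seg = pseudomolecules[r["object"]][int(r["object_beg"]) - 1 : int(r["object_end"])]
        if r["orientation"] == "-":
            seg = str(Seq(seg).reverse_complement())
        out[r["component_id"]] = seg
    return out


def assembly_stats(lengths) -> dict:
    """Contig-length summary: count, total, N50, N90, mean, max, min.

    N50 is the smallest length L such that contigs of length >= L sum to at
    least half the total (N90 analogously at 90%).
    """
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if len(arr) == 0:
        raise ValueError("assembly_stats requires at least one contig")
    total = int(arr.sum())
    cum = np.cumsum(arr)

    def n_stat(frac: float) -> int:
        return int(arr[np.searchsorted(cum, frac * total)])

    return {
        "count": int(len(arr)),
        "total": total,
        "N50": n_stat(0.5),
        "N90": n_stat(0.9),
        "mean": float(total / len(arr)),
        "max": int(arr[0]),
        "min": int(arr[-1]),
    }


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
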