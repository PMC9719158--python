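"""Domain types and the central assembly-state container.

The package operates on four tables held in an :class:`AssemblyObject`:

* a contig catalog (``contig_id``, ``length``) with optional sequences,
* a restriction-fragment map tiling each contig,
* a Hi-C read-pair table (mapped positions, not reads),
* a guide-map marker alignment table.

All internal coordinates are 0-based, half-open.  AGP output is 1-based
inclusive (the AGP standard) and PAF input is 0-based half-open; conversion
happens only at the file-format edges.

Contig identifiers are treated as opaque strings: no case folding, no
whitespace stripping beyond field splitting, and no "autocorrection" of the
kind spreadsheet programs apply to gene-like names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssemblyObject",
    "HiCMap",
    "ContactMatrix",
    "UNASSIGNED",
    "new_assembly",
    "canonicalize_pairs",
    "CONTIG_COLUMNS",
    "FRAGMENT_COLUMNS",
    "PAIR_COLUMNS",
    "ALIGNMENT_COLUMNS",
    "ASSIGNMENT_COLUMNS",
    "MAP_COLUMNS",
]

#: Sentinel chromosome label for contigs that could not be assigned.
UNASSIGNED = "UNASSIGNED"

CONTIG_COLUMNS = ["contig_id", "length"]
FRAGMENT_COLUMNS = ["contig_id", "start", "end", "index"]
PAIR_COLUMNS = ["contig1", "pos1", "mapq1", "contig2", "pos2", "mapq2"]
ALIGNMENT_COLUMNS = [
    "marker_id",
    "guide_chr",
    "guide_pos",
    "contig_id",
    "contig_pos",
    "aligned_len",
    "identity",
    "orientation",
]
ASSIGNMENT_COLUMNS = [
    "contig_id",
    "chromosome",
    "support",
    "purity",
    "guide_pos",
    "chimera_flag",
]
MAP_COLUMNS = ["chromosome", "rank", "contig_id", "orientation", "length", "offset"]

_MANIFEST_VERSION = 1


class ReferenceError_(KeyError):
    """An operation referenced a contig id absent from the catalog."""


class BoundsError(ValueError):
    """A coordinate fell outside the referenced contig."""


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair so that (contig1, pos1) <= (contig2, pos2) lexicographically."""
    if len(pairs) == 0:
        return pairs.reset_index(drop=True)
    c1 = pairs["contig1"].to_numpy(dtype=object)
    c2 = pairs["contig2"].to_numpy(dtype=object)
    p1 = pairs["pos1"].to_numpy()
    p2 = pairs["pos2"].to_numpy()
    swap = (c1 > c2) | ((c1 == c2) & (p1 > p2))
    out = pairs.copy()
    for a, b in (("contig1", "contig2"), ("pos1", "pos2"), ("mapq1", "mapq2")):
        va = pairs[a].to_numpy()
        vb = pairs[b].to_numpy()
        out[a] = np.where(swap, vb, va)
        out[b] = np.where(swap, va, vb)
    return out.reset_index(drop=True)


@dataclass
class AssemblyObject:
    """Central mutable state: contig catalog plus Hi-C and guide-map tables.

    Chimera breaking (:func:`goldenpath.chimera.break_contigs`) replaces all
    four tables in a coordinated update; everything else only reads them.
    """

    contigs: pd.DataFrame
    fragments: pd.DataFrame
    pairs: pd.DataFrame
    alignments: pd.DataFrame
    sequences: dict[str, str] | None = None

    # -- validation ---------------------------------------------------------

    def contig_lengths(self) -> pd.Series:
        return self.contigs.set_index("contig_id")["length"]

    def validate(self) -> None:
        """Re-check all construction invariants; raises on the first violation."""
        cat = self.contigs
        if cat["contig_id"].duplicated().any():
            dup = cat.loc[cat["contig_id"].duplicated(), "contig_id"].iloc[0]
            raise ValueError(f"duplicate contig id in catalog: {dup!r}")
        if len(cat) and (cat["length"].to_numpy() < 1).any():
            raise ValueError("contig lengths must be >= 1")
        lengths = self.contig_lengths()
        if self.sequences is not None:
            for cid, seq in self.sequences.items():
                if cid not in lengths.index:
                    raise ReferenceError_(f"sequence for unknown contig {cid!r}")
                if len(seq) != lengths[cid]:
                    raise ValueError(
                        f"sequence length {len(seq)} != catalog length "
                        f"{lengths[cid]} for contig {cid!r}"
                    )
        self._check_fragments(lengths)
        self._check_positions(self.pairs, "contig1", "pos1", lengths, "pair")
        self._check_positions(self.pairs, "contig2", "pos2", lengths, "pair")
        self._check_positions(
            self.alignments, "contig_id", "contig_pos", lengths, "marker alignment"
        )

    def _check_fragments(self, lengths: pd.Series) -> None:
        frags = self.fragments
        if len(frags) == 0:
            return
        unknown = set(frags["contig_id"]) - set(lengths.index)
        if unknown:
            raise ReferenceError_(f"fragments reference unknown contig {sorted(unknown)[0]!r}")
        for cid, grp in frags.groupby("contig_id", sort=False):
            grp = grp.sort_values("index")
            if not (grp["index"].to_numpy() == np.arange(len(grp))).all():
                raise ValueError(f"fragment indices of {cid!r} not consecutive from 0")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != lengths[cid]:
                raise ValueError(f"fragments of {cid!r} do not tile [0, length)")
            if len(grp) > 1 and not (ends[:-1] == starts[1:]).all():
                raise ValueError(f"fragments of {cid!r} have gaps or overlaps")
            if (ends <= starts).any():
                raise ValueError(f"zero- or negative-length fragment on {cid!r}")

    @staticmethod
    def _check_positions(
        table: pd.DataFrame, id_col: str, pos_col: str, lengths: pd.Series, what: str
    ) -> None:
        if len(table) == 0:
            return
        ids = table[id_col]
        unknown = set(ids) - set(lengths.index)
        if unknown:
            raise ReferenceError_(f"{what} references unknown contig {sorted(unknown)[0]!r}")
        lens = lengths.reindex(ids).to_numpy()
        pos = table[pos_col].to_numpy()
        bad = (pos < 0) | (pos >= lens)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            row = table.iloc[i]
            raise BoundsError(
                f"{what} position out of bounds: {dict(row[[id_col, pos_col]])} "
                f"(contig length {lens[i]})"
            )

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Persist as a directory of TSV tables plus a JSON manifest."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tables = {
            "contigs": self.contigs,
            "fragments": self.fragments,
            "pairs": self.pairs,
            "alignments": self.alignments,
        }
        for name, tbl in tables.items():
            tbl.to_csv(d / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "format": "goldenpath-assembly",
            "version": _MANIFEST_VERSION,
            "tables": {name: f"{name}.tsv" for name in tables},
            "has_sequences": self.sequences is not None,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if self.sequences is not None:
            from .pseudomolecule import write_fasta

            write_fasta(self.sequences, d / "contigs.fasta")

    @classmethod
    def load(cls, directory) -> "AssemblyObject":
        from pathlib import Path

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest.get("format") != "goldenpath-assembly":
            raise ValueError(f"{d}: not an assembly directory")

        def read(name: str, columns: list[str], dtypes: dict) -> pd.DataFrame:
            tbl = pd.read_csv(d / manifest["tables"][name], sep="\t", dtype=dtypes)
            return tbl if len(tbl) else _empty(columns)

        str_ = {"contig_id": str, "contig1": str, "contig2": str, "marker_id": str,
                "guide_chr": str}
        contigs = read("contigs", CONTIG_COLUMNS, str_)
        fragments = read("fragments", FRAGMENT_COLUMNS, str_)
        pairs = read("pairs", PAIR_COLUMNS, str_)
        alignments = read("alignments", ALIGNMENT_COLUMNS, str_)
        sequences = None
        if manifest.get("has_sequences"):
            from .pseudomolecule import read_fasta

            sequences = read_fasta(d / "contigs.fasta")
        return cls(contigs, fragments, pairs, alignments, sequences)


def new_assembly(
    contigs: pd.DataFrame,
    fragments: pd.DataFrame | None = None,
    pairs: pd.DataFrame | None = None,
    alignments: pd.DataFrame | None = None,
    sequences: dict[str, str] | None = None,
) -> AssemblyObject:
    """Initiate an assembly object from its component tables.

    Pairs are canonically ordered on ingestion.  All referenced contig ids
    must exist in the catalog and all coordinates must be in bounds.
    """
    obj = AssemblyObject(
        contigs=contigs.reset_index(drop=True),
        fragments=(fragments if fragments is not None else _empty(FRAGMENT_COLUMNS)),
        pairs=canonicalize_pairs(pairs if pairs is not None else _empty(PAIR_COLUMNS)),
        alignments=(alignments if alignments is not None else _empty(ALIGNMENT_COLUMNS)),
        sequences=sequences,
    )
    obj.validate()
    return obj


@dataclass
class HiCMap:
    """Per-chromosome ordered, oriented, offset contig layout.

    ``table`` columns: chromosome, rank (1-based, consecutive per chromosome),
    contig_id, orientation (+1/-1), length, offset (pseudomolecule start, bp).
    ``unplaced`` lists contigs not assigned to any chromosome.
    """

    table: pd.DataFrame
    unplaced: list[str] = field(default_factory=list)
    gap: int = 100

    def validate(self) -> None:
        t = self.table
        if t["contig_id"].duplicated().any():
            dup = t.loc[t["contig_id"].duplicated(), "contig_id"].iloc[0]
            raise ValueError(f"contig {dup!r} placed more than once")
        placed = set(t["contig_id"])
        twice = placed & set(self.unplaced)
        if twice:
            raise ValueError(f"contig {sorted(twice)[0]!r} both placed and unplaced")
        for chrom, grp in t.groupby("chromosome", sort=False):
            grp = grp.sort_values("rank")
            if not (grp["rank"].to_numpy() == np.arange(1, len(grp) + 1)).all():
                raise ValueError(f"ranks on {chrom} not consecutive from 1")
            off = grp["offset"].to_numpy()
            if len(off) > 1 and not (np.diff(off) > 0).all():
                raise ValueError(f"offsets on {chrom} not strictly increasing")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome_length(self, chromosome: str) -> int:
        grp = self.table[self.table["chromosome"] == chromosome]
        if len(grp) == 0:
            return 0
        last = grp.loc[grp["rank"].idxmax()]
        return int(last["offset"] + last["length"])

    def recompute_offsets(self) -> "HiCMap":
        """Recompute offsets from ranks and lengths with the map's gap size."""
        t = self.table.sort_values(["chromosome", "rank"], kind="stable").reset_index(drop=True)
        offsets = np.zeros(len(t), dtype=np.int64)
        for _, idx in t.groupby("chromosome", sort=False).groups.items():
            pos = 0
            for i in idx:
                offsets[i] = pos
                pos += int(t.at[i, "length"]) + self.gap
        t["offset"] = offsets
        return HiCMap(table=t, unplaced=list(self.unplaced), gap=self.gap)

    def locate(self, chromosome: str, position: int) -> str | None:
        """Name the contig under a pseudomolecule coordinate (gap -> None)."""
        grp = self.table[self.table["chromosome"] == chromosome]
        for _, row in grp.iterrows():
            if row["offset"] <= position < row["offset"] + row["length"]:
                return str(row["contig_id"])
        return None

    def midpoints(self) -> pd.DataFrame:
        """Per placed contig: chromosome and pseudomolecule midpoint coordinate."""
        t = self.table
        return pd.DataFrame(
            {
                "contig_id": t["contig_id"],
                "chromosome": t["chromosome"],
                "midpoint": t["offset"].to_numpy() + t["length"].to_numpy() / 2.0,
            }
        )


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C link-count matrix over a HiCMap's coordinate system.

    ``bins``: one row per (chromosome, bin) axis label, with the global matrix
    row index.  ``counts``: dense symmetric matrix; each pair is counted once
    (symmetry is a storage convention, so off-diagonal cells appear mirrored
    but the upper triangle plus diagonal sums to the number of pairs).
    """

    bin_size: int
    bins: pd.DataFrame  # columns: chromosome, bin, start
    counts: np.ndarray

    def n_pairs(self) -> int:
        return int(np.triu(self.counts).sum())

    def chromosome_slice(self, chromosome: str) -> slice:
        idx = np.flatnonzero((self.bins["chromosome"] == chromosome).to_numpy())
        if len(idx) == 0:
            raise KeyError(chromosome)
        return slice(int(idx[0]), int(idx[-1]) + 1)
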