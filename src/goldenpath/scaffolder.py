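"""Order and orient chromosome-assigned contigs with normalized Hi-C links.

The guide map constrains chromosome membership and global orientation; the
local contig order within a chromosome comes from Hi-C alone.  The ordering
heuristic builds a minimum spanning tree on the graph of normalized link
densities (edge cost -log weight), takes the tree's diameter path as the
backbone, and greedily inserts the remaining contigs next to their tree
attachment point on whichever side maximizes the summed link weight to the
new neighbors.  Contigs without usable links fall back to their guide-map
position.  Finally the whole order is reversed if needed so ranks correlate
positively with guide positions (Spearman), which anchors each pseudomolecule
to the guide map's chromosomal orientation.

All tie-breaks are lexicographic on contig id: output is deterministic for a
fixed input.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model import MAP_COLUMNS, UNASSIGNED, AssemblyObject, HiCMap

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_links",
    "order_chromosome",
    "orient_contigs",
    "build_hic_map",
    "scaffold_assembly",
    "adjacency_objective",
]


def normalize_links(
    links: pd.DataFrame, fragment_counts: pd.Series, method: str = "fragments",
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Set link weights: n_links / (f_i * f_j), self-links excluded.

    ``f`` is the contig's restriction-fragment count (``method="fragments"``,
    a proxy for mappable restriction-site density) or its length in Mb
    (``method="length"``).  Every linked contig must have f >= 1.
    """
    out = links[links["contig1"] != links["contig2"]].reset_index(drop=True)
    if len(out) == 0:
        out["weight"] = pd.Series(dtype=float)
        return out
    if method == "fragments":
        f = fragment_counts
    elif method == "length":
        if lengths is None:
            raise ValueError("length normalization requires contig lengths")
        f = lengths / 1e6
    else:
        raise ValueError(f"unknown normalization {method!r}")
    f1 = f.reindex(out["contig1"]).to_numpy(dtype=float)
    f2 = f.reindex(out["contig2"]).to_numpy(dtype=float)
    if np.isnan(f1).any() or np.isnan(f2).any() or (f1 <= 0).any() or (f2 <= 0).any():
        bad = pd.concat([out["contig1"][np.isnan(f1) | (f1 <= 0)],
                         out["contig2"][np.isnan(f2) | (f2 <= 0)]])
        raise ValueError(f"contig without fragments in link table: {sorted(set(bad))[:3]}")
    out["weight"] = out["n_links"].to_numpy(dtype=float) / (f1 * f2)
    return out


def adjacency_objective(order: list[str], weights: pd.DataFrame) -> float:
    """Sum of link weights between adjacent contigs of an order."""
    w = _weight_lookup(weights)
    return float(
        sum(w.get(_key(a, b), 0.0) for a, b in zip(order[:-1], order[1:]))
    )


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _weight_lookup(weights: pd.DataFrame) -> dict:
    return {
        _key(r.contig1, r.contig2): float(r.weight)
        for r in weights.itertuples()
        if r.contig1 != r.contig2
    }


def order_chromosome(
    assignments: pd.DataFrame, weights: pd.DataFrame, chromosome: str
) -> list[str]:
    """Order the contigs assigned to one chromosome (see module docstring)."""
    sub = assignments[assignments["chromosome"] == chromosome]
    members = sorted(sub["contig_id"])
    if len(members) <= 1:
        return members
    guide_pos = sub.set_index("contig_id")["guide_pos"].to_dict()
    member_set = set(members)
    w = {
        k: v
        for k, v in _weight_lookup(weights).items()
        if k[0] in member_set and k[1] in member_set
    }

    G = nx.Graph()
    G.add_nodes_from(members)
    for (a, b), wt in sorted(w.items()):
        G.add_edge(a, b, weight=wt, cost=-np.log(wt))
    T = nx.minimum_spanning_tree(G, weight="cost", algorithm="kruskal")

    components = sorted(
        (c for c in nx.connected_components(T)),
        key=lambda c: (-len(c), min(c)),
    )
    main = components[0]
    if len(main) == 1:
        order: list[str] = [min(main)]
    else:
        Tm = T.subgraph(main)
        order = _diameter_path(Tm, w)
        order = _insert_branches(Tm, order, w)

    # remaining components and isolated contigs: guide-position fallback
    rest = [c for comp in components[1:] for c in sorted(comp)]
    for cid in rest:
        _insert_by_guide(order, cid, guide_pos)

    order = _align_to_guide(order, guide_pos)
    return order


def _diameter_path(T: nx.Graph, w: dict) -> list[str]:
    """Maximum-cardinality path in the tree; ties by summed weight, then ids."""
    best = None
    nodes = sorted(T.nodes)
    sp = dict(nx.all_pairs_shortest_path(T))
    for u in nodes:
        for v in nodes:
            if v <= u:
                continue
            path = sp[u][v]
            total = sum(w.get(_key(a, b), 0.0) for a, b in zip(path[:-1], path[1:]))
            key = (len(path), total)
            if best is None or key > best[0]:
                cand = path if path[0] <= path[-1] else path[::-1]
                best = (key, cand)
    return list(best[1])


def _insert_branches(T: nx.Graph, backbone: list[str], w: dict) -> list[str]:
    """Insert off-backbone tree nodes next to their attachment, best side."""
    order = list(backbone)
    placed = set(order)
    # BFS out from the backbone so a node's tree parent is placed first
    frontier = list(backbone)
    parent: dict[str, str] = {}
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(T.neighbors(u)):
                if v not in placed and v not in parent:
                    parent[v] = u
                    nxt.append(v)
        for v in nxt:
            i = order.index(parent[v])
            left = order[i - 1] if i > 0 else None
            right = order[i + 1] if i + 1 < len(order) else None
            score_before = w.get(_key(v, parent[v]), 0.0) + (
                w.get(_key(v, left), 0.0) if left else 0.0
            )
            score_after = w.get(_key(v, parent[v]), 0.0) + (
                w.get(_key(v, right), 0.0) if right else 0.0
            )
            if score_after > score_before:
                order.insert(i + 1, v)
            else:
                order.insert(i, v)
            placed.add(v)
        frontier = nxt
    return order


def _insert_by_guide(order: list[str], cid: str, guide_pos: dict) -> None:
    g = guide_pos.get(cid)
    if g is None or (isinstance(g, float) and np.isnan(g)):
        order.append(cid)
        return
    known = [(i, guide_pos[c]) for i, c in enumerate(order)
             if c in guide_pos and not np.isnan(guide_pos[c])]
    if len(known) < 2:
        order.append(cid)
        return
    idx, gp = zip(*known)
    rho = stats.spearmanr(idx, gp).statistic if len(known) > 2 else (
        1.0 if gp[-1] >= gp[0] else -1.0
    )
    ascending = not (rho < 0)
    for i, g_i in known:
        if (ascending and g_i > g) or (not ascending and g_i < g):
            order.insert(i, cid)
            return
    order.append(cid)


def _align_to_guide(order: list[str], guide_pos: dict) -> list[str]:
    """Reverse the order when ranks anticorrelate with guide positions."""
    pts = [(i, guide_pos[c]) for i, c in enumerate(order)
           if c in guide_pos and not np.isnan(guide_pos[c])]
    if len(pts) >= 2:
        idx, gp = zip(*pts)
        if len(set(gp)) > 1:
            rho = stats.spearmanr(idx, gp).statistic
            if rho < 0:
                return order[::-1]
    return order


def orient_contigs(
    order: list[str],
    alignments: pd.DataFrame,
    pairs: pd.DataFrame,
    lengths: pd.Series,
    min_markers: int = 2,
) -> dict[str, int]:
    """Orientation per contig of an ordered chromosome.

    Contigs with at least ``min_markers`` guide markers take the sign of the
    Spearman correlation between marker positions on the contig and on the
    guide (ties fall through to the Hi-C rule).  Markerless contigs use Hi-C:
    a contig points forward when its pair ends linking to predecessor contigs
    sit, on average, before the ends linking to successors.  Isolated contigs
    default to +1.
    """
    rank = {c: i for i, c in enumerate(order)}
    aln = alignments[alignments["contig_id"].isin(rank)]
    out: dict[str, int] = {}
    for cid in order:
        sub = aln[aln["contig_id"] == cid]
        ori = 0
        if len(sub) >= min_markers:
            cp = sub["contig_pos"].to_numpy(dtype=float)
            gp = sub["guide_pos"].to_numpy(dtype=float)
            if len(set(cp)) > 1 and len(set(gp)) > 1:
                rho = stats.spearmanr(cp, gp).statistic
                if not np.isnan(rho) and rho != 0:
                    ori = 1 if rho > 0 else -1
        if ori == 0:
            ori = _hic_orientation(cid, rank, pairs, float(lengths[cid]))
        out[cid] = ori
    return out


def _hic_orientation(cid: str, rank: dict, pairs: pd.DataFrame, length: float) -> int:
    r = rank[cid]
    m1 = pairs["contig1"] == cid
    m2 = pairs["contig2"] == cid
    # ends on this contig whose mate is elsewhere in the order
    own_pos, mate_rank = [], []
    for own, mate, mpos in ((m1, "contig2", "pos1"), (m2, "contig1", "pos2")):
        sub = pairs[own & (pairs[mate] != cid)]
        mr = sub[mate].map(rank)
        keep = mr.notna()
        own_pos.append(sub.loc[keep, mpos].to_numpy(dtype=float))
        mate_rank.append(mr[keep].to_numpy(dtype=float))
    own_pos = np.concatenate(own_pos) if own_pos else np.array([])
    mate_rank = np.concatenate(mate_rank) if mate_rank else np.array([])
    pred = mate_rank < r
    succ = mate_rank > r
    if pred.any() and succ.any():
        return 1 if own_pos[pred].mean() < own_pos[succ].mean() else -1
    if pred.any():
        return 1 if own_pos[pred].mean() < length / 2 else -1
    if succ.any():
        return 1 if own_pos[succ].mean() > length / 2 else -1
    return 1


def build_hic_map(
    assembly: AssemblyObject,
    assignments: pd.DataFrame,
    weights: pd.DataFrame,
    gap: int = 100,
    min_markers: int = 2,
) -> HiCMap:
    """Order + orient every assigned chromosome and lay contigs out with gaps.

    Chromosomes are emitted in sorted label order; unassigned contigs are
    listed as unplaced.  Offsets place contig k+1 at
    offset_k + length_k + gap.
    """
    lengths = assembly.contig_lengths()
    chroms = sorted(set(assignments["chromosome"]) - {UNASSIGNED})
    rows = []
    placed = set()
    for chrom in chroms:
        order = order_chromosome(assignments, weights, chrom)
        if not order:
            continue
        orients = orient_contigs(
            order, assembly.alignments, assembly.pairs, lengths, min_markers=min_markers
        )
        offset = 0
        for rank_i, cid in enumerate(order, start=1):
            L = int(lengths[cid])
            rows.append(
                {
                    "chromosome": chrom, "rank": rank_i, "contig_id": cid,
                    "orientation": orients[cid], "length": L, "offset": offset,
                }
            )
            offset += L + gap
            placed.add(cid)
    table = pd.DataFrame(rows, columns=MAP_COLUMNS)
    unplaced = sorted(set(assembly.contigs["contig_id"]) - placed)
    hic_map = HiCMap(table=table, unplaced=unplaced, gap=gap)
    hic_map.validate()
    logger.info(
        "built Hi-C map: %d chromosomes, %d placed, %d unplaced contigs",
        len(chroms), len(placed), len(unplaced),
    )
    return hic_map


def scaffold_assembly(
    assembly: AssemblyObject,
    gap: int = 100,
    normalize: str = "fragments",
    min_support: int = 2,
    min_purity: float = 0.75,
    min_markers: int = 2,
) -> HiCMap:
    """Full scaffolding pass: assign, normalize, order, orient, lay out."""
    from .digest_links import aggregate_links
    from .guidemap import assign_chromosomes

    assignments = assign_chromosomes(
        assembly.alignments, assembly.contigs,
        min_support=min_support, min_purity=min_purity,
    )
    links = aggregate_links(assembly.pairs)
    frag_counts = assembly.fragments.groupby("contig_id").size()
    if normalize == "fragments" and len(assembly.fragments) == 0:
        # no digestion available: fall back to length normalization
        normalize = "length"
    weights = normalize_links(
        links, frag_counts, method=normalize, lengths=assembly.contig_lengths()
    )
    return build_hic_map(
        assembly, assignments, weights, gap=gap, min_markers=min_markers
    )
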