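"""Linkage grouping, homolog separation and weighted-least-squares map
fitting for tetraploid coupling-phase marker data.

Markers are grouped at a LOD threshold (default > 4) into connected
components.  Because the recombination fraction between same-position
markers on different homologs is 1/3 — about 40 cM under Kosambi — a
jointly mapped group that actually contains several homologs shows large
gaps; splitting at a configurable gap threshold (default 35 cM) separates
the homologs.  Bridge markers (duplex×nulliplex, simplex×simplex) and
shared source contigs then connect homolog groups into chromosomes.
Within a group, markers are ordered by 1-D principal-coordinate seriation
of Kosambi-transformed recombination fractions with a greedy adjacent-swap
polish, and positions are fitted by weighted least squares (weights LOD²)
on all pairwise Kosambi distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .mapfunc import inverse_kosambi, kosambi

__all__ = [
    "LinkageGroup",
    "GeneticMap",
    "MapSummary",
    "kosambi",
    "inverse_kosambi",
    "group_markers",
    "phase_components",
    "split_homologs",
    "connect_homologs",
    "order_and_fit",
    "summarize_maps",
    "contig_id",
    "write_map_tsv",
    "write_mapchart",
]


@dataclass
class LinkageGroup:
    group_id: str
    markers: list[str]
    parent: str = ""
    chromosome: str | None = None
    homolog: str | None = None

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("linkage group cannot be empty")


@dataclass
class GeneticMap:
    """Ordered markers with cM positions (first marker at 0)."""

    name: str
    markers: list[str]
    positions: np.ndarray
    fit_stress: float = np.nan
    parent: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != self.positions.size:
            raise ValueError("markers and positions must align")
        if np.any(np.diff(self.positions) < -1e-9):
            raise ValueError("positions must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if self.positions.size else 0.0


@dataclass
class MapSummary:
    per_group: pd.DataFrame
    total_length_cm: float
    total_markers: int
    mean_interval_cm: float
    max_interval_cm: float


def contig_id(marker_name: str) -> str:
    """Source contig of an array SNP: the name up to the final
    underscore-delimited position token (``K001_123`` → ``K001``)."""
    return marker_name.rsplit("_", 1)[0]


def group_markers(
    pairs: pd.DataFrame, lod_threshold: float = 4.0, markers=None, parent: str = ""
):
    """Connected components of the LOD > threshold linkage graph.

    Returns ``(groups, singletons)``; grouping is invariant to input order
    (components are sorted by size then lexicographically smallest member).
    """
    g = nx.Graph()
    universe = set(markers) if markers is not None else set()
    if not pairs.empty:
        universe |= set(pairs["marker1"]) | set(pairs["marker2"])
        linked = pairs[pairs["lod"] > lod_threshold]
        g.add_edges_from(zip(linked["marker1"], linked["marker2"]))
    g.add_nodes_from(universe)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    groups, singletons = [], []
    for i, comp in enumerate(c for c in comps if len(c) > 1):
        groups.append(LinkageGroup(f"LG{i + 1:02d}", comp, parent))
    singletons = sorted(m for c in comps if len(c) == 1 for m in c)
    return groups, singletons


def phase_components(
    markers: list[str],
    pairs: pd.DataFrame,
    lod_threshold: float = 4.0,
    min_bridge_side: int = 4,
) -> list[list[str]]:
    """Split a linkage group into candidate homologs by assigned phase.

    Same-homolog markers are linked in coupling on the original marker
    coding; markers on different homologs only reach high LOD through the
    mirrored (repulsion) orientation.  Connected components of the
    non-mirrored coupling subgraph at LOD > threshold are therefore
    candidate homologs — the primary separation step, with the ~40 cM gap
    rule as the backstop for residual merges.

    A genuine homolog chain is locally dense (each marker links to several
    neighbours), so a single graph bridge joining two well-populated sides
    (≥ ``min_bridge_side`` markers each) is treated as a spurious linkage
    and removed, lowest LOD first.
    """
    g = nx.Graph()
    g.add_nodes_from(markers)
    mset = set(markers)
    if not pairs.empty:
        sub = pairs[pairs["marker1"].isin(mset) & pairs["marker2"].isin(mset)]
        strong = sub[(sub["lod"] > lod_threshold) & (~sub["mirrored"])]
        for m1, m2, lod in zip(strong["marker1"], strong["marker2"], strong["lod"]):
            if g.has_edge(m1, m2):
                g[m1][m2]["lod"] = max(g[m1][m2]["lod"], lod)
            else:
                g.add_edge(m1, m2, lod=lod)
    while True:
        candidates = []
        for u, v in nx.bridges(g):
            h = g.copy()
            h.remove_edge(u, v)
            side_u = nx.node_connected_component(h, u)
            side_v = nx.node_connected_component(h, v)
            if len(side_u) >= min_bridge_side and len(side_v) >= min_bridge_side:
                candidates.append((g[u][v]["lod"], u, v))
        if not candidates:
            break
        _, u, v = min(candidates)
        g.remove_edge(u, v)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def split_homologs(gmap: GeneticMap, gap_threshold_cm: float = 35.0) -> list[list[str]]:
    """Split an ordered map at every inter-marker gap above the threshold.

    Each fragment is a candidate homolog (coupling-phase linkage group).
    """
    if gmap.n_markers == 0:
        return []
    gaps = np.diff(gmap.positions)
    cuts = np.where(gaps > gap_threshold_cm)[0]
    fragments, start = [], 0
    for c in cuts:
        fragments.append(gmap.markers[start : c + 1])
        start = c + 1
    fragments.append(gmap.markers[start:])
    return fragments


def connect_homologs(
    homolog_groups: list[list[str]],
    bridge_pairs: pd.DataFrame | None = None,
    lod_threshold: float = 4.0,
    use_contigs: bool = True,
    overlap_col: str = "mother_overlap",
    max_homologs: int = 4,
):
    """Merge homolog groups into chromosome-level clusters.

    Two groups join when a bridge marker has coupling-phase (overlap ≥ 1)
    LOD > threshold pairs into both, or when they contain SNPs from the
    same source contig.  Returns ``(clusters, flags)`` where clusters are
    lists of group indices and a flag marks any cluster implying more than
    ``max_homologs`` homologs (no silent merge beyond reporting).
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(homolog_groups)))
    member = {}
    for gi, grp in enumerate(homolog_groups):
        for m in grp:
            member[m] = gi
    if bridge_pairs is not None and not bridge_pairs.empty:
        strong = bridge_pairs[bridge_pairs["lod"] > lod_threshold]
        if overlap_col in strong.columns:
            strong = strong[strong[overlap_col] >= 1]
        bridge_to_groups: dict[str, set[int]] = {}
        for _, row in strong.iterrows():
            m1, m2 = row["marker1"], row["marker2"]
            in1, in2 = m1 in member, m2 in member
            if in1 and in2:
                g.add_edge(member[m1], member[m2])
            elif in1 != in2:
                bridge, grouped = (m2, m1) if in1 else (m1, m2)
                bridge_to_groups.setdefault(bridge, set()).add(member[grouped])
        for touched in bridge_to_groups.values():
            touched = sorted(touched)
            for a, b in zip(touched, touched[1:]):
                g.add_edge(a, b)
    if use_contigs:
        by_contig: dict[str, set[int]] = {}
        for m, gi in member.items():
            by_contig.setdefault(contig_id(m), set()).add(gi)
        for touched in by_contig.values():
            touched = sorted(touched)
            for a, b in zip(touched, touched[1:]):
                g.add_edge(a, b)
    clusters = [sorted(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    flags = [len(c) > max_homologs for c in clusters]
    return clusters, flags


# ---------------------------------------------------------------------------
# ordering and WLS distance fitting
# ---------------------------------------------------------------------------


def _pair_matrices(markers: list[str], pairs: pd.DataFrame, max_r: float = 0.49):
    """Symmetric Kosambi-distance and LOD² weight matrices for a group."""
    idx = {m: i for i, m in enumerate(markers)}
    m = len(markers)
    d = np.full((m, m), np.nan)
    w = np.zeros((m, m))
    sub = pairs[pairs["marker1"].isin(idx) & pairs["marker2"].isin(idx)]
    for _, row in sub.iterrows():
        i, j = idx[row["marker1"]], idx[row["marker2"]]
        r = min(float(row["r_hat"]), 0.4999)
        if float(row["r_hat"]) >= max_r:
            continue  # Kosambi diverges towards r = 0.5
        dist = kosambi(r)
        weight = float(row["lod"]) ** 2
        if weight > w[i, j]:
            d[i, j] = d[j, i] = dist
            w[i, j] = w[j, i] = weight
    np.fill_diagonal(d, 0.0)
    return d, w


def _wls_positions(order: np.ndarray, d: np.ndarray, w: np.ndarray):
    """Weighted LS positions for a fixed order; first marker pinned at 0."""
    m = order.size
    pos_of = np.empty(m, dtype=int)
    pos_of[order] = np.arange(m)
    rows_i, rows_j, dists, weights = [], [], [], []
    for i in range(m):
        for j in range(i + 1, m):
            if w[i, j] > 0 and np.isfinite(d[i, j]):
                a, b = (i, j) if pos_of[i] < pos_of[j] else (j, i)
                rows_i.append(a)
                rows_j.append(b)
                dists.append(d[i, j])
                weights.append(w[i, j])
    if not rows_i:
        return np.zeros(m), np.inf
    n_eq = len(rows_i)
    a_mat = np.zeros((n_eq, m))
    a_mat[np.arange(n_eq), rows_j] = 1.0
    a_mat[np.arange(n_eq), rows_i] = -1.0
    sw = np.sqrt(np.asarray(weights))
    rhs = np.asarray(dists) * sw
    first = order[0]
    keep = [k for k in range(m) if k != first]
    sol, *_ = np.linalg.lstsq(a_mat[:, keep] * sw[:, None], rhs, rcond=None)
    x = np.zeros(m)
    x[keep] = sol
    resid = (a_mat @ x - np.asarray(dists)) * sw
    denom = float(np.sum(np.asarray(weights) * np.asarray(dists) ** 2))
    stress = float(np.sqrt(np.sum(resid**2) / denom)) if denom > 0 else 0.0
    return x, stress


def _seriate_fiedler(w: np.ndarray) -> np.ndarray:
    """Spectral seriation: order by the Fiedler vector of the weight graph."""
    deg = w.sum(axis=1)
    lap = np.diag(deg) - w
    evals, evecs = np.linalg.eigh(lap)
    fiedler = evecs[:, np.argsort(evals)[1]] if w.shape[0] > 1 else np.zeros(1)
    return np.argsort(fiedler, kind="stable")


def _seriate_mds(d: np.ndarray) -> np.ndarray:
    """Initial order from the first principal coordinate of the distance
    matrix (missing entries completed by shortest paths)."""
    dc = d.copy()
    if np.isnan(dc).any():
        adj = np.where(np.isnan(dc), 0.0, dc)
        mask = ~np.isnan(dc)
        graph = np.where(mask, adj, 0.0)
        sp = shortest_path(graph, method="D", directed=False, unweighted=False)
        sp[np.isinf(sp)] = np.nanmax(dc) * 2 if np.isfinite(np.nanmax(dc)) else 1.0
        dc = np.where(mask, dc, sp)
    n = dc.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dc**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    axis = evecs[:, np.argmax(evals)]
    return np.argsort(axis, kind="stable")


def order_and_fit(
    markers: list[str],
    pairs: pd.DataFrame,
    name: str = "LG",
    parent: str = "",
    max_polish_passes: int = 10,
) -> GeneticMap:
    """Order a linkage group and fit cM positions by weighted least squares.

    Seriation via a 1-D principal-coordinate embedding of the Kosambi
    distances, greedy adjacent-swap polish minimising the weighted stress,
    then WLS positions (weights LOD², pairs with r̂ ≥ 0.49 dropped).  The
    fitted map starts at 0; markers are re-sorted by fitted position so
    the result is non-decreasing.  Raises if the group is disconnected.
    """
    if len(markers) < 2:
        if len(markers) == 1:
            return GeneticMap(name, list(markers), np.zeros(1), 0.0, parent)
        raise ValueError("a group needs at least 2 markers")
    d, w = _pair_matrices(markers, pairs)
    g = nx.Graph()
    g.add_nodes_from(range(len(markers)))
    ii, jj = np.where(w > 0)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        names = [sorted(markers[i] for i in c)[:3] for c in comps]
        raise ValueError(f"group {name!r} is disconnected: components {names}")
    m = len(markers)

    def _polished(order):
        x, stress = _wls_positions(order, d, w)
        order = order[np.argsort(x[order], kind="stable")]
        x, stress = _wls_positions(order, d, w)
        max_seg = m if m <= 30 else 6
        for _ in range(max_polish_passes):
            improved = False
            # segment reversals of every window (includes adjacent swaps)
            for k in range(m - 1):
                for seg in range(2, min(max_seg, m - k) + 1):
                    cand = order.copy()
                    cand[k : k + seg] = cand[k : k + seg][::-1]
                    xc, sc = _wls_positions(cand, d, w)
                    if sc < stress - 1e-12:
                        order, x, stress = cand, xc, sc
                        improved = True
            # single-marker re-insertions (kept to modest group sizes)
            if m <= 30:
                for i in range(m):
                    marker = order[i]
                    base = np.delete(order, i)
                    for j in range(m):
                        if j == i:
                            continue
                        cand = np.insert(base, j, marker)
                        xc, sc = _wls_positions(cand, d, w)
                        if sc < stress - 1e-12:
                            order, x, stress = cand, xc, sc
                            improved = True
                            break
            if not improved:
                break
        return order, x, stress

    starts = [_seriate_mds(np.where(w > 0, d, np.nan)), _seriate_fiedler(w)]
    best = None
    for start in starts:
        cand = _polished(start)
        if best is None or cand[2] < best[2] - 1e-12:
            best = cand
    order, x, stress = best
    order = order[np.argsort(x[order], kind="stable")]
    x, stress = _wls_positions(order, d, w)
    pos = x[order] - x[order[0]]
    pos = np.maximum.accumulate(pos)  # guard tiny numeric decreases
    return GeneticMap(name, [markers[i] for i in order], pos, stress, parent)


def summarize_maps(maps: list[GeneticMap]) -> MapSummary:
    """Per-group lengths and marker counts, totals, and the mean/maximum
    adjacent marker interval across all groups."""
    if not maps:
        raise ValueError("at least one map is required")
    rows = [
        {"group": g.name, "parent": g.parent, "length_cM": g.length_cm,
         "n_markers": g.n_markers}
        for g in maps
    ]
    per_group = pd.DataFrame(rows)
    intervals = np.concatenate(
        [np.diff(g.positions) for g in maps if g.n_markers > 1]
        or [np.empty(0)]
    )
    return MapSummary(
        per_group=per_group,
        total_length_cm=float(per_group["length_cM"].sum()),
        total_markers=int(per_group["n_markers"].sum()),
        mean_interval_cm=float(intervals.mean()) if intervals.size else np.nan,
        max_interval_cm=float(intervals.max()) if intervals.size else np.nan,
    )


def write_map_tsv(maps: list[GeneticMap], path) -> None:
    """Per-homolog map TSV: marker, group, position_cM."""
    rows = []
    for g in maps:
        for m, p in zip(g.markers, g.positions):
            rows.append({"marker": m, "group": g.name, "parent": g.parent,
                         "position_cM": f"{p:.3f}"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_mapchart(maps: list[GeneticMap], path) -> None:
    """MapChart-compatible text: ``group <name>`` then ``marker position``."""
    with open(path, "w") as fh:
        for g in maps:
            fh.write(f"group {g.name}\n")
            for m, p in zip(g.markers, g.positions):
                fh.write(f"{m} {p:.3f}\n")
            fh.write("\n")
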