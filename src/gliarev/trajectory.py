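"""Principal-tree pseudotime and the branch-occupancy deviance statistic.

The tree is a simplified principal graph: k-means centroids in (covariate-
residualized) PCA space joined by their Euclidean minimum spanning tree;
cells are projected onto the nearest edge segment.  Branches are the maximal
segments between nodes of degree != 2.  The tree is rooted at the terminus
of the branch with the highest occupancy share among young control
(young-GFP) cells, and pseudotime is geodesic arc length from the root.

The sum-of-deviance statistic compares branch-occupancy proportion vectors:
D(s, r) = sum_b |p_s(b) - p_r(b)|, the L1 distance on the branch simplex
(range [0, 2]).  Each sample is paired with every young-GFP reference
replicate (never itself), giving one data point per pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .cluster import pca_scores
from .cohort import CellCohort, CohortDesign, ParameterError


@dataclass
class TrajectoryTree:
    """Principal tree with per-cell projections.

    ``branches`` lists node paths; ``cell_index`` holds the cohort cell
    indices the per-cell arrays refer to.
    """

    nodes: np.ndarray  # k x d centroid coordinates
    edges: list[tuple[int, int]]
    branches: list[list[int]]  # node paths, maximal deg!=2 segments, sorted by id
    cell_index: np.ndarray
    cell_edge: np.ndarray  # index into edges
    cell_offset: np.ndarray  # position along the edge in [0, 1]
    cell_branch: np.ndarray  # branch id per cell
    celltype: str
    root: int | None = None
    cell_pseudotime: np.ndarray | None = None
    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch_endpoints(self, b: int) -> tuple[int, int]:
        path = self.branches[b]
        return path[0], path[-1]

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes.tolist(),
            "edges": [list(e) for e in self.edges],
            "branches": [list(map(int, p)) for p in self.branches],
            "root": None if self.root is None else int(self.root),
            "celltype": self.celltype,
        }


def _enumerate_branches(graph: nx.Graph) -> list[list[int]]:
    """Maximal node paths between nodes of degree != 2, deterministically ordered."""
    if graph.number_of_nodes() == 1:
        return [[next(iter(graph.nodes))]]
    breakpoints = sorted(n for n in graph.nodes if graph.degree(n) != 2)
    if not breakpoints:  # cycle cannot occur in a tree; single-edge path handled above
        breakpoints = [min(graph.nodes)]
    seen_edges: set[tuple[int, int]] = set()
    paths: list[list[int]] = []
    for bp in breakpoints:
        for nbr in sorted(graph.neighbors(bp)):
            e = (min(bp, nbr), max(bp, nbr))
            if e in seen_edges:
                continue
            path = [bp, nbr]
            seen_edges.add(e)
            prev, cur = bp, nbr
            while graph.degree(cur) == 2:
                nxt = next(n for n in graph.neighbors(cur) if n != prev)
                seen_edges.add((min(cur, nxt), max(cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            paths.append(path)
    # Canonical orientation and order: smaller endpoint first, sort by endpoints.
    canon = []
    for p in paths:
        if p[-1] < p[0]:
            p = p[::-1]
        canon.append(p)
    canon.sort(key=lambda p: (min(p[0], p[-1]), max(p[0], p[-1]), len(p)))
    return canon


def _project_cells(
    scores: np.ndarray, nodes: np.ndarray, edges: list[tuple[int, int]],
    branches: list[list[int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-edge-segment projection: (edge index, offset in [0,1], branch id)."""
    edge_branch: dict[tuple[int, int], int] = {}
    for bid, path in enumerate(branches):
        for a, b in zip(path[:-1], path[1:]):
            edge_branch[(min(a, b), max(a, b))] = bid
    m = scores.shape[0]
    if not edges:
        return np.zeros(m, dtype=int), np.zeros(m), np.zeros(m, dtype=int)
    d2 = np.empty((m, len(edges)))
    offs = np.empty((m, len(edges)))
    for e, (a, b) in enumerate(edges):
        A, B = nodes[a], nodes[b]
        ab = B - A
        denom = float(ab @ ab)
        s = np.clip((scores - A) @ ab / max(denom, 1e-12), 0.0, 1.0)
        proj = A + s[:, None] * ab
        d2[:, e] = ((scores - proj) ** 2).sum(axis=1)
        offs[:, e] = s
    cell_edge = d2.argmin(axis=1)
    cell_offset = offs[np.arange(m), cell_edge]
    cell_branch = np.array([edge_branch[edges[e]] for e in cell_edge])
    return cell_edge, cell_offset, cell_branch


def _mst_graph(nodes: np.ndarray) -> nx.Graph:
    dist = cdist(nodes, nodes)
    mst = minimum_spanning_tree(sp.csr_matrix(dist))
    rows, cols = mst.nonzero()
    graph = nx.Graph()
    graph.add_nodes_from(range(nodes.shape[0]))
    for i, j in zip(rows.tolist(), cols.tolist()):
        graph.add_edge(min(i, j), max(i, j), length=float(dist[i, j]))
    return graph


def principal_tree(
    scores: np.ndarray,
    n_nodes: int = 20,
    min_branch_share: float = 0.1,
    n_smooth_iter: int = 8,
    elastic: float = 0.5,
    celltype: str = "",
    cell_index: np.ndarray | None = None,
    seed: int = 0,
) -> TrajectoryTree:
    """Centroid-MST principal tree over arbitrary embedding coordinates.

    Leaf branches holding fewer than ``min_branch_share`` of the cells are
    pruned iteratively (noise spurs of the MST, as in principal-graph
    practice), so the surviving branches are the population-level segments.
    """
    scores = np.asarray(scores, dtype=float)
    idx = np.arange(scores.shape[0]) if cell_index is None else cell_index
    if n_nodes > scores.shape[0]:
        raise ParameterError(f"n_nodes={n_nodes} exceeds {scores.shape[0]} cells")
    km = KMeans(n_clusters=n_nodes, random_state=seed, n_init=10).fit(scores)
    nodes = km.cluster_centers_

    # Elastic relaxation: pull each node toward the mean of its MST neighbours
    # (a light principal-graph energy term) and rebuild the MST, straightening
    # noise-induced zigzags before branch enumeration.
    for _ in range(n_smooth_iter):
        graph = _mst_graph(nodes)
        new = nodes.copy()
        for n in graph.nodes:
            nbrs = list(graph.neighbors(n))
            if nbrs:
                new[n] = (1.0 - elastic) * nodes[n] + elastic * nodes[nbrs].mean(axis=0)
        nodes = new
    graph = _mst_graph(nodes)

    while True:
        edges = sorted(tuple(sorted(e)) for e in graph.edges)
        branches = _enumerate_branches(graph)
        cell_edge, cell_offset, cell_branch = _project_cells(scores, nodes, edges, branches)
        if len(branches) <= 1:
            break
        share = np.bincount(cell_branch, minlength=len(branches)) / max(idx.size, 1)
        deg = dict(graph.degree())
        # Leaf branches: exactly one endpoint of degree 1.
        prunable = [
            b for b, path in enumerate(branches)
            if share[b] < min_branch_share
            and (deg[path[0]] == 1) != (deg[path[-1]] == 1)
        ]
        if not prunable:
            break
        b = min(prunable, key=lambda b: (share[b], b))
        path = branches[b]
        if deg[path[-1]] == 1:
            path = path[::-1]  # leaf end first, junction last
        graph.remove_nodes_from(path[:-1])

    return TrajectoryTree(
        nodes=nodes,
        edges=edges,
        branches=branches,
        cell_index=idx,
        cell_edge=cell_edge,
        cell_offset=cell_offset,
        cell_branch=cell_branch,
        celltype=celltype,
        graph=graph,
    )


def fit_tree(
    cohort: CellCohort,
    celltype: str,
    n_nodes: int = 20,
    n_components: int = 3,
    min_branch_share: float = 0.1,
    seed: int = 0,
) -> TrajectoryTree:
    """Principal tree for one cell type, fit in covariate-residualized PCA
    space; branch assignments are written to cell_table["branch"]."""
    scores, idx = pca_scores(cohort, celltype, n_components=n_components, seed=seed)
    tree = principal_tree(
        scores, n_nodes=n_nodes, min_branch_share=min_branch_share,
        celltype=celltype, cell_index=idx, seed=seed,
    )
    if "branch" not in cohort.cell_table.columns:
        cohort.cell_table["branch"] = pd.array([None] * cohort.n_cells, dtype="Int64")
    cohort.cell_table.loc[cohort.cell_table.index[idx], "branch"] = tree.cell_branch
    return tree


def _cell_arc_lengths(tree: TrajectoryTree, node_dist: dict[int, float]) -> np.ndarray:
    """Geodesic arc length from the node_dist source to every cell projection."""
    if not tree.edges:
        return np.zeros(tree.cell_index.size)
    lengths = np.array([tree.graph.edges[e]["length"] for e in tree.edges])
    da = np.array([node_dist[e[0]] for e in tree.edges])
    db = np.array([node_dist[e[1]] for e in tree.edges])
    L = lengths[tree.cell_edge]
    s = tree.cell_offset
    via_a = da[tree.cell_edge] + s * L
    via_b = db[tree.cell_edge] + (1.0 - s) * L
    return np.minimum(via_a, via_b)


def branch_occupancy(tree: TrajectoryTree, mask: np.ndarray) -> np.ndarray:
    """Occupancy proportion vector over branches for a boolean cell mask
    (over tree.cell_index order)."""
    counts = np.bincount(tree.cell_branch[mask], minlength=tree.n_branches).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def root_tree_from_mask(tree: TrajectoryTree, ref: np.ndarray) -> TrajectoryTree:
    """Root at the terminus of the branch richest in reference cells (boolean
    mask over the tree's cells) and compute geodesic pseudotime."""
    ref = np.asarray(ref, dtype=bool)
    if not ref.any():
        raise ParameterError("rooting requires reference cells in the tree's cell type")
    occ = branch_occupancy(tree, ref)
    best = int(np.flatnonzero(occ == occ.max()).min())  # ties -> lower branch id
    a, b = tree.branch_endpoints(best)
    # Terminus of the winning branch: its outer (degree-1) end.  When both or
    # neither end is a leaf (a single-branch path tree, or an internal
    # segment), take the end nearer on average to the young-control cells so
    # pseudotime starts where they concentrate; exact ties -> lower node id.
    deg = dict(tree.graph.degree())
    leaves = [n for n in sorted((a, b)) if deg.get(n, 0) <= 1]
    if len(leaves) == 1 or a == b:
        root = leaves[0] if leaves else a
    else:
        candidates = leaves if leaves else sorted((a, b))
        root = candidates[0]
        if tree.edges:
            dists = []
            for cand in candidates:
                nd = nx.single_source_dijkstra_path_length(tree.graph, cand, weight="length")
                dists.append(_cell_arc_lengths(tree, nd)[ref].mean())
            if dists[1] < dists[0] - 1e-12:
                root = candidates[1]
    tree.root = root

    node_dist = nx.single_source_dijkstra_path_length(tree.graph, root, weight="length")
    tree.cell_pseudotime = _cell_arc_lengths(tree, node_dist)
    return tree


def root_tree(
    tree: TrajectoryTree,
    cohort: CellCohort,
    design: CohortDesign | None = None,
) -> TrajectoryTree:
    """Root by the young-control occupancy rule and write cell_table["pseudotime"]."""
    design = design or CohortDesign.from_cell_table(cohort.cell_table)
    group = cohort.group.iloc[tree.cell_index].to_numpy()
    root_tree_from_mask(tree, group == "youngGFP")
    if "pseudotime" not in cohort.cell_table.columns:
        cohort.cell_table["pseudotime"] = np.nan
    cohort.cell_table.loc[cohort.cell_table.index[tree.cell_index], "pseudotime"] = (
        tree.cell_pseudotime
    )
    return tree


def l1_deviance(p: np.ndarray, q: np.ndarray) -> float:
    """Sum over branches of |p(b) - q(b)|; L1 distance on the simplex, in [0, 2]."""
    return float(np.abs(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)).sum())


def sum_of_deviance(
    tree: TrajectoryTree,
    cohort: CellCohort,
    design: CohortDesign | None = None,
) -> pd.DataFrame:
    """One deviance point per (sample, young-GFP reference replicate) pairing.

    Occupancy vectors are within-sample branch proportions; a young-GFP
    replicate is never paired with itself.  Samples with no cells of the
    tree's type are skipped with a flag row.
    """
    design = design or CohortDesign.from_cell_table(cohort.cell_table)
    samples = cohort.cell_table["sample"].iloc[tree.cell_index].to_numpy()
    group_of = design.group_of_sample
    refs = design.samples_in_group("youngGFP")
    if not refs:
        raise ParameterError("no young-GFP reference replicates in design")
    occ: dict[str, np.ndarray | None] = {}
    for s in design.samples.index:
        mask = samples == s
        occ[s] = branch_occupancy(tree, mask) if mask.any() else None

    rows = []
    for s in design.samples.index:
        for r in refs:
            if r == s:
                continue
            if occ[s] is None or occ[r] is None:
                rows.append(
                    {"sample": s, "group": group_of[s], "reference": r,
                     "D": np.nan, "skipped": True}
                )
                continue
            terms = np.abs(occ[s] - occ[r])
            row = {"sample": s, "group": group_of[s], "reference": r,
                   "D": float(terms.sum()), "skipped": False}
            row.update({f"term_b{b}": float(t) for b, t in enumerate(terms)})
            rows.append(row)
    return pd.DataFrame(rows)


def deviance_summary(deviance: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of the deviance points per design group."""
    ok = deviance[~deviance["skipped"]]
    return (
        ok.groupby("group")["D"].agg(["mean", "std", "count"]).reset_index()
    )
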