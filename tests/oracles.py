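"""Independent reference computations used to cross-check the package.

These deliberately use different algorithms and libraries than the
implementation: brute-force partition sums for imbalances, a
shortest-path graph plus a transportation linear program for the KR
distance, and textbook column-wise formulas for the summary statistics.
"""

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from phyloplace import MassPointsOnTree, ReferenceTree
from phyloplace.masses import MassVector


def brute_force_imbalances(mv: MassVector) -> np.ndarray:
    """O(m^2) imbalance: re-sum both partitions for every edge."""
    tree = mv.tree
    m = tree.num_edges
    out = np.empty(m)
    for col in range(m):
        e = int(tree.edge_order[col])
        sub = set(int(c) for c in tree.subtree_edge_columns(e))
        root_side = [c for c in range(m) if c != col and c not in sub]
        out[col] = sum(mv.values[c] for c in root_side) - sum(mv.values[c] for c in sub)
    return out


def _mass_point_graph(tree: ReferenceTree, points: list[MassPointsOnTree]):
    """Graph of tree nodes plus one node per mass point, edge weights =
    path lengths, for exact pairwise mass-point distances."""
    g = nx.Graph()
    lens = tree.branch_lengths
    for v in range(tree.num_nodes):
        p = tree.parent[v]
        if p >= 0:
            col = tree.edge_column(int(tree.node_edge_num[v]))
            g.add_edge(("n", v), ("n", int(p)), weight=lens[col])
    labels = []
    for col in range(tree.num_edges):
        v = tree.edge_child_node(col)
        on_edge = []
        for pi, pts in enumerate(points):
            for j, (pos, mass) in enumerate(zip(pts.positions[col], pts.masses[col])):
                node = ("p", pi, col, j)
                labels.append((pi, node, mass))
                on_edge.append((pos, node))
        # chain the points along the edge so same-edge distances are exact
        on_edge.sort(key=lambda t: t[0])
        if v == 0:  # root edge: only the distal end attaches to the tree
            prev, prev_pos = ("n", 0), lens[col]
            for pos, node in reversed(on_edge):
                g.add_edge(prev, node, weight=prev_pos - pos)
                prev, prev_pos = node, pos
        else:
            prev, prev_pos = ("n", int(tree.parent[v])), 0.0
            for pos, node in on_edge:
                g.add_edge(prev, node, weight=pos - prev_pos)
                prev, prev_pos = node, pos
            g.add_edge(prev, ("n", v), weight=lens[col] - prev_pos)
    return g, labels


def lp_kr_distance(a: MassPointsOnTree, b: MassPointsOnTree) -> float:
    """Earth-mover distance by solving the transportation LP on the
    pairwise path-distance matrix of the mass points."""
    tree = a.tree
    g, labels = _mass_point_graph(tree, [a, b])
    a_nodes = [(n, m) for pi, n, m in labels if pi == 0]
    b_nodes = [(n, m) for pi, n, m in labels if pi == 1]
    na, nb = len(a_nodes), len(b_nodes)
    d = np.zeros((na, nb))
    for i, (an, _) in enumerate(a_nodes):
        dist = nx.single_source_dijkstra_path_length(g, an)
        for j, (bn, _) in enumerate(b_nodes):
            d[i, j] = dist[bn]
    # min sum f_ij d_ij  s.t. row sums = a masses, col sums = b masses
    c = d.ravel()
    A_eq = []
    b_eq = []
    for i in range(na):
        row = np.zeros((na, nb))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
        b_eq.append(a_nodes[i][1])
    for j in range(nb - 1):  # drop one redundant constraint
        col = np.zeros((na, nb))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
        b_eq.append(b_nodes[j][1])
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
    assert res.success, res.message
    return float(res.fun)
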