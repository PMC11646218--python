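"""Distance trees under the Fitch–Margoliash weighted least-squares criterion.

The criterion scores an unrooted tree with branch lengths x against an
observed distance matrix d by

    sum_{i<j}  (d_ij - p_ij)^2 / d_ij^power

where p_ij is the patristic (path-length) distance between leaves i and j.
``power = 2`` is the classic Fitch–Margoliash weighting: relative rather
than absolute deviations are penalised, so short distances — measured with
proportionally better accuracy — constrain the fit more.

Branch lengths for a fixed topology are the non-negative weighted
least-squares solution of the path-incidence system; the topology itself is
found by stepwise taxon addition followed by nearest-neighbour-interchange
(NNI) hill climbing, with seeded random restarts over addition orders.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "PhyloTree",
    "DegenerateMatrixError",
    "fm_objective",
    "ls_branch_lengths",
    "fitch_tree",
    "robinson_foulds",
    "all_topologies",
]


class DegenerateMatrixError(ValueError):
    """Duplicate taxa (zero mutual distance, identical rows) make the fit singular."""


@dataclass
class PhyloTree:
    """Unrooted tree with non-negative branch lengths over leaf labels.

    ``adj`` maps node id -> {neighbour: branch length}; ``leaves`` maps the
    node ids of degree-one nodes to their labels.  Internal nodes are
    unlabeled.  Node ids are arbitrary ints.
    """

    adj: dict[int, dict[int, float]]
    leaves: dict[int, str]

    # -- basic accessors ----------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return sorted(self.leaves.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_node(self, label: str) -> int:
        for node, lab in self.leaves.items():
            if lab == label:
                return node
        raise KeyError(label)

    def edges(self) -> list[tuple[int, int]]:
        """Edges as (u, v) with u < v, sorted — a deterministic order."""
        return sorted({(min(u, v), max(u, v)) for u in self.adj for v in self.adj[u]})

    def copy(self) -> "PhyloTree":
        return PhyloTree({u: dict(nb) for u, nb in self.adj.items()}, dict(self.leaves))

    def total_length(self) -> float:
        return sum(l for _, nb in self.adj.items() for l in nb.values()) / 2.0

    # -- structure ----------------------------------------------------------

    def _split_sides(self) -> dict[tuple[int, int], frozenset[str]]:
        """For every edge, the leaf labels on the side of the smaller node id."""
        out = {}
        for u, v in self.edges():
            side = self._leafset_behind(u, v)
            out[(u, v)] = side
        return out

    def _leafset_behind(self, u: int, away_from: int) -> frozenset[str]:
        """Labels of leaves reachable from u without crossing edge (u, away_from)."""
        seen = {away_from, u}
        stack = [u]
        labels = set()
        while stack:
            x = stack.pop()
            if x in self.leaves:
                labels.add(self.leaves[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(labels)

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Canonicalised splits: the block not containing the smallest label."""
        all_labels = frozenset(self.labels)
        ref = min(all_labels)
        out = set()
        for (u, v), side in self._split_sides().items():
            block = all_labels - side if ref in side else side
            if include_trivial or 2 <= len(block) <= len(all_labels) - 2:
                out.add(block)
        return out

    def patristic_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Leaf-to-leaf path-length distances, rows/cols in ``order``."""
        order = order or self.labels
        E, edge_index = self._leaf_edge_incidence(order)
        lengths = np.array(
            [self.adj[u][v] for (u, v) in sorted(edge_index, key=edge_index.get)]
        )
        P = np.zeros((len(order), len(order)))
        for i in range(len(order)):
            xor = E[i] ^ E
            P[i] = xor @ lengths
        return P

    def _leaf_edge_incidence(
        self, order: list[str]
    ) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
        """Boolean leaf-by-edge matrix: 1 iff the edge lies on the root path."""
        edge_index = {e: k for k, e in enumerate(self.edges())}
        root = next(iter(self.adj))
        parent = {root: None}
        stack = [root]
        dfs_order = []
        while stack:
            x = stack.pop()
            dfs_order.append(x)
            for y in self.adj[x]:
                if y not in parent:
                    parent[y] = x
                    stack.append(y)
        path_vec: dict[int, np.ndarray] = {
            root: np.zeros(len(edge_index), dtype=bool)
        }
        for x in dfs_order[1:]:
            p = parent[x]
            vec = path_vec[p].copy()
            vec[edge_index[(min(x, p), max(x, p))]] = True
            path_vec[x] = vec
        node_of = {lab: n for n, lab in self.leaves.items()}
        E = np.stack([path_vec[node_of[lab]] for lab in order])
        return E, edge_index

    # -- Newick -------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string (branch lengths, no internal labels), rooted for
        display at an internal node adjacent to the first sorted leaf."""
        first = self.leaf_node(self.labels[0])
        root = next(iter(self.adj[first])) if self.adj[first] else first

        def quote(name: str) -> str:
            if any(c in name for c in " ()[]':;,"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def rec(node: int, parent: int | None) -> str:
            children = [c for c in self.adj[node] if c != parent]
            if not children:
                return quote(self.leaves[node])
            inner = ",".join(
                f"{rec(c, node)}:{self.adj[node][c]:.10g}" for c in children
            )
            return f"({inner})"

        return rec(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string (via dendropy) into an unrooted tree."""
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")
        t.encode_bipartitions(suppress_unifurcations=False)
        adj: dict[int, dict[int, float]] = {}
        leaves: dict[int, str] = {}
        ids: dict[object, int] = {}

        def nid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
                adj[ids[node]] = {}
            return ids[node]

        for edge in t.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            ln = float(edge.length) if edge.length is not None else 0.0
            adj[u][v] = adj[v][u] = ln
        for leaf in t.leaf_node_iter():
            leaves[nid(leaf)] = leaf.taxon.label
        tree = cls(adj, leaves)
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.adj):
                if node not in self.leaves and len(self.adj[node]) == 2:
                    (a, la), (b, lb) = self.adj[node].items()
                    del self.adj[a][node]
                    del self.adj[b][node]
                    del self.adj[node]
                    self.adj[a][b] = self.adj[b][a] = la + lb
                    changed = True


# ---------------------------------------------------------------------------
# weighted least squares on a fixed topology


def _fm_weights(D: np.ndarray, power: float) -> np.ndarray:
    """Per-pair weights d^-power; zero off-diagonal distances use the
    smallest positive distance divided by 10 to keep the criterion finite."""
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    d = D[iu].copy()
    pos = d[d > 0]
    if len(pos) == 0:
        return np.ones_like(d)
    eps = pos.min() / 10.0
    d[d <= 0] = eps
    return d ** (-power)


def _check_degenerate(dm) -> None:
    D = dm.d
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == 0 and np.allclose(D[i], D[j]):
                raise DegenerateMatrixError(
                    f"duplicate taxa {dm.labels[i]!r} and {dm.labels[j]!r} "
                    "(zero distance, identical rows)"
                )


def _incidence_system(tree: PhyloTree, order: list[str]) -> tuple[np.ndarray, list]:
    E, edge_index = tree._leaf_edge_incidence(order)
    n = len(order)
    ia, ib = np.triu_indices(n, 1)
    A = (E[ia] ^ E[ib]).astype(float)
    edges_sorted = sorted(edge_index, key=edge_index.get)
    return A, edges_sorted


def _solve_lengths(
    A: np.ndarray,
    dvec: np.ndarray,
    w: np.ndarray,
    force_nnls: bool = False,
    exact: bool = True,
) -> tuple[np.ndarray, float]:
    """Weighted least squares min sum w (d - A x)^2 with x >= 0.

    The unconstrained normal-equations solution is used when it is already
    non-negative (then it equals the constrained optimum); otherwise the
    active-set NNLS solver runs.  With ``exact=False`` the unconstrained
    objective is returned even when some lengths go negative — a cheap
    lower bound used only to rank topologies during search.
    """
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    dw = dvec * sw
    G = Aw.T @ Aw
    b = Aw.T @ dw
    try:
        x = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        x, *_ = np.linalg.lstsq(Aw, dw, rcond=None)
    neg = bool(np.any(x < -1e-12))
    if (neg and exact) or force_nnls:
        x, _ = nnls(Aw, dw)
    elif neg:
        resid = dw - Aw @ x
        return x, float(resid @ resid)
    x = np.maximum(x, 0.0)
    resid = dw - Aw @ x
    return x, float(resid @ resid)


def fm_objective(dm, tree: PhyloTree, power: float = 2.0) -> float:
    """Fitch–Margoliash misfit of a tree's own branch lengths to a matrix."""
    if set(tree.labels) != set(dm.labels):
        raise ValueError("tree leaves and matrix labels differ")
    order = dm.labels if isinstance(dm.labels, list) else list(dm.labels)
    order = sorted(order)
    idx = [dm.labels.index(l) for l in order]
    D = dm.d[np.ix_(idx, idx)]
    P = tree.patristic_matrix(order)
    iu = np.triu_indices(len(order), 1)
    w = _fm_weights(D, power)
    r = D[iu] - P[iu]
    return float(np.sum(w * r * r))


def ls_branch_lengths(topology: PhyloTree, dm, power: float = 2.0) -> PhyloTree:
    """Optimal non-negative branch lengths for a fixed topology.

    Solves the weighted non-negative least-squares path-incidence system;
    unconstrained negative solutions are clamped by the NNLS active-set
    solve, never by truncation.
    """
    _check_degenerate(dm)
    order = sorted(dm.labels)
    idx = [dm.labels.index(l) for l in order]
    D = dm.d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(order), 1)
    A, edges_sorted = _incidence_system(topology, order)
    w = _fm_weights(D, power)
    x, _ = _solve_lengths(A, D[iu], w, force_nnls=True)
    out = topology.copy()
    for (u, v), ln in zip(edges_sorted, x):
        out.adj[u][v] = out.adj[v][u] = float(ln)
    return out


def _eval_topology(
    topology: PhyloTree, D: np.ndarray, order: list[str], w, iu, exact: bool = True
) -> float:
    A, _ = _incidence_system(topology, order)
    _, obj = _solve_lengths(A, D[iu], w, exact=exact)
    return obj


def _refit_lengths(
    tree: PhyloTree, D: np.ndarray, order: list[str], w, iu, exact: bool
) -> PhyloTree:
    A, edges_sorted = _incidence_system(tree, order)
    x, _ = _solve_lengths(A, D[iu], w, exact=exact)
    out = tree.copy()
    for (u, v), ln in zip(edges_sorted, np.maximum(x, 0.0)):
        out.adj[u][v] = out.adj[v][u] = float(ln)
    return out


def _node_leaf_dists(tree: PhyloTree, leaf_order: list[str]) -> dict[int, np.ndarray]:
    """Path distance from every node to every leaf (leaves in given order)."""
    out = {node: np.zeros(len(leaf_order)) for node in tree.adj}
    node_of = {lab: n for n, lab in tree.leaves.items()}
    for li, lab in enumerate(leaf_order):
        start = node_of[lab]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            xn = stack.pop()
            for y, ln in tree.adj[xn].items():
                if y not in dist:
                    dist[y] = dist[xn] + ln
                    stack.append(y)
        for node, dv in dist.items():
            out[node][li] = dv
    return out


# ---------------------------------------------------------------------------
# topology search


def _star_tree(labels: list[str]) -> PhyloTree:
    center = 0
    adj: dict[int, dict[int, float]] = {0: {}}
    leaves = {}
    for k, lab in enumerate(labels, start=1):
        adj[center][k] = 1.0
        adj[k] = {center: 1.0}
        leaves[k] = lab
    return PhyloTree(adj, leaves)


def _attach_leaf(tree: PhyloTree, edge: tuple[int, int], label: str) -> PhyloTree:
    """New tree with ``label`` attached to the midpoint of ``edge``."""
    t = tree.copy()
    u, v = edge
    new_internal = max(t.adj) + 1
    new_leaf = new_internal + 1
    ln = t.adj[u][v]
    del t.adj[u][v]
    del t.adj[v][u]
    t.adj[new_internal] = {u: ln / 2, v: ln / 2, new_leaf: 1.0}
    t.adj[u][new_internal] = ln / 2
    t.adj[v][new_internal] = ln / 2
    t.adj[new_leaf] = {new_internal: 1.0}
    t.leaves[new_leaf] = label
    return t


def _nni_at_edge(tree: PhyloTree, u: int, v: int):
    """Yield the two NNI rearrangements of the internal edge (u, v)."""
    u_nb = [x for x in tree.adj[u] if x != v]
    v_nb = [x for x in tree.adj[v] if x != u]
    if len(u_nb) != 2 or len(v_nb) != 2:
        return  # only binary internal edges are rearranged
    a = u_nb[1]
    for b in v_nb:
        t = tree.copy()
        la = t.adj[u].pop(a)
        t.adj[a].pop(u)
        lb = t.adj[v].pop(b)
        t.adj[b].pop(v)
        t.adj[u][b] = t.adj[b][u] = lb
        t.adj[v][a] = t.adj[a][v] = la
        yield t


def _nni_neighbors(tree: PhyloTree):
    """Yield all NNI rearrangements of every internal edge."""
    for u, v in tree.edges():
        if u in tree.leaves or v in tree.leaves:
            continue
        yield from _nni_at_edge(tree, u, v)


def fitch_tree(
    dm,
    power: float = 2.0,
    n_restarts: int = 10,
    seed: int = 1729,
) -> PhyloTree:
    """Fitch–Margoliash tree search: stepwise addition + NNI hill climbing.

    Each restart shuffles the taxon addition order (seeded; the shuffle acts
    on the canonical sorted label order, so the result is invariant to the
    input matrix's label ordering); taxa are added at the least-squares-best
    edge, then NNI moves are applied while they strictly decrease the
    objective.  The best restart's tree, with non-negative least-squares
    branch lengths, is returned.  Deterministic given ``seed``.
    """
    _check_degenerate(dm)
    order = sorted(dm.labels)
    n = len(order)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    idx = [dm.labels.index(l) for l in order]
    D = dm.d[np.ix_(idx, idx)]
    iu = np.triu_indices(n, 1)
    w_full = _fm_weights(D, power)

    exact = n <= 10  # exact NNLS scoring at small n; unconstrained bound above
    best_tree = None
    best_obj = np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        add_order = list(order)
        if r > 0:
            rng.shuffle(add_order)
        tree = _build_stepwise(add_order, D, order, power, exact)
        tree, obj = _nni_search(tree, D, order, power, exact)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_tree = tree

    return ls_branch_lengths(best_tree, dm, power=power)


def _sub_system(D: np.ndarray, order: list[str], subset: list[str], power: float):
    pos = {l: i for i, l in enumerate(order)}
    idx = [pos[l] for l in sorted(subset)]
    Ds = D[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    return Ds, sorted(subset), _fm_weights(Ds, power), iu


def _score_placement(ndist, edge_len, on_u, dL, w):
    """Weighted LS misfit of attaching a new leaf along one edge.

    Two free parameters: the attachment position along the edge and the
    pendant branch length (box-constrained); existing branch lengths stay
    fixed, so comparing this score across edges ranks placements.
    """
    du, dv = ndist
    c = np.where(on_u, du, dv + edge_len)
    s = np.where(on_u, 1.0, -1.0)
    y = dL - c
    # solve min sum w (y - s*beta - e)^2 over beta in [0, edge_len], e >= 0
    sw = w
    S11 = float(np.sum(sw))
    Ss = float(np.sum(sw * s))
    Sss = S11  # s^2 == 1
    Sy = float(np.sum(sw * y))
    Ssy = float(np.sum(sw * s * y))
    det = Sss * S11 - Ss * Ss
    if det > 1e-14:
        beta = (Ssy * S11 - Ss * Sy) / det
        e = (Sy * Sss - Ss * Ssy) / det
    else:
        beta, e = 0.0, Sy / S11 if S11 > 0 else 0.0

    def clamped(beta, e):
        return min(max(beta, 0.0), edge_len), max(e, 0.0)

    candidates = [clamped(beta, e)]
    # re-solve with each variable pinned at its bound
    for b_fix in (0.0, edge_len):
        e_fix = (Sy - b_fix * Ss) / S11 if S11 > 0 else 0.0
        candidates.append(clamped(b_fix, e_fix))
    e0 = 0.0
    b_free = Ssy / Sss if Sss > 0 else 0.0
    candidates.append(clamped(b_free, e0))
    best = np.inf
    for b, e in candidates:
        r = y - s * b - e
        best = min(best, float(np.sum(sw * r * r)))
    return best


def _build_stepwise(add_order, D, order, power, exact):
    pos = {l: i for i, l in enumerate(order)}
    tree = _star_tree(sorted(add_order[:3]))
    # fit the initial triplet exactly
    sub = sorted(add_order[:3])
    Ds, sub_order, w, iu = _sub_system(D, order, sub, power)
    tree = _refit_lengths(tree, Ds, sub_order, w, iu, exact=True)
    for k in range(3, len(add_order)):
        label = add_order[k]
        placed = sorted(add_order[:k])
        dL = np.array([D[pos[label], pos[l]] for l in placed])
        wL = _fm_weights_vector(dL, power)
        ndist = _node_leaf_dists(tree, placed)
        best = (np.inf, None)
        for u, v in tree.edges():
            on_u = ndist[u] < ndist[v]
            score = _score_placement(
                (ndist[u], ndist[v]), tree.adj[u][v], on_u, dL, wL
            )
            if score < best[0] - 1e-12:
                best = (score, (u, v))
        tree = _attach_leaf(tree, best[1], label)
        subset = add_order[: k + 1]
        Ds, sub_order, w, iu = _sub_system(D, order, subset, power)
        tree = _refit_lengths(tree, Ds, sub_order, w, iu, exact=exact)
    return tree


def _fm_weights_vector(d: np.ndarray, power: float) -> np.ndarray:
    d = d.copy()
    pos = d[d > 0]
    if len(pos) == 0:
        return np.ones_like(d)
    eps = pos.min() / 10.0
    d[d <= 0] = eps
    return d ** (-power)


def _nni_search(tree, D, order, power, exact):
    """First-improvement NNI scan, repeated until a full pass changes nothing."""
    w = _fm_weights(D, power)
    iu = np.triu_indices(len(order), 1)
    cur_obj = _eval_topology(tree, D, order, w, iu, exact=exact)
    improved = True
    while improved:
        improved = False
        for u, v in tree.edges():
            if (
                u in tree.leaves or v in tree.leaves
                or v not in tree.adj.get(u, {})
            ):
                continue
            for cand in _nni_at_edge(tree, u, v):
                obj = _eval_topology(cand, D, order, w, iu, exact=exact)
                if obj < cur_obj - 1e-10:
                    cur_obj, tree = obj, cand
                    improved = True
                    break
    return tree, cur_obj


# ---------------------------------------------------------------------------
# tree comparison and enumeration


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions (even, >= 0)."""
    if set(t1.labels) != set(t2.labels):
        raise ValueError("trees have different leaf sets")
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    return len(b1 ^ b2)


def all_topologies(labels: list[str]):
    """Yield every distinct unrooted binary topology on the labels.

    (2n-5)!! trees: 1, 3, 15, 105, ... for n = 3, 4, 5, 6, ...  Unit branch
    lengths; intended for exhaustive-search oracles at small n.
    """
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def rec(tree: PhyloTree, remaining: list[str]):
        if not remaining:
            yield tree
            return
        lab = remaining[0]
        for edge in tree.edges():
            yield from rec(_attach_leaf(tree, edge, lab), remaining[1:])

    yield from rec(_star_tree(labels[:3]), labels[3:])
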