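"""Reconstruct an unweighted graph from printed centrality columns.

The published network is only available as a per-node table of degree,
betweenness and closeness (plus a handful of structural statements in the
text, e.g. that the cortisol-slope node hangs off the sleep node as a
pendant).  This module inverts that table: a pruned backtracking search
enumerates *all* simple labeled graphs whose degree sequence matches the
degree column exactly and whose closeness (or betweenness) column matches
the printed values within a rounding tolerance.  The recovered graph(s)
then serve as a worked in-paper example against which the centrality
implementation is validated.

Conventions mirror :mod:`pnnet.metrics`: closeness is the reciprocal of
the unweighted shortest-path distance sum, betweenness is unnormalized
Brandes counting with each unordered pair counted once.

Search strategy
---------------
Degree-1 (pendant) nodes are eliminated analytically: their single
attachment is enumerated up front, and for a pendant ``p`` attached to
``x`` the identity ``distsum(p) = distsum(x) + n - 2`` propagates the
closeness constraint onto the attachment.  The remaining core is
enumerated by deciding each node's full neighborhood in descending-degree
order, pruned by:

* Erdős–Gallai graphicality of the residual degree sequence;
* per-node distance-sum lower bounds from BFS over the "potential graph"
  (decided edges plus a clique over nodes that can still gain edges) --
  a valid lower bound because future edges can only appear there;
* per-node distance-sum upper bounds from BFS over decided edges alone;
* when the betweenness column is the constraint: zero-betweenness nodes
  must have clique neighborhoods (any non-adjacent neighbor pair would
  contribute at least 1/10 to betweenness on a 12-node graph), and the
  identity ``sum_pairs d(u,v) = sum_v betweenness(v) + C(n,2)`` pins the
  total distance sum exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

from .metrics import centrality_indices, girvan_newman_communities

__all__ = [
    "CentralityConstraints",
    "reconstruct_graph",
    "verify_centrality_table",
    "load_reference_centrality",
    "reference_communities",
    "reference_constraints",
    "REFERENCE_FORCED_EDGES",
]

#: the one edge the accompanying text pins down: the cortisol-slope node is
#: a pendant attached to the sleep node (their negative association).
REFERENCE_FORCED_EDGES = (("sleep", "cortisol_slope"),)

_REFERENCE_COMMUNITIES = (
    frozenset({"sleep", "depression", "anxiety", "oral_pain", "fatigue",
               "cortisol_slope", "crp"}),
    frozenset({"il6", "il10", "tnfa", "age", "bmi"}),
)


@dataclass(frozen=True)
class CentralityConstraints:
    """Target centrality columns for the reconstruction search.

    ``degrees`` is a hard, exact constraint.  At least one of
    ``closeness`` / ``betweenness`` should be given; each is matched
    within its tolerance.  ``communities`` (a partition into node sets),
    when given, requires the modularity-best Girvan-Newman partition of a
    candidate to equal it.
    """

    degrees: dict[str, int]
    closeness: dict[str, float] | None = None
    betweenness: dict[str, float] | None = None
    closeness_tol: float = 0.0015
    betweenness_tol: float = 0.005
    forced_edges: tuple[tuple[str, str], ...] = ()
    communities: tuple[frozenset, ...] | None = None

    def __post_init__(self) -> None:
        if self.closeness_tol < 0 or self.betweenness_tol < 0:
            raise ValueError("tolerances must be non-negative")
        if sum(self.degrees.values()) % 2:
            raise ValueError("degree sum must be even (handshake lemma)")
        n = len(self.degrees)
        for v, d in self.degrees.items():
            if not 0 <= d <= n - 1:
                raise ValueError(f"degree of {v} out of range")
        for a, b in self.forced_edges:
            if a not in self.degrees or b not in self.degrees:
                raise ValueError(f"forced edge ({a}, {b}) names unknown node")
            if a == b:
                raise ValueError("self-loops are not allowed")
        for column in (self.closeness, self.betweenness):
            if column is not None:
                unknown = set(column) - set(self.degrees)
                if unknown:
                    raise ValueError(f"targets for unknown nodes {unknown}")


def _admissible_distsums(c: float, tol: float, n: int) -> set[int]:
    # distance sums over n-1 other nodes range from n-1 to ~ (n-1)n/2
    hi = (n - 1) * n // 2 + n
    return {s for s in range(n - 1, hi + 1) if abs(1.0 / s - c) <= tol + 1e-12}


def _erdos_gallai(seq: list[int]) -> bool:
    seq = sorted(seq, reverse=True)
    if sum(seq) % 2:
        return False
    n = len(seq)
    pre = 0
    for k in range(1, n + 1):
        pre += seq[k - 1]
        rhs = k * (k - 1) + sum(min(seq[i], k) for i in range(k, n))
        if pre > rhs:
            return False
    return True


def _bfs(adj: list[int], v: int, full: int, extra_mask: int = 0) -> tuple[int, int]:
    """(reached mask, distance sum) of BFS from v over bitmask adjacency.

    Nodes in ``extra_mask`` are treated as mutually adjacent on top of
    ``adj`` (the potential-edge clique used for lower bounds).
    """
    seen = 1 << v
    frontier = seen
    total = 0
    d = 0
    while frontier:
        d += 1
        nxt = 0
        f = frontier
        while f:
            u = (f & -f).bit_length() - 1
            f &= f - 1
            nxt |= adj[u]
            if extra_mask and (extra_mask >> u) & 1:
                nxt |= extra_mask
        nxt &= ~seen & full
        total += d * nxt.bit_count()
        seen |= nxt
        frontier = nxt
    return seen, total


def reconstruct_graph(
    constraints: CentralityConstraints,
    max_solutions: int | None = None,
) -> list[nx.Graph]:
    """All simple labeled graphs satisfying the centrality constraints.

    Returns a (possibly empty) list of connected ``networkx`` graphs,
    deduplicated by edge set.  Only connected solutions are considered,
    since the closeness column of the reference table is finite for every
    node.
    """
    labels = sorted(constraints.degrees)
    n = len(labels)
    idx = {v: i for i, v in enumerate(labels)}
    deg = [constraints.degrees[v] for v in labels]
    full = (1 << n) - 1

    clos = constraints.closeness
    btw = constraints.betweenness
    if clos is None and btw is None:
        raise ValueError("need a closeness or betweenness column to constrain the search")

    dom = dmin = dmax = None
    if clos is not None:
        dom = [_admissible_distsums(clos[v], constraints.closeness_tol, n) for v in labels]
        if any(not d for d in dom):
            return []
        dmin = [min(d) for d in dom]
        dmax = [max(d) for d in dom]

    target_distsum = None
    zero_b: list[int] = []
    if btw is not None:
        if set(btw) == set(labels):
            # sum over pairs of d(u,v) = sum of betweenness + #pairs
            tot = sum(btw.values())
            slack = n * constraints.betweenness_tol
            cands = [
                s for s in range(int(tot - slack) + n * (n - 1) // 2 - 1,
                                 int(tot + slack) + n * (n - 1) // 2 + 2)
                if abs(s - (tot + n * (n - 1) / 2)) <= slack + 1e-9
            ]
            if len(cands) == 1:
                target_distsum = 2 * cands[0]
        zero_b = [
            i for i, v in enumerate(labels)
            if deg[i] >= 2 and btw.get(v, 1.0) <= constraints.betweenness_tol
        ]

    # pendant elimination
    pendants = [i for i in range(n) if deg[i] == 1]
    forced: dict[tuple[int, int], bool] = {}
    for a, b in constraints.forced_edges:
        ia, ib = idx[a], idx[b]
        forced[(min(ia, ib), max(ia, ib))] = True
    forced_nb: dict[int, int] = {}
    for (ia, ib) in forced:
        if ia in pendants:
            forced_nb[ia] = ib
        if ib in pendants:
            forced_nb[ib] = ia
    free_pendants = [p for p in pendants if p not in forced_nb]
    core = [i for i in range(n) if i not in pendants]

    solutions: dict[frozenset, nx.Graph] = {}

    def leaf_check(adj: list[int]) -> None:
        seen, _ = _bfs(adj, 0, full)
        if seen != full:
            return
        ds = [_bfs(adj, v, full)[1] for v in range(n)]
        if dom is not None and any(ds[v] not in dom[v] for v in range(n)):
            return
        if target_distsum is not None and sum(ds) != target_distsum:
            return
        edges = frozenset(
            (min(u, v), max(u, v))
            for v in range(n)
            for u in range(n)
            if (adj[v] >> u) & 1
        )
        if edges in solutions:
            return
        G = nx.Graph()
        G.add_nodes_from(labels)
        G.add_edges_from((labels[a], labels[b]) for a, b in edges)
        if btw is not None:
            bc = nx.betweenness_centrality(G, normalized=False)
            if any(
                abs(bc[v] - t) > constraints.betweenness_tol + 1e-9
                for v, t in btw.items()
            ):
                return
        if constraints.communities is not None:
            part = set(girvan_newman_communities(G).communities)
            if part != set(constraints.communities):
                return
        solutions[edges] = G

    def attach_and_search(attach: dict[int, int]) -> None:
        adj = [0] * n
        resid = deg[:]
        for p, x in attach.items():
            if (adj[p] >> x) & 1 or resid[x] <= 0:
                return
            adj[p] |= 1 << x
            adj[x] |= 1 << p
            resid[p] -= 1
            resid[x] -= 1
        if dom is not None:
            for p, x in attach.items():
                shifted = {s - (n - 2) for s in dom[p]}
                if not shifted & set(range(dmin[x], dmax[x] + 1)):
                    return
        order = sorted(core, key=lambda i: (-resid[i], i))
        pos = {v: k for k, v in enumerate(order)}

        def feasible(k: int) -> bool:
            rem = [resid[u] for u in order[k + 1:]]
            if rem and not _erdos_gallai(rem):
                return False
            rmask = 0
            for u in order[k + 1:]:
                if resid[u] > 0:
                    rmask |= 1 << u
            for z in zero_b:
                m = adj[z]
                nbrs = []
                while m:
                    u = (m & -m).bit_length() - 1
                    m &= m - 1
                    nbrs.append(u)
                for a, b in itertools.combinations(nbrs, 2):
                    ep = a if pos.get(a, n) < pos.get(b, n) else b
                    if pos.get(ep, n) <= k and not (adj[a] >> b) & 1:
                        return False
            if dom is not None:
                for kk in range(k + 1):
                    w = order[kk]
                    seen, lb = _bfs(adj, w, full, rmask)
                    if seen != full:
                        return False
                    if lb > dmax[w]:
                        return False
                    seen_ub, ub = _bfs(adj, w, full)
                    if seen_ub == full and ub < dmin[w]:
                        return False
            if target_distsum is not None:
                lbsum = 0
                ubsum = 0
                conn = True
                for w in range(n):
                    seen, lb = _bfs(adj, w, full, rmask)
                    if seen != full:
                        return False
                    lbsum += lb
                    seen_ub, ub = _bfs(adj, w, full)
                    if seen_ub == full:
                        ubsum += ub
                    else:
                        conn = False
                if lbsum > target_distsum:
                    return False
                if conn and ubsum < target_distsum:
                    return False
            return True

        def rec(k: int) -> None:
            if max_solutions is not None and len(solutions) >= max_solutions:
                return
            if k == len(order):
                leaf_check(adj)
                return
            v = order[k]
            need = resid[v]
            cands = [
                u for u in order[k + 1:]
                if resid[u] > 0 and not (adj[v] >> u) & 1
            ]
            if need > len(cands):
                return
            for combo in itertools.combinations(cands, need):
                for u in combo:
                    adj[v] |= 1 << u
                    adj[u] |= 1 << v
                    resid[u] -= 1
                saved = resid[v]
                resid[v] = 0
                if feasible(k):
                    rec(k + 1)
                resid[v] = saved
                for u in combo:
                    adj[v] &= ~(1 << u)
                    adj[u] &= ~(1 << v)
                    resid[u] += 1

        # forced non-pendant edges are seeded before the search
        for (ia, ib) in forced:
            if ia in attach or ib in attach or (ia in forced_nb) or (ib in forced_nb):
                continue
            if not (adj[ia] >> ib) & 1:
                adj[ia] |= 1 << ib
                adj[ib] |= 1 << ia
                resid[ia] -= 1
                resid[ib] -= 1
                if resid[ia] < 0 or resid[ib] < 0:
                    return
        rec(0)

    if n == 2 and deg == [1, 1]:
        attach_and_search({0: 1})
        return list(solutions.values())

    if free_pendants:
        for combo in itertools.product(core, repeat=len(free_pendants)):
            attach = dict(forced_nb)
            attach.update(dict(zip(free_pendants, combo)))
            attach_and_search(attach)
            if max_solutions is not None and len(solutions) >= max_solutions:
                break
    else:
        attach_and_search(dict(forced_nb))
    return list(solutions.values())


def verify_centrality_table(
    graph: nx.Graph,
    reference: pd.DataFrame,
    tolerances: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Cell-by-cell comparison of a graph's centralities with a reference.

    ``reference`` is indexed by node with columns degree / betweenness /
    closeness.  Default tolerances: degree exact, betweenness ±0.005,
    closeness ±0.0015 (one rounding step loose).  The returned frame has
    one row per (node, index) cell with computed and reference values and
    a ``passed`` flag; the frame's ``.attrs["passed"]`` is the overall
    verdict.
    """
    tol = {"degree": 0.0, "betweenness": 0.005, "closeness": 0.0015}
    if tolerances:
        tol.update(tolerances)
    if set(graph.nodes) != set(reference.index):
        raise ValueError("graph nodes and reference labels do not match")
    computed = centrality_indices(graph)
    rows = []
    for v in reference.index:
        for col in ("degree", "betweenness", "closeness"):
            got = float(computed.loc[v, col])
            want = float(reference.loc[v, col])
            rows.append(
                {
                    "node": v,
                    "index": col,
                    "computed": got,
                    "reference": want,
                    "passed": abs(got - want) <= tol[col] + 1e-12,
                }
            )
    report = pd.DataFrame(rows)
    report.attrs["passed"] = bool(report["passed"].all())
    return report


def load_reference_centrality() -> pd.DataFrame:
    """The packaged published centrality table (degree/betweenness/closeness)."""
    with resources.files("pnnet.data").joinpath("reference_centrality.csv").open() as fh:
        table = pd.read_csv(fh)
    return table.set_index("node")


def reference_communities() -> tuple[frozenset, ...]:
    """The two published community memberships."""
    return _REFERENCE_COMMUNITIES


def reference_constraints(
    use: str = "closeness",
    communities: bool = False,
    forced_edges: tuple[tuple[str, str], ...] = REFERENCE_FORCED_EDGES,
) -> CentralityConstraints:
    """Constraints built from the packaged reference table.

    ``use="closeness"`` constrains degree + closeness (betweenness
    withheld); ``use="betweenness"`` constrains degree + betweenness
    (closeness withheld).  ``communities=True`` additionally requires the
    published two-cluster memberships.
    """
    table = load_reference_centrality()
    degrees = {v: int(table.loc[v, "degree"]) for v in table.index}
    kwargs = dict(degrees=degrees, forced_edges=tuple(forced_edges))
    if use == "closeness":
        kwargs["closeness"] = {v: float(table.loc[v, "closeness"]) for v in table.index}
    elif use == "betweenness":
        kwargs["betweenness"] = {v: float(table.loc[v, "betweenness"]) for v in table.index}
    else:
        raise ValueError("use must be 'closeness' or 'betweenness'")
    if communities:
        kwargs["communities"] = reference_communities()
    return CentralityConstraints(**kwargs)
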