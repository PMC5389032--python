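"""Random-walk (walktrap) community detection with max-modularity cut selection.

The detector follows the classic walktrap heuristic: short random walks of
length ``t`` (default 3) probe the neighborhood of each node, nodes with
similar t-step visit profiles are agglomerated Ward-style into communities,
and the dendrogram level maximizing Newman's modularity

    Q = sum over modules m of (e_mm - a_m^2)

is reported, where e_mm is the fraction of edges inside module m and a_m the
fraction of edge endpoints in m.  Q > 0 means more within-module connectivity
than expected in a random network with the same degree sequence; strongly
modular networks typically score 0.3-0.7.

Everything here is deterministic: the walk probabilities are exact matrix
powers, not sampled walks, and all tie-breaks are fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .network_model import AnatomicalNetwork, InputError

_TIE_EPS = 1e-12


class ParameterError(ValueError):
    """An out-of-range algorithm parameter."""


@dataclass(frozen=True)
class WalkProfile:
    """Exact t-step random-walk transition probabilities on the walk-eligible nodes.

    The walk is lazy, as in the canonical walktrap formulation: every node
    carries an implicit self-loop, so one step from a node of degree d goes to
    itself or to each neighbor with probability 1/(d+1).  Laziness makes the
    walk aperiodic; without it, near-bipartite regions alias at odd/even walk
    lengths and the profiles misrank community candidates.  The profile
    composes the one-step rule ``t`` times (row ``i`` of ``probabilities`` is
    the distribution of a length-t walk started at node ``nodes[i]``).  Only
    nodes of degree >= 1 are walk-eligible; isolates carry no walk information.
    ``degrees`` stores the lazy-walk degree d+1 used to weight distances.
    """

    t: int
    nodes: tuple[int, ...]
    probabilities: np.ndarray  # (n, n), rows sum to 1
    degrees: np.ndarray        # (n,), lazy-walk degree d+1

    def index_of(self, node_id: int) -> int:
        try:
            return self.nodes.index(node_id)
        except ValueError:
            raise ParameterError(f"node {node_id} is isolated or unknown") from None


@dataclass(frozen=True)
class MergeTree:
    """Agglomeration history: communities 0..leaf_count-1 are the walk-eligible
    nodes in ascending id order; merge ``i`` consumes two community ids and
    creates community ``leaf_count + i``.  A connected component of n nodes
    contributes n-1 merges; components never merge with each other."""

    merges: tuple[tuple[int, int, float], ...]
    leaf_count: int
    nodes: tuple[int, ...]  # walk-eligible node per leaf community id


@dataclass(frozen=True)
class Partition:
    """A node -> module assignment with its modularity breakdown.

    ``module_fractions`` maps each module label to ``(e_mm, a_m)``; ``Q`` is
    the stored modularity, always recomputable from ``assignments`` plus the
    network; ``M`` counts modules excluding flagged isolate singletons.
    """

    assignments: dict[int, int]
    module_fractions: dict[int, tuple[float, float]]
    Q: float
    M: int
    isolates: frozenset[int] = frozenset()

    def modules(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for node, mod in self.assignments.items():
            out.setdefault(mod, set()).add(node)
        return out

    def module_sizes(self) -> dict[int, int]:
        return {m: len(v) for m, v in self.modules().items()}


# ---------------------------------------------------------------------------
# walk profiles and distances
# ---------------------------------------------------------------------------

def transition_profile(network: AnatomicalNetwork, t: int = 3) -> WalkProfile:
    """Exact t-step lazy-walk transition probabilities for every walk-eligible node."""
    if t < 1:
        raise ParameterError(f"walk length must be >= 1, got {t}")
    g = network.graph
    nodes = sorted(n for n in g if g.degree(n) >= 1)
    if not nodes:
        raise InputError("network has no edges: all nodes are isolated")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    P = np.zeros((n, n))
    for u in nodes:
        i = index[u]
        step = 1.0 / (g.degree(u) + 1)  # +1: implicit self-loop (lazy walk)
        P[i, i] = step
        for v in g.neighbors(u):
            P[i, index[v]] = step
    Pt = np.linalg.matrix_power(P, t)
    degrees = np.array([g.degree(u) + 1 for u in nodes], dtype=float)
    return WalkProfile(t=t, nodes=tuple(nodes), probabilities=Pt, degrees=degrees)


def vertex_distance(profile: WalkProfile, i: int, j: int) -> float:
    """Degree-weighted Euclidean distance between two nodes' walk profiles.

    r_ij = sqrt( sum_k (p_ik - p_jk)^2 / degree(k) ), with degree(k) the
    lazy-walk degree d(k)+1; nodes whose walks spread over the same
    neighborhoods at the same rates are close.
    """
    a, b = profile.index_of(i), profile.index_of(j)
    diff = profile.probabilities[a] - profile.probabilities[b]
    return float(np.sqrt(np.sum(diff * diff / profile.degrees)))


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

def walktrap_merge_tree(network: AnatomicalNetwork, t: int = 3) -> MergeTree:
    """Ward-style agglomeration of walk profiles over edge-adjacent communities.

    Starting from singletons, repeatedly merge the edge-adjacent community pair
    with minimal cost

        dsigma(C1, C2) = (1/n) * |C1||C2| / (|C1|+|C2|) * r^2(C1, C2),

    where a community's profile is the mean of its members' profiles, r is the
    degree-weighted Euclidean distance between community profiles, and n is the
    walk-eligible size of the connected component.  Costs of merged communities
    to bystanders follow the Lance-Williams Ward update; a pair that first
    becomes edge-adjacent after a merge gets its cost directly from the stored
    mean profiles (algebraically the same quantity).  Equal-cost candidates are
    broken toward the lexicographically smallest (min id, max id) pair.
    """
    profile = transition_profile(network, t)
    nodes = profile.nodes
    index = {n: i for i, n in enumerate(nodes)}
    # transform coordinates so community distance is plain Euclidean
    Y = profile.probabilities / np.sqrt(profile.degrees)[None, :]

    g = network.graph
    comp_size: dict[int, int] = {}
    for comp in nx.connected_components(g.subgraph(nodes)):
        for u in comp:
            comp_size[u] = len(comp)

    # live community state
    size = {c: 1 for c in range(len(nodes))}
    centroid = {c: Y[c].copy() for c in range(len(nodes))}
    norm = {c: 1.0 / comp_size[nodes[c]] for c in range(len(nodes))}
    adjacency: dict[int, set[int]] = {c: set() for c in range(len(nodes))}
    for u, v in g.edges(nodes):
        cu, cv = index[u], index[v]
        adjacency[cu].add(cv)
        adjacency[cv].add(cu)

    def direct_cost(a: int, b: int) -> float:
        d = centroid[a] - centroid[b]
        r2 = float(d @ d)
        return norm[a] * size[a] * size[b] / (size[a] + size[b]) * r2

    costs: dict[tuple[int, int], float] = {}
    for a in adjacency:
        for b in adjacency[a]:
            if a < b:
                costs[(a, b)] = direct_cost(a, b)

    merges: list[tuple[int, int, float]] = []
    next_id = len(nodes)
    while costs:
        # gather near-minimal pairs (float-jitter tolerant), pick smallest ids
        best_cost = min(costs.values())
        tied = [p for p, c in costs.items() if c <= best_cost + _TIE_EPS]
        a, b = min(tied)
        cost_ab = costs.pop((a, b))
        merges.append((a, b, cost_ab))

        new = next_id
        next_id += 1
        sa, sb = size[a], size[b]
        size[new] = sa + sb
        centroid[new] = (sa * centroid[a] + sb * centroid[b]) / (sa + sb)
        norm[new] = norm[a]
        neighbors = (adjacency[a] | adjacency[b]) - {a, b}
        adjacency[new] = neighbors
        for c in neighbors:
            adjacency[c].discard(a)
            adjacency[c].discard(b)
            adjacency[c].add(new)
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            if key_ac in costs and key_bc in costs:
                sc = size[c]
                cost = (
                    (sa + sc) * costs[key_ac]
                    + (sb + sc) * costs[key_bc]
                    - sc * cost_ab
                ) / (sa + sb + sc)
            else:
                cost = direct_cost(new, c)
            costs.pop(key_ac, None)
            costs.pop(key_bc, None)
            costs[(min(new, c), max(new, c))] = cost
        for state in (size, centroid, norm, adjacency):
            state.pop(a, None)
            state.pop(b, None)

    return MergeTree(merges=tuple(merges), leaf_count=len(nodes), nodes=nodes)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity(
    network: AnatomicalNetwork, assignments: Mapping[int, int]
) -> Partition:
    """Newman modularity Q = sum_m (e_mm - a_m^2) of a node -> module mapping.

    e_mm is the fraction of edges with both endpoints in module m; a_m is the
    fraction of edge endpoints falling in m.  Isolated nodes contribute
    e = a = 0 and may be left unassigned; an unassigned non-isolated node is
    an error.
    """
    g = network.graph
    m_edges = g.number_of_edges()
    if m_edges == 0:
        raise InputError("modularity is undefined on an edgeless network")
    isolated = network.isolates()
    for node in g:
        if node not in assignments and node not in isolated:
            raise InputError(f"non-isolated node {node} has no module assignment")

    labels = sorted({assignments[n] for n in g if n in assignments})
    within = dict.fromkeys(labels, 0)
    endpoints = dict.fromkeys(labels, 0)
    for u, v in g.edges:
        mu, mv = assignments[u], assignments[v]
        endpoints[mu] += 1
        endpoints[mv] += 1
        if mu == mv:
            within[mu] += 1
    fractions = {
        m: (within[m] / m_edges, endpoints[m] / (2 * m_edges)) for m in labels
    }
    q = sum(e - a * a for e, a in fractions.values())
    return Partition(
        assignments={n: assignments[n] for n in g if n in assignments},
        module_fractions=fractions,
        Q=float(q),
        M=len(labels),
    )


def _tree_levels(tree: MergeTree):
    """Yield (k, membership dict community->module index) for each dendrogram level."""
    parent = {c: c for c in range(tree.leaf_count)}

    def root(c: int) -> int:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    assignment = {tree.nodes[c]: c for c in range(tree.leaf_count)}
    yield tree.leaf_count, dict(assignment)
    next_id = tree.leaf_count
    for a, b, _ in tree.merges:
        new = next_id
        next_id += 1
        parent[a] = parent[b] = parent.setdefault(new, new)
        for node in assignment:
            assignment[node] = root(assignment[node])
        k = len(set(assignment.values()))
        yield k, dict(assignment)


def modularity_curve(
    network: AnatomicalNetwork, tree: MergeTree
) -> list[tuple[int, float]]:
    """(number of modules, Q) at every agglomeration level, singletons first.

    Module counts cover walk-eligible communities only; isolates contribute
    nothing to Q and are not counted.
    """
    _check_tree(network, tree)
    return [
        (k, modularity(network, member).Q) for k, member in _tree_levels(tree)
    ]


def _check_tree(network: AnatomicalNetwork, tree: MergeTree) -> None:
    eligible = tuple(sorted(n for n in network.graph if network.graph.degree(n) >= 1))
    if eligible != tree.nodes:
        raise InputError("merge tree does not match the network's walk-eligible nodes")


def best_partition(network: AnatomicalNetwork, tree: MergeTree) -> Partition:
    """The dendrogram cut with maximal Q; ties broken toward fewer modules.

    Isolated nodes are appended as flagged singleton modules and excluded from
    the reported module count M.
    """
    _check_tree(network, tree)
    best: tuple[int, dict[int, int]] | None = None
    best_q = -np.inf
    for k, member in _tree_levels(tree):
        q = modularity(network, member).Q
        if q > best_q + _TIE_EPS or (q >= best_q - _TIE_EPS and best is not None
                                     and k < best[0]):
            best_q, best = q, (k, member)
    assert best is not None
    _, member = best
    return _finalize_partition(network, member)


def _finalize_partition(
    network: AnatomicalNetwork, member: Mapping[int, int]
) -> Partition:
    """Relabel modules 1..M by smallest member id; append flagged isolates."""
    groups: dict[int, list[int]] = {}
    for node, mod in member.items():
        groups.setdefault(mod, []).append(node)
    ordered = sorted(groups.values(), key=min)
    assignments = {
        node: label for label, nodes in enumerate(ordered, start=1) for node in nodes
    }
    m_real = len(ordered)
    isolated = sorted(network.isolates())
    for offset, node in enumerate(isolated, start=1):
        assignments[node] = m_real + offset
    part = modularity(network, assignments)
    return Partition(
        assignments=part.assignments,
        module_fractions=part.module_fractions,
        Q=part.Q,
        M=m_real,
        isolates=frozenset(isolated),
    )


def detect_modules(network: AnatomicalNetwork, t: int = 3) -> Partition:
    """Full detection pipeline: walk profiles -> agglomeration -> max-Q cut."""
    if network.n_edges == 0:
        raise InputError("cannot detect modules in an edgeless network")
    tree = walktrap_merge_tree(network, t)
    return best_partition(network, tree)


# ---------------------------------------------------------------------------
# exhaustive oracle for small graphs
# ---------------------------------------------------------------------------

def _set_partition_assignments(n: int):
    """All set partitions of range(n) as restricted-growth assignment tuples."""
    a = [0] * n
    m = [0] * n  # m[i] = max(a[:i+1])
    while True:
        yield tuple(a)
        for i in range(n - 1, 0, -1):
            if a[i] <= m[i - 1]:
                a[i] += 1
                m[i] = max(m[i - 1], a[i])
                for j in range(i + 1, n):
                    a[j] = 0
                    m[j] = m[i]
                break
        else:
            return


def brute_force_max_modularity(network: AnatomicalNetwork) -> Partition:
    """Globally Q-maximal partition by exhaustive enumeration (<= 12 active nodes).

    Ties go to fewer modules, then to the lexicographically smallest canonical
    assignment.  Intended as a test oracle; Bell(12) ~ 4.2e6 partitions is the
    practical ceiling.
    """
    if network.n_edges == 0:
        raise InputError("modularity is undefined on an edgeless network")
    active = sorted(n for n in network.graph if network.graph.degree(n) >= 1)
    if len(active) > 12:
        raise ParameterError(
            f"{len(active)} non-isolated nodes exceeds the exhaustive limit of 12"
        )
    edges = [
        (active.index(u), active.index(v))
        for u, v in network.graph.edges(active)
    ]
    m_edges = len(edges)
    degree = [0] * len(active)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1

    best_q = -np.inf
    best_assign: tuple[int, ...] | None = None
    best_k = None
    for assign in _set_partition_assignments(len(active)):
        k = max(assign) + 1
        within = [0] * k
        for u, v in edges:
            if assign[u] == assign[v]:
                within[assign[u]] += 1
        ends = [0] * k
        for i, mod in enumerate(assign):
            ends[mod] += degree[i]
        q = sum(
            w / m_edges - (e / (2 * m_edges)) ** 2 for w, e in zip(within, ends)
        )
        if (
            q > best_q + _TIE_EPS
            or (abs(q - best_q) <= _TIE_EPS and (k, assign) < (best_k, best_assign))
        ):
            best_q, best_assign, best_k = q, assign, k
    member = {node: best_assign[i] for i, node in enumerate(active)}
    return _finalize_partition(network, member)
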