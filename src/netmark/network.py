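"""Rooted phylogenetic networks with branch lengths, per-branch population
mutation rates, and inheritance probabilities.

A phylogenetic network here is a rooted DAG whose leaves are bijectively
labeled by taxa.  Nodes of in-degree 2 are reticulation (hybridization)
nodes and carry an inheritance probability ``gamma`` on each incoming edge
(the pair sums to 1).  Every edge has a length ``tau`` in expected mutations
per site and a population mutation rate ``theta`` (= 4N mu) per site; a
branch of length tau spans ``2 tau / theta`` coalescent units.  An implicit
infinite branch above the root carries its own theta (``root_theta``) so
that all lineages eventually coalesce.

The serialization dialect is a "rich Newick": each node is written as
``name:length:theta`` with a fourth ``:gamma`` field on reticulation edges,
reticulation nodes appear twice joined by a shared ``#H<i>`` tag, and an
optional leading ``[theta]`` gives the root-branch theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Edge",
    "PhyloNetwork",
    "Diagnostics",
    "parse_rich_newick",
    "write_rich_newick",
    "validate_network",
    "find_lowest_articulation_nodes",
    "reticulation_diameter",
    "backbone_tree",
    "rf_distance",
    "networks_isomorphic",
    "random_network",
]

GAMMA_TOL = 1e-9
TIME_TOL = 1e-9


@dataclass
class Edge:
    """Parameters of one directed branch (parent -> child)."""

    length: float
    theta: float
    gamma: float | None = None  # set only on reticulation edges


@dataclass
class Diagnostics:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


class NetworkError(ValueError):
    pass


class PhyloNetwork:
    """A rooted phylogenetic network.

    Nodes are stable small integers.  ``children``/``parents`` hold the
    adjacency, ``edges`` maps ``(parent, child)`` to :class:`Edge`, and
    ``labels`` maps leaf ids to taxon names (internal nodes may carry
    display names too).  Node heights (divergence times above the leaves,
    same units as branch lengths) are kept in ``heights`` when available;
    branch lengths are the primary storage and heights are derived.
    """

    def __init__(self) -> None:
        self.children: dict[int, list[int]] = {}
        self.parents: dict[int, list[int]] = {}
        self.edges: dict[tuple[int, int], Edge] = {}
        self.labels: dict[int, str] = {}
        self.root_theta: float = 0.005
        self.heights: dict[int, float] = {}
        self._next_id = 0

    # ------------------------------------------------------------------ #
    # construction primitives
    # ------------------------------------------------------------------ #
    def new_node(self, label: str | None = None) -> int:
        v = self._next_id
        self._next_id += 1
        self.children[v] = []
        self.parents[v] = []
        if label:
            self.labels[v] = label
        return v

    def add_edge(self, u: int, v: int, length: float = 0.0,
                 theta: float = 0.005, gamma: float | None = None) -> None:
        self.children[u].append(v)
        self.parents[v].append(u)
        self.edges[(u, v)] = Edge(length, theta, gamma)

    def remove_edge(self, u: int, v: int) -> Edge:
        self.children[u].remove(v)
        self.parents[v].remove(u)
        return self.edges.pop((u, v))

    def remove_node(self, v: int) -> None:
        for p in list(self.parents[v]):
            self.remove_edge(p, v)
        for c in list(self.children[v]):
            self.remove_edge(v, c)
        del self.children[v]
        del self.parents[v]
        self.labels.pop(v, None)
        self.heights.pop(v, None)

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #
    @property
    def nodes(self) -> list[int]:
        return list(self.children)

    def root(self) -> int:
        roots = [v for v in self.children if not self.parents[v]]
        if len(roots) != 1:
            raise NetworkError(f"network has {len(roots)} root(s)")
        return roots[0]

    def leaves(self) -> list[int]:
        return [v for v in self.children if not self.children[v]]

    def leaf_names(self) -> set[str]:
        return {self.labels[v] for v in self.leaves()}

    def is_reticulation(self, v: int) -> bool:
        return len(self.parents[v]) == 2

    def reticulations(self) -> list[int]:
        """Reticulation nodes in post-order discovery order.

        The position of a node in this list is its persistent reticulation
        index, which labeled-partial-likelihood label vectors refer to.
        """
        seen: list[int] = []
        for v in self.postorder():
            if self.is_reticulation(v):
                seen.append(v)
        return seen

    @property
    def num_reticulations(self) -> int:
        return sum(1 for v in self.children if self.is_reticulation(v))

    def postorder(self) -> list[int]:
        """Children-before-parents order (each node once)."""
        order: list[int] = []
        state: dict[int, int] = {}
        stack = [self.root()]
        while stack:
            v = stack[-1]
            i = state.get(v, 0)
            kids = self.children[v]
            if i < len(kids):
                state[v] = i + 1
                c = kids[i]
                if c not in state:
                    stack.append(c)
            else:
                order.append(v)
                stack.pop()
        return order

    def copy(self) -> "PhyloNetwork":
        net = PhyloNetwork()
        net.children = {v: list(c) for v, c in self.children.items()}
        net.parents = {v: list(p) for v, p in self.parents.items()}
        net.edges = {e: Edge(d.length, d.theta, d.gamma)
                     for e, d in self.edges.items()}
        net.labels = dict(self.labels)
        net.root_theta = self.root_theta
        net.heights = dict(self.heights)
        net._next_id = self._next_id
        return net

    # ------------------------------------------------------------------ #
    # heights <-> lengths
    # ------------------------------------------------------------------ #
    def compute_heights(self) -> dict[int, float]:
        """Node heights from branch lengths, leaves pinned at 0.

        On a time-consistent network every directed path gives the same
        height; otherwise the maximum over children paths is stored and
        :func:`validate_network` reports the inconsistency.
        """
        h: dict[int, float] = {}
        for v in self.postorder():
            if not self.children[v]:
                h[v] = 0.0
            else:
                h[v] = max(h[c] + self.edges[(v, c)].length
                           for c in self.children[v])
        self.heights = h
        return h

    def set_lengths_from_heights(self) -> None:
        for (u, v), e in self.edges.items():
            e.length = self.heights[u] - self.heights[v]

    # ------------------------------------------------------------------ #
    # small surgery helpers (shared by the simulator of random networks
    # and the reversible-jump sampler)
    # ------------------------------------------------------------------ #
    def split_edge(self, u: int, v: int, height: float,
                   lower_theta: float | None = None) -> int:
        """Insert a new node on edge (u, v) at the given height.

        The upper segment keeps the edge's theta (and gamma); the lower
        segment takes ``lower_theta`` (defaults to the same theta).
        Returns the new node id.
        """
        e = self.remove_edge(u, v)
        w = self.new_node()
        self.heights[w] = height
        hv = self.heights[v]
        hu = self.heights[u]
        # gamma describes inheritance INTO v, so it stays on the lower segment
        self.add_edge(u, w, hu - height, e.theta)
        self.add_edge(w, v, height - hv,
                      e.theta if lower_theta is None else lower_theta,
                      e.gamma)
        return w

    def suppress_node(self, v: int) -> None:
        """Remove an in-degree-1, out-degree-1 node, merging its branches.

        Lengths of the two segments are summed; the merged branch keeps the
        upper segment's theta and gamma.
        """
        (p,) = self.parents[v]
        (c,) = self.children[v]
        up = self.remove_edge(p, v)
        low = self.remove_edge(v, c)
        self.remove_node(v)
        gamma = low.gamma if low.gamma is not None else up.gamma
        self.add_edge(p, c, up.length + low.length, up.theta, gamma)


# ---------------------------------------------------------------------- #
# rich-Newick I/O
# ---------------------------------------------------------------------- #
_SPECIALS = set("(),:;[]")


def parse_rich_newick(text: str) -> PhyloNetwork:
    """Parse a rich-Newick network string.

    Reticulation nodes are written twice with a shared ``#H<i>`` tag; the
    per-node colon fields are ``name:length:theta[:gamma]``; an optional
    leading ``[theta]`` gives the theta of the infinite branch above the
    root.
    """
    s = text.strip()
    net = PhyloNetwork()
    pos = 0
    if s.startswith("["):
        end = s.index("]")
        net.root_theta = float(s[1:end])
        pos = end + 1

    hybrids: dict[str, int] = {}

    def parse_fields(i: int) -> tuple[str, str | None, list[float], int]:
        # name[#Htag][:len[:theta[:gamma]]]
        j = i
        while j < len(s) and s[j] not in _SPECIALS and s[j] != "#":
            j += 1
        name = s[i:j].strip()
        tag = None
        if j < len(s) and s[j] == "#":
            j += 1
            t0 = j
            while j < len(s) and s[j] not in _SPECIALS:
                j += 1
            tag = s[t0:j].strip()
        nums: list[float] = []
        while j < len(s) and s[j] == ":":
            j += 1
            t0 = j
            while j < len(s) and s[j] not in _SPECIALS:
                j += 1
            try:
                nums.append(float(s[t0:j]))
            except ValueError as exc:
                raise NetworkError(f"bad numeric field {s[t0:j]!r}") from exc
        return name, tag, nums, j

    def attach(parent: int | None, node: int, nums: list[float],
               is_hybrid: bool) -> None:
        if parent is None:
            return
        length = nums[0] if len(nums) > 0 else 0.0
        theta = nums[1] if len(nums) > 1 else net.root_theta
        gamma = None
        if is_hybrid:
            if len(nums) > 2:
                gamma = nums[2]
        net.add_edge(parent, node, length, theta, gamma)

    def parse_subtree(i: int, parent: int | None) -> int:
        if i >= len(s) and parent is None:
            raise NetworkError("empty network string")
        if s[i] == "(":
            # internal node: gather children after creating the node
            kids_start = i + 1
            name = None
            # we must parse the fields after the matching ')' first to know
            # whether this is a (second occurrence of a) hybrid; but fields
            # follow the subtree, so create the node lazily below.
            node = net.new_node()
            i = kids_start
            while True:
                i = parse_children(i, node)
                if i >= len(s):
                    raise NetworkError("unexpected end of network string")
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise NetworkError(f"unexpected {s[i]!r} at {i}")
            name, tag, nums, i = parse_fields(i)
            if name:
                net.labels[node] = name
            if tag is not None:
                if tag in hybrids:
                    # fuse: move children onto the existing hybrid node
                    h = hybrids[tag]
                    for c in list(net.children[node]):
                        e = net.remove_edge(node, c)
                        net.add_edge(h, c, e.length, e.theta, e.gamma)
                    net.remove_node(node)
                    node = h
                else:
                    hybrids[tag] = node
                attach(parent, node, nums, is_hybrid=True)
            else:
                attach(parent, node, nums, is_hybrid=False)
            return i
        # leaf or bare hybrid occurrence
        name, tag, nums, i = parse_fields(i)
        if tag is not None:
            if tag in hybrids:
                node = hybrids[tag]
            else:
                node = net.new_node(name or None)
                hybrids[tag] = node
            if name:
                net.labels[node] = name
            attach(parent, node, nums, is_hybrid=True)
            return i
        if not name:
            raise NetworkError(f"unnamed leaf at position {i}")
        node = net.new_node(name)
        attach(parent, node, nums, is_hybrid=False)
        return i

    def parse_children(i: int, parent: int) -> int:
        return parse_subtree(i, parent)

    # top level: a single subtree whose node is the root
    if pos >= len(s) or s[pos] != "(":
        raise NetworkError("network string must start with '('")
    pos = parse_subtree(pos, None)
    if pos >= len(s) or s[pos] != ";":
        raise NetworkError("network string must end with ';'")

    diag = validate_network(net)
    hard = [v for v in diag.violations if not v.startswith("time")]
    if hard:
        raise NetworkError("; ".join(hard))
    net.compute_heights()
    # branch lengths are primary; if they do not define consistent node
    # times (non-ultrametric input), drop the derived heights
    if any(abs(net.heights[a] - net.heights[b] - e.length) > 1e-6
           for (a, b), e in net.edges.items()):
        net.heights = {}
    return net


def write_rich_newick(net: PhyloNetwork, include_root_theta: bool = True,
                      topology_only: bool = False) -> str:
    """Serialize a network in the rich-Newick dialect.

    ``topology_only`` drops all numeric fields (used for topology keys and
    plain-Newick export of trees).
    """
    root = net.root()
    retics = net.reticulations()
    tag_of = {v: f"H{i + 1}" for i, v in enumerate(retics)}
    written: set[int] = set()

    def fields(u: int, v: int) -> str:
        if topology_only:
            return ""
        e = net.edges[(u, v)]
        out = f":{e.length:.10g}:{e.theta:.10g}"
        if e.gamma is not None:
            out += f":{e.gamma:.10g}"
        return out

    def emit(v: int, parent: int | None) -> str:
        name = net.labels.get(v, "")
        tag = f"#{tag_of[v]}" if v in tag_of else ""
        suffix = "" if parent is None else fields(parent, v)
        if v in tag_of and v in written:
            return f"{name}{tag}{suffix}"
        written.add(v)
        if not net.children[v]:
            return f"{name}{tag}{suffix}"
        inner = ",".join(emit(c, v) for c in net.children[v])
        return f"({inner}){name}{tag}{suffix}"

    prefix = ""
    if include_root_theta and not topology_only:
        prefix = f"[{net.root_theta:.10g}]"
    return f"{prefix}{emit(root, None)};"


# ---------------------------------------------------------------------- #
# validation
# ---------------------------------------------------------------------- #
def validate_network(net: PhyloNetwork) -> Diagnostics:
    """Structural diagnostics; never raises on violations.

    The sampler relies on violations mapping to prior 0, so diagnostics are
    returned rather than thrown.
    """
    v: list[str] = []
    roots = [x for x in net.children if not net.parents[x]]
    if len(roots) != 1:
        v.append(f"root: expected exactly one root, found {len(roots)}")
    for x in net.children:
        ind, outd = len(net.parents[x]), len(net.children[x])
        if ind > 2:
            v.append(f"degree: node {x} has in-degree {ind}")
        if outd > 2:
            v.append(f"degree: node {x} has out-degree {outd}")
        if ind == 2 and outd != 1:
            v.append(f"degree: reticulation {x} has out-degree {outd}")
        if ind == 2:
            g1 = net.edges[(net.parents[x][0], x)].gamma
            g2 = net.edges[(net.parents[x][1], x)].gamma
            if g1 is None or g2 is None:
                v.append(f"gamma: reticulation {x} missing gamma")
            elif abs(g1 + g2 - 1.0) > GAMMA_TOL:
                v.append(f"gamma: reticulation {x} gammas sum to {g1 + g2}")
    # acyclicity (Kahn's algorithm on the adjacency dicts)
    indeg = {x: len(net.parents[x]) for x in net.children}
    queue = [x for x, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        x = queue.pop()
        seen += 1
        for c in net.children[x]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if seen != len(net.children):
        v.append("cycle: directed cycle present")
    # leaf labels
    leaves = net.leaves()
    names = [net.labels.get(x) for x in leaves]
    if None in names:
        v.append("labels: unlabeled leaf")
    elif len(set(names)) != len(names):
        v.append("labels: duplicate leaf labels")
    # branch lengths / time consistency
    for (a, b), e in net.edges.items():
        if e.length < -TIME_TOL:
            v.append(f"time: edge ({a},{b}) has negative length {e.length}")
    if not v and net.heights:
        for (a, b), e in net.edges.items():
            if abs(net.heights[a] - net.heights[b] - e.length) > 1e-6:
                v.append(f"time: edge ({a},{b}) length inconsistent with "
                         "node divergence times")
                break
        for (a, b) in net.edges:
            if net.heights[a] <= net.heights[b] - TIME_TOL:
                v.append(f"time: node {b} not younger than its parent {a}")
    return Diagnostics(ok=not v, violations=v)


# ---------------------------------------------------------------------- #
# articulation structure
# ---------------------------------------------------------------------- #
def _undirected_with_s(net: PhyloNetwork) -> tuple[nx.Graph, str]:
    g = nx.Graph()
    g.add_nodes_from(net.children)
    g.add_edges_from(net.edges)
    s = "__above_root__"
    g.add_edge(s, net.root())
    return g, s


def articulation_nodes(net: PhyloNetwork) -> set[int]:
    """Cut vertices of the underlying undirected graph.

    The implicit node above the root is included in the graph (so the root
    of any network is always an articulation node) but never reported.
    """
    g, s = _undirected_with_s(net)
    return {v for v in nx.articulation_points(g) if v != s}


def find_lowest_articulation_nodes(net: PhyloNetwork) -> set[int]:
    """Articulation nodes with at least one child that is neither an
    articulation node nor a leaf.

    At such nodes all labeled partial likelihoods can be collapsed into a
    single unlabeled one, which is the key cost optimization of the
    likelihood engine.
    """
    arts = articulation_nodes(net)
    lowest = set()
    for v in arts:
        for c in net.children[v]:
            if c not in arts and net.children[c]:
                lowest.add(v)
                break
    return lowest


def reticulation_diameter(net: PhyloNetwork, retic: int) -> float:
    """Sum of branch lengths on the minimal undirected cycle through a
    reticulation node (the two paths from its parents up to their reunion
    node, plus the two reticulation edges)."""
    if not net.is_reticulation(retic):
        raise NetworkError(f"node {retic} is not a reticulation")
    p1, p2 = net.parents[retic]
    g = nx.Graph()
    for (a, b), e in net.edges.items():
        if retic in (a, b):
            continue
        # parallel edges between the same pair: keep the shorter
        if g.has_edge(a, b):
            g[a][b]["weight"] = min(g[a][b]["weight"], e.length)
        else:
            g.add_edge(a, b, weight=e.length)
    try:
        path_len = nx.shortest_path_length(g, p1, p2, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        path_len = 0.0  # parents coincide (p1 == p2) or degenerate
    if p1 == p2:
        path_len = 0.0
    return (path_len
            + net.edges[(p1, retic)].length
            + net.edges[(p2, retic)].length)


# ---------------------------------------------------------------------- #
# backbone tree, RF distance, isomorphism
# ---------------------------------------------------------------------- #
def backbone_tree(net: PhyloNetwork, tie_break: str | None = None) -> PhyloNetwork:
    """Delete, at each reticulation, the incoming edge with the smaller
    inheritance probability; suppress the resulting degree-2 nodes.

    With a gamma tie at exactly 0.5 the default is to raise; passing
    ``tie_break="postorder"`` keeps the edge whose parent appears earlier
    in post-order.
    """
    tree = net.copy()
    post = {v: i for i, v in enumerate(tree.postorder())}
    for r in list(tree.reticulations()):
        p1, p2 = tree.parents[r]
        g1 = tree.edges[(p1, r)].gamma
        g2 = tree.edges[(p2, r)].gamma
        if g1 is None or g2 is None:
            raise NetworkError(f"reticulation {r} lacks gamma")
        if abs(g1 - g2) <= GAMMA_TOL:
            if tie_break != "postorder":
                raise NetworkError(
                    f"gamma tie at reticulation {r}; pass tie_break='postorder'")
            drop = p1 if post[p1] < post[p2] else p2
        else:
            drop = p1 if g1 < g2 else p2
        tree.remove_edge(drop, r)
        tree.edges[(next(iter(tree.parents[r])), r)].gamma = None
        _cleanup_degree2(tree)
    return tree


def _cleanup_degree2(tree: PhyloNetwork) -> None:
    changed = True
    while changed:
        changed = False
        for v in list(tree.children):
            if v not in tree.children:
                continue
            ind, outd = len(tree.parents[v]), len(tree.children[v])
            if ind == 1 and outd == 1:
                tree.suppress_node(v)
                changed = True
            elif ind == 0 and outd == 1 and tree.children[v]:
                # root left with a single child: child becomes the root
                (c,) = tree.children[v]
                tree.remove_edge(v, c)
                tree.remove_node(v)
                changed = True
            elif ind == 1 and outd == 0 and v not in tree.labels:
                # dangling unlabeled tip (cannot arise from minor-edge
                # removal, but keep the cleanup total)
                tree.remove_node(v)
                changed = True


def to_plain_newick(tree: PhyloNetwork) -> str:
    """Plain Newick (names and lengths only) for a tree; for use with
    standard tree toolkits."""
    if tree.num_reticulations:
        raise NetworkError("plain Newick export requires a tree")

    def emit(v: int, parent: int | None) -> str:
        suffix = "" if parent is None else f":{tree.edges[(parent, v)].length:.10g}"
        if not tree.children[v]:
            return f"{tree.labels[v]}{suffix}"
        inner = ",".join(emit(c, v) for c in tree.children[v])
        return f"({inner}){suffix}"

    return emit(tree.root(), None) + ";"


def rf_distance(t1: PhyloNetwork, t2: PhyloNetwork) -> int:
    """Robinson-Foulds distance (symmetric difference of nontrivial
    bipartitions, unrooted) between two trees on the same leaf set."""
    import dendropy

    if t1.leaf_names() != t2.leaf_names():
        raise NetworkError("leaf sets differ")
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=to_plain_newick(t1), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=to_plain_newick(t2), schema="newick",
                           taxon_namespace=tns)
    return int(dendropy.calculate.treecompare.symmetric_difference(d1, d2))


def networks_isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """Leaf-label-preserving digraph isomorphism of topologies (parameters
    ignored)."""
    if n1.leaf_names() != n2.leaf_names():
        raise NetworkError("leaf sets differ")

    def digraph(net: PhyloNetwork) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in net.children:
            g.add_node(v, label=net.labels.get(v) if not net.children[v] else None)
        g.add_edges_from(net.edges)
        return g

    gm = nx.algorithms.isomorphism.DiGraphMatcher(
        digraph(n1), digraph(n2),
        node_match=lambda a, b: a["label"] == b["label"])
    return gm.is_isomorphic()


def topology_key(net: PhyloNetwork) -> str:
    """A string that is equal for topologically identical embeddings.

    Not a perfect canonical form across all isomorphisms (reticulation
    traversal order can differ), so callers group keys with
    :func:`networks_isomorphic`."""
    retics = net.reticulations()
    tag_of = {v: i for i, v in enumerate(retics)}
    memo: set[int] = set()

    def emit(v: int) -> str:
        if v in tag_of and v in memo:
            return f"#{tag_of[v]}"
        memo.add(v)
        tag = f"#{tag_of[v]}" if v in tag_of else ""
        if not net.children[v]:
            return net.labels[v] + tag
        parts = sorted(emit(c) for c in net.children[v])
        return "(" + ",".join(parts) + ")" + tag

    return emit(net.root())


# ---------------------------------------------------------------------- #
# random networks (test inputs and sampler support)
# ---------------------------------------------------------------------- #
def add_random_reticulation(net: PhyloNetwork, rng, gamma: float | None = None,
                            theta: float | None = None) -> bool:
    """Insert one reticulation by picking a destination edge and a source
    attachment (another edge, or the infinite root branch) with compatible
    times.  Returns False if the picked pair was infeasible."""
    edges = list(net.edges)
    if not edges:
        return False
    e1 = edges[rng.integers(len(edges))]
    h_top = net.heights[e1[0]]
    h_bot = net.heights[e1[1]]
    t1 = rng.uniform(h_bot, h_top)
    others = [e for e in edges if e != e1]
    root = net.root()
    pick = rng.integers(len(others) + 1)
    if gamma is None:
        gamma = float(rng.uniform(0.05, 0.95))
    if theta is None:
        theta = float(net.edges[e1].theta)
    if pick == len(others):
        # attach above the root
        t2 = net.heights[root] + float(rng.exponential(
            max(net.heights[root], 1e-3)))
        r = net.split_edge(*e1, t1)
        w = net.new_node()
        net.heights[w] = t2
        old_root_edgeless = root
        net.add_edge(w, old_root_edgeless, t2 - net.heights[root], net.root_theta)
        net.add_edge(w, r, t2 - t1, theta, gamma)
        net.edges[(net.parents[r][0], r)].gamma = 1.0 - gamma
        return True
    e2 = others[pick]
    lo = max(t1, net.heights[e2[1]])
    hi = net.heights[e2[0]]
    if hi <= lo:
        return False
    t2 = rng.uniform(lo, hi)
    r = net.split_edge(*e1, t1)
    w = net.split_edge(*e2, t2)
    net.add_edge(w, r, t2 - t1, theta, gamma)
    net.edges[(net.parents[r][0], r)].gamma = 1.0 - gamma
    return True


def random_network(rng, n_leaves: int = 4, n_reticulations: int = 1,
                   theta_range: tuple[float, float] = (0.003, 0.02),
                   height_scale: float = 0.02,
                   taxa: list[str] | None = None) -> PhyloNetwork:
    """A random ultrametric network: a coalescent-shaped random tree with
    reticulations attached at random time-compatible points."""
    net = PhyloNetwork()
    if taxa is None:
        taxa = [chr(ord("A") + i) for i in range(n_leaves)]
    active = [net.new_node(t) for t in taxa]
    for v in active:
        net.heights[v] = 0.0

    def rand_theta() -> float:
        return float(rng.uniform(*theta_range))

    h = 0.0
    while len(active) > 1:
        h += float(rng.exponential(height_scale / len(active)))
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        p = net.new_node()
        net.heights[p] = h
        net.add_edge(p, a, h - net.heights[a], rand_theta())
        net.add_edge(p, b, h - net.heights[b], rand_theta())
        active = [v for v in active if v not in (a, b)] + [p]
    net.root_theta = rand_theta()
    added = 0
    attempts = 0
    while added < n_reticulations and attempts < 200:
        attempts += 1
        if add_random_reticulation(net, rng):
            added += 1
    net.set_lengths_from_heights()
    diag = validate_network(net)
    if not diag.ok:  # pragma: no cover - generator invariant
        raise NetworkError("random_network produced invalid network: "
                           + "; ".join(diag.violations))
    return net
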