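"""Exact likelihood of a phylogenetic network given bi-allelic markers.

The likelihood of a network for one site integrates over all gene trees.
Following the species-tree algorithm of SNAPP, that integral is computed
without enumerating gene trees, by propagating partial-likelihood vectors
``F(n, r)`` -- the joint probability of the observed data below a point on
a branch and of there being ``n`` ancestral lineages there, ``r`` of which
carry the red allele -- up the phylogeny with the matrix exponential of a
coalescent-with-mutation rate matrix.

On a network a set of lineages entering a reticulation node must be
bipartitioned in every possible way between the two parent branches.  Each
such split produces a *pair* of partial likelihoods that must be recombined
exactly once when the two parent paths reunite.  This is bookkept by
"labeled partial likelihoods" (LPLs): a partial-likelihood vector together
with an integer label vector, one coordinate per reticulation, where a
fresh label value marks the two halves of one split and 0 means "did not
pass through that reticulation".  Two LPLs may merge only when their labels
are compatible (equal or zero coordinatewise).

At a *lowest articulation node* (a cut vertex with a child that is neither
a cut vertex nor a leaf) all pending LPLs can be summed into a single
unlabeled one, which keeps the LPL sets small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .markers import MarkerMatrix, MutationModel, SpeciesSite
from .network import PhyloNetwork, validate_network

__all__ = [
    "LPL",
    "build_rate_matrix",
    "leaf_partials",
    "leaf_partials_dominant",
    "propagate_top",
    "split_at_reticulation",
    "merge_at_tree_node",
    "merge_at_articulation",
    "root_stationary",
    "LikelihoodEngine",
    "site_likelihood",
    "dataset_loglik",
    "enumerate_site_patterns",
]

# A partial likelihood F is a sparse mapping (n, r) -> value with
# 0 <= r <= n; the (0, 0) entry acts as a "no lineages on this branch"
# placeholder carrying a multiplicative factor.
FVec = dict[tuple[int, int], float]


@dataclass(frozen=True)
class LPL:
    """Labeled partial likelihood: (F, s)."""

    F: tuple[tuple[tuple[int, int], float], ...]
    s: tuple[int, ...]

    @classmethod
    def make(cls, f: FVec, s: tuple[int, ...]) -> "LPL":
        return cls(tuple(f.items()), s)

    def fdict(self) -> FVec:
        return dict(self.F)


def compatible(s1: tuple[int, ...], s2: tuple[int, ...]) -> bool:
    """Labels are compatible iff coordinatewise equal or one side is 0."""
    if len(s1) != len(s2):
        raise ValueError("label length mismatch")
    return all(a == b or a * b == 0 for a, b in zip(s1, s2))


def merge_labels(s1: tuple[int, ...], s2: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(a if a else b for a, b in zip(s1, s2))


# ---------------------------------------------------------------------- #
# (n, r) index set and the rate matrix
# ---------------------------------------------------------------------- #
def index_pairs(M: int) -> list[tuple[int, int]]:
    """All (n, r) with 0 <= r <= n <= M, (0,0) first; length
    (1 + (M+1)) (M+1) / 2."""
    return [(n, r) for n in range(M + 1) for r in range(n + 1)]


def pair_index(M: int) -> dict[tuple[int, int], int]:
    return {p: i for i, p in enumerate(index_pairs(M))}


def build_rate_matrix(theta: float, model: MutationModel, M: int) -> np.ndarray:
    """Rate matrix of the lineage-count/allele-count Markov chain.

    Indexed by (n, r); transitions: mutation within level n
    ((n,r)->(n,r-1) at (n-r+1)v, (n,r)->(n,r+1) at (r+1)u) and coalescence
    to level n-1 ((n,r)->(n-1,r) at (n-1-r)n/theta, (n,r)->(n-1,r-1) at
    (r-1)n/theta); diagonal -n(n-1)/theta - (n-r)v - ru.  The (0,0) row is
    zero so placeholder mass is preserved under propagation.  The operator
    is not a conservative generator: the combinatorial weighting of F
    absorbs the deficit.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if M < 1:
        raise ValueError("M must be >= 1")
    u, v = model.u, model.v
    pairs = index_pairs(M)
    idx = {p: i for i, p in enumerate(pairs)}
    Q = np.zeros((len(pairs), len(pairs)))
    for (n, r) in pairs:
        if n == 0:
            continue
        i = idx[(n, r)]
        if (n, r - 1) in idx:
            Q[i, idx[(n, r - 1)]] = (n - r + 1) * v
        if r + 1 <= n:
            Q[i, idx[(n, r + 1)]] = (r + 1) * u
        if (n - 1, r) in idx and n - 1 - r >= 0:
            Q[i, idx[(n - 1, r)]] = (n - 1 - r) * n / theta
        if r - 1 >= 0 and (n - 1, r - 1) in idx:
            Q[i, idx[(n - 1, r - 1)]] = (r - 1) * n / theta
        Q[i, i] = -n * (n - 1) / theta - (n - r) * v - r * u
    return Q


def root_stationary(theta: float, model: MutationModel, M: int) -> FVec:
    """Stationary vector x with Qx = 0, normalized so x(1,0)+x(1,1) = 1.

    x(n, r) = Pr[R = r | N = n] for n lineages sampled from a single
    stationary population.  Solved level by level in n: the within-level
    block is strictly diagonally dominant, hence nonsingular.
    """
    u, v = model.u, model.v
    x: FVec = {(1, 0): u / (u + v), (1, 1): v / (u + v)}
    Q = build_rate_matrix(theta, model, M)
    idx = pair_index(M)
    for n in range(2, M + 1):
        W = np.array([[Q[idx[(n, r)], idx[(n, rp)]] for rp in range(n + 1)]
                      for r in range(n + 1)])
        b = np.zeros(n + 1)
        for r in range(n + 1):
            for rp in range(n):
                b[r] -= Q[idx[(n, r)], idx[(n - 1, rp)]] * x.get((n - 1, rp), 0.0)
        cond = np.linalg.cond(W)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"stationary solve ill-conditioned at level n={n} (cond={cond:.2e})")
        xn = np.linalg.solve(W, b)
        for r in range(n + 1):
            x[(n, r)] = float(xn[r])
    x[(0, 0)] = 0.0
    return x


# ---------------------------------------------------------------------- #
# leaf initialization
# ---------------------------------------------------------------------- #
def leaf_partials(n_x: int, r_x: int, k: int) -> LPL:
    """Haploid / co-dominant leaf: unit mass at (n_x, r_x), zero label."""
    if not 0 <= r_x <= n_x:
        raise ValueError(f"need 0 <= r_x <= n_x, got {r_x} > {n_x}")
    return LPL.make({(n_x, r_x): 1.0}, (0,) * k)


def leaf_partials_dominant(n_x: int, r_x: int, k: int) -> LPL:
    """Dominant-marker leaf (red dominant): n_x diploid individuals of
    which r_x show the band.

    F(2 n_x, r) for r_x <= r <= 2 r_x is the probability of the observed
    band pattern given r red alleles among the 2 n_x lineages with the
    individual pairing fixed: r - r_x individuals homozygous red, 2 r_x - r
    heterozygous, n_x - r_x homozygous green, giving
    n_x! / ((r-r_x)! (2 r_x - r)! (n_x - r_x)!) * 2^(2 r_x - r) / C(2 n_x, r).
    Matches exhaustive enumeration of allele placements.
    """
    if not 0 <= r_x <= n_x:
        raise ValueError(f"need 0 <= r_x <= n_x, got {r_x} > {n_x}")
    f: FVec = {}
    n2 = 2 * n_x
    for r in range(r_x, 2 * r_x + 1):
        num = (math.factorial(n_x)
               // (math.factorial(r - r_x) * math.factorial(2 * r_x - r)
                   * math.factorial(n_x - r_x)))
        f[(n2, r)] = num * 2 ** (2 * r_x - r) / math.comb(n2, r)
    if r_x == 0:
        f = {(n2, 0): 1.0}
    return LPL.make(f, (0,) * k)


# ---------------------------------------------------------------------- #
# branch propagation
# ---------------------------------------------------------------------- #
def branch_propagator(theta: float, model: MutationModel, M: int,
                      t: float) -> np.ndarray:
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    return expm(build_rate_matrix(theta, model, M) * t)


def propagate_top(lpls: list[LPL], P: np.ndarray, M: int) -> list[LPL]:
    """Bottom-to-top of one branch: F -> F . exp(Q t); labels unchanged."""
    idx = pair_index(M)
    pairs = index_pairs(M)
    out = []
    for lpl in lpls:
        row = np.zeros(len(pairs))
        for (n, r), val in lpl.F:
            row += val * P[idx[(n, r)]]
        f = {pairs[i]: float(row[i]) for i in np.nonzero(row)[0]}
        out.append(LPL.make(f, lpl.s))
    return out


# ---------------------------------------------------------------------- #
# decompose-and-split at a reticulation node
# ---------------------------------------------------------------------- #
def split_at_reticulation(lpls: list[LPL], gamma: float, retic_id: int,
                          ) -> tuple[list[LPL], list[LPL]]:
    """Bipartition the lineages entering a reticulation in every way.

    Each nonzero entry (n_i, r_i) of each incoming F is split over all
    feasible (n_y, r_y); the y side carries the binomial inheritance weight
    F(n_i, r_i) C(n_i, n_y) gamma^n_y (1-gamma)^(n_i-n_y) and the z side a
    bare indicator; the two halves share a fresh label value at coordinate
    ``retic_id`` so they recombine exactly once.  Splits with r_z > n_z are
    zero-probability states and are skipped.
    """
    if gamma < 0 or gamma > 1:
        raise ValueError("gamma must be in [0, 1]")
    py: list[LPL] = []
    pz: list[LPL] = []
    o = 0
    for lpl in lpls:
        if retic_id >= len(lpl.s):
            raise ValueError("reticulation index out of range")
        if not lpl.F:  # empty support passes through unchanged
            py.append(lpl)
            pz.append(lpl)
            continue
        for (ni, ri), val in lpl.F:
            for ny in range(ni + 1):
                nz = ni - ny
                rlo = max(0, ri - nz)
                rhi = min(ri, ny)
                for ry in range(rlo, rhi + 1):
                    rz = ri - ry
                    o += 1
                    s = list(lpl.s)
                    s[retic_id] = o
                    s_t = tuple(s)
                    delta = (val * math.comb(ni, ny)
                             * gamma ** ny * (1.0 - gamma) ** nz)
                    py.append(LPL.make({(ny, ry): delta}, s_t))
                    pz.append(LPL.make({(nz, rz): 1.0}, s_t))
    return py, pz


# ---------------------------------------------------------------------- #
# merge at a tree node
# ---------------------------------------------------------------------- #
def _compact(lpls: list[LPL]) -> list[LPL]:
    """Sum partial-likelihood vectors sharing an identical label vector
    (they are interchangeable in all later steps) and drop zero entries."""
    acc: dict[tuple[int, ...], FVec] = {}
    for lpl in lpls:
        f = acc.setdefault(lpl.s, {})
        for key, val in lpl.F:
            f[key] = f.get(key, 0.0) + val
    out = []
    for s, f in acc.items():
        f = {k: v for k, v in f.items() if v != 0.0}
        if f:
            out.append(LPL.make(f, s))
    return out


def merge_at_tree_node(py: list[LPL], pz: list[LPL]) -> list[LPL]:
    """Combine the LPL sets of the two child branches of a tree node.

    For every compatible pair, labels merge coordinatewise and the F
    vectors convolve with the hypergeometric interleaving weight
    C(r, r_y) C(n-r, n_y-r_y) / C(n, n_y).  A (0,0) placeholder on either
    side acts as a scalar factor.
    """
    out: list[LPL] = []
    comb = math.comb
    for ly in py:
        fy = ly.F
        sy = ly.s
        for lz in pz:
            sz = lz.s
            if len(sy) != len(sz):
                raise ValueError("label length mismatch")
            if not all(a == b or a * b == 0 for a, b in zip(sy, sz)):
                continue
            f: FVec = {}
            for (ny, ry), vy in fy:
                for (nz, rz), vz in lz.F:
                    n, r = ny + nz, ry + rz
                    w = (comb(r, ry) * comb(n - r, ny - ry)
                         / comb(n, ny))
                    key = (n, r)
                    if key in f:
                        f[key] += vy * vz * w
                    else:
                        f[key] = vy * vz * w
            out.append(LPL(tuple(f.items()),
                           tuple(a if a else b for a, b in zip(sy, sz))))
    return _compact(out)


def merge_at_articulation(lpls: list[LPL]) -> list[LPL]:
    """At a lowest articulation node, sum all partial-likelihood vectors
    into a single LPL with an all-zero (empty) label."""
    if not lpls:
        raise ValueError("empty LPL set at articulation node")
    k = len(lpls[0].s)
    f: FVec = {}
    for lpl in lpls:
        for key, val in lpl.F:
            f[key] = f.get(key, 0.0) + val
    return [LPL.make(f, (0,) * k)]


# ---------------------------------------------------------------------- #
# the engine
# ---------------------------------------------------------------------- #
class LikelihoodEngine:
    """Per-network, per-model state for repeated site evaluations.

    Branch propagator matrices depend only on (theta, length, M) and are
    cached, so evaluating many site patterns (or re-evaluating after a
    proposal that touched one branch) does not recompute every matrix
    exponential.
    """

    def __init__(self, net: PhyloNetwork, model: MutationModel,
                 lineages_per_species: dict[str, int],
                 use_articulation_opt: bool = True,
                 propagator_cache: dict | None = None) -> None:
        diag = validate_network(net)
        if not diag.ok:
            raise ValueError("invalid network: " + "; ".join(diag.violations))
        self.net = net
        self.model = model
        self.lineages = dict(lineages_per_species)
        self.use_articulation_opt = use_articulation_opt
        self._cache = propagator_cache if propagator_cache is not None else {}
        self.retic_index = {v: i for i, v in enumerate(net.reticulations())}
        self.k = len(self.retic_index)
        self.postorder = net.postorder()
        self._subtended()
        self.collapse_points = (self.collapse_nodes
                                if use_articulation_opt else set())
        self._x: FVec | None = None

    def _subtended(self) -> None:
        """Per-node lineage bounds and safe collapse points.

        ``M_node[v]``: total lineages of leaves reachable from v (a tight
        per-branch bound on n).  ``collapse_nodes``: nodes at which all
        labels below are provably dead -- every reticulation descendant
        has both parents inside the node's descendant set -- so the LPL
        set may be summed into a single unlabeled vector.  Such nodes are
        articulation nodes; the quoted "lowest articulation" definition
        admits nodes where a descendant reticulation escapes sideways, and
        collapsing there would pair split halves incorrectly.
        """
        net = self.net
        desc: dict[int, set[int]] = {}
        for v in self.postorder:
            d = {v}
            for c in net.children[v]:
                d |= desc[c]
            desc[v] = d
        self.M_node = {
            v: sum(self.lineages[net.labels[leaf]]
                   for leaf in desc[v] if not net.children[leaf])
            for v in self.postorder
        }
        self.M_total = self.M_node[net.root()]
        retics = set(self.retic_index)
        self.collapse_nodes = set()
        for v in self.postorder:
            if not net.children[v]:
                continue
            ok = all(set(net.parents[r]) <= desc[v]
                     for r in retics & (desc[v] - {v}))
            if ok:
                self.collapse_nodes.add(v)

    def _propagator(self, theta: float, t: float, M: int) -> np.ndarray:
        key = (theta, t, M, self.model.u, self.model.v)
        P = self._cache.get(key)
        if P is None:
            P = branch_propagator(theta, self.model, M, t)
            self._cache[key] = P
            if len(self._cache) > 20000:
                self._cache.clear()
        return P

    # -------------------------------------------------------------- #
    def site_likelihood(self, site: dict[str, SpeciesSite]) -> float:
        """Likelihood of one site pattern (Algorithm: bottom-up traversal
        applying leaf init, branch propagation, decompose-and-split at
        reticulations, merge at tree nodes, and collapsing at lowest
        articulation nodes; terminated by the stationary root vector)."""
        net = self.net
        k = self.k
        top: dict[tuple[int, int], list[LPL]] = {}

        def propagate(edge: tuple[int, int], bottom: list[LPL]) -> None:
            e = net.edges[edge]
            M = self.M_node[edge[1]]
            P = self._propagator(e.theta, e.length, M)
            top[edge] = propagate_top(bottom, P, M)

        root = net.root()
        for v in self.postorder:
            if not net.children[v]:
                obs = site[net.labels[v]]
                if obs.dominant:
                    lpl = leaf_partials_dominant(obs.n, obs.r, k)
                else:
                    lpl = leaf_partials(obs.n, obs.r, k)
                bottom = [lpl]
            elif net.is_reticulation(v):
                (c,) = net.children[v]
                inc = top[(v, c)]
                if v in self.collapse_points:
                    inc = merge_at_articulation(inc)
                p1, p2 = net.parents[v]
                g1 = net.edges[(p1, v)].gamma
                py, pz = split_at_reticulation(inc, g1, self.retic_index[v])
                propagate((p1, v), py)
                propagate((p2, v), pz)
                continue
            else:
                kids = net.children[v]
                if len(kids) == 1:
                    bottom = top[(v, kids[0])]
                else:
                    bottom = merge_at_tree_node(top[(v, kids[0])],
                                                top[(v, kids[1])])
            if v in self.collapse_points:
                bottom = merge_at_articulation(bottom)
            if v == root:
                return self._terminate(bottom)
            (p,) = net.parents[v]
            propagate((p, v), bottom)
        raise AssertionError("traversal did not reach the root")

    def _terminate(self, root_bottom: list[LPL]) -> float:
        f_rho: FVec = {}
        for lpl in root_bottom:
            for key, val in lpl.F:
                f_rho[key] = f_rho.get(key, 0.0) + val
        if self._x is None:
            self._x = root_stationary(self.net.root_theta, self.model,
                                      self.M_total)
        x = self._x
        lik = sum(val * x.get(key, 0.0) for key, val in f_rho.items())
        return float(lik)

    # -------------------------------------------------------------- #
    def monomorphic_probability(self) -> float:
        """Pr[all sampled lineages share one allele] under the model, used
        to condition on polymorphism."""
        red = {sp: SpeciesSite(n, n) for sp, n in self.lineages.items()}
        green = {sp: SpeciesSite(n, 0) for sp, n in self.lineages.items()}
        return self.site_likelihood(red) + self.site_likelihood(green)


def _engine_for(net: PhyloNetwork, model: MutationModel,
                site: dict[str, SpeciesSite],
                use_articulation_opt: bool = True) -> LikelihoodEngine:
    lineages = {sp: o.lineages for sp, o in site.items()}
    return LikelihoodEngine(net, model, lineages,
                            use_articulation_opt=use_articulation_opt)


def site_likelihood(net: PhyloNetwork, site: dict[str, SpeciesSite],
                    model: MutationModel,
                    use_articulation_opt: bool = True) -> float:
    """One-shot site likelihood (builds a fresh engine)."""
    return _engine_for(net, model, site, use_articulation_opt).site_likelihood(site)


def dataset_loglik(net: PhyloNetwork, markers: MarkerMatrix,
                   model: MutationModel, threads: int = 1,
                   condition_on_polymorphic: bool | None = None,
                   use_articulation_opt: bool = True,
                   propagator_cache: dict | None = None) -> float:
    """Log-likelihood of a marker matrix: sum over deduplicated site
    patterns of weight * log site-likelihood.

    ``condition_on_polymorphic`` (default: the matrix's own flag) divides
    each site likelihood by 1 - Pr[monomorphic], matching data collected
    with monomorphic sites discarded.  Patterns are evaluated in a fixed
    sorted order, so the result is independent of site order and of
    ``threads`` (accepted for interface compatibility; evaluation is
    sequential).
    """
    if markers.n_sites == 0:
        raise ValueError("empty marker matrix")
    per = 2 if markers.diploid else 1
    lineages = {sp: per * len(inds) for sp, inds in markers.taxon_map.items()}
    engine = LikelihoodEngine(net, model, lineages,
                              use_articulation_opt=use_articulation_opt,
                              propagator_cache=propagator_cache)
    if condition_on_polymorphic is None:
        condition_on_polymorphic = markers.polymorphic_only
    log_norm = 0.0
    if condition_on_polymorphic:
        p_mono = engine.monomorphic_probability()
        log_norm = math.log1p(-p_mono)
    total = 0.0
    for pattern, weight in markers.patterns():
        lik = engine.site_likelihood(pattern)
        if lik <= 0.0:
            raise ValueError(f"zero likelihood for site pattern {pattern}")
        total += weight * (math.log(lik) - log_norm)
    return total


def enumerate_site_patterns(lineages_per_species: dict[str, int]
                            ) -> list[dict[str, SpeciesSite]]:
    """All haploid-coded site patterns for the given sampling design (used
    for exhaustive normalization checks)."""
    species = sorted(lineages_per_species)
    patterns: list[dict[str, SpeciesSite]] = [{}]
    for sp in species:
        n = lineages_per_species[sp]
        patterns = [dict(p, **{sp: SpeciesSite(n, r)})
                    for p in patterns for r in range(n + 1)]
    return patterns
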