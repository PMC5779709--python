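"""Simulation of bi-allelic markers on a phylogenetic network.

Two stages: (1) gene trees are drawn inside the network under the
multispecies network coalescent -- lineages coalesce within each branch as
a Kingman process at pairwise rate 2/theta in expected-mutation time, and
each lineage entering a reticulation node independently follows a parent
edge with that edge's inheritance probability; (2) a two-state mutation
process is run down each gene tree from a stationary root draw.

Optional features mirror common data-collection artifacts: restriction to
polymorphic sites (failed draws discard gene tree and site together),
linked blocks of sites sharing one gene tree, discrete-Gamma +
invariant-sites rate variation across markers or across gene-tree
lineages, and diploid / dominant encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .markers import MarkerMatrix, MutationModel
from .network import PhyloNetwork

__all__ = ["GeneTree", "SimConfig", "sample_gene_tree", "simulate_site",
           "simulate_markers", "encode_diploid_dominant",
           "discrete_gamma_rates"]

RED, GREEN = 0, 1


@dataclass
class GeneTree:
    """Rooted binary gene tree; leaves are sampled haploid lineages.

    Times are heights above the sampling instant in expected mutations per
    site; every parent is strictly older than its children.
    """

    times: dict[int, float] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    leaf_label: dict[int, str] = field(default_factory=dict)
    root: int = -1
    # per reticulation node of the species network: (lineages routed to the
    # first-listed parent, lineages arriving) -- diagnostics for the
    # gamma-routing process
    routing: dict[int, tuple[int, int]] = field(default_factory=dict)

    def new_node(self, time: float, kids: list[int] | None = None,
                 label: str | None = None) -> int:
        v = len(self.times)
        self.times[v] = time
        self.children[v] = kids or []
        if label is not None:
            self.leaf_label[v] = label
        return v

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)


@dataclass
class SimConfig:
    n_sites: int = 1000
    sites_per_genetree: int = 1
    polymorphic_only: bool = False
    diploid: bool = False
    dominant: bool = False
    # rate variation: None, "lineages", or "markers"
    rate_variation: str | None = None
    invariant_prop: float = 0.0
    gamma_shape: float = 1.0
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        if self.n_sites % self.sites_per_genetree:
            raise ValueError("n_sites must be divisible by sites_per_genetree")
        if not 0.0 <= self.invariant_prop < 1.0:
            raise ValueError("invariant proportion must be in [0, 1)")
        if self.gamma_shape <= 0 or self.gamma_categories < 1:
            raise ValueError("bad gamma rate-variation parameters")
        if self.rate_variation not in (None, "lineages", "markers"):
            raise ValueError("rate_variation must be None, 'lineages' or 'markers'")
        if self.dominant and not self.diploid:
            raise ValueError("dominant markers require diploid data")


def _haploid_lineages(taxon_map: dict[str, list[str]], diploid: bool
                      ) -> dict[str, list[str]]:
    """Haploid lineage names per species; a diploid individual contributes
    a fixed pair ind|a, ind|b."""
    out: dict[str, list[str]] = {}
    for sp, inds in taxon_map.items():
        if diploid:
            out[sp] = [f"{i}|{c}" for i in inds for c in ("a", "b")]
        else:
            out[sp] = list(inds)
    return out


def sample_gene_tree(net: PhyloNetwork, taxon_map: dict[str, list[str]],
                     rng: np.random.Generator,
                     diploid: bool = False) -> GeneTree:
    """One gene tree under the multispecies network coalescent."""
    if not net.heights:
        net.compute_heights()
    gt = GeneTree()
    lineages = _haploid_lineages(taxon_map, diploid)
    # lineages waiting at the bottom of each network edge
    pending: dict[tuple[int, int], list[int]] = {e: [] for e in net.edges}
    label_of_leaf = {net.labels[v]: v for v in net.leaves()}
    for sp, lins in lineages.items():
        leaf = label_of_leaf[sp]
        (p,) = net.parents[leaf]
        for name in lins:
            pending[(p, leaf)].append(gt.new_node(0.0, label=name))

    def coalesce(active: list[int], t0: float, t1: float, theta: float
                 ) -> list[int]:
        t = t0
        active = list(active)
        while len(active) >= 2:
            m = len(active)
            rate = m * (m - 1) / theta  # pairs * pairwise rate 2/theta
            t += rng.exponential(1.0 / rate)
            if t > t1:
                break
            i = int(rng.integers(m))
            j = int(rng.integers(m - 1))
            if j >= i:
                j += 1
            a, b = active[i], active[j]
            parent = gt.new_node(t, kids=[a, b])
            if i < j:
                i, j = j, i
            active[i] = active[-1]
            active.pop()
            active[j] = parent
        return active

    order = sorted((v for v in net.children if net.children[v]),
                   key=lambda v: net.heights[v])
    root = net.root()
    survivors_at: dict[int, list[int]] = {}
    for v in order:
        arrived: list[int] = []
        for c in net.children[v]:
            e = net.edges[(v, c)]
            arrived.extend(coalesce(pending[(v, c)], net.heights[c],
                                    net.heights[v], e.theta))
        survivors_at[v] = arrived
        if v == root:
            continue
        if net.is_reticulation(v):
            p1, p2 = net.parents[v]
            g1 = net.edges[(p1, v)].gamma
            to_first = 0
            for lin in arrived:
                if rng.random() < g1:
                    pending[(p1, v)].append(lin)
                    to_first += 1
                else:
                    pending[(p2, v)].append(lin)
            a, b = gt.routing.get(v, (0, 0))
            gt.routing[v] = (a + to_first, b + len(arrived))
        else:
            (p,) = net.parents[v]
            pending[(p, v)].extend(arrived)
    # infinite branch above the root
    active = survivors_at[root]
    t = net.heights[root]
    while len(active) >= 2:
        rate = len(active) * (len(active) - 1) / net.root_theta
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent = gt.new_node(t, kids=[a, b])
        active = [x for x in active if x not in (a, b)] + [parent]
    gt.root = active[0]
    return gt


def simulate_site(gt: GeneTree, model: MutationModel,
                  rate_multiplier, rng: np.random.Generator
                  ) -> dict[str, int]:
    """Two-state mutation down a gene tree; returns 0/1 (1 = red) per
    sampled lineage.

    ``rate_multiplier`` is a scalar applied to every branch, or a mapping
    from child node id to a per-branch multiplier (rate variation across
    lineages).
    """
    import math

    per_branch = rate_multiplier if isinstance(rate_multiplier, dict) else None
    scalar = 1.0 if per_branch is not None else float(rate_multiplier)
    tot = model.u + model.v
    pr = model.v / tot  # stationary red frequency
    state = {gt.root: RED if rng.random() < pr else GREEN}
    out: dict[str, int] = {}
    stack = [gt.root]
    times = gt.times
    children = gt.children
    while stack:
        v = stack.pop()
        kids = children[v]
        if not kids:
            out[gt.leaf_label[v]] = 1 if state[v] == RED else 0
            continue
        tv = times[v]
        sv = state[v]
        for c in kids:
            mult = per_branch[c] if per_branch is not None else scalar
            e = math.exp(-tot * (tv - times[c]) * mult)
            p_red = pr + (1.0 - pr) * e if sv == RED else pr * (1.0 - e)
            state[c] = RED if rng.random() < p_red else GREEN
            stack.append(c)
    return out


def discrete_gamma_rates(shape: float, categories: int) -> np.ndarray:
    """Mean rates of equal-probability categories of a Gamma(shape)
    distribution with mean 1 (discrete-Gamma rate heterogeneity)."""
    a = shape
    qs = gamma_dist.ppf(np.linspace(0, 1, categories + 1), a, scale=1.0 / a)
    bounds = qs * a  # quantiles of the rate-a parameterization
    bounds[0], bounds[-1] = 0.0, np.inf
    upper = gammainc(a + 1, bounds)
    return categories * (upper[1:] - upper[:-1])


def _draw_multiplier(cfg: SimConfig, rates: np.ndarray,
                     rng: np.random.Generator) -> float:
    if rng.random() < cfg.invariant_prop:
        return 0.0
    return float(rates[rng.integers(len(rates))])


def encode_diploid_dominant(haploid_pair: tuple[int, int],
                            dominant: bool) -> int:
    """Collapse the two haploid alleles of one diploid individual:
    co-dominant genotype = red-allele count; dominant (red dominant) band =
    1 iff at least one red allele."""
    if len(haploid_pair) != 2:
        raise ValueError("a diploid individual needs exactly two haploids")
    count = sum(haploid_pair)
    return (1 if count > 0 else 0) if dominant else count


def simulate_markers(net: PhyloNetwork, taxon_map: dict[str, list[str]],
                     model: MutationModel, cfg: SimConfig,
                     rng: np.random.Generator) -> MarkerMatrix:
    """Simulate a marker matrix; the returned object carries a
    ``sim_stats`` dict with the realized polymorphic fraction and the
    number of gene trees drawn."""
    lineages = _haploid_lineages(taxon_map, cfg.diploid)
    lineage_names = [x for v in lineages.values() for x in v]
    if cfg.polymorphic_only and len(lineage_names) < 2:
        raise ValueError("polymorphic-only filtering needs >= 2 lineages")
    rates = (discrete_gamma_rates(cfg.gamma_shape, cfg.gamma_categories)
             if cfg.rate_variation else np.array([1.0]))

    columns: list[dict[str, int]] = []
    n_polymorphic = 0
    n_trees = 0
    n_blocks = cfg.n_sites // cfg.sites_per_genetree
    for _ in range(n_blocks):
        gt = sample_gene_tree(net, taxon_map, rng, diploid=cfg.diploid)
        n_trees += 1
        branch_mults = None
        if cfg.rate_variation == "lineages":
            branch_mults = {v: _draw_multiplier(cfg, rates, rng)
                            for v in gt.times if v != gt.root}
        sites_done = 0
        guard = 0
        while sites_done < cfg.sites_per_genetree:
            guard += 1
            if guard > 10_000_000:  # pragma: no cover - safety valve
                raise RuntimeError("polymorphic-site rejection not terminating")
            if cfg.rate_variation == "markers":
                mult = _draw_multiplier(cfg, rates, rng)
            elif cfg.rate_variation == "lineages":
                mult = branch_mults
            else:
                mult = 1.0
            colors = simulate_site(gt, model, mult, rng)
            vals = [colors[x] for x in lineage_names]
            poly = 0 < sum(vals) < len(vals)
            if cfg.polymorphic_only and not poly:
                if cfg.sites_per_genetree == 1:
                    # discard gene tree and site together
                    gt = sample_gene_tree(net, taxon_map, rng,
                                          diploid=cfg.diploid)
                    n_trees += 1
                continue
            if poly:
                n_polymorphic += 1
            columns.append(colors)
            sites_done += 1

    individuals = [i for v in taxon_map.values() for i in v]
    data = np.zeros((len(individuals), cfg.n_sites), dtype=int)
    for j, colors in enumerate(columns):
        for i, ind in enumerate(individuals):
            if cfg.diploid:
                pair = (colors[f"{ind}|a"], colors[f"{ind}|b"])
                data[i, j] = encode_diploid_dominant(pair, cfg.dominant)
            else:
                data[i, j] = colors[ind]
    df = pd.DataFrame(data, index=individuals,
                      columns=[f"site_{j}" for j in range(cfg.n_sites)])
    mm = MarkerMatrix(df, taxon_map, diploid=cfg.diploid,
                      dominant=cfg.dominant,
                      polymorphic_only=cfg.polymorphic_only)
    mm.sim_stats = {"polymorphic_fraction": n_polymorphic / cfg.n_sites,
                    "gene_trees": n_trees}
    return mm
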