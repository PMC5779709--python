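"""Bayesian inference of phylogenetic networks from bi-allelic markers.

The posterior is p(net | S) proportional to L(net | S) p(net), with a
composite prior: an (unnormalized over topologies) Poisson on the number
of reticulations, exponential densities on reticulation-cycle diameters
and on node divergence times, Gamma(2, zeta) on every branch's population
mutation rate, and Beta(alpha, beta) on inheritance probabilities.  A
structurally invalid candidate (cycle, bad degrees, time inconsistency)
gets prior 0, which is how illegal proposals are rejected.

Sampling uses a reversible-jump MCMC kernel over node heights, per-branch
thetas, inheritance probabilities, and reticulation insertion/removal.
The insertion move picks a destination edge and a source attachment (a
second edge or the infinite root branch), draws the two new node heights,
an inheritance probability, and three fresh thetas from their proposal
densities; removal drops one of a reticulation's two incoming edges (so
repeated insert/remove also traverses tree topologies, like a rooted SPR)
and its Hastings ratio is the exact reverse insertion density.  A
Metropolis-coupled (heated-chains) phase can be run first to find a good
starting state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .likelihood import dataset_loglik
from .markers import MarkerMatrix, MutationModel
from .network import (PhyloNetwork, reticulation_diameter, validate_network,
                      write_rich_newick, networks_isomorphic, topology_key)

__all__ = ["PriorConfig", "ProposalConfig", "PosteriorState",
           "PosteriorTarget", "SampleTrace", "log_prior", "log_posterior",
           "propose", "run_rjmcmc", "run_mc3_preburnin", "summarize",
           "effective_sample_size"]

NEG_INF = float("-inf")


@dataclass
class PriorConfig:
    """Hyperparameters of the network prior.

    ``nu``: Poisson mean on the reticulation count (not normalized by the
    number of topologies per count).  ``eta``: rate of the exponential
    prior on reticulation diameters (None disables the factor).
    ``delta``: rate of the exponential prior on divergence times.
    ``zeta``: scale of the Gamma(2, zeta) prior on each branch theta
    (mean 2 zeta).  ``alpha``/``beta``: Beta prior on inheritance
    probabilities (1, 1 = uniform).  ``time_prior``: "iid-exp" puts an
    independent Exp(delta) on every internal-node height; "exp-height"
    puts Exp(delta) on the root height with other heights uniform given it.
    """

    nu: float = 1.0
    eta: float | None = 2.0
    delta: float = 2.0
    zeta: float = 0.003
    alpha: float = 1.0
    beta: float = 1.0
    max_reticulations: int = 2
    time_prior: str = "iid-exp"

    def __post_init__(self) -> None:
        if min(self.nu, self.delta, self.zeta, self.alpha, self.beta) <= 0:
            raise ValueError("prior rates/scales must be positive")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive or None")
        if self.time_prior not in ("iid-exp", "exp-height"):
            raise ValueError("time_prior must be 'iid-exp' or 'exp-height'")


@dataclass
class ProposalConfig:
    """Tuning of the proposal kernel."""

    height_window: float = 0.01
    scale_log_window: float = 0.15
    theta_log_window: float = 0.6
    gamma_window: float = 0.15
    # move-type probabilities; infeasible picks (e.g. delete at k = 0)
    # propose nothing and count as rejected, keeping the menu fixed
    weights: dict[str, float] = field(default_factory=lambda: {
        "height": 0.25, "scale": 0.05, "theta": 0.20, "gamma": 0.10,
        "spr": 0.20, "add": 0.10, "delete": 0.10})


# ---------------------------------------------------------------------- #
# prior and posterior
# ---------------------------------------------------------------------- #
def _canonical_gamma(net: PhyloNetwork, r: int) -> float:
    p = sorted(net.parents[r])[0]
    return net.edges[(p, r)].gamma


def _gamma2_logpdf(x: float, zeta: float) -> float:
    # Gamma(shape 2, scale zeta)
    if x <= 0:
        return NEG_INF
    return math.log(x) - x / zeta - 2.0 * math.log(zeta)


def _beta_logpdf(x: float, a: float, b: float) -> float:
    if not 0.0 < x < 1.0:
        if x in (0.0, 1.0) and a == b == 1.0:
            return 0.0
        return NEG_INF
    lognorm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
    return lognorm + (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x)


def log_prior(net: PhyloNetwork, cfg: PriorConfig) -> float:
    """Log prior density; -inf encodes rejection of invalid candidates."""
    diag = validate_network(net)
    if not diag.ok:
        return NEG_INF
    retics = net.reticulations()
    k = len(retics)
    if k > cfg.max_reticulations:
        return NEG_INF
    lp = k * math.log(cfg.nu) - cfg.nu - math.lgamma(k + 1)
    if cfg.eta is not None:
        for r in retics:
            d = reticulation_diameter(net, r)
            lp += math.log(cfg.eta) - cfg.eta * d
    if not net.heights:
        net.compute_heights()
    internal = [v for v in net.children if net.children[v]]
    root = net.root()
    h_root = net.heights[root]
    if cfg.time_prior == "iid-exp":
        for v in internal:
            h = net.heights[v]
            if h < 0:
                return NEG_INF
            lp += math.log(cfg.delta) - cfg.delta * h
    else:  # exp-height
        lp += math.log(cfg.delta) - cfg.delta * h_root
        for v in internal:
            if v == root:
                continue
            h = net.heights[v]
            if h <= h_root:
                if h_root <= 0:
                    return NEG_INF
                lp -= math.log(h_root)
            else:  # nodes above the root cannot occur in this mode
                return NEG_INF
    for e in net.edges.values():
        if e.theta <= 0:
            return NEG_INF
        lp += _gamma2_logpdf(e.theta, cfg.zeta)
    lp += _gamma2_logpdf(net.root_theta, cfg.zeta)
    for r in retics:
        g = _canonical_gamma(net, r)
        if g is None or not 0 <= g <= 1:
            return NEG_INF
        lp += _beta_logpdf(g, cfg.alpha, cfg.beta)
    return float(lp)


@dataclass
class PosteriorState:
    net: PhyloNetwork
    log_lik: float
    log_pri: float
    temperature: float = 1.0

    @property
    def log_post(self) -> float:
        return self.log_lik + self.log_pri


class PosteriorTarget:
    """Evaluates log posterior = log likelihood + log prior; a shared
    propagator cache makes re-evaluation after single-branch moves cheap.
    With ``markers=None`` the likelihood is identically 0 (prior-only
    sampling, used to validate the jump kernel)."""

    def __init__(self, markers: MarkerMatrix | None, model: MutationModel,
                 cfg: PriorConfig) -> None:
        self.markers = markers
        self.model = model
        self.cfg = cfg
        self.cache: dict = {}

    def make_state(self, net: PhyloNetwork, temperature: float = 1.0
                   ) -> PosteriorState:
        lp = log_prior(net, self.cfg)
        if lp == NEG_INF:
            return PosteriorState(net, NEG_INF, NEG_INF, temperature)
        ll = 0.0
        if self.markers is not None:
            ll = dataset_loglik(net, self.markers, self.model,
                                propagator_cache=self.cache)
        return PosteriorState(net, ll, lp, temperature)


def log_posterior(state: PosteriorState, target: PosteriorTarget) -> float:
    """Posterior of a state, short-circuiting when the prior is 0."""
    if state.log_pri == NEG_INF:
        return NEG_INF
    return state.log_post


# ---------------------------------------------------------------------- #
# proposal kernel
# ---------------------------------------------------------------------- #
def _internal_nodes(net: PhyloNetwork) -> list[int]:
    return [v for v in net.children if net.children[v]]


def _move_height(net: PhyloNetwork, rng, prop: ProposalConfig):
    nodes = _internal_nodes(net)
    v = nodes[rng.integers(len(nodes))]
    net.heights[v] += rng.uniform(-prop.height_window, prop.height_window)
    net.set_lengths_from_heights()
    return 0.0


def _move_scale(net: PhyloNetwork, rng, prop: ProposalConfig):
    u = rng.uniform(-prop.scale_log_window, prop.scale_log_window)
    c = math.exp(u)
    nodes = _internal_nodes(net)
    for v in nodes:
        net.heights[v] *= c
    net.set_lengths_from_heights()
    return len(nodes) * u


def _move_theta(net: PhyloNetwork, rng, prop: ProposalConfig):
    edges = list(net.edges)
    i = rng.integers(len(edges) + 1)
    u = rng.uniform(-prop.theta_log_window, prop.theta_log_window)
    if i == len(edges):
        net.root_theta *= math.exp(u)
    else:
        net.edges[edges[i]].theta *= math.exp(u)
    return u


def _move_gamma(net: PhyloNetwork, rng, prop: ProposalConfig):
    retics = net.reticulations()
    if not retics:
        return None
    r = retics[rng.integers(len(retics))]
    p1, p2 = sorted(net.parents[r])
    g = net.edges[(p1, r)].gamma + rng.uniform(-prop.gamma_window,
                                               prop.gamma_window)
    # reflect into [0, 1] (symmetric proposal)
    g = g % 2.0
    if g > 1.0:
        g = 2.0 - g
    net.edges[(p1, r)].gamma = g
    net.edges[(p2, r)].gamma = 1.0 - g
    return 0.0


def _log_gamma_pdf(x: float, zeta: float) -> float:
    return _gamma2_logpdf(x, zeta)


def _move_add(net: PhyloNetwork, rng, prior: PriorConfig,
              prop: ProposalConfig, weights: dict[str, float]):
    """Insert one reticulation; returns the log Hastings ratio."""
    edges = list(net.edges)
    if not edges:
        return None
    root = net.root()
    e1 = edges[rng.integers(len(edges))]
    others = [e for e in edges if e != e1]
    j = rng.integers(len(others) + 1)
    lo1, hi1 = net.heights[e1[1]], net.heights[e1[0]]
    if hi1 <= lo1:
        return None
    t1 = rng.uniform(lo1, hi1)
    log_q = (-math.log(len(edges)) - math.log(len(others) + 1)
             - math.log(hi1 - lo1))
    h_root = net.heights[root]
    if j == len(others):
        # source attachment above the root
        t2 = h_root + rng.exponential(1.0 / prior.delta)
        log_q += math.log(prior.delta) - prior.delta * (t2 - h_root)
        use_rho = True
    else:
        e2 = others[j]
        lo2 = max(t1, net.heights[e2[1]])
        hi2 = net.heights[e2[0]]
        if hi2 <= lo2:
            return None
        t2 = rng.uniform(lo2, hi2)
        log_q += -math.log(hi2 - lo2)
        use_rho = False
    g = rng.beta(prior.alpha, prior.beta)
    log_q += _beta_logpdf(g, prior.alpha, prior.beta)
    th = [float(rng.gamma(2, prior.zeta)) for _ in range(3)]
    log_q += sum(_log_gamma_pdf(x, prior.zeta) for x in th)
    # surgery
    r = net.split_edge(*e1, t1, lower_theta=th[0])
    if use_rho:
        w = net.new_node()
        net.heights[w] = t2
        net.add_edge(w, root, t2 - h_root, th[1])
    else:
        w = net.split_edge(*e2, t2, lower_theta=th[1])
    net.add_edge(w, r, t2 - t1, th[2], g)
    up = [p for p in net.parents[r] if p != w][0]
    net.edges[(up, r)].gamma = 1.0 - g
    k_new = net.num_reticulations
    log_q_rev = (math.log(weights["delete"]) - math.log(k_new) - math.log(2))
    return log_q_rev - (math.log(weights["add"]) + log_q)


def _move_delete_impl(net: PhyloNetwork, rng, prior: PriorConfig,
                      prop: ProposalConfig, weights: dict[str, float]):
    """Remove one incoming edge of one reticulation; the Hastings ratio is
    the density of the insertion that would exactly restore it."""
    retics = net.reticulations()
    if not retics:
        return None
    k = len(retics)
    r = retics[rng.integers(k)]
    p1, p2 = net.parents[r]
    if p1 == p2:  # parallel-edge bubble: outside the sampled support
        return None
    drop = (p1, p2)[int(rng.integers(2))]
    keep = p2 if drop == p1 else p1
    (c,) = net.children[r]
    if (keep, c) in net.edges:
        return None  # suppressing r would create a parallel edge
    if len(net.children[drop]) != 2:
        # the source is a reticulation (or chain node) with no second
        # child; removing this in-edge has no single-step reverse insertion
        return None
    root = net.root()
    t1 = net.heights[r]
    t2 = net.heights[drop]
    dropped = net.remove_edge(drop, r)
    g_star = dropped.gamma
    th_h = dropped.theta
    th_1b = net.edges[(r, c)].theta
    net.edges[(keep, r)].gamma = None
    net.suppress_node(r)  # restores (keep, c) with the upper theta
    use_rho = drop == root
    if use_rho:
        (d,) = net.children[drop]
        th_2b = net.remove_edge(drop, d).theta
        net.remove_node(drop)  # d becomes the root
        rev_t2_lo = None
        rev_t2_hi = None
    else:
        (d,) = net.children[drop]
        (pd,) = net.parents[drop]
        if (pd, d) in net.edges:
            return None  # suppressing the source would duplicate an edge
        th_2b = net.edges[(drop, d)].theta
        net.suppress_node(drop)
        rev_t2_lo = max(t1, net.heights[d])
        rev_t2_hi = net.heights[pd]
    log_q_fwd = math.log(weights["delete"]) - math.log(k) - math.log(2)
    # density of the reverse insertion on the reduced network
    n_edges = len(net.edges)
    lo1, hi1 = net.heights[c], net.heights[keep]
    if not lo1 < t1 < hi1:
        return None
    log_q_rev = (math.log(weights["add"]) - 2 * math.log(n_edges)
                 - math.log(hi1 - lo1))
    if use_rho:
        h_root_new = net.heights[net.root()]
        if t2 <= h_root_new:
            return None
        log_q_rev += math.log(prior.delta) - prior.delta * (t2 - h_root_new)
    else:
        if not rev_t2_lo < t2 < rev_t2_hi:
            return None
        log_q_rev += -math.log(rev_t2_hi - rev_t2_lo)
    log_q_rev += _beta_logpdf(g_star, prior.alpha, prior.beta)
    for x in (th_1b, th_2b, th_h):
        log_q_rev += _log_gamma_pdf(x, prior.zeta)
    return log_q_rev - log_q_fwd


def _spr_candidates(net: PhyloNetwork) -> list[tuple[int, int]]:
    """Detachable parent edges: (p, w) where p has two children (so it can
    be suppressed).  When w is a reticulation this relocates one hybrid
    source; otherwise it is a rooted SPR respecting node heights."""
    root = net.root()
    out = []
    for (p, w) in net.edges:
        if w != root and len(net.children[p]) == 2:
            out.append((p, w))
    return out


def _move_spr(net: PhyloNetwork, rng, prior: PriorConfig,
              prop: ProposalConfig, weights: dict[str, float]):
    """Detach a subtree (or one incoming hybrid edge) and reattach it at a
    random time-compatible point; the pruned edge keeps its theta and
    inheritance probability.  The Hastings ratio accounts for candidate
    counts, attachment densities, and the one theta that is dropped at
    the suppressed node versus the one drawn at the new split."""
    cands = _spr_candidates(net)
    if not cands:
        return None
    p, w = cands[int(rng.integers(len(cands)))]
    h_w = net.heights[w]
    root = net.root()
    t_old = net.heights[p]
    moved = net.remove_edge(p, w)
    # suppress the vacated node p; record how the reverse move would have
    # to re-create the old attachment in the shared intermediate state
    if p == root:
        (d,) = net.children[p]
        theta_lost = net.remove_edge(p, d).theta
        net.remove_node(p)
        old_rho = True
        old_span = None
    else:
        (d,) = net.children[p]
        (pp,) = net.parents[p]
        if (pp, d) in net.edges:
            return None  # suppression would duplicate an edge
        theta_lost = net.edges[(p, d)].theta
        net.suppress_node(p)
        old_rho = False
        old_span = (max(h_w, net.heights[d]), net.heights[pp])
    # intermediate state: w floats; the resident root is the in-degree-0
    # node outside w's component
    res_roots = [v for v in net.children if not net.parents[v] and v != w]
    if len(res_roots) != 1:
        return None
    h_res = net.heights[res_roots[0]]
    base = max(h_res, h_w)
    edges = list(net.edges)
    # choose the new attachment: any edge, or the (infinite) root branch
    j = int(rng.integers(len(edges) + 1))
    theta_new = float(rng.gamma(2, prior.zeta))
    if j == len(edges):
        t_new = base + rng.exponential(1.0 / prior.delta)
        log_f_new = math.log(prior.delta) - prior.delta * (t_new - base)
        pnew = net.new_node()
        net.heights[pnew] = t_new
        net.add_edge(pnew, res_roots[0], t_new - h_res, theta_new)
    else:
        e = edges[j]
        lo = max(h_w, net.heights[e[1]])
        hi = net.heights[e[0]]
        if hi <= lo:
            return None
        t_new = rng.uniform(lo, hi)
        log_f_new = -math.log(hi - lo)
        pnew = net.split_edge(*e, t_new, lower_theta=theta_new)
    net.add_edge(pnew, w, t_new - h_w, moved.theta, moved.gamma)
    log_q_fwd = (-math.log(len(cands)) - math.log(len(edges) + 1)
                 + log_f_new + _log_gamma_pdf(theta_new, prior.zeta))
    # reverse: the same move type picks (pnew, w) in the new state and
    # reattaches at the old location in the same intermediate state
    cands_rev = len(_spr_candidates(net))
    if old_rho:
        if t_old <= base:
            return None
        log_f_old = math.log(prior.delta) - prior.delta * (t_old - base)
    else:
        lo, hi = old_span
        if not lo < t_old < hi:
            return None
        log_f_old = -math.log(hi - lo)
    log_q_rev = (-math.log(cands_rev) - math.log(len(edges) + 1)
                 + log_f_old + _log_gamma_pdf(theta_lost, prior.zeta))
    return log_q_rev - log_q_fwd


def _choose(weights: dict[str, float], rng) -> str:
    names = sorted(weights)
    total = sum(weights[n] for n in names)
    u = rng.random() * total
    acc = 0.0
    for n in names:
        acc += weights[n]
        if u < acc:
            return n
    return names[-1]


def propose(state: PosteriorState, rng, prior: PriorConfig,
            prop: ProposalConfig, target: PosteriorTarget
            ) -> tuple[PosteriorState, float, str]:
    """One proposal from the current state.

    Returns (proposed state, log Hastings ratio, move name); an infeasible
    pick returns the current state with ratio -inf (always rejected).
    """
    move = _choose(prop.weights, rng)
    net = state.net.copy()
    if move == "height":
        lhr = _move_height(net, rng, prop)
    elif move == "scale":
        lhr = _move_scale(net, rng, prop)
    elif move == "theta":
        lhr = _move_theta(net, rng, prop)
    elif move == "gamma":
        lhr = _move_gamma(net, rng, prop)
    elif move == "spr":
        lhr = _move_spr(net, rng, prior, prop, prop.weights)
    elif move == "add":
        lhr = _move_add(net, rng, prior, prop, prop.weights)
    else:
        lhr = _move_delete_impl(net, rng, prior, prop, prop.weights)
    if lhr is None:
        return state, NEG_INF, move
    new = target.make_state(net, state.temperature)
    return new, lhr, move


# ---------------------------------------------------------------------- #
# samplers
# ---------------------------------------------------------------------- #
@dataclass
class SampleTrace:
    """Thinned post-burn-in samples plus chain bookkeeping."""

    iterations: list[int] = field(default_factory=list)
    networks: list[str] = field(default_factory=list)  # rich Newick
    k_values: list[int] = field(default_factory=list)
    log_posts: list[float] = field(default_factory=list)
    log_liks: list[float] = field(default_factory=list)
    accept_counts: dict[str, int] = field(default_factory=dict)
    propose_counts: dict[str, int] = field(default_factory=dict)
    burnin: int = 0
    sample_freq: int = 1

    def __len__(self) -> int:
        return len(self.networks)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"iteration": self.iterations, "k": self.k_values,
                             "log_posterior": self.log_posts,
                             "log_likelihood": self.log_liks,
                             "network": self.networks})


def _accept(cur: PosteriorState, new: PosteriorState, lhr: float,
            rng) -> bool:
    if lhr == NEG_INF or new.log_pri == NEG_INF:
        return False
    delta = (new.log_post - cur.log_post) / cur.temperature + lhr
    return delta >= 0 or math.log(rng.random()) < delta


def run_rjmcmc(markers: MarkerMatrix | None, model: MutationModel,
               prior: PriorConfig, chain_length: int, burnin: int,
               sample_freq: int, start: PhyloNetwork,
               rng: np.random.Generator,
               prop: ProposalConfig | None = None,
               threads: int = 1,
               debug_check_every: int = 0) -> SampleTrace:
    """Reversible-jump MCMC; returns the thinned post-burn-in trace.

    ``markers=None`` samples from the prior alone (the kernel-validation
    mode).  ``debug_check_every`` > 0 re-derives the cached log posterior
    from scratch periodically and raises on disagreement.
    """
    if burnin >= chain_length:
        raise ValueError("burnin must be smaller than chain_length")
    prop = prop or ProposalConfig()
    target = PosteriorTarget(markers, model, prior)
    state = target.make_state(start.copy())
    if state.log_pri == NEG_INF:
        raise ValueError("starting network has prior 0")
    trace = SampleTrace(burnin=burnin, sample_freq=sample_freq)
    for it in range(1, chain_length + 1):
        new, lhr, move = propose(state, rng, prior, prop, target)
        trace.propose_counts[move] = trace.propose_counts.get(move, 0) + 1
        if _accept(state, new, lhr, rng):
            state = new
            trace.accept_counts[move] = trace.accept_counts.get(move, 0) + 1
        if debug_check_every and it % debug_check_every == 0:
            fresh = target.make_state(state.net)
            if abs(fresh.log_post - state.log_post) > 1e-9 * max(
                    1.0, abs(fresh.log_post)):
                raise AssertionError(
                    f"cache drift at iteration {it}: "
                    f"{state.log_post} vs fresh {fresh.log_post}")
        if it > burnin and (it - burnin) % sample_freq == 0:
            trace.iterations.append(it)
            trace.networks.append(write_rich_newick(state.net))
            trace.k_values.append(state.net.num_reticulations)
            trace.log_posts.append(state.log_post)
            trace.log_liks.append(state.log_lik)
    return trace


def run_mc3_preburnin(markers: MarkerMatrix | None, model: MutationModel,
                      prior: PriorConfig, start: PhyloNetwork,
                      temperatures: tuple[float, ...], iterations: int,
                      rng: np.random.Generator,
                      prop: ProposalConfig | None = None,
                      swap_every: int = 10) -> PhyloNetwork:
    """Metropolis-coupled pre-burn-in: heated chains (posterior^(1/T)) with
    periodic adjacent swaps; returns the highest-likelihood network
    visited by any chain."""
    if 1.0 not in temperatures:
        raise ValueError("temperatures must include 1.0")
    prop = prop or ProposalConfig()
    target = PosteriorTarget(markers, model, prior)
    rngs = rng.spawn(len(temperatures))
    states = [target.make_state(start.copy(), temperature=t)
              for t in temperatures]
    best_net, best_ll = start.copy(), states[0].log_lik
    for it in range(1, iterations + 1):
        for i, st in enumerate(states):
            new, lhr, _ = propose(st, rngs[i], prior, prop, target)
            if _accept(st, new, lhr, rngs[i]):
                states[i] = new
                if new.log_lik > best_ll:
                    best_ll = new.log_lik
                    best_net = new.net.copy()
        if len(states) > 1 and it % swap_every == 0:
            i = int(rng.integers(len(states) - 1))
            a, b = states[i], states[i + 1]
            d = (1.0 / a.temperature - 1.0 / b.temperature) * (
                b.log_post - a.log_post)
            if d >= 0 or math.log(rng.random()) < d:
                a.temperature, b.temperature = b.temperature, a.temperature
                states[i], states[i + 1] = b, a
    return best_net


# ---------------------------------------------------------------------- #
# posterior summaries
# ---------------------------------------------------------------------- #
def effective_sample_size(x) -> float:
    """Autocorrelation-based ESS (initial positive sequence estimator)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (n * var)
    s = 0.0
    for t in range(1, n):
        if acf[t] + (acf[t + 1] if t + 1 < n else 0.0) < 0:
            break
        s += acf[t]
    return float(n / (1.0 + 2.0 * s))


def summarize(trace: SampleTrace,
              reference: PhyloNetwork | None = None) -> dict:
    """MAP topology, reticulation-count distribution, per-parameter means
    for samples matching a reference topology, and an ESS estimate."""
    from .network import parse_rich_newick

    if not len(trace):
        raise ValueError("empty trace")
    nets = [parse_rich_newick(s) for s in trace.networks]
    # group samples into topology classes
    classes: list[tuple[PhyloNetwork, list[int]]] = []
    key_cache: dict[str, int] = {}
    for i, net in enumerate(nets):
        key = topology_key(net)
        ci = key_cache.get(key)
        if ci is None:
            for j, (rep, _) in enumerate(classes):
                if (rep.num_reticulations == net.num_reticulations
                        and networks_isomorphic(rep, net)):
                    ci = j
                    break
            if ci is None:
                classes.append((net, []))
                ci = len(classes) - 1
            key_cache[key] = ci
        classes[ci][1].append(i)
    freqs = [(len(idx) / len(nets), rep, idx) for rep, idx in classes]
    freqs.sort(key=lambda t: -t[0])
    # MAP topology: the class containing the highest-posterior sample
    i_map = int(np.argmax(trace.log_posts))
    map_class = next(f for f in freqs if i_map in f[2])
    k_arr = np.array(trace.k_values)
    k_dist = {int(k): float((k_arr == k).mean()) for k in np.unique(k_arr)}
    out = {
        "n_samples": len(nets),
        "map_topology": write_rich_newick(map_class[1]),
        "map_log_posterior": float(trace.log_posts[i_map]),
        "topology_frequencies": [(f, write_rich_newick(rep))
                                 for f, rep, _ in freqs[:10]],
        "k_distribution": k_dist,
        "ess_log_posterior": effective_sample_size(trace.log_posts),
    }
    if reference is not None:
        match = [n for n in nets
                 if n.num_reticulations == reference.num_reticulations
                 and n.leaf_names() == reference.leaf_names()
                 and networks_isomorphic(n, reference)]
        out["reference_match_fraction"] = len(match) / len(nets)
        if match:
            gammas = []
            heights = []
            thetas = []
            for n in match:
                for r in n.reticulations():
                    g = _canonical_gamma(n, r)
                    gammas.append(min(g, 1 - g))
                heights.append(n.heights[n.root()])
                thetas.extend(e.theta for e in n.edges.values())
            out["reference_mean_minor_gamma"] = (float(np.mean(gammas))
                                                 if gammas else None)
            out["reference_mean_root_height"] = float(np.mean(heights))
            out["reference_mean_theta"] = float(np.mean(thetas))
    return out
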