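"""Species-tree-only partial-likelihood recursion, coded independently of
the network engine (no labels, no splits) as a cross-check for the k = 0
case.  Deliberately minimal and self-contained: it builds its own rate
matrix and merges child vectors directly."""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

from .markers import MutationModel, SpeciesSite
from .network import PhyloNetwork


def _pairs(M: int) -> list[tuple[int, int]]:
    out = []
    for n in range(M + 1):
        out.extend((n, r) for r in range(n + 1))
    return out


def _rate(theta: float, u: float, v: float, M: int) -> np.ndarray:
    pairs = _pairs(M)
    loc = {p: i for i, p in enumerate(pairs)}
    Q = np.zeros((len(pairs),) * 2)
    for n in range(1, M + 1):
        for r in range(n + 1):
            i = loc[(n, r)]
            if r >= 1:
                Q[i, loc[(n, r - 1)]] = (n - r + 1) * v
            if r < n:
                Q[i, loc[(n, r + 1)]] = (r + 1) * u
            if n >= 2 and n - 1 - r >= 0 and r <= n - 1:
                Q[i, loc[(n - 1, r)]] = (n - 1 - r) * n / theta
            if n >= 2 and r >= 1:
                Q[i, loc[(n - 1, r - 1)]] = (r - 1) * n / theta
            Q[i, i] = -n * (n - 1) / theta - (n - r) * v - r * u
    return Q


def tree_site_likelihood(tree: PhyloNetwork, site: dict[str, SpeciesSite],
                         model: MutationModel) -> float:
    """Exact site likelihood on a species tree (no reticulations)."""
    if tree.num_reticulations:
        raise ValueError("tree reference requires k = 0")
    u, v = model.u, model.v
    M = sum(o.lineages for o in site.values())
    pairs = _pairs(M)
    loc = {p: i for i, p in enumerate(pairs)}

    def leaf_vec(obs: SpeciesSite) -> np.ndarray:
        f = np.zeros(len(pairs))
        if obs.dominant:
            n2 = 2 * obs.n
            if obs.r == 0:
                f[loc[(n2, 0)]] = 1.0
            else:
                for r in range(obs.r, 2 * obs.r + 1):
                    c = (math.factorial(obs.n)
                         / (math.factorial(r - obs.r)
                            * math.factorial(2 * obs.r - r)
                            * math.factorial(obs.n - obs.r)))
                    f[loc[(n2, r)]] = c * 2 ** (2 * obs.r - r) / math.comb(n2, r)
        else:
            f[loc[(obs.n, obs.r)]] = 1.0
        return f

    def merge(fy: np.ndarray, fz: np.ndarray) -> np.ndarray:
        f = np.zeros(len(pairs))
        for (ny, ry), iy in loc.items():
            if fy[iy] == 0.0:
                continue
            for (nz, rz), iz in loc.items():
                if fz[iz] == 0.0:
                    continue
                n, r = ny + nz, ry + rz
                if n > M:
                    continue
                w = (math.comb(r, ry) * math.comb(n - r, ny - ry)
                     / math.comb(n, ny))
                f[loc[(n, r)]] += fy[iy] * fz[iz] * w
        return f

    def bottom(v_node: int) -> np.ndarray:
        kids = tree.children[v_node]
        if not kids:
            return leaf_vec(site[tree.labels[v_node]])
        tops = []
        for c in kids:
            e = tree.edges[(v_node, c)]
            P = expm(_rate(e.theta, u, v, M) * e.length)
            tops.append(bottom(c) @ P)
        if len(tops) == 1:
            return tops[0]
        return merge(tops[0], tops[1])

    f_root = bottom(tree.root())
    # stationary vector of the root-branch chain, solved level by level
    Q = _rate(tree.root_theta, u, v, M)
    x = np.zeros(len(pairs))
    x[loc[(1, 0)]] = u / (u + v)
    x[loc[(1, 1)]] = v / (u + v)
    for n in range(2, M + 1):
        rows = [loc[(n, r)] for r in range(n + 1)]
        prev = [loc[(n - 1, r)] for r in range(n)]
        W = Q[np.ix_(rows, rows)]
        b = -Q[np.ix_(rows, prev)] @ x[prev]
        x[rows] = np.linalg.solve(W, b)
    return float(f_root @ x)
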