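"""Bi-allelic marker data and the two-state mutation model.

Markers are coded red/green; per site each sampled haploid lineage carries
one allele.  Three observation modes are supported:

* haploid: per individual 0 (green) / 1 (red);
* diploid co-dominant: per individual the red-allele count 0/1/2;
* diploid dominant (AFLP bands, red dominant): per individual 0/1 band
  presence, where heterozygote and red homozygote are indistinguishable.

Missing values are coded ``?`` on file and -1 in memory; a missing
individual simply does not contribute lineages at that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

__all__ = ["MutationModel", "SpeciesSite", "MarkerMatrix",
           "parse_taxon_map", "format_taxon_map"]

MISSING = -1


@dataclass(frozen=True)
class MutationModel:
    """Two-state mutation: rate u red->green, v green->red (forward in
    time).  Stationary frequencies are v/(u+v) red and u/(u+v) green."""

    u: float = 1.0
    v: float = 1.0

    def __post_init__(self) -> None:
        if self.u <= 0 or self.v <= 0:
            raise ValueError("mutation rates must be positive")

    @classmethod
    def from_pi0(cls, pi0: float) -> "MutationModel":
        """Map a stationary green frequency pi0 to (u, v): u = 1/(2 pi0),
        v = 1/(2 (1 - pi0)); pi0 = 0.5 gives u = v = 1."""
        if not 0 < pi0 < 1:
            raise ValueError("pi0 must be in (0, 1)")
        return cls(u=1.0 / (2.0 * pi0), v=1.0 / (2.0 * (1.0 - pi0)))

    @property
    def stationary_red(self) -> float:
        return self.v / (self.u + self.v)

    def transition(self, t: float) -> np.ndarray:
        """2x2 transition matrix over states (red, green) after time t."""
        tot = self.u + self.v
        e = np.exp(-tot * t)
        pr = self.v / tot  # stationary red
        return np.array([[pr + (1 - pr) * e, (1 - pr) * (1 - e)],
                         [pr * (1 - e), (1 - pr) + pr * e]])


@dataclass(frozen=True)
class SpeciesSite:
    """Observation for one species at one site.

    ``n`` counts sampled diploid individuals when ``dominant`` else sampled
    haploid lineages; ``r`` counts band-present individuals when
    ``dominant`` else red lineages.
    """

    n: int
    r: int
    dominant: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.r <= self.n:
            raise ValueError(f"need 0 <= r <= n, got r={self.r} n={self.n}")

    @property
    def lineages(self) -> int:
        return 2 * self.n if self.dominant else self.n


class MarkerMatrix:
    """Individuals x sites bi-allelic observations plus a taxon map."""

    def __init__(self, data: pd.DataFrame, taxon_map: dict[str, list[str]],
                 diploid: bool = False, dominant: bool = False,
                 polymorphic_only: bool = False) -> None:
        if dominant and not diploid:
            raise ValueError("dominant markers require diploid data")
        self.data = data
        self.taxon_map = {sp: list(inds) for sp, inds in taxon_map.items()}
        self.diploid = diploid
        self.dominant = dominant
        self.polymorphic_only = polymorphic_only
        inds = [i for v in taxon_map.values() for i in v]
        if set(inds) != set(data.index):
            raise ValueError("taxon map does not match matrix rows")
        vmax = 2 if (diploid and not dominant) else 1
        vals = data.to_numpy()
        bad = (vals != MISSING) & ((vals < 0) | (vals > vmax))
        if bad.any():
            raise ValueError("marker values out of range for the declared "
                             "ploidy/dominance")

    # -------------------------------------------------------------- #
    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @property
    def species(self) -> list[str]:
        return list(self.taxon_map)

    def total_lineages(self) -> int:
        per = 2 if self.diploid else 1
        return per * sum(len(v) for v in self.taxon_map.values())

    def site_observation(self, j: int) -> dict[str, SpeciesSite]:
        """Per-species (n, r) summary for site column j; missing
        individuals are dropped from the sample at that site."""
        col = self.data.iloc[:, j]
        out: dict[str, SpeciesSite] = {}
        for sp, inds in self.taxon_map.items():
            vals = col.loc[inds].to_numpy()
            vals = vals[vals != MISSING]
            if self.dominant:
                out[sp] = SpeciesSite(len(vals), int((vals > 0).sum()),
                                      dominant=True)
            elif self.diploid:
                out[sp] = SpeciesSite(2 * len(vals), int(vals.sum()))
            else:
                out[sp] = SpeciesSite(len(vals), int(vals.sum()))
        return out

    def patterns(self) -> list[tuple[dict[str, SpeciesSite], int]]:
        """Deduplicated site patterns with multiplicities; weights sum to
        the site count.  Computed once and cached (vectorized over sites)."""
        cached = getattr(self, "_patterns", None)
        if cached is not None:
            return cached
        species = list(self.taxon_map)
        rows = {sp: [self.data.index.get_loc(i) for i in inds]
                for sp, inds in self.taxon_map.items()}
        vals = self.data.to_numpy()
        ns = np.empty((len(species), self.n_sites), dtype=int)
        rs = np.empty_like(ns)
        for si, sp in enumerate(species):
            block = vals[rows[sp], :]
            present = block != MISSING
            n_ind = present.sum(axis=0)
            if self.dominant:
                ns[si] = n_ind
                rs[si] = ((block > 0) & present).sum(axis=0)
            else:
                ns[si] = (2 * n_ind) if self.diploid else n_ind
                rs[si] = np.where(present, block, 0).sum(axis=0)
        counter: Counter = Counter(map(tuple, np.concatenate([ns, rs]).T))
        out = []
        for key, w in sorted(counter.items()):
            kn, kr = key[:len(species)], key[len(species):]
            obs = {sp: SpeciesSite(int(kn[si]), int(kr[si]),
                                   dominant=self.dominant)
                   for si, sp in enumerate(species)}
            out.append((obs, int(w)))
        self._patterns = out
        return out

    # -------------------------------------------------------------- #
    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df = df.astype(object).where(df != MISSING, "?")
        df.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path, taxon_map: dict[str, list[str]] | str,
                 diploid: bool = False, dominant: bool = False,
                 polymorphic_only: bool = False) -> "MarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col="individual", dtype=str)
        df = df.replace("?", str(MISSING)).astype(int)
        if isinstance(taxon_map, str):
            taxon_map = parse_taxon_map(taxon_map)
        return cls(df, taxon_map, diploid=diploid, dominant=dominant,
                   polymorphic_only=polymorphic_only)


def parse_taxon_map(text: str) -> dict[str, list[str]]:
    """Parse ``"<A:A_0; C:C_0,C_1>"`` (angle brackets optional)."""
    text = text.strip().lstrip("<").rstrip(">").strip()
    out: dict[str, list[str]] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip().rstrip(";")
        if not chunk:
            continue
        sp, _, inds = chunk.partition(":")
        out[sp.strip()] = [i.strip() for i in inds.split(",") if i.strip()]
    return out


def format_taxon_map(tm: dict[str, list[str]]) -> str:
    return "<" + "; ".join(f"{sp}:{','.join(inds)}" for sp, inds in tm.items()) + ">"
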