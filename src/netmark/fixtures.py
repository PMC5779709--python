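"""Named model networks used throughout the tests and examples.

``model_1retic`` is a 5-taxon, 1-reticulation network (hybridization from
the R lineage into Q, inheritance 0.7/0.3), ``model_2retic`` adds a second
hybridization from C into A, and ``model_4taxon`` is a small 4-taxon
network with inheritance 0.8/0.2 used for multi-individual sampling
studies.  Branch lengths are in expected mutations per site; external
branches carry theta 0.006 (0.005 throughout the 4-taxon network) and
internal branches 0.005.
"""

from __future__ import annotations

from .network import PhyloNetwork, parse_rich_newick

MODEL_1RETIC = (
    "[0.006](((((Q:0.004:0.006)I5#H1:0.002:0.005:0.7,A:0.006:0.006)"
    "I3:0.016:0.005,L:0.022:0.006)I2:0.02:0.005,(I5#H1:0.003:0.005:0.3,"
    "R:0.007:0.006)I4:0.035:0.005)I1:0.038:0.005,C:0.08:0.006);"
)

MODEL_2RETIC = (
    "[0.006](((((Q:0.004:0.006)I5#H1:0.002:0.005:0.7,(A:0.003:0.006)"
    "I6#H2:0.003:0.005:0.6)I3:0.016:0.005,L:0.022:0.006)I2:0.02:0.005,"
    "(I5#H1:0.003:0.005:0.3,R:0.014:0.006)I4:0.028:0.005)I1:0.038:0.005,"
    "(C:0.005:0.006,I6#H2:0.002:0.005:0.4)I7:0.075:0.005);"
)

MODEL_4TAXON = (
    "[0.005]((((C:0.005:0.005)I1#H1:0.006:0.005:0.8,D:0.011:0.005)"
    ":0.009:0.005,(B:0.014:0.005,I1#H1:0.009:0.005:0.2):0.006:0.005)"
    ":0.005:0.005,A:0.025:0.005);"
)

FIXTURES = {
    "model_1retic": MODEL_1RETIC,
    "model_2retic": MODEL_2RETIC,
    "model_4taxon": MODEL_4TAXON,
}

TAXON_MAP_5 = {sp: [f"{sp}_0"] for sp in ("A", "C", "L", "Q", "R")}


def load_fixture(kind: str) -> PhyloNetwork:
    try:
        return parse_rich_newick(FIXTURES[kind])
    except KeyError as exc:
        raise KeyError(f"unknown fixture {kind!r}; have {sorted(FIXTURES)}") from exc


def make_fixtures(kind: str, outdir) -> list[str]:
    """Write the named fixture network(s) to ``outdir``; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kinds = list(FIXTURES) if kind == "all" else [kind]
    paths = []
    for k in kinds:
        load_fixture(k)  # validates
        p = outdir / f"{k}.rich_newick"
        p.write_text(FIXTURES[k] + "\n")
        paths.append(str(p))
    return paths
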