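"""Packaged reference data for the human bromodomain (BRD) protein family.

The family list holds the 42 human gene symbols encoding bromodomain-containing
proteins. The clique file holds the curated maximal cliques (size >= 3) of the
BRD-BRD interaction network, one clique per line as comma-separated symbols;
it is the published complex-prediction result that the clique machinery is
validated against as a fixed point (reconstruct the graph from the cliques,
re-enumerate, recover the same cliques).
"""

from __future__ import annotations

from importlib import resources


def _read_data_text(name: str) -> str:
    return resources.files("brdnet.data").joinpath(name).read_text(encoding="utf-8")


def load_brd_family() -> list[str]:
    """Return the 42 BRD-family gene symbols, sorted."""
    symbols = [line.strip().upper() for line in _read_data_text("brd_family.txt").splitlines()]
    return sorted(s for s in symbols if s)


def load_brd_cliques() -> list[frozenset[str]]:
    """Return the curated BRD-BRD maximal cliques as frozensets of symbols."""
    cliques = []
    for line in _read_data_text("brd_family_cliques.txt").splitlines():
        line = line.strip()
        if line:
            cliques.append(frozenset(sym.strip().upper() for sym in line.split(",")))
    return cliques
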