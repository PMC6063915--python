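"""Interaction-network loading and the score/measured-gene filters."""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from . import io as pio

logger = logging.getLogger(__name__)

SCORE_MIN_DEFAULT = 500  # confidence cutoff: edges with score < 500 are dropped


class InteractionNetwork:
    """Undirected gene-gene edges with integer confidence scores in [0, 1000].

    Edges are keyed by the sorted endpoint pair; self-loops and duplicate
    undirected edges are rejected at construction.
    """

    def __init__(self, edges: dict[tuple[str, str], int] | None = None):
        self.edges: dict[tuple[str, str], int] = {}
        for (a, b), score in (edges or {}).items():
            self.add_edge(a, b, score)

    def add_edge(self, a: str, b: str, score: int) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not 0 <= int(score) <= 1000:
            raise ValueError(f"score {score} outside [0, 1000] for edge ({a}, {b})")
        key = (a, b) if a < b else (b, a)
        if key in self.edges:
            raise ValueError(f"duplicate undirected edge {key}")
        self.edges[key] = int(score)

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a < b else (b, a)) in self.edges

    def neighbors(self, gene: str):
        for (a, b) in self.edges:
            if a == gene:
                yield b
            elif b == gene:
                yield a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), score in self.edges.items():
            g.add_edge(a, b, score=score)
        return g

    def __eq__(self, other):
        return isinstance(other, InteractionNetwork) and self.edges == other.edges

    def __repr__(self):
        return f"InteractionNetwork({len(self.nodes)} nodes, {len(self.edges)} edges)"


def load_interactions(
    path,
    score_min: int = SCORE_MIN_DEFAULT,
    alias_path=None,
    normalize_case: bool = True,
) -> InteractionNetwork:
    """Load a 3-column edge-list TSV and apply the confidence filter.

    Edges with score < ``score_min`` are removed; reciprocal duplicates are
    collapsed keeping the maximum score; self-loops are dropped and counted in
    the log. An optional 2-column alias TSV remaps identifiers before
    case-normalization.
    """
    rows = pio.read_edge_rows(path)
    aliases = pio.read_alias_map(alias_path) if alias_path is not None else {}
    best: dict[tuple[str, str], int] = {}
    n_self = 0
    n_low = 0
    for a, b, score in rows:
        a = aliases.get(a, a)
        b = aliases.get(b, b)
        if normalize_case:
            a, b = a.upper(), b.upper()
        if a == b:
            n_self += 1
            continue
        if score < score_min:
            n_low += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best or score > best[key]:
            best[key] = score
    net = InteractionNetwork(best)
    logger.info(
        "load_interactions(%s): kept %d edges over %d nodes "
        "(dropped %d below score %d, %d self-loops)",
        Path(path).name, net.n_edges(), len(net.nodes), n_low, score_min, n_self,
    )
    return net


def restrict_to_measured(network: InteractionNetwork, gene_universe) -> InteractionNetwork:
    """Keep edges whose both endpoints are in the measured-gene universe."""
    universe = set(gene_universe)
    kept = {
        pair: score for pair, score in network.edges.items()
        if pair[0] in universe and pair[1] in universe
    }
    out = InteractionNetwork(kept)
    logger.info(
        "restrict_to_measured: kept %d of %d edges (%d nodes)",
        out.n_edges(), network.n_edges(), len(out.nodes),
    )
    return out


def write_interactions(network: InteractionNetwork, path) -> None:
    pio.write_edge_rows(
        [(a, b, s) for (a, b), s in sorted(network.edges.items())], path
    )
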