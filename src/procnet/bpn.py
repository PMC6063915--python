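"""Linking enriched gene sets through interactions between perturbed genes.

Candidate links connect two enriched gene sets when at least one network edge
joins a perturbed gene assignable to one set with a perturbed gene assignable
to the other. A Metropolis sampler then explores subsets of candidate links
under the target density pi(S) proportional to exp(beta * score(S)) with

    score(S) = coverage(S) - lambda * |S|

where coverage(S) is the number of distinct network edges explained by at
least one selected link. Posterior link probabilities are inclusion
frequencies over post-burn-in (thinned) states; thresholding at a probability
cutoff yields the final process-network graph.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .gsea import EnrichmentResult
from .network import InteractionNetwork


@dataclass(frozen=True)
class SupportInteraction:
    """One network edge supporting a link, oriented (side-a gene, side-b gene)."""

    gene_a: str
    gene_b: str
    a_in_leading_edge: bool
    b_in_leading_edge: bool

    @property
    def edge(self) -> tuple[str, str]:
        """Undirected edge key (sorted endpoints)."""
        return (self.gene_a, self.gene_b) if self.gene_a < self.gene_b else (self.gene_b, self.gene_a)

    @property
    def both_in_leading_edges(self) -> bool:
        return self.a_in_leading_edge and self.b_in_leading_edge


@dataclass(frozen=True)
class CandidateLink:
    set_a: str
    set_b: str
    support: tuple[SupportInteraction, ...]

    def __post_init__(self):
        if self.set_a == self.set_b:
            raise ValueError("a link may not join a gene set to itself")
        if not self.support:
            raise ValueError("candidate link needs at least one supporting interaction")
        for s in self.support:
            if s.gene_a == s.gene_b:
                raise ValueError("supporting interaction endpoints must differ")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.set_a, self.set_b) if self.set_a < self.set_b else (self.set_b, self.set_a)

    @property
    def support_edges(self) -> frozenset:
        return frozenset(s.edge for s in self.support)


@dataclass
class BpnConfig:
    burn_in_steps: int = 10_000_000
    mcmc_steps: int = 100_000_000
    link_penalty: float = 2.0  # lambda; calibration knob
    inverse_temperature: float = 1.0  # beta; calibration knob
    thinning: int = 100
    probability_threshold: float = 0.45
    rng_seed: int = 0

    def __post_init__(self):
        if self.mcmc_steps <= 0:
            raise ValueError("mcmc_steps must be positive")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be >= 0")
        if self.link_penalty < 0:
            raise ValueError("link_penalty must be >= 0")
        if self.inverse_temperature <= 0 and self.inverse_temperature != 0:
            raise ValueError("inverse_temperature must be >= 0")
        if not 0 <= self.probability_threshold <= 1:
            raise ValueError("probability_threshold must lie in [0, 1]")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class BpnResult:
    candidates: list[CandidateLink]
    probabilities: np.ndarray  # posterior inclusion probability per candidate
    best_state: frozenset  # candidate indices of the best-scoring subset visited
    best_score: float
    n_samples: int
    config: BpnConfig

    def probability_of(self, set_a: str, set_b: str) -> float:
        pair = (set_a, set_b) if set_a < set_b else (set_b, set_a)
        for link, p in zip(self.candidates, self.probabilities):
            if link.pair == pair:
                return float(p)
        raise KeyError(f"no candidate link between {set_a!r} and {set_b!r}")


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------

def build_candidate_links(
    significant: list[EnrichmentResult],
    perturbed: set[str],
    network: InteractionNetwork,
) -> list[CandidateLink]:
    """Collect, per unordered pair of significant sets, the supporting edges.

    An edge (u, v) with both endpoints perturbed supports the pair (A, B) if
    the endpoints can be assigned to different sets (u in A and v in B, or
    v in A and u in B). A gene annotated to both sets may serve either side,
    but an edge never links a set to itself. When both orientations are
    valid the one with more leading-edge endpoints is recorded.
    """
    members = {r.name: frozenset(r.members) for r in significant}
    leading = {r.name: frozenset(r.leading_edge_genes) for r in significant}
    if len(members) != len(significant):
        raise ValueError("duplicate gene set name among significant results")
    gene_to_sets: dict[str, list[str]] = {}
    for r in significant:
        for g in r.members:
            gene_to_sets.setdefault(g, []).append(r.name)

    support: dict[tuple[str, str], list[SupportInteraction]] = {}
    for (u, v) in sorted(network.edges):
        if u not in perturbed or v not in perturbed:
            continue
        sets_u = gene_to_sets.get(u, ())
        sets_v = gene_to_sets.get(v, ())
        if not sets_u or not sets_v:
            continue
        pairs = {
            (a, b) if a < b else (b, a)
            for a in sets_u for b in sets_v if a != b
        }
        for a, b in sorted(pairs):
            orientations = []
            if u in members[a] and v in members[b]:
                orientations.append(
                    SupportInteraction(u, v, u in leading[a], v in leading[b])
                )
            if v in members[a] and u in members[b]:
                orientations.append(
                    SupportInteraction(v, u, v in leading[a], u in leading[b])
                )
            chosen = max(
                orientations,
                key=lambda s: (s.a_in_leading_edge + s.b_in_leading_edge),
            )
            support.setdefault((a, b), []).append(chosen)

    return [
        CandidateLink(a, b, tuple(interactions))
        for (a, b), interactions in sorted(support.items())
    ]


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def coverage(selected) -> int:
    """Distinct network edges explained by at least one selected link."""
    edges: set = set()
    for link in selected:
        edges.update(link.support_edges)
    return len(edges)


def bpn_score(selected, link_penalty: float = 2.0) -> float:
    """Parsimony objective: coverage minus lambda times the number of links."""
    selected = list(selected)
    return coverage(selected) - link_penalty * len(selected)


# ---------------------------------------------------------------------------
# Metropolis sampler
# ---------------------------------------------------------------------------

def mcmc_bpn(candidates: list[CandidateLink], config: BpnConfig | None = None) -> BpnResult:
    """Sample link subsets with single-candidate-toggle Metropolis moves.

    The chain starts from the empty subset; each step toggles one uniformly
    chosen candidate and accepts with probability min(1, exp(beta * dscore)).
    The proposal is symmetric, so the stationary distribution is
    pi(S) proportional to exp(beta * score(S)). Posterior probabilities are
    inclusion frequencies over post-burn-in states taken every ``thinning``
    steps. Fully reproducible from ``config.rng_seed``.
    """
    if config is None:
        config = BpnConfig()
    k = len(candidates)
    if k == 0:
        raise ValueError(
            "no candidate links to sample; review the significance threshold "
            "and interaction filters upstream"
        )
    edge_ids: dict[tuple[str, str], int] = {}
    support_idx: list[np.ndarray] = []
    for link in candidates:
        idx = []
        for edge in sorted(link.support_edges):
            if edge not in edge_ids:
                edge_ids[edge] = len(edge_ids)
            idx.append(edge_ids[edge])
        support_idx.append(np.asarray(idx, dtype=np.int64))

    rng = np.random.default_rng(config.rng_seed)
    beta = float(config.inverse_temperature)
    lam = float(config.link_penalty)
    counts = np.zeros(len(edge_ids), dtype=np.int64)
    state = np.zeros(k, dtype=bool)
    score = 0.0
    best_score = 0.0
    best_state: frozenset = frozenset()
    inclusion = np.zeros(k, dtype=np.int64)
    n_samples = 0

    total = config.burn_in_steps + config.mcmc_steps
    block = 65536
    step = 0
    while step < total:
        b = min(block, total - step)
        picks = rng.integers(0, k, size=b)
        us = rng.random(b)
        for t in range(b):
            i = picks[t]
            idx = support_idx[i]
            if state[i]:
                dscore = -int(np.count_nonzero(counts[idx] == 1)) + lam
            else:
                dscore = int(np.count_nonzero(counts[idx] == 0)) - lam
            if dscore >= 0 or us[t] < math.exp(beta * dscore):
                if state[i]:
                    counts[idx] -= 1
                    state[i] = False
                else:
                    counts[idx] += 1
                    state[i] = True
                score += dscore
                if score > best_score:
                    best_score = score
                    best_state = frozenset(np.nonzero(state)[0].tolist())
            global_step = step + t + 1
            if global_step > config.burn_in_steps and (
                (global_step - config.burn_in_steps) % config.thinning == 0
            ):
                inclusion += state
                n_samples += 1
        step += b

    if n_samples == 0:
        raise ValueError("no post-burn-in samples; increase mcmc_steps or lower thinning")
    return BpnResult(
        candidates=list(candidates),
        probabilities=inclusion / n_samples,
        best_state=best_state,
        best_score=float(best_score),
        n_samples=n_samples,
        config=config,
    )


def enumerate_posterior(
    candidates: list[CandidateLink], link_penalty: float = 2.0, inverse_temperature: float = 1.0
) -> np.ndarray:
    """Exact posterior marginals by enumerating all 2^k subsets (small k only)."""
    k = len(candidates)
    if k > 20:
        raise ValueError("exact enumeration limited to k <= 20 candidates")
    log_w = np.empty(2 ** k)
    member = np.zeros((2 ** k, k), dtype=bool)
    for bits in range(2 ** k):
        sel = [candidates[i] for i in range(k) if bits >> i & 1]
        log_w[bits] = inverse_temperature * bpn_score(sel, link_penalty)
        for i in range(k):
            member[bits, i] = bool(bits >> i & 1)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return (w[:, None] * member).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# thresholding and reporting
# ---------------------------------------------------------------------------

def threshold_bpn(
    result: BpnResult,
    tau: float | None = None,
    directions: dict[str, str] | None = None,
    q_values: dict[str, float] | None = None,
) -> tuple[nx.Graph, list[tuple[str, ...]]]:
    """Retain links with posterior probability >= tau (inclusive boundary).

    Returns the thresholded graph (nodes carry ``direction`` and ``q_value``
    attributes when provided) and its connected components as sorted tuples in
    deterministic order.
    """
    if tau is None:
        tau = result.config.probability_threshold
    if not 0 <= tau <= 1:
        raise ValueError(f"probability threshold {tau} outside [0, 1]")
    graph = nx.Graph()
    for link, p in zip(result.candidates, result.probabilities):
        if p >= tau:
            a, b = link.pair
            graph.add_edge(a, b, probability=float(p), n_support=len(link.support))
    for node in graph.nodes:
        if directions is not None:
            graph.nodes[node]["direction"] = directions.get(node, "unknown")
        if q_values is not None:
            graph.nodes[node]["q_value"] = q_values.get(node, float("nan"))
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c),
    )
    return graph, components


def quantile_threshold(
    result: BpnResult, top_fraction: float, n_possible_links: int | None = None
) -> float:
    """Probability cutoff retaining the top fraction of possible links.

    ``n_possible_links`` defaults to C(m, 2) over the m gene sets appearing in
    the candidate list; pass the count over all significant sets to use that
    denominator instead. Ties at the cutoff are retained together.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if n_possible_links is None:
        sets = {s for link in result.candidates for s in link.pair}
        m = len(sets)
        n_possible_links = m * (m - 1) // 2
    n_keep = math.ceil(top_fraction * n_possible_links)
    probs = np.sort(result.probabilities)[::-1]
    if n_keep >= len(probs):
        return float(probs[-1])
    return float(probs[n_keep - 1])


@dataclass
class LinkReport:
    set_a: str
    set_b: str
    n_support: int
    n_leading_edge_support: int
    interactions: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.set_a} -- {self.set_b}: "
            f"{self.n_leading_edge_support} of {self.n_support} supporting "
            "interactions connect leading-edge genes on both sides"
        )


def link_report(link: CandidateLink, results: list[EnrichmentResult] | None = None) -> LinkReport:
    """Dissect one link: total support vs support inside both leading edges."""
    interactions = [
        {
            "gene_a": s.gene_a,
            "gene_b": s.gene_b,
            "a_in_leading_edge": s.a_in_leading_edge,
            "b_in_leading_edge": s.b_in_leading_edge,
        }
        for s in link.support
    ]
    n_le = sum(1 for s in link.support if s.both_in_leading_edges)
    return LinkReport(
        set_a=link.set_a,
        set_b=link.set_b,
        n_support=len(link.support),
        n_leading_edge_support=n_le,
        interactions=interactions,
    )


def links_to_frame(result: BpnResult):
    import pandas as pd

    rows = []
    for link, p in zip(result.candidates, result.probabilities):
        n_le = sum(1 for s in link.support if s.both_in_leading_edges)
        rows.append(
            {
                "set_a": link.pair[0],
                "set_b": link.pair[1],
                "n_support": len(link.support),
                "n_leading_edge_support": n_le,
                "probability": float(p),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["probability", "set_a", "set_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def write_sif(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\tlink\t{b}\n")
        for node in sorted(graph.nodes):
            if graph.degree[node] == 0:
                fh.write(f"{node}\n")
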