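"""Synthetic fixtures with planted structure for end-to-end testing.

Three generators share one seed: gene set collections with controllable
overlap, two-condition log-scale expression matrices with planted
differentially expressed (DE) sets, and interaction networks with planted
excess connectivity between chosen set pairs over an Erdos-Renyi background.
The planted truth is returned alongside each matrix so recovery rates can be
scored without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleGroup
from .gsea import Contrast, GeneSetCollection
from .network import InteractionNetwork

# fixed sub-stream keys so each generator is deterministic regardless of call order
_STREAMS = {"sets": 1, "expression": 2, "network": 3}

PLANTED_SCORE = 900  # above the default confidence cutoff


@dataclass
class SyntheticConfig:
    n_genes: int = 1000
    n_replicates_per_group: int = 3
    n_sets: int = 20
    set_size_range: tuple[int, int] = (10, 50)
    set_overlap_fraction: float = 0.0
    n_planted_de_sets: int = 3
    effect_size: float = 2.0  # log-scale shift in units of gene noise SD
    noise_sd: float = 1.0
    background_edge_prob: float = 0.0
    planted_links: list[tuple[str, str, int]] = field(default_factory=list)
    rng_seed: int = 0
    planted_de_set_names: list[str] | None = None  # default: seeded random choice

    def validate(self) -> None:
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError(f"set_size_range {self.set_size_range} outside [1, {self.n_genes}]")
        if self.n_planted_de_sets > self.n_sets:
            raise ValueError("n_planted_de_sets exceeds n_sets")
        if not 0 <= self.set_overlap_fraction <= 1:
            raise ValueError("set_overlap_fraction must lie in [0, 1]")
        if not 0 <= self.background_edge_prob <= 1:
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        for a, b, k in self.planted_links:
            if a == b:
                raise ValueError(f"planted link joins set {a!r} to itself")
            if k < 0:
                raise ValueError("planted link edge count must be >= 0")


@dataclass
class SyntheticTruth:
    planted_de_set_names: list[str]
    planted_up_or_down: dict[str, str]  # set name -> "up" | "down"
    planted_link_pairs: list[tuple[str, str]]
    de_gene_list: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_link_pairs"] = [tuple(p) for p in d["planted_link_pairs"]]
        return cls(**d)


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(n_genes)]


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.rng_seed])


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(config: SyntheticConfig) -> GeneSetCollection:
    """Draw ``n_sets`` sets with sizes uniform in ``set_size_range``.

    A fraction ``set_overlap_fraction`` of each set (after the first) is drawn
    from genes already used by earlier sets; the remainder comes from unused
    genes while they last, then from the whole universe. With overlap 0 and
    enough genes, sets are pairwise disjoint by construction.
    """
    config.validate()
    rng = _rng(config, "sets")
    genes = gene_universe(config.n_genes)
    lo, hi = config.set_size_range
    unused = list(genes)
    used: list[str] = []
    sets: dict[str, tuple[str, ...]] = {}
    for s in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        n_overlap = min(int(round(config.set_overlap_fraction * size)), len(used))
        chosen: list[str] = []
        if n_overlap:
            chosen.extend(rng.choice(used, size=n_overlap, replace=False).tolist())
        n_new = size - len(chosen)
        if n_new <= len(unused):
            picked = rng.choice(len(unused), size=n_new, replace=False)
            fresh = [unused[i] for i in sorted(picked)]
        else:
            fresh = list(unused)
            pool = sorted(set(genes) - set(chosen) - set(fresh))
            extra = rng.choice(pool, size=n_new - len(fresh), replace=False)
            fresh.extend(extra.tolist())
        chosen.extend(fresh)
        fresh_set = set(fresh)
        unused = [g for g in unused if g not in fresh_set]
        used.extend(g for g in fresh if g not in set(used))
        sets[f"S{s:04d}"] = tuple(sorted(set(chosen)))
    return GeneSetCollection(sets, {name: "synthetic" for name in sets})


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig, gene_sets: GeneSetCollection
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition log-scale matrix with planted DE sets.

    Per-gene baseline means are drawn once from Normal(8, 2); every value adds
    Normal(0, noise_sd) noise. Genes in planted DE sets are shifted in the
    treated group by effect_size * noise_sd with a seed-determined sign per
    set, recorded in the returned truth.
    """
    config.validate()
    rng = _rng(config, "expression")
    genes = gene_universe(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for name in gene_sets.names:
        for g in gene_sets[name]:
            if g not in gene_index:
                raise ValueError(f"gene set {name!r} references unknown gene {g!r}")

    if config.planted_de_set_names is not None:
        for name in config.planted_de_set_names:
            if name not in gene_sets:
                raise ValueError(f"planted DE set {name!r} absent from the collection")
        planted = list(config.planted_de_set_names)
    else:
        planted = sorted(
            rng.choice(gene_sets.names, size=config.n_planted_de_sets, replace=False).tolist()
        )
    directions = {name: ("up" if rng.random() < 0.5 else "down") for name in planted}

    n_rep = config.n_replicates_per_group
    control = [f"ctrl_{i + 1}" for i in range(n_rep)]
    treated = [f"trt_{i + 1}" for i in range(n_rep)]
    samples = control + treated
    baseline = rng.normal(8.0, 2.0, size=config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    values = baseline[:, None] + noise

    shift = np.zeros(config.n_genes)
    gene_sign: dict[str, float] = {}
    for name in planted:
        sign = 1.0 if directions[name] == "up" else -1.0
        for g in gene_sets[name]:
            gene_sign.setdefault(g, sign)  # first planted set claims a shared gene
    for g, sign in gene_sign.items():
        shift[gene_index[g]] = sign * config.effect_size * config.noise_sd
    values[:, n_rep:] += shift[:, None]

    ann = pd.DataFrame(
        {
            "cell_type": "sim",
            "culture_condition": ["control"] * n_rep + ["treated"] * n_rep,
            "day": "12",
            "replicate": [str(i + 1) for i in range(n_rep)] * 2,
        },
        index=samples,
    )
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), ann)
    truth = SyntheticTruth(
        planted_de_set_names=planted,
        planted_up_or_down=directions,
        planted_link_pairs=[
            (a, b) if a < b else (b, a) for a, b, _ in config.planted_links
        ],
        de_gene_list=sorted(gene_sign),
    )
    return matrix, truth


def default_contrast(matrix: ExpressionMatrix) -> Contrast:
    """treated-vs-control contrast for a generated matrix."""
    ann = matrix.sample_annotations
    ctrl = tuple(ann.index[ann["culture_condition"] == "control"])
    trt = tuple(ann.index[ann["culture_condition"] == "treated"])
    return Contrast(
        test_group=SampleGroup("treated", trt),
        reference_group=SampleGroup("control", ctrl),
        name="treated_vs_control",
    )


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def _decode_pair(t: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pair index -> (i, j), i < j, over n items."""
    i = (n - 2 - np.floor((np.sqrt(-8.0 * t + 4.0 * n * (n - 1) - 7.0) - 1.0) / 2.0)).astype(np.int64)
    j = (t + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2).astype(np.int64)
    return i, j


def generate_network(config: SyntheticConfig, gene_sets: GeneSetCollection) -> InteractionNetwork:
    """Erdos-Renyi background plus planted excess inter-set connectivity.

    Background edges over the full gene universe appear independently with
    ``background_edge_prob``; each planted link (A, B, k) adds k extra edges
    between distinct members of A and B. All scores are set above the default
    downstream confidence cutoff; no self-loops or duplicate edges.
    """
    config.validate()
    rng = _rng(config, "network")
    genes = gene_universe(config.n_genes)
    n = config.n_genes
    edges: dict[tuple[str, str], int] = {}

    if config.background_edge_prob > 0 and n >= 2:
        n_pairs = n * (n - 1) // 2
        m = int(rng.binomial(n_pairs, config.background_edge_prob))
        if m:
            picked = rng.choice(n_pairs, size=m, replace=False)
            ii, jj = _decode_pair(np.sort(picked).astype(np.float64), n)
            for i, j in zip(ii, jj):
                edges[(genes[i], genes[j])] = PLANTED_SCORE

    for a, b, k in config.planted_links:
        for name in (a, b):
            if name not in gene_sets:
                raise ValueError(f"planted link references unknown set {name!r}")
        if a == b:
            raise ValueError(f"planted link joins set {a!r} to itself")
        cross = sorted(
            {
                (u, v) if u < v else (v, u)
                for u in gene_sets[a]
                for v in gene_sets[b]
                if u != v
            }
            - set(edges)
        )
        if k > len(cross):
            raise ValueError(
                f"planted link ({a}, {b}) requests {k} edges but only {len(cross)} new pairs exist"
            )
        if k:
            picked = rng.choice(len(cross), size=k, replace=False)
            for idx in sorted(picked):
                edges[cross[idx]] = PLANTED_SCORE

    return InteractionNetwork(edges)
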