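"""Gene set enrichment analysis built from first principles.

Pipeline: rank all genes by a signal-to-noise ratio (SNR) between two sample
groups, score each gene set with a weighted running-sum statistic, estimate
nominal p-values against a gene-set permutation null, control FDR with the
Benjamini-Hochberg step-up procedure, and extract per-set leading edges.

The running sum walks the full descending gene list; set members ("hits")
increment it by |SNR|^p normalized by the total hit weight, non-members
decrement it by 1/(N - N_hits). The enrichment score (ES) is the running-sum
value of maximal absolute deviation from zero, keeping its sign, so
ES is always in [-1, 1]. The leading edge is the subset of members at or
before the maximum (ES > 0), or at or after the minimum (ES < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleGroup


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; SNR sign is test minus reference."""

    test_group: SampleGroup
    reference_group: SampleGroup
    name: str = "contrast"

    def __post_init__(self):
        if set(self.test_group.members) & set(self.reference_group.members):
            raise ValueError("contrast groups must be disjoint")
        if len(self.test_group.members) < 2 or len(self.reference_group.members) < 2:
            raise ValueError("each contrast group needs at least 2 samples")


@dataclass
class RankedList:
    """Genes in strictly descending score order with 1-based ranks."""

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        self.genes = tuple(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list has duplicate genes")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self):
        return len(self.genes)

    def rank_of(self, gene: str) -> int:
        """1-based position in the full descending list."""
        return self._index[gene] + 1

    def score_of(self, gene: str) -> float:
        return float(self.scores[self._index[gene]])

    def __contains__(self, gene):
        return gene in self._index


class GeneSetCollection:
    """Named gene sets with optional category labels (GMT-backed)."""

    def __init__(self, sets: dict[str, tuple[str, ...]], categories: dict[str, str] | None = None):
        self.sets: dict[str, tuple[str, ...]] = {}
        for name, members in sets.items():
            members = tuple(dict.fromkeys(members))  # dedupe, keep order
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = members
        self.categories = dict(categories or {})

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name) -> tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name):
        return name in self.sets

    def category(self, name) -> str:
        return self.categories.get(name, "uncategorized")

    def gene_universe(self) -> set[str]:
        return {g for members in self.sets.values() for g in members}

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        from . import io as pio

        rows = pio.read_gmt(path)
        return cls(
            {name: members for name, _, members in rows},
            {name: desc for name, desc, _ in rows},
        )

    def to_gmt(self, path) -> None:
        from . import io as pio

        pio.write_gmt(
            [(n, self.category(n), m) for n, m in self.sets.items()], path
        )


@dataclass(frozen=True)
class LeadingEdgeGene:
    gene: str
    snr: float
    rank: int  # 1-based position in the full descending list


@dataclass
class EnrichmentResult:
    name: str
    category: str
    size: int  # effective size: members present in the ranked list
    es: float
    nominal_p: float
    q_value: float
    direction: str  # "up" iff es > 0 else "down"
    leading_edge: tuple[LeadingEdgeGene, ...]
    members: tuple[str, ...]  # members present in the ranked list
    result_rank: int = 0

    @property
    def leading_edge_genes(self) -> tuple[str, ...]:
        return tuple(g.gene for g in self.leading_edge)


@dataclass
class GseaConfig:
    min_set_size: int = 10
    max_set_size: int = 500
    n_permutations: int = 5000
    weight_exponent: float = 1.0
    q_threshold: float = 0.01
    rng_seed: int = 0
    sd_ddof: int = 1  # sample sd denominator n-1 by convention

    def __post_init__(self):
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must be <= max_set_size")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


# ---------------------------------------------------------------------------
# SNR ranking
# ---------------------------------------------------------------------------

def _floored_sd(values: np.ndarray, ddof: int) -> np.ndarray:
    """Per-gene sd with the variance-stabilizing floor used for tiny groups.

    sd' = max(sd, 0.2 * |mean|); when the mean is 0, sd' = max(sd, 0.2).
    """
    sd = values.std(axis=1, ddof=ddof)
    mean = values.mean(axis=1)
    floor = np.where(mean == 0.0, 0.2, 0.2 * np.abs(mean))
    return np.maximum(sd, floor)


def snr_ranking(matrix: ExpressionMatrix, contrast: Contrast, sd_ddof: int = 1) -> RankedList:
    """Rank all genes by SNR = (mean_test - mean_ref) / (sd_test' + sd_ref').

    Ties in SNR are broken by gene id ascending so the order is total.
    """
    for group in (contrast.test_group, contrast.reference_group):
        if len(group.members) < 2:
            raise ValueError(f"group {group.name!r} has fewer than 2 samples")
        missing = set(group.members) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"group {group.name!r} has unknown samples: {sorted(missing)}")
    test = matrix.values[list(contrast.test_group.members)].to_numpy(dtype=float)
    ref = matrix.values[list(contrast.reference_group.members)].to_numpy(dtype=float)
    snr = (test.mean(axis=1) - ref.mean(axis=1)) / (
        _floored_sd(test, sd_ddof) + _floored_sd(ref, sd_ddof)
    )
    genes = np.asarray(matrix.row_ids, dtype=object)
    order = np.lexsort((genes, -snr))
    return RankedList(tuple(genes[order]), snr[order])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

@dataclass
class EsProfile:
    es: float
    running_sum: np.ndarray
    leading_edge_positions: np.ndarray  # 0-based positions in the ranked list
    extremum_position: int


def _hit_weights(scores: np.ndarray, hits: np.ndarray, weight_exponent: float) -> np.ndarray:
    w = np.where(hits, np.abs(scores) ** weight_exponent, 0.0)
    total = w.sum()
    if total == 0.0:
        # degenerate all-zero hit scores: fall back to uniform hit weights
        w = hits.astype(float)
        total = w.sum()
    return w / total


def enrichment_score(
    ranked: RankedList, set_members, weight_exponent: float = 1.0
) -> EsProfile:
    """Weighted running-sum enrichment score of one gene set.

    Returns the signed ES, the full running-sum profile, and the 0-based
    ranked-list positions of the leading-edge members.
    """
    members = set(set_members)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    n = len(ranked)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list (miss weight undefined)")
    increments = _hit_weights(ranked.scores, hits, weight_exponent)
    increments[~hits] = -1.0 / (n - n_hits)
    running = np.cumsum(increments)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es, extremum = float(running[i_max]), i_max
        le_pos = np.nonzero(hits[: extremum + 1])[0]
    else:
        es, extremum = float(running[i_min]), i_min
        le_pos = np.nonzero(hits)[0]
        le_pos = le_pos[le_pos >= extremum]
    es = float(np.clip(es, -1.0, 1.0))  # guard against float drift past the bounds
    return EsProfile(es=es, running_sum=running, leading_edge_positions=le_pos, extremum_position=extremum)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _null_es(
    weights: np.ndarray, k: int, n_permutations: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    """ES values of random k-gene sets drawn without replacement.

    ``weights`` is |score|^p for every gene in ranked order. Works from the
    sorted hit positions of each draw: each ascending stretch peaks right
    after a hit, each descending stretch bottoms out right before the next
    hit (and at 0 at the very end), so only 2k candidates per draw matter.
    """
    n = len(weights)
    if not 0 < k < n:
        raise ValueError(f"set size {k} invalid for ranked list of {n}")
    miss = 1.0 / (n - k)
    out = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        keys = rng.random((b, n))
        pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
        w = weights[pos]
        cum = np.cumsum(w, axis=1)
        total = cum[:, -1:].copy()
        degenerate = total[:, 0] == 0.0
        if degenerate.any():  # all-zero hit weights -> uniform
            cum[degenerate] = np.arange(1, k + 1, dtype=float)
            total[degenerate] = float(k)
        cum = cum / total
        j = np.arange(k)
        after_hit = cum - (pos - j) * miss
        before_hit = np.concatenate([np.zeros((b, 1)), cum[:, :-1]], axis=1) - (pos - j) * miss
        top = after_hit.max(axis=1)
        bottom = np.minimum(before_hit.min(axis=1), 0.0)
        out[done : done + b] = np.where(top >= -bottom, top, bottom)
        done += b
    return out


def permutation_p(observed_es: float, null_es: np.ndarray) -> float:
    """One-sided permutation p against the same-signed portion of the null.

    The observed ES is compared only with null ES values of the same sign,
    with a +1 pseudocount so p never reaches 0:
    p = (1 + #{same-signed null with |ES| >= |observed|}) / (1 + #same-signed).
    Normalizing by the same-signed null count (rather than all permutations)
    keeps null p-values uniform on [0, 1].
    """
    if observed_es > 0:
        side = null_es[null_es > 0]
        count = int(np.sum(side >= observed_es))
    elif observed_es < 0:
        side = null_es[null_es < 0]
        count = int(np.sum(side <= observed_es))
    else:
        return 1.0
    return (1 + count) / (1 + len(side))


def null_es_distribution(
    ranked: RankedList, set_size: int, config: GseaConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Null ES distribution for random gene sets of a given size."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    weights = np.abs(ranked.scores) ** config.weight_exponent
    return _null_es(weights, set_size, config.n_permutations, rng)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# full run + perturbed genes
# ---------------------------------------------------------------------------

def run_gsea(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    collection: GeneSetCollection,
    config: GseaConfig | None = None,
) -> list[EnrichmentResult]:
    """Run the full enrichment chain on a gene-level matrix.

    Sets are filtered to effective size (members present on the ranked list)
    within [min_set_size, max_set_size]; one shared permutation null is drawn
    per distinct effective size. Results are ranked by
    (q asc, nominal p asc, |ES| desc, name asc).
    """
    if config is None:
        config = GseaConfig()
    if len(collection) == 0:
        raise ValueError("gene set collection is empty")
    ranked = snr_ranking(matrix, contrast, sd_ddof=config.sd_ddof)
    testable: list[tuple[str, tuple[str, ...]]] = []
    for name in collection.names:
        present = tuple(g for g in collection[name] if g in ranked)
        if config.min_set_size <= len(present) <= config.max_set_size and len(present) < len(ranked):
            testable.append((name, present))
    if not testable:
        raise ValueError(
            f"no gene set has effective size in [{config.min_set_size}, {config.max_set_size}]"
        )
    rng = np.random.default_rng(config.rng_seed)
    weights = np.abs(ranked.scores) ** config.weight_exponent
    null_cache: dict[int, np.ndarray] = {}
    # one null draw per distinct size, in sorted size order for seed stability
    for k in sorted({len(m) for _, m in testable}):
        null_cache[k] = _null_es(weights, k, config.n_permutations, rng)

    results = []
    pvals = []
    for name, present in testable:
        profile = enrichment_score(ranked, present, config.weight_exponent)
        p = permutation_p(profile.es, null_cache[len(present)])
        pvals.append(p)
        leading = tuple(
            LeadingEdgeGene(ranked.genes[i], float(ranked.scores[i]), int(i) + 1)
            for i in profile.leading_edge_positions
        )
        results.append(
            EnrichmentResult(
                name=name,
                category=collection.category(name),
                size=len(present),
                es=profile.es,
                nominal_p=p,
                q_value=np.nan,
                direction="up" if profile.es > 0 else "down",
                leading_edge=leading,
                members=present,
            )
        )
    qvals = bh_fdr(pvals)
    for res, q in zip(results, qvals):
        res.q_value = float(q)
    results.sort(key=lambda r: (r.q_value, r.nominal_p, -abs(r.es), r.name))
    for i, res in enumerate(results, start=1):
        res.result_rank = i
    return results


def leading_edge_union(results: list[EnrichmentResult], q_threshold: float = 0.01) -> set[str]:
    """Perturbed genes: union of leading edges of sets with q <= threshold."""
    perturbed: set[str] = set()
    for res in results:
        if res.q_value <= q_threshold:
            perturbed.update(res.leading_edge_genes)
    return perturbed


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "rank": r.result_rank,
            "set": r.name,
            "category": r.category,
            "size": r.size,
            "ES": r.es,
            "p": r.nominal_p,
            "q": r.q_value,
            "direction": r.direction,
            "leading_edge": ",".join(r.leading_edge_genes),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def results_to_json(results: list[EnrichmentResult]) -> list[dict]:
    return [
        {
            "rank": r.result_rank,
            "set": r.name,
            "category": r.category,
            "size": r.size,
            "ES": r.es,
            "p": r.nominal_p,
            "q": r.q_value,
            "direction": r.direction,
            "members": list(r.members),
            "leading_edge": [
                {"gene": g.gene, "snr": g.snr, "rank": g.rank} for g in r.leading_edge
            ],
        }
        for r in results
    ]


def results_from_json(records: list[dict]) -> list[EnrichmentResult]:
    out = []
    for rec in records:
        out.append(
            EnrichmentResult(
                name=rec["set"],
                category=rec.get("category", "uncategorized"),
                size=rec["size"],
                es=rec["ES"],
                nominal_p=rec["p"],
                q_value=rec["q"],
                direction=rec["direction"],
                leading_edge=tuple(
                    LeadingEdgeGene(g["gene"], g["snr"], g["rank"])
                    for g in rec["leading_edge"]
                ),
                members=tuple(rec["members"]),
                result_rank=rec.get("rank", 0),
            )
        )
    return out
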