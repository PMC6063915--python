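"""Expression matrices, probe collapsing, group distances and sample clustering.

The central object is :class:`ExpressionMatrix`: a genes-or-probes x samples
table of log-scale intensities with per-sample annotations. Downstream
operations cover probe-to-gene summarization, mean-replicate imputation,
average within/between group distances, and agglomerative hierarchical
clustering with deterministic tie-breaking and Newick export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from . import io as pio

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("cell_type", "culture_condition", "day", "replicate")

#: maps public metric names onto scipy metric names
_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "correlation": "correlation"}

_LINKAGES = ("single", "complete", "average")


@dataclass(frozen=True)
class SampleGroup:
    """A named group of sample ids (e.g. replicates of one condition)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.name!r} has duplicate members")


class ExpressionMatrix:
    """Log-scale expression values (rows x samples) plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by unique probe/gene ids with unique sample columns;
        every cell must be finite.
    sample_annotations
        Optional DataFrame indexed by sample id with columns
        ``cell_type, culture_condition, day, replicate``. Missing annotations
        are filled with placeholders so that every sample is covered.
    """

    def __init__(self, values: pd.DataFrame, sample_annotations: pd.DataFrame | None = None):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate row id {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must all be finite")
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if sample_annotations is None:
            sample_annotations = pd.DataFrame(index=self.values.columns)
        ann = sample_annotations.copy()
        ann.index = ann.index.astype(str)
        missing = set(self.values.columns) - set(ann.index)
        if missing:
            raise ValueError(f"annotations missing for samples: {sorted(missing)}")
        for col in ANNOTATION_COLUMNS:
            if col not in ann.columns:
                ann[col] = "unknown"
        self.sample_annotations = ann.loc[list(self.values.columns), list(ANNOTATION_COLUMNS)]

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.sample_annotations)

    def __eq__(self, other):
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.equals(other.values)
            and self.sample_annotations.equals(other.sample_annotations)
        )

    def __repr__(self):
        return f"ExpressionMatrix({self.values.shape[0]} rows x {self.values.shape[1]} samples)"


def load_expression(path, format: str = "tsv", annotations_path=None) -> ExpressionMatrix:
    """Load a matrix from ``gct`` or ``tsv``; optionally join an annotation TSV."""
    if format == "gct":
        values = pio.read_gct(path)
    elif format == "tsv":
        values = pio.read_tsv_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'gct' or 'tsv')")
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values, ann)


def write_expression(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    if format == "gct":
        pio.write_gct(matrix.values, path)
    elif format == "tsv":
        pio.write_tsv_matrix(matrix.values, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_sample_annotations(matrix: ExpressionMatrix, path) -> None:
    ann = matrix.sample_annotations.copy()
    ann.index.name = "sample_id"
    ann.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# probe -> gene summarization
# ---------------------------------------------------------------------------

def collapse_probes(
    matrix: ExpressionMatrix,
    probe_gene_map: dict[str, str],
    method: str = "max_per_sample",
) -> ExpressionMatrix:
    """Summarize probe-level rows into one row per gene.

    ``max_per_sample`` takes, for every gene and sample, the maximum over that
    gene's probes in that sample; ``mean_per_sample`` / ``median_per_sample``
    are exposed as alternatives. Probes absent from the map are dropped and
    counted in the log.
    """
    reducers = {"max_per_sample": "max", "mean_per_sample": "mean", "median_per_sample": "median"}
    if method not in reducers:
        raise ValueError(f"unknown collapse method {method!r}")
    mapped = [p for p in matrix.row_ids if p in probe_gene_map]
    n_dropped = len(matrix.row_ids) - len(mapped)
    if not mapped:
        raise ValueError("no probe in the matrix is present in the probe-gene map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = matrix.values.loc[mapped]
    genes = pd.Index([probe_gene_map[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes, sort=True).agg(reducers[method])
    return ExpressionMatrix(collapsed, matrix.sample_annotations)


def impute_mean_replicate(
    matrix: ExpressionMatrix, group: SampleGroup, new_sample_id: str | None = None
) -> ExpressionMatrix:
    """Append a synthetic third replicate equal to the mean of a 2-sample group."""
    if len(group.members) != 2:
        raise ValueError(
            f"mean-replicate imputation requires exactly 2 samples, group {group.name!r} has {len(group.members)}"
        )
    a, b = group.members
    for s in (a, b):
        if s not in matrix.values.columns:
            raise ValueError(f"sample {s!r} not in matrix")
    if new_sample_id is None:
        new_sample_id = f"{group.name}_imputed"
    if new_sample_id in matrix.values.columns:
        raise ValueError(f"sample id {new_sample_id!r} already present")
    values = matrix.values.copy()
    values[new_sample_id] = (values[a] + values[b]) / 2.0
    ann = matrix.sample_annotations.copy()
    row = ann.loc[a].copy()
    row["replicate"] = "imputed"
    ann.loc[new_sample_id] = row
    return ExpressionMatrix(values, ann)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _sample_matrix(matrix: ExpressionMatrix, sample_ids) -> np.ndarray:
    for s in sample_ids:
        if s not in matrix.values.columns:
            raise ValueError(f"sample {s!r} not in matrix")
    return matrix.values[list(sample_ids)].to_numpy(dtype=float).T


def average_group_distance(
    matrix: ExpressionMatrix,
    group_a: SampleGroup,
    group_b: SampleGroup | None = None,
    metric: str = "euclidean",
) -> float:
    """Mean pairwise distance within one group or across two disjoint groups.

    Within-group: mean over all unordered pairs. Between-group: mean over all
    cross pairs. ``correlation`` distance is 1 - Pearson r.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    scipy_metric = _METRICS[metric]
    if group_b is None:
        if len(group_a.members) < 2:
            raise ValueError(f"within-group distance needs >=2 members in {group_a.name!r}")
        X = _sample_matrix(matrix, group_a.members)
        return float(np.mean(pdist(X, metric=scipy_metric)))
    if not group_a.members or not group_b.members:
        raise ValueError("between-group distance needs both groups non-empty")
    if set(group_a.members) & set(group_b.members):
        raise ValueError("groups in a between-group distance must be disjoint")
    A = _sample_matrix(matrix, group_a.members)
    B = _sample_matrix(matrix, group_b.members)
    return float(np.mean(cdist(A, B, metric=scipy_metric)))


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DendrogramNode:
    height: float
    leaves: frozenset
    children: tuple = ()  # empty for leaves
    name: str | None = None  # set for leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Result of agglomerative clustering: merge list plus tree structure."""

    root: DendrogramNode
    #: (left leaf set, right leaf set, merge height), in merge order
    merges: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)

    @property
    def leaf_names(self) -> frozenset:
        return self.root.leaves

    def clades(self) -> list[frozenset]:
        """All clade leaf-sets (leaves included), deterministic order."""
        out = []

        def walk(node):
            out.append(node.leaves)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def newick(self) -> str:
        """Ultrametric Newick string; branch length = parent height - child height."""

        def fmt(node, parent_height):
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:g}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def cluster_samples(
    matrix: ExpressionMatrix, linkage: str = "complete", metric: str = "euclidean"
) -> Dendrogram:
    """Agglomerative clustering of samples with deterministic tie-breaking.

    Ties in the minimum inter-cluster distance are broken lexicographically by
    the smallest member sample id of each cluster. Cluster distances follow
    Lance-Williams updates for single/complete/average linkage, so merge
    heights are monotone non-decreasing.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    ids = matrix.sample_ids
    if len(ids) < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = _sample_matrix(matrix, ids)
    D = squareform(pdist(X, metric=_METRICS[metric]))

    nodes = [DendrogramNode(0.0, frozenset([s]), name=s) for s in ids]
    sizes = [1] * len(ids)
    mins = list(ids)  # smallest member id per active cluster
    active = set(range(len(ids)))
    dist = {(i, j): D[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))}
    merges: list[tuple[frozenset, frozenset, float]] = []

    def pair_key(i, j):
        a, b = sorted((mins[i], mins[j]))
        return (dist[(min(i, j), max(i, j))], a, b)

    while len(active) > 1:
        act = sorted(active)
        best = min(
            ((i, j) for k, i in enumerate(act) for j in act[k + 1 :]),
            key=lambda p: pair_key(*p),
        )
        i, j = best
        h = dist[(i, j)]
        left, right = nodes[i], nodes[j]
        # order children by smallest member id for deterministic serialization
        if mins[j] < mins[i]:
            left, right = right, left
        merges.append((left.leaves, right.leaves, h))
        new = DendrogramNode(h, left.leaves | right.leaves, children=(left, right))
        k = len(nodes)
        nodes.append(new)
        sizes.append(sizes[i] + sizes[j])
        mins.append(min(mins[i], mins[j]))
        active.discard(i)
        active.discard(j)
        for m in sorted(active):
            d_mi = dist[(min(m, i), max(m, i))]
            d_mj = dist[(min(m, j), max(m, j))]
            if linkage == "single":
                d = min(d_mi, d_mj)
            elif linkage == "complete":
                d = max(d_mi, d_mj)
            else:  # average (UPGMA)
                d = (sizes[i] * d_mi + sizes[j] * d_mj) / (sizes[i] + sizes[j])
            dist[(m, k)] = d
        active.add(k)

    return Dendrogram(root=nodes[-1], merges=merges)


def clade_purity(tree: Dendrogram, groups: list[SampleGroup]) -> dict[str, bool]:
    """True per group iff some clade's leaf set equals exactly that group."""
    leaf_names = tree.leaf_names
    for g in groups:
        unknown = set(g.members) - set(leaf_names)
        if unknown:
            raise ValueError(f"group {g.name!r} has unknown sample ids: {sorted(unknown)}")
    clade_sets = set(tree.clades())
    return {g.name: frozenset(g.members) in clade_sets for g in groups}


def plot_dendrogram(tree: Dendrogram, ax=None):
    """Minimal dendrogram plot helper (lazy matplotlib import)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    # assign leaf x positions in Newick order
    xs: dict[frozenset, float] = {}
    counter = [0.0]

    def walk(node):
        if node.is_leaf:
            xs[node.leaves] = counter[0]
            counter[0] += 1.0
            return counter[0] - 1.0
        child_x = [walk(c) for c in node.children]
        x = sum(child_x) / len(child_x)
        for c, cx in zip(node.children, child_x):
            ax.plot([cx, cx], [c.height, node.height], color="k", lw=1)
        ax.plot([child_x[0], child_x[-1]], [node.height, node.height], color="k", lw=1)
        xs[node.leaves] = x
        return x

    walk(tree.root)
    leaves = sorted(
        ((x, next(iter(ls))) for ls, x in xs.items() if len(ls) == 1), key=lambda t: t[0]
    )
    ax.set_xticks([x for x, _ in leaves])
    ax.set_xticklabels([name for _, name in leaves], rotation=90)
    ax.set_ylabel("merge height")
    return ax
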