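"""Panel-based stratification: z-scoring, Ward clustering, rescaled cut, labels.

Samples are clustered on the z-scored stress-panel genes with Ward's
minimum-variance method. Merge heights are the Ward objective increments
ΔSSE = (n_i n_j / (n_i + n_j))·‖c_i − c_j‖², computed by the Lance–Williams
recurrence on initial pairwise values ‖x_i − x_j‖²/2. The dendrogram is cut
on the SPSS-style axis where heights are linearly rescaled to 0–25
("rescaled distance cluster combine"); the cut threshold the study design
uses is 20. The two resulting clusters are labeled by directional
concordance: the cluster with higher mean z over stress-up genes minus mean
z over stress-down genes is the high stress-response (HSR) stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import Direction, ExpressionMatrix, GenePanel


@dataclass
class StandardizedMatrix:
    """Panel-restricted gene × sample z-score matrix (per-gene mean 0, sd 1)."""

    z_values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z_values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z_values.columns)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: node ids of the merged clusters, the ΔSSE
    height, and the size of the resulting cluster. Leaves are 0..n−1 in
    sample order; internal nodes continue from n."""

    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    merges: list[Merge]
    leaf_ids: list[str]

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def leaves_under(self, node: int) -> frozenset[int]:
        """Set of leaf indices under a node id."""
        n = len(self.leaf_ids)
        if node < n:
            return frozenset([node])
        m = self.merges[node - n]
        return self.leaves_under(m.left) | self.leaves_under(m.right)


@dataclass
class StrataLabeling:
    assignment: dict[str, str]  # sample -> "HSR" | "LSR"
    concordance: dict[int, float]  # cluster id -> concordance score


def zscore_standardize(matrix: ExpressionMatrix, panel: GenePanel) -> StandardizedMatrix:
    """Restrict to panel genes and z-score each gene across samples.

    Uses the sample standard deviation (n−1 denominator). Raises if a panel
    gene is missing or has zero variance.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least 2 samples to standardize")
    mapping = panel.resolve(matrix.gene_ids)  # raises naming missing genes
    rows = matrix.values.loc[[mapping[s] for s in mapping]]
    rows.index = list(mapping)  # report panel symbols
    arr = rows.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance panel gene(s), cannot standardize: "
            f"{[rows.index[i] for i in zero]}"
        )
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return StandardizedMatrix(pd.DataFrame(z, index=rows.index, columns=rows.columns))


def ward_cluster(std: StandardizedMatrix) -> Dendrogram:
    """Agglomerate samples with Ward's method via the Lance–Williams update.

    Each step merges the active pair with the smallest ΔSSE; ties break on
    the lexicographically smallest (left-leaf-index, right-leaf-index) pair,
    where a cluster is identified by its minimum original leaf index, so the
    merge order is deterministic across platforms.
    """
    X = std.z_values.to_numpy(dtype=float).T  # samples × genes
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    # initial ΔSSE between singletons: squared Euclidean distance / 2
    d0 = squareform(pdist(X, metric="sqeuclidean")) / 2.0
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d0[i, j]

    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    active = set(range(n))
    merges: list[Merge] = []
    next_id = n

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    while len(active) > 1:
        best = None
        for (a, b), d in dist.items():
            la, lb = min_leaf[a], min_leaf[b]
            if la > lb:
                la, lb = lb, la
            cand = (d, la, lb, a, b)
            if best is None or cand[:3] < best[:3]:
                best = cand
        d, _, _, a, b = best
        if min_leaf[a] > min_leaf[b]:
            a, b = b, a
        new = next_id
        next_id += 1
        merges.append(Merge(left=a, right=b, height=d, size=size[a] + size[b]))
        # Lance–Williams update for Ward ΔSSE
        for c in active:
            if c in (a, b):
                continue
            dac = dist.pop(key(a, c))
            dbc = dist.pop(key(b, c))
            sc, sa, sb = size[c], size[a], size[b]
            dist[key(new, c)] = (
                (sa + sc) * dac + (sb + sc) * dbc - sc * d
            ) / (sa + sb + sc)
        del dist[key(a, b)]
        active.discard(a)
        active.discard(b)
        active.add(new)
        size[new] = size[a] + size[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])

    return Dendrogram(merges=merges, leaf_ids=std.sample_ids)


def rescaled_heights(dendro: Dendrogram, schedule: str = "incremental") -> np.ndarray:
    """Merge heights rescaled to the 0–25 dendrogram axis.

    ``schedule`` selects whether the raw heights are the per-merge ΔSSE
    increments (default) or the cumulative agglomeration coefficients that
    SPSS tabulates; both are monotone, so the rescaling h' = 25·h/h_max
    applies either way.
    """
    h = dendro.heights()
    if schedule == "cumulative":
        h = np.cumsum(h)
    elif schedule != "incremental":
        raise ValueError("schedule must be 'incremental' or 'cumulative'")
    hmax = h[-1] if len(h) else 0.0
    if hmax == 0:
        return np.zeros_like(h)
    return 25.0 * h / hmax


def cut_rescaled(
    dendro: Dendrogram, threshold: float = 20.0, schedule: str = "incremental"
) -> dict[str, int]:
    """Partition samples by cutting the dendrogram at a rescaled height.

    All merges at rescaled height ≤ ``threshold`` are applied; the partition
    is the resulting forest. Threshold must lie in (0, 25]; 25 always yields
    one cluster and a threshold below the first rescaled merge height yields
    all singletons. A degenerate dendrogram (all heights 0) collapses to a
    single cluster with a warning.
    """
    if not (0 < threshold <= 25):
        raise ValueError("threshold must be in (0, 25]")
    n = len(dendro.leaf_ids)
    h = dendro.heights()
    if len(h) and h[-1] == 0 and (schedule == "incremental" or np.sum(h) == 0):
        warnings.warn("degenerate dendrogram (all heights 0): single cluster")
        return {s: 0 for s in dendro.leaf_ids}
    rs = rescaled_heights(dendro, schedule)

    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, m in enumerate(dendro.merges):
        node = n + k
        if rs[k] <= threshold:
            parent[find(m.left)] = node
            parent[find(m.right)] = node

    labels: dict[str, int] = {}
    root_to_id: dict[int, int] = {}
    for leaf, sample in enumerate(dendro.leaf_ids):
        r = find(leaf)
        if r not in root_to_id:
            root_to_id[r] = len(root_to_id)
        labels[sample] = root_to_id[r]
    return labels


def label_strata(
    partition: dict[str, int], std: StandardizedMatrix, panel: GenePanel
) -> StrataLabeling:
    """Label the two clusters HSR/LSR by directional concordance.

    Concordance of a cluster = mean z over stress-UP genes − mean z over
    stress-DOWN genes, computed over the cluster's samples; VARIABLE genes
    are excluded. The higher-concordance cluster is HSR. Requires exactly
    two clusters and at least one UP and one DOWN panel gene; an exact
    concordance tie is an error rather than a silent choice.
    """
    clusters = sorted(set(partition.values()))
    if len(clusters) != 2:
        raise ValueError(
            f"expected exactly 2 clusters, found {len(clusters)}; "
            "adjust the rescaled-distance threshold"
        )
    up = [g for g in panel.genes_with(Direction.UP) if g in std.gene_ids]
    down = [g for g in panel.genes_with(Direction.DOWN) if g in std.gene_ids]
    if not up or not down:
        raise ValueError("labeling needs at least one UP and one DOWN panel gene")

    concordance: dict[int, float] = {}
    for c in clusters:
        cols = [s for s, cid in partition.items() if cid == c]
        zc = std.z_values.loc[:, cols]
        concordance[c] = float(
            zc.loc[up].to_numpy().mean() - zc.loc[down].to_numpy().mean()
        )
    c0, c1 = clusters
    if concordance[c0] == concordance[c1]:
        raise ValueError("exact concordance tie between clusters; cannot label")
    hsr = c0 if concordance[c0] > concordance[c1] else c1
    assignment = {
        s: ("HSR" if cid == hsr else "LSR") for s, cid in partition.items()
    }
    return StrataLabeling(assignment=assignment, concordance=concordance)
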