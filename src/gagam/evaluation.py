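"""Validation toolkit: LSI embedding, clustering, and the agreement /
informativeness metrics (ARI, AMI, RAGI) plus differential-activity ranking.

RAGI (residual average Gini index) contrasts how concentrated marker-gene
activity is across clusters against housekeeping genes: per gene the Gini
index of the per-cluster mean activities is computed; RAGI is the mean
marker Gini minus the mean housekeeping Gini, with a two-sided
Mann-Whitney U p-value between the two Gini samples.  Positive RAGI means
the clustering captures biologically specific activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("one label per cell required")
        uniq = np.unique(self.labels)
        if uniq.size and not np.array_equal(uniq, np.arange(uniq.size)):
            # remap to contiguous ids from 0 by first occurrence
            order = {lab: i for i, lab in enumerate(pd.unique(self.labels))}
            self.labels = np.array([order[l] for l in self.labels])

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @classmethod
    def read_tsv(cls, path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["cell", "cluster"])
        return cls(df["cell"].astype(str).tolist(), df["cluster"].to_numpy())

    def write_tsv(self, path) -> None:
        pd.DataFrame({"cell": self.cell_ids, "cluster": self.labels}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class GeneSetPair:
    markers: set[str]
    housekeeping: set[str]

    def __post_init__(self) -> None:
        if self.markers & self.housekeeping:
            raise ValueError("marker and housekeeping sets must be disjoint")


def read_gene_set(path) -> set[str]:
    """One gene symbol per line, plain text."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# Embedding and clustering


def tfidf(M: np.ndarray) -> np.ndarray:
    """TF-IDF weighting of a non-negative features-by-cells matrix: term
    frequency per cell scaled by log(1 + n_cells / document frequency)."""
    M = np.asarray(M, dtype=float)
    cell_totals = M.sum(axis=0)
    tf = np.divide(M, cell_totals, out=np.zeros_like(M), where=cell_totals > 0)
    df = (M > 0).sum(axis=1)
    idf = np.zeros(M.shape[0])
    present = df > 0
    idf[present] = np.log(1.0 + M.shape[1] / df[present])
    return tf * idf[:, np.newaxis]


def lsi_embed(
    M,
    n_components: int = 30,
    drop_first: bool = True,
    random_state: int = 0,
) -> np.ndarray:
    """Latent semantic indexing of a features-by-cells matrix.

    TF-IDF weighting followed by truncated SVD; the first component, which
    typically tracks per-cell depth, is dropped by default.  Returns a
    cells-by-components embedding.
    """
    from sklearn.decomposition import TruncatedSVD

    M = np.asarray(M.todense() if hasattr(M, "todense") else M, dtype=float)
    if (M < 0).any():
        raise ValueError("matrix must be non-negative")
    if not M.any():
        raise ValueError("all-zero matrix cannot be embedded")
    if n_components >= min(M.shape):
        raise ValueError(
            f"n_components={n_components} must be < min(shape)={min(M.shape)}"
        )
    X = tfidf(M).T  # cells x features
    svd = TruncatedSVD(n_components=n_components, random_state=random_state)
    emb = svd.fit_transform(X)
    return emb[:, 1:] if drop_first else emb


def cluster_cells(
    embedding: np.ndarray,
    cell_ids,
    method: str = "kmeans",
    param: float = 2,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster cells in an embedding: k-means (param = k) or Leiden on a
    shared-neighbor graph (param = resolution).  Deterministic given seed."""
    embedding = np.asarray(embedding, dtype=float)
    if not np.isfinite(embedding).all():
        raise ValueError("embedding must be finite")
    n = embedding.shape[0]
    if method == "kmeans":
        from sklearn.cluster import KMeans

        k = int(param)
        if k > n:
            raise ValueError(f"k={k} exceeds number of cells {n}")
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(
            embedding
        )
    elif method == "leiden":
        import igraph
        import leidenalg
        from sklearn.neighbors import kneighbors_graph

        knn = kneighbors_graph(embedding, n_neighbors=min(15, n - 1))
        sources, targets = knn.nonzero()
        g = igraph.Graph(n=n, edges=list(zip(sources.tolist(), targets.tolist())))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(param),
            seed=seed,
        )
        labels = np.array(part.membership)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterAssignment(list(cell_ids), labels)


# ---------------------------------------------------------------------------
# Agreement metrics


def _check_same_cells(a: ClusterAssignment, b: ClusterAssignment) -> None:
    if a.cell_ids != b.cell_ids:
        raise ValueError("cluster assignments cover different cell sets")


def ari(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    _check_same_cells(a, b)
    return float(adjusted_rand_score(a.labels, b.labels))


def ami(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Adjusted mutual information, arithmetic-mean normalization."""
    _check_same_cells(a, b)
    return float(
        adjusted_mutual_info_score(a.labels, b.labels, average_method="arithmetic")
    )


# ---------------------------------------------------------------------------
# RAGI


def gini(values) -> float:
    """Gini index by mean absolute pairwise difference:
    ``sum_ij |x_i - x_j| / (2 n^2 mean)``; an all-zero vector gives 0."""
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if (x < 0).any():
        raise ValueError("values must be non-negative")
    n = x.size
    if n == 0 or x.sum() == 0:
        return 0.0
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * n * n * x.mean()))


def cluster_mean_activity(
    gam_matrix: np.ndarray, gene_ids: list[str], clusters: ClusterAssignment
) -> pd.DataFrame:
    """Genes-by-clusters table of mean activity per cluster."""
    X = np.asarray(gam_matrix, dtype=float)
    k = clusters.n_clusters
    means = np.column_stack(
        [X[:, clusters.labels == c].mean(axis=1) for c in range(k)]
    )
    return pd.DataFrame(means, index=gene_ids, columns=range(k))


def ragi(
    gam_matrix: np.ndarray,
    gene_ids: list[str],
    clusters: ClusterAssignment,
    sets: GeneSetPair,
    test: str = "mannwhitney",
) -> tuple[float, float, pd.Series]:
    """Residual average Gini index and its p-value.

    Returns ``(ragi, p, per_gene_gini)`` where per_gene_gini is indexed by
    gene.  Genes absent from the matrix are skipped with a warning; at
    least one marker and one housekeeping gene must be present, and at
    least two clusters.
    """
    if clusters.n_clusters < 2:
        raise ValueError("RAGI requires at least 2 clusters")
    present = set(gene_ids)
    markers = sorted(sets.markers & present)
    housekeeping = sorted(sets.housekeeping & present)
    missing = (len(sets.markers) - len(markers)) + (
        len(sets.housekeeping) - len(housekeeping)
    )
    if missing:
        log.warning("%d marker/housekeeping genes absent from the matrix", missing)
    if not markers:
        raise ValueError("no marker genes found in the matrix")
    if not housekeeping:
        raise ValueError("no housekeeping genes found in the matrix")

    means = cluster_mean_activity(gam_matrix, gene_ids, clusters)
    per_gene = pd.Series(
        {g: gini(means.loc[g].to_numpy()) for g in markers + housekeeping}
    )
    gm = per_gene[markers].to_numpy()
    gh = per_gene[housekeeping].to_numpy()
    score = float(gm.mean() - gh.mean())
    if np.allclose(gm, gm[0]) and np.allclose(gh, gh[0]) and np.isclose(gm[0], gh[0]):
        p = 1.0  # identical constant samples: no evidence of difference
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(gm, gh, alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(gm, gh, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return score, p, per_gene


# ---------------------------------------------------------------------------
# Differential activity


def rank_differential_activity(
    gam_matrix: np.ndarray,
    gene_ids: list[str],
    clusters: ClusterAssignment,
    top_n: int = 10,
) -> pd.DataFrame:
    """Per-cluster one-vs-rest Wilcoxon rank-sum ranking of gene activity.

    Genes are ranked by effect size (difference of means, descending) with
    the p-value as tie-break; the top ``top_n`` genes per cluster are
    returned as a table with columns cluster, gene, effect, pvalue, rank.
    """
    if clusters.n_clusters < 2:
        raise ValueError("differential activity requires at least 2 clusters")
    X = np.asarray(gam_matrix, dtype=float)
    records = []
    for c in range(clusters.n_clusters):
        mask = clusters.labels == c
        inside, outside = X[:, mask], X[:, ~mask]
        effects = inside.mean(axis=1) - outside.mean(axis=1)
        pvals = np.ones(len(gene_ids))
        for gi in range(len(gene_ids)):
            a, b = inside[gi], outside[gi]
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                continue  # constant gene: p stays 1
            pvals[gi] = stats.ranksums(a, b).pvalue
        order = sorted(
            range(len(gene_ids)), key=lambda gi: (-effects[gi], pvals[gi], gene_ids[gi])
        )
        for rank, gi in enumerate(order[:top_n], start=1):
            records.append(
                {
                    "cluster": c,
                    "gene": gene_ids[gi],
                    "effect": float(effects[gi]),
                    "pvalue": float(pvals[gi]),
                    "rank": rank,
                }
            )
    return pd.DataFrame.from_records(records)
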