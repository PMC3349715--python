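"""Expression subtype discovery and prediction.

Discovery follows the resampling consensus-clustering procedure: repeatedly
subsample tumors, cluster each subsample (agglomerative average linkage on
1 - Pearson correlation), and record how often each pair of tumors lands in
the same cluster among the subsamples containing both. The consensus CDF and
its relative area gain across cluster totals k select the most stable k.

Prediction is nearest-centroid: per-subtype mean profiles over a
discriminative gene list (default 506 genes, balanced across subtypes);
new cohorts are gene-median-centered within-cohort before assignment, which
absorbs cross-platform location differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import SUBTYPES
from .io_formats import read_matrix, write_matrix


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median; missing values preserved."""
    if matrix.isna().all(axis=1).any():
        gene = matrix.index[matrix.isna().all(axis=1)][0]
        raise ValueError(f"gene {gene!r} has no non-missing values")
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)


def select_variable_genes(matrix: pd.DataFrame, fraction: float) -> list[str]:
    """Top ``fraction`` of genes by variance; ties break by gene id."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = max(1, int(np.floor(fraction * len(matrix) + 1e-9)))
    disp = matrix.var(axis=1, skipna=True)
    order = sorted(matrix.index, key=lambda g: (-disp[g], g))
    return order[:n_keep]


def _correlation_distance(matrix: pd.DataFrame) -> np.ndarray:
    """1 - Pearson correlation between sample columns."""
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.sqrt((x**2).sum(axis=0, keepdims=True))
    norm[norm == 0] = 1.0
    x = x / norm
    corr = np.clip(x.T @ x, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ConsensusResult:
    """Consensus matrices, labels, CDF areas and the chosen cluster total."""

    consensus: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]
    area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    n = vals.size
    # integral of the step CDF over [0, 1]
    area = 0.0
    prev_x, prev_cdf = 0.0, 0.0
    for i, x in enumerate(vals):
        area += (x - prev_x) * prev_cdf
        prev_x, prev_cdf = x, (i + 1) / n
    area += (1.0 - prev_x) * prev_cdf
    return float(area)


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    n_reps: int = 500,
    subsample_frac: float = 0.8,
    seed: int | np.random.Generator = 0,
    delta_threshold: float = 0.1,
    chosen_k: int | None = None,
) -> ConsensusResult:
    """Monti-style resampling consensus clustering of sample columns.

    ``matrix`` is genes x samples (already filtered / centered as desired).
    ``chosen_k`` overrides the automatic delta-area rule.
    """
    samples = list(matrix.columns)
    n = len(samples)
    if n < max(k_range) * 3:
        raise ValueError("too few samples for the requested k range")
    if not 0.0 < subsample_frac < 1.0:
        raise ValueError("subsample_frac must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full_dist = _correlation_distance(matrix)
    m = int(round(subsample_frac * n))
    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = full_dist[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        co_sampled[np.ix_(idx, idx)] += 1.0
        for k in k_range:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same
    if (co_sampled == 0).sum() - n > 0.01 * n * (n - 1):
        raise ValueError("more than 1% of sample pairs never co-sampled")
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {
            k: np.where(co_sampled > 0, co_cluster[k] / co_sampled, np.nan)
            for k in k_range
        }
    for k in k_range:
        np.fill_diagonal(consensus[k], 1.0)
        consensus[k] = np.nan_to_num(consensus[k], nan=0.0)
    labels, areas = {}, {}
    for k in k_range:
        cons_dist = 1.0 - consensus[k]
        np.fill_diagonal(cons_dist, 0.0)
        Z = linkage(squareform(cons_dist, checks=False), method="average")
        labels[k] = pd.Series(
            fcluster(Z, t=k, criterion="maxclust"), index=samples, name="cluster"
        )
        areas[k] = _cdf_area(consensus[k])
    ks = sorted(k_range)
    delta = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        delta[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
    if chosen_k is None:
        candidates = [k for k in ks if delta[k] >= delta_threshold]
        chosen_k = max(candidates) if candidates else ks[0]
    return ConsensusResult(
        consensus={
            k: pd.DataFrame(consensus[k], index=samples, columns=samples)
            for k in k_range
        },
        labels=labels,
        area=areas,
        delta_area=delta,
        chosen_k=int(chosen_k),
    )


@dataclass
class SubtypeModel:
    """Nearest-centroid subtype predictor.

    ``centroids``: genes x subtypes frame of per-class mean centered
    expression over the selected gene list.
    """

    centroids: pd.DataFrame
    subtype_names: tuple[str, ...] = SUBTYPES

    def __post_init__(self) -> None:
        if self.centroids.isna().any().any():
            raise ValueError("centroids contain missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)

    def save(self, genes_path, centroids_path) -> None:
        pd.Series(self.gene_ids, name="gene").to_csv(
            genes_path, sep="\t", index=False
        )
        write_matrix(self.centroids, centroids_path)

    @classmethod
    def load(cls, genes_path, centroids_path) -> "SubtypeModel":
        centroids = read_matrix(centroids_path, index_name="gene").astype(float)
        genes = pd.read_csv(genes_path, sep="\t")["gene"]
        centroids = centroids.loc[genes]
        return cls(centroids=centroids, subtype_names=tuple(centroids.columns))


def train_centroid_predictor(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_genes: int = 506,
) -> SubtypeModel:
    """Train a nearest-centroid predictor on labelled expression.

    Genes are scored per class by the one-vs-rest standardised mean
    difference of gene-median-centered expression; the top genes are taken
    in a balanced round-robin over classes until ``n_genes`` distinct genes
    are selected. Centroids are per-class means over those genes.
    """
    if n_genes > len(matrix):
        raise ValueError(f"n_genes={n_genes} exceeds {len(matrix)} available genes")
    classes = [c for c in SUBTYPES if c in set(labels)] or sorted(set(labels))
    counts = labels.value_counts()
    if (counts.reindex(classes) < 2).any():
        raise ValueError("need >= 2 samples per class")
    centered = median_center(matrix[labels.index])
    x = centered.to_numpy(dtype=float)
    rankings = {}
    for cls_name in classes:
        in_mask = (labels == cls_name).to_numpy()
        x_in, x_out = x[:, in_mask], x[:, ~in_mask]
        diff = np.nanmean(x_in, axis=1) - np.nanmean(x_out, axis=1)
        pooled_sd = np.sqrt(
            (np.nanvar(x_in, axis=1, ddof=1) + np.nanvar(x_out, axis=1, ddof=1)) / 2.0
        )
        score = np.abs(diff) / (pooled_sd + 1e-12)
        order = sorted(
            range(len(matrix.index)), key=lambda i: (-score[i], matrix.index[i])
        )
        rankings[cls_name] = [matrix.index[i] for i in order]
    selected: list[str] = []
    seen = set()
    depth = 0
    while len(selected) < n_genes:
        for cls_name in classes:
            if len(selected) >= n_genes:
                break
            gene = rankings[cls_name][depth]
            if gene not in seen:
                seen.add(gene)
                selected.append(gene)
        depth += 1
    centroids = pd.DataFrame(
        {
            cls_name: centered.loc[selected, labels.index[labels == cls_name]].mean(axis=1)
            for cls_name in classes
        }
    )
    return SubtypeModel(centroids=centroids, subtype_names=tuple(classes))


def predict_subtype(model: SubtypeModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Assign each sample to the nearest centroid (1 - Pearson correlation).

    Returns a frame with columns ``subtype`` and ``flag``; the new cohort is
    gene-median-centered over its own samples first. Requires >= 50% of the
    model's genes to be present.
    """
    shared = [g for g in model.gene_ids if g in matrix.index]
    if len(shared) < 0.5 * len(model.gene_ids):
        raise ValueError(
            f"only {len(shared)}/{len(model.gene_ids)} model genes present"
        )
    centered = median_center(matrix.loc[shared])
    cent = model.centroids.loc[shared]
    out = []
    for sample in matrix.columns:
        v = centered[sample].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() == 0:
            out.append((sample, None, "no model genes measured"))
            continue
        dists = []
        for cls_name in model.subtype_names:
            c = cent[cls_name].to_numpy(dtype=float)[ok]
            vv = v[ok]
            denom = np.std(vv) * np.std(c)
            corr = 0.0 if denom == 0 else float(np.corrcoef(vv, c)[0, 1])
            dists.append(1.0 - corr)
        dists = np.asarray(dists)
        best = int(np.argmin(dists))
        tie = np.sum(np.isclose(dists, dists[best], atol=1e-12)) > 1
        out.append(
            (sample, model.subtype_names[best], "tie broken by subtype order" if tie else "")
        )
    return pd.DataFrame(out, columns=["sample_id", "subtype", "flag"]).set_index(
        "sample_id"
    )
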