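"""Evaluation: prediction metrics, stratified analyses, naive baselines and
cell-type clustering.

Metrics are computed only on positions with true methylation available
(the target mask). PCC and mean absolute error use the continuous levels;
MCC, average precision and ROC AUC binarize the truth at a threshold
(default 0.5) and use the predictions as scores (MCC also thresholds the
predictions). Clustering follows the ARI-all-data / ARI-two-components
scheme: K-means (k = 4) on the full cells x CpG-position prediction
matrix, and on the top-2 t-SNE components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .graphs import PromoterGraph

__all__ = [
    "MetricReport",
    "ClusterReport",
    "compute_metrics",
    "error_by_true_level",
    "true_level_distribution",
    "naive_predictor",
    "degree_analysis",
    "ari",
    "cluster_cells",
    "rank_promoters_by_ari",
    "prediction_matrix",
]


@dataclass
class MetricReport:
    pcc: float
    mcc: float
    average_precision: float
    auc: float
    mean_abs_error: float
    n_evaluated_positions: int
    single_class: bool = False

    def to_table(self) -> str:
        return (
            "metric\tvalue\n"
            f"pcc\t{self.pcc:.6f}\nmcc\t{self.mcc:.6f}\n"
            f"average_precision\t{self.average_precision:.6f}\n"
            f"auc\t{self.auc:.6f}\nmean_abs_error\t{self.mean_abs_error:.6f}\n"
            f"n_evaluated_positions\t{self.n_evaluated_positions}\n"
        )


def _flatten_masked(pred, true, mask):
    pred, true, mask = (np.asarray(a) for a in (pred, true, mask))
    return pred[mask.astype(bool)], true[mask.astype(bool)]


def compute_metrics(pred, true, mask, threshold: float = 0.5) -> MetricReport:
    """All five metrics on the mask-true positions.

    When the binarized truth has a single class, MCC/AP/AUC are reported
    as NaN with ``single_class`` set; PCC and MAE are still computed.
    """
    p, t = _flatten_masked(pred, true, mask)
    if len(p) < 2:
        raise ValueError("need at least two evaluated positions")
    mae = float(np.abs(p - t).mean())
    if np.std(p) == 0 or np.std(t) == 0:
        pcc = np.nan
    else:
        pcc = float(pearsonr(p, t)[0])
    labels = (t >= threshold).astype(int)
    if labels.min() == labels.max():
        return MetricReport(pcc, np.nan, np.nan, np.nan, mae, len(p), single_class=True)
    mcc = float(matthews_corrcoef(labels, (p >= threshold).astype(int)))
    ap = float(average_precision_score(labels, p))
    auc = float(roc_auc_score(labels, p))
    return MetricReport(pcc, mcc, ap, auc, mae, len(p))


_LEVEL_BINS = (
    ["0"]
    + [f"({lo / 10:.1f},{(lo + 1) / 10:.1f}]" for lo in range(10)]
    + ["1"]
)


def _level_bin(x: float) -> str:
    """Bin label: exact 0 and exact 1 are their own bins, else (k/10,(k+1)/10]."""
    if x == 0.0:
        return "0"
    if x == 1.0:
        return "1"
    k = min(int(np.ceil(x * 10) - 1), 9)
    return _LEVEL_BINS[1 + max(k, 0)]


def error_by_true_level(pred, true, mask, bin_width: float = 0.1) -> pd.DataFrame:
    """Mean |pred - true| per true-level bin (exact 0/1 as their own bins)."""
    p, t = _flatten_masked(pred, true, mask)
    if len(p) == 0:
        raise ValueError("empty mask")
    df = pd.DataFrame({"true": t, "abs_error": np.abs(p - t)})
    df["bin"] = [_level_bin(x) for x in t]
    out = (
        df.groupby("bin")["abs_error"]
        .agg(["mean", "count"])
        .reindex(_LEVEL_BINS)
        .reset_index()
        .rename(columns={"mean": "mean_abs_error"})
    )
    out["count"] = out["count"].fillna(0).astype(int)
    return out


def true_level_distribution(true, mask) -> pd.DataFrame:
    """Fraction of true levels per bin; fractions sum to 1."""
    t = np.asarray(true)[np.asarray(mask).astype(bool)]
    counts = pd.Series([_level_bin(x) for x in t]).value_counts()
    counts = counts.reindex(_LEVEL_BINS).fillna(0).astype(int)
    return pd.DataFrame(
        {"bin": _LEVEL_BINS, "count": counts.values, "fraction": counts.values / max(len(t), 1)}
    )


def naive_predictor(
    graph: PromoterGraph, variant: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Baselines that copy the true methylation of spatial neighbors.

    Variant 1 copies the bp-wise true levels of the single most-connected
    neighbor (highest aggregated contact count; ties go to the lowest
    node index). Variant 2 takes the contact-count-weighted mean of all
    neighbors' true levels at alignable window offsets. Isolated nodes
    (and offsets no neighbor covers) get no prediction. Returns
    (predictions, prediction mask), both (n, window).
    """
    if graph.aggregated_counts is None:
        raise ValueError("graph lacks aggregated contact counts")
    agg = graph.aggregated_counts
    n, window = graph.targets.shape
    pred = np.zeros((n, window))
    pred_mask = np.zeros((n, window), dtype=bool)
    adj = graph.adjacency()
    for i in range(n):
        neighbors = np.flatnonzero(adj[i])
        if len(neighbors) == 0:
            continue
        if variant == 1:
            best = neighbors[np.argmax(agg[i, neighbors])]
            pred[i] = graph.targets[best]
            pred_mask[i] = graph.target_mask[best]
        elif variant == 2:
            weights = agg[i, neighbors].astype(float)
            cover = graph.target_mask[neighbors]  # (m, window)
            values = graph.targets[neighbors]
            wsum = (weights[:, None] * cover).sum(axis=0)
            ok = wsum > 0
            pred[i, ok] = (weights[:, None] * cover * values).sum(axis=0)[ok] / wsum[ok]
            pred_mask[i] = ok
        else:
            raise ValueError(f"unknown naive-predictor variant {variant}")
    return pred, pred_mask


def degree_analysis(
    graphs: Sequence[PromoterGraph],
    predictions: Sequence[np.ndarray],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics per node degree, plus the degree distribution across graphs.

    Positions are pooled across all nodes of a given degree in all graphs;
    degree-0 nodes are excluded (the degree table starts at 1).
    """
    by_degree: dict[int, tuple[list, list]] = {}
    degree_counts: dict[int, int] = {}
    for graph, pred in zip(graphs, predictions):
        degrees = graph.degrees()
        for i, deg in enumerate(degrees):
            degree_counts[int(deg)] = degree_counts.get(int(deg), 0) + 1
            if deg == 0:
                continue
            m = graph.target_mask[i]
            if m.sum() == 0:
                continue
            bucket = by_degree.setdefault(int(deg), ([], []))
            bucket[0].append(pred[i][m])
            bucket[1].append(graph.targets[i][m])
    rows = []
    for deg in sorted(by_degree):
        p = np.concatenate(by_degree[deg][0])
        t = np.concatenate(by_degree[deg][1])
        if len(p) < 2:
            continue
        r = compute_metrics(p, t, np.ones_like(p, dtype=bool), threshold)
        rows.append(
            {
                "degree": deg, "pcc": r.pcc, "mcc": r.mcc,
                "average_precision": r.average_precision, "auc": r.auc,
                "mean_abs_error": r.mean_abs_error, "n_positions": r.n_evaluated_positions,
            }
        )
    metrics = pd.DataFrame(rows)
    dist = pd.DataFrame(
        sorted(degree_counts.items()), columns=["degree", "n_nodes"]
    )
    return metrics, dist


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError(f"length mismatch: {len(labels_a)} vs {len(labels_b)}")
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def prediction_matrix(
    cell_ids: Sequence[str],
    graphs_by_cell: dict[str, Sequence[PromoterGraph]],
    predictions_by_cell: dict[str, Sequence[np.ndarray]],
    genome: Optional[dict[str, str]] = None,
    use_truth_mask: bool = False,
    missing_value: float = -1.0,
) -> pd.DataFrame:
    """Cells x CpG-position matrix of predicted levels.

    Columns are (chrom, position) of C/G sites of reference CpGs when a
    genome is given (all window positions otherwise). With
    ``use_truth_mask``, positions without true methylation for a cell are
    set to ``missing_value`` (the -1 convention for mixed true/missing
    matrices); otherwise predictions are used everywhere.
    """
    from .io import cpg_mask_for_region  # deferred: io imports core only, avoids heavy import at module load

    rows = []
    for cell_id in cell_ids:
        row: dict[tuple[str, int], float] = {}
        for graph, pred in zip(graphs_by_cell[cell_id], predictions_by_cell[cell_id]):
            for node_idx, region in enumerate(graph.regions):
                start, _ = region.seq_window
                window = graph.targets.shape[1]
                if genome is not None:
                    site_mask = cpg_mask_for_region(genome, region)
                    offsets = np.flatnonzero(site_mask)
                else:
                    offsets = np.arange(window)
                for off in offsets:
                    if off >= window:
                        continue
                    key = (graph.chrom, start + int(off))
                    if use_truth_mask and not graph.target_mask[node_idx, off]:
                        row[key] = missing_value
                    else:
                        row[key] = float(pred[node_idx, off])
        rows.append(row)
    df = pd.DataFrame(rows, index=list(cell_ids))
    df = df[sorted(df.columns)]
    return df.fillna(missing_value)


@dataclass
class ClusterReport:
    kmeans_labels: np.ndarray
    tsne_xy: np.ndarray
    ari_all_data: float
    ari_two_components: float

    def tsne_table(self, cell_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": list(cell_ids), "x": self.tsne_xy[:, 0], "y": self.tsne_xy[:, 1]}
        )


def cluster_cells(
    matrix: np.ndarray,
    true_types: Sequence[str],
    n_clusters: int = 4,
    seed: int = 0,
    perplexity: float = 30.0,
) -> ClusterReport:
    """K-means + t-SNE clustering of cells from predicted methylation levels.

    ari_all_data scores K-means (10 restarts) on the full matrix against
    the true types; ari_two_components scores K-means on the top-2 t-SNE
    components. Perplexity is capped below the number of cells.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_cells = matrix.shape[0]
    if n_cells < n_clusters:
        raise ValueError(f"{n_cells} cells < {n_clusters} clusters")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(matrix)
    perplexity = min(perplexity, (n_cells - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=max(perplexity, 2.0), init="pca")
    xy = tsne.fit_transform(matrix)
    km2 = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels2 = km2.fit_predict(xy)
    true_types = list(true_types)
    return ClusterReport(
        kmeans_labels=labels,
        tsne_xy=xy,
        ari_all_data=ari(labels, true_types),
        ari_two_components=ari(labels2, true_types),
    )


def rank_promoters_by_ari(
    per_promoter: dict[str, np.ndarray],
    true_types: Sequence[str],
    n_clusters: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank promoters by single-promoter ARI-all-data; cumulative top-k curve.

    ``per_promoter`` maps promoter id -> (cells x positions) prediction
    matrix. The curve concatenates the top-k promoters' columns and
    re-clusters.
    """
    scores = []
    for gene_id, mat in per_promoter.items():
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(np.asarray(mat, dtype=float))
        scores.append({"gene_id": gene_id, "ari_all_data": ari(labels, true_types)})
    ranking = (
        pd.DataFrame(scores)
        .sort_values(["ari_all_data", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    curve_rows = []
    stacked = None
    for k, gene_id in enumerate(ranking["gene_id"], start=1):
        mat = np.asarray(per_promoter[gene_id], dtype=float)
        stacked = mat if stacked is None else np.hstack([stacked, mat])
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(stacked)
        curve_rows.append({"top_k": k, "ari_all_data": ari(labels, true_types)})
    return ranking, pd.DataFrame(curve_rows)
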