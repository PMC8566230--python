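"""Tumor subtype discovery on growth-factor-gene expression.

Samples are embedded with UMAP (correlation metric) on log2 fold-from-mean
expression and clustered with HDBSCAN; density outliers keep the label -1
("no cluster").  Cluster markers are called gene-by-gene with two-sided
Mann-Whitney tests (cluster vs rest) under Benjamini-Hochberg correction,
and cell lines are assigned to clusters with the additive marker score
S = sum_i log2(exp_i) * c_i, where c_i is +1 for a cluster's up-regulated
markers and -1 for down-regulated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import HDBSCAN

from .matrix import ExpressionMatrix, adjust_pvalues

#: floor applied to fold values before taking log2 (a fold of 0 would be -inf)
LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class ClusterParams:
    """UMAP + HDBSCAN settings.

    The defaults (n_neighbors=50, min_dist=0, correlation metric,
    min_samples=50, min_cluster_size=100) assume a cohort of roughly a
    thousand tumors; for smaller cohorts scale ``min_cluster_size`` down,
    e.g. max(10, n_samples // 12).
    """

    n_neighbors: int = 50
    min_dist: float = 0.0
    metric: str = "correlation"
    min_samples: int = 50
    min_cluster_size: int = 100
    seed: int = 0


@dataclass(frozen=True)
class ClusterModel:
    embedding: pd.DataFrame  # samples x (umap1, umap2)
    labels: pd.Series  # 1..k, -1 = no cluster
    params: ClusterParams

    @property
    def n_clusters(self) -> int:
        return int((np.unique(self.labels) > 0).sum())


def _log2_fold(m: ExpressionMatrix) -> np.ndarray:
    if m.norm_state != "fold_from_mean":
        raise ValueError("expected fold_from_mean-normalized expression")
    v = m.data.to_numpy(dtype=float)
    if (v < LOG_FLOOR).any():
        warnings.warn("fold values below 1e-6 floored before log2")
    return np.log2(np.maximum(v, LOG_FLOOR))


def embed_and_cluster(m: ExpressionMatrix, params: ClusterParams | None = None) -> ClusterModel:
    """UMAP embedding followed by HDBSCAN density clustering.

    Clusters are relabeled 1..k by decreasing size; noise points get -1.
    The embedding and labels are deterministic for a fixed seed.
    """
    params = params or ClusterParams()
    if m.n_samples < params.min_cluster_size:
        raise ValueError(
            f"{m.n_samples} samples < min_cluster_size={params.min_cluster_size}"
        )
    import umap  # deferred: numba compilation makes this import expensive

    x = _log2_fold(m)
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        n_components=2,
        random_state=params.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        emb = reducer.fit_transform(x)
    raw = HDBSCAN(
        min_samples=params.min_samples,
        min_cluster_size=params.min_cluster_size,
        copy=True,
    ).fit_predict(emb)

    # stable relabeling: 1..k by decreasing cluster size
    labels = np.full(m.n_samples, -1, dtype=int)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    for new, old in enumerate(ids[np.argsort(-counts, kind="stable")], start=1):
        labels[raw == old] = new
    return ClusterModel(
        embedding=pd.DataFrame(emb, index=m.data.index, columns=["umap1", "umap2"]),
        labels=pd.Series(labels, index=m.data.index, name="cluster"),
        params=params,
    )


def call_cluster_degs(m: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Cluster-vs-rest marker genes by two-sided Mann-Whitney tests.

    Noise samples (label -1) are excluded.  log2 fold change is computed
    against the mean expression across all clustered samples; q-values are
    BH-corrected over every (cluster, gene) test.  Returns columns
    (cluster, gene, log2fc, p, q, direction).
    """
    labels = labels.loc[m.data.index]
    mask = labels.to_numpy() > 0
    clusters = sorted(int(c) for c in np.unique(labels[mask]))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for marker calling")
    x = m.data.to_numpy(dtype=float)[mask]
    lab = labels.to_numpy()[mask]
    for c in clusters:
        if (lab == c).sum() < 3:
            raise ValueError(f"cluster {c} has fewer than 3 samples")
    overall_mean = x.mean(axis=0)
    rows = []
    for c in clusters:
        in_c = lab == c
        u, p = sps.mannwhitneyu(x[in_c], x[~in_c], alternative="two-sided", axis=0)
        log2fc = np.log2(
            np.maximum(x[in_c].mean(axis=0), LOG_FLOOR)
            / np.maximum(overall_mean, LOG_FLOOR)
        )
        for g, fc, pv in zip(m.gene_ids, log2fc, p):
            rows.append({"cluster": c, "gene": g, "log2fc": float(fc), "p": float(pv)})
    out = pd.DataFrame(rows)
    out["q"] = adjust_pvalues(out["p"], "bh_fdr")
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def assign_cluster(
    cell_expr: pd.Series, degs: pd.DataFrame, q_threshold: float = 0.05
) -> tuple[dict[int, float], int | None]:
    """Score one fold-from-mean-normalized sample against cluster markers.

    Per cluster, S = sum over its significant markers of log2(exp) * c with
    c = +1 (up) / -1 (down); the sample is assigned to the argmax cluster.
    Ties return assignment None ("ambiguous").
    """
    sig = degs[degs["q"] < q_threshold]
    if sig.empty:
        raise ValueError("no significant cluster markers to score against")
    missing = sorted(set(sig["gene"]) - set(cell_expr.index))
    if missing:
        raise KeyError(f"marker genes missing from sample: {missing[:5]}")
    vals = cell_expr[sig["gene"]].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("expression must be positive to take log2")
    contrib = np.log2(vals) * np.where(sig["direction"].to_numpy() == "up", 1.0, -1.0)
    scores = (
        pd.Series(contrib, index=sig["cluster"].to_numpy()).groupby(level=0).sum()
    )
    scores_d = {int(c): float(s) for c, s in scores.items()}
    best = max(scores_d.values())
    winners = [c for c, s in scores_d.items() if s == best]
    return scores_d, (winners[0] if len(winners) == 1 else None)
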