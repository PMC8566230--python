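"""Pre-ranked gene set enrichment analysis.

Genes are ranked by Pearson correlation with a target gene's expression;
the weighted Kolmogorov-Smirnov-style enrichment score (ES) of each set is
the extremum of a running sum that increments by |metric|^p / sum over hits
at member genes and decrements by 1/(N - N_hits) elsewhere.  Significance
comes from a gene-set-membership permutation null of matched size: the
normalized enrichment score (NES) divides ES by the mean |null ES| of the
same sign, nominal p-values are empirical within the same-sign null, and
the FDR follows the sign-stratified pooled-null procedure.  Sets passing
nominal p < 0.05 and FDR < 0.25 are reported, best NES first, truncated to
the top 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: int


def rank_by_correlation(m: ExpressionMatrix, target_gene: str) -> pd.Series:
    """Rank all other genes by Pearson correlation with `target_gene`.

    Returns a Series (gene -> r) in descending metric order; ties are broken
    lexicographically by gene id for determinism.  Zero-variance genes get
    metric 0 with a warning.
    """
    if target_gene not in m.data.columns:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    if m.n_samples < 10:
        raise ValueError("need >= 10 samples for correlation ranking")
    x = m.data.to_numpy(dtype=float)
    target = m.data[target_gene].to_numpy(dtype=float)
    tc = target - target.mean()
    t_ss = np.sqrt((tc**2).sum())
    xc = x - x.mean(axis=0)
    x_ss = np.sqrt((xc**2).sum(axis=0))
    degenerate = (x_ss == 0) | (t_ss == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) assigned metric 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, xc.T @ tc / (x_ss * t_ss + (x_ss == 0)))
    s = pd.Series(r, index=m.data.columns).drop(index=target_gene)
    # round-off-tolerant tie grouping so equal correlations sort by gene id
    order = sorted(s.index, key=lambda g: (-round(s[g], 12), g))
    return s[order]


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum."""
    genes = list(gene_set.genes) if hasattr(gene_set, "genes") else list(gene_set)
    hit = np.asarray(ranked.index.isin(set(genes)))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranking")
    metric = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    return _es_from_arrays(metric, hit.astype(bool))


def _es_from_arrays(weighted_metric: np.ndarray, hit: np.ndarray) -> tuple[float, np.ndarray]:
    n = hit.size
    n_hits = int(hit.sum())
    hit_total = weighted_metric[hit].sum()
    if hit_total == 0:
        # all member metrics are exactly 0; fall back to unweighted hits
        inc = hit / n_hits
    else:
        inc = np.where(hit, weighted_metric / hit_total, 0.0)
    if n == n_hits:
        running = np.cumsum(inc)
    else:
        dec = (~hit) / (n - n_hits)
        running = np.cumsum(inc - dec)
    es_idx = int(np.argmax(np.abs(running)))
    return float(running[es_idx]), running


def _leading_edge(running: np.ndarray, hit: np.ndarray, es: float) -> int:
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        return int(hit[: peak + 1].sum())
    return int(hit[peak:].sum())


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.25,
    top_n: int = 100,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Run pre-ranked GSEA over a collection with a membership-permutation null.

    Returns the passing sets (nominal p and FDR below the thresholds) as a
    DataFrame sorted by NES descending, truncated to ``top_n`` rows.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    metric = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    n = metric.size
    ranked_genes = set(ranked.index)

    records = []
    null_by_size: dict[int, np.ndarray] = {}
    for gs in collection:
        members = [g for g in gs.genes if g in ranked_genes]
        size = len(members)
        if size == 0:
            warnings.warn(f"set {gs.name!r} has no overlap with the ranking; skipped")
            continue
        if size >= n:
            warnings.warn(f"set {gs.name!r} covers the whole ranking; skipped")
            continue
        hit = np.asarray(ranked.index.isin(set(members)))
        es, running = _es_from_arrays(metric, hit)
        if size not in null_by_size:
            null = np.empty(n_perm)
            for i in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=size, replace=False)] = True
                null[i], _ = _es_from_arrays(metric, mask)
            null_by_size[size] = null
        null = null_by_size[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
            null_nes = np.array([])
        else:
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else 0.0
        # normalize this set's null the same way, for the pooled FDR null
        pos, neg = null[null >= 0], null[null < 0]
        null_nes = np.concatenate(
            [
                pos / pos.mean() if pos.size else pos,
                -neg / neg.mean() if neg.size else neg,
            ]
        )
        records.append(
            {
                "set_name": gs.name,
                "es": es,
                "nes": float(nes),
                "p": float(p),
                "size": size,
                "leading_edge": _leading_edge(running, hit, es),
                "_null_nes": null_nes,
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["set_name", "es", "nes", "p", "fdr", "size", "leading_edge"]
        )
    df = pd.DataFrame(records)
    pooled = np.concatenate(df["_null_nes"].to_list())
    obs = df["nes"].to_numpy()
    fdr = np.empty(len(df))
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_frac = np.mean(pooled[pooled >= 0] >= nes) if (pooled >= 0).any() else 1.0
            obs_frac = np.mean(obs[obs >= 0] >= nes)
        else:
            null_frac = np.mean(pooled[pooled < 0] <= nes) if (pooled < 0).any() else 1.0
            obs_frac = np.mean(obs[obs < 0] <= nes)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    df["fdr"] = fdr
    df = df.drop(columns="_null_nes")
    passing = df[(df["p"] < p_threshold) & (df["fdr"] < fdr_threshold)]
    out = passing.sort_values("nes", ascending=False).head(top_n)
    return out.reset_index(drop=True)[
        ["set_name", "es", "nes", "p", "fdr", "size", "leading_edge"]
    ]
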