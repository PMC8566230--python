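"""Gene-set prognostic scoring (GPScore).

Each gene's prognostic direction is classified by a Kaplan-Meier / log-rank
comparison of the cohort split at the gene's median expression: a gene is
"unfavorable" when high expression associates with worse overall survival
and "favorable" otherwise, with Bonferroni correction over the number of
genes tested.  A gene set is then scored as the unfavorable fraction of its
prognosis-significant members,

    GPScore = Nu / (Nu + Nf),

calibrated against randomly drawn gene sets (null mean, SD and a 3-sigma
band), and a set is called significant when its per-dataset scores differ
from the random-set baseline by a two-sided t-test with FDR q < 0.01.
A sample-level companion score (the mean squared fold-from-mean expression
of the set's genes, split into quartiles Q1 = highest .. Q4 = lowest) turns
a significant set into a risk stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ClinicalTable, ExpressionMatrix, adjust_pvalues
from .stats import logrank_test

DIRECTIONS = ("unfavorable", "favorable", "ns")


@dataclass(frozen=True)
class GenePrognosis:
    gene: str
    direction: str
    p: float
    p_adj: float


@dataclass(frozen=True)
class GPScoreRecord:
    set_name: str
    nu: int
    nf: int

    @property
    def score(self) -> float | None:
        if self.nu + self.nf == 0:
            return None
        return self.nu / (self.nu + self.nf)


@dataclass(frozen=True)
class NullCalibration:
    """Baseline GPScore distribution from random gene sets."""

    mean: float
    sd: float
    scores: np.ndarray

    @property
    def low3(self) -> float:
        return self.mean - 3 * self.sd

    @property
    def high3(self) -> float:
        return self.mean + 3 * self.sd


def gene_prognosis(
    m: ExpressionMatrix,
    clinical: ClinicalTable,
    gene: str,
    n_tests: int,
    cutoff: str = "median",
    scan_quantiles: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
) -> GenePrognosis:
    """Classify one gene's association of high expression with survival.

    ``cutoff="median"`` splits at the median (deterministic, conservative);
    ``cutoff="scan"`` tries a grid of expression quantiles and keeps the
    best split, with an extra Bonferroni factor for the number of cutoffs
    tried.  Bonferroni over ``n_tests`` genes decides significance at 0.05.
    """
    if m.n_samples < 20:
        raise ValueError("need >= 20 samples for a prognostic call")
    clinical = clinical.aligned_to(m)
    values = m.data[gene].to_numpy(dtype=float)
    times = clinical.df["os_time"].to_numpy(dtype=float)
    events = clinical.df["os_event"].to_numpy(dtype=bool)

    if np.ptp(values) == 0:
        warnings.warn(f"gene {gene!r} is constant; no prognostic call")
        return GenePrognosis(gene, "ns", np.nan, np.nan)

    if cutoff == "median":
        quantiles: Sequence[float] = (0.5,)
        m_cutoffs = 1
    elif cutoff == "scan":
        quantiles = scan_quantiles
        m_cutoffs = len(scan_quantiles)
    else:
        raise ValueError(f"unknown cutoff policy {cutoff!r}")

    best_p, best_dir = np.inf, "ns"
    for q in quantiles:
        thr = np.quantile(values, q)
        high = values > thr
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        if not (events[high].any() or events[~high].any()):
            continue
        res = logrank_test(times[high], events[high], times[~high], events[~high])
        if res.p < best_p:
            best_p = res.p
            best_dir = "unfavorable" if res.direction > 0 else "favorable"
    if not np.isfinite(best_p):
        return GenePrognosis(gene, "ns", np.nan, np.nan)
    p_adj = min(1.0, best_p * n_tests * m_cutoffs)
    direction = best_dir if p_adj < 0.05 else "ns"
    return GenePrognosis(gene, direction, float(best_p), float(p_adj))


def prognosis_scan(
    m: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: Iterable[str] | None = None,
    cutoff: str = "median",
) -> dict[str, GenePrognosis]:
    """Prognostic calls for many genes; Bonferroni m = number tested."""
    genes = list(genes) if genes is not None else m.gene_ids
    n_tests = len(genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            g: gene_prognosis(m, clinical, g, n_tests=n_tests, cutoff=cutoff)
            for g in genes
        }


def gpscore(
    gene_set, prognoses: Mapping[str, GenePrognosis]
) -> GPScoreRecord:
    """Unfavorable fraction of a set's prognosis-significant members."""
    genes = list(gene_set.genes) if hasattr(gene_set, "genes") else list(gene_set)
    name = getattr(gene_set, "name", "gene_set")
    members = [prognoses[g] for g in genes if g in prognoses]
    nu = sum(1 for gp in members if gp.direction == "unfavorable")
    nf = sum(1 for gp in members if gp.direction == "favorable")
    rec = GPScoreRecord(set_name=name, nu=nu, nf=nf)
    if rec.score is None:
        warnings.warn(f"set {name!r} has no prognostic genes; score undefined")
    return rec


def null_calibration(
    prognoses: Mapping[str, GenePrognosis],
    n_random: int = 20,
    size_range: tuple[int, int] = (50, 1000),
    seed: int = 0,
) -> NullCalibration:
    """GPScore baseline from random gene sets of the measured universe.

    ``n_random`` sets with sizes uniform on ``size_range`` are drawn without
    replacement from all genes with a prognostic call; sets that happen to
    contain no significant gene are excluded from the statistics.
    """
    universe = list(prognoses)
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError(
            f"size_range upper bound {hi} exceeds gene universe ({len(universe)})"
        )
    if lo < 1 or lo > hi:
        raise ValueError("invalid size_range")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        rec = gpscore(list(members), prognoses)
        if rec.score is not None:
            scores.append(rec.score)
    if not scores:
        raise ValueError("no random set contained a prognostic gene")
    arr = np.asarray(scores, dtype=float)
    return NullCalibration(mean=float(arr.mean()), sd=float(arr.std(ddof=1) if arr.size > 1 else 0.0), scores=arr)


def score_significance(
    per_dataset_scores: pd.DataFrame, null_means: pd.Series
) -> pd.DataFrame:
    """Compare each set's per-dataset GPScores with the random-set baseline.

    ``per_dataset_scores`` is sets x datasets; ``null_means`` holds each
    dataset's random-set mean score.  A two-sided one-sample t-test on the
    per-dataset deviations (score - null mean) is BH-corrected over sets;
    significance is q < 0.01.
    """
    if per_dataset_scores.shape[1] < 2:
        raise ValueError("need scores from at least 2 datasets")
    missing = per_dataset_scores.columns.difference(null_means.index)
    if len(missing):
        raise ValueError(f"datasets without null means: {list(missing)}")
    dev = per_dataset_scores.sub(null_means[per_dataset_scores.columns], axis=1)
    t, p = sps.ttest_1samp(dev.to_numpy(dtype=float), popmean=0.0, axis=1)
    out = pd.DataFrame(
        {
            "set_name": per_dataset_scores.index,
            "mean_score": per_dataset_scores.mean(axis=1).to_numpy(),
            "mean_deviation": dev.mean(axis=1).to_numpy(),
            "t": t,
            "p": p,
        }
    ).set_index("set_name")
    out["q"] = adjust_pvalues(np.nan_to_num(out["p"], nan=1.0), "bh_fdr")
    out["significant"] = out["q"] < 0.01
    return out


def shared_sets(
    per_gene_enriched: Mapping[str, Iterable[str]], k_min: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene sets enriched for multiple receptor genes.

    Returns (shared, pairwise): ``shared`` lists each set with the number of
    genes it is enriched for, filtered at ``k_min``; ``pairwise`` counts
    shared enriched sets per gene pair (the ribbon widths of a circos-style
    rendering).
    """
    if len(per_gene_enriched) < 2:
        raise ValueError("need enrichments for at least 2 genes")
    sets_by_gene = {g: set(s) for g, s in per_gene_enriched.items()}
    counts: dict[str, int] = {}
    for s in sets_by_gene.values():
        for name in s:
            counts[name] = counts.get(name, 0) + 1
    shared = (
        pd.DataFrame(
            [(name, c) for name, c in counts.items() if c >= k_min],
            columns=["set_name", "n_genes"],
        )
        .sort_values(["n_genes", "set_name"], ascending=[False, True])
        .reset_index(drop=True)
    )
    genes = list(sets_by_gene)
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            rows.append(
                {"gene_a": a, "gene_b": b, "n_shared": len(sets_by_gene[a] & sets_by_gene[b])}
            )
    return shared, pd.DataFrame(rows)


def sample_set_score(
    m: ExpressionMatrix, gene_set
) -> tuple[pd.Series, pd.Series, bool]:
    """Mean squared fold-from-mean expression of a set, with quartile labels.

    Returns (scores, quartiles, degenerate).  Quartiles run Q1 (highest
    scores) to Q4 (lowest); if all samples score identically the split is
    meaningless and ``degenerate`` is True (labels are all Q1).
    """
    if m.norm_state != "fold_from_mean":
        raise ValueError("expression must be fold_from_mean normalized")
    genes = list(gene_set.genes) if hasattr(gene_set, "genes") else list(gene_set)
    present = [g for g in genes if g in m.data.columns]
    if not present:
        raise ValueError("gene set has no overlap with the matrix")
    scores = (m.data[present] ** 2).mean(axis=1)
    scores.name = "set_score"
    if np.ptp(scores.to_numpy()) == 0:
        warnings.warn("all samples score identically; quartile split degenerate")
        return scores, pd.Series("Q1", index=scores.index, name="quartile"), True
    # rank descending so Q1 = highest scores
    ranks = scores.rank(ascending=False, method="first")
    quartiles = pd.cut(
        ranks, bins=4, labels=["Q1", "Q2", "Q3", "Q4"]
    ).astype(str)
    quartiles.name = "quartile"
    return scores, quartiles, False
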