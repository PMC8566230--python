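"""Synthetic cohorts with known ground truth.

The generators emulate the data structure of a multi-dataset neuroblastoma
expression study: log-normal background expression, three planted expression
subtypes with cluster-specific differentially expressed genes, a
MYCN-amplification flag enriched in the aggressive cluster, Weibull
proportional-hazards survival driven by planted prognostic genes, pathway
databases with planted activation shifts between phenotype groups, and
Bliss-consistent dose-response grids.  Every generator is fully determined
by its seed so downstream tests can assert recovery against stored truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .drugresponse import DoseResponseGrid
from .matrix import ClinicalTable, ExpressionMatrix
from .pal import PathwayDef


@dataclass(frozen=True)
class PathwaySpec:
    """Blueprint for one synthetic pathway: member roles and the planted
    log2 shift applied to group-A samples (activators up, repressors down)."""

    name: str
    members: Mapping[str, float]  # gene -> ARR
    shift_log2: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for cohort generation.

    Defaults follow the structure of the emulated study: three expression
    subtypes, MYCN amplification strongly enriched in cluster 1 (48%) and
    nearly absent from cluster 3 (1%), multiplicative (log-normal) expression
    noise, and Weibull proportional-hazards survival with uniform censoring.
    Prognostic genes act on the log hazard with coefficient beta per unit
    log2 expression; with ``module_loading`` > 0 the positive-beta and
    negative-beta genes each share a latent per-sample program activity,
    emulating co-regulated prognostic processes.
    """

    n_samples: int = 600
    n_genes: int = 300
    n_clusters: int = 3
    cluster_weights: tuple[float, ...] | None = None
    frac_mycn_amp: tuple[float, ...] = (0.48, 0.10, 0.01)
    de_genes_per_cluster: int = 20
    de_log2fc: float = 2.0
    prognostic_genes: tuple[tuple[str, float], ...] = ()
    module_loading: float = 0.0
    weibull_shape: float = 1.5
    baseline_scale: float = 3000.0  # days
    censor_time_max: float = 6000.0  # days
    base_log2_range: tuple[float, float] = (3.0, 8.0)
    noise_sd_log2: float = 0.5
    pathway_specs: tuple[PathwaySpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.de_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("more DE genes requested than genes available")
        if len(self.frac_mycn_amp) != self.n_clusters:
            raise ValueError("frac_mycn_amp needs one entry per cluster")
        if any(not 0 <= f <= 1 for f in self.frac_mycn_amp):
            raise ValueError("MYCN fractions must lie in [0, 1]")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth stored alongside a generated cohort."""

    cluster_labels: pd.Series
    de_genes: dict[int, list[str]]
    prognostic_betas: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "cluster_labels": {k: int(v) for k, v in self.cluster_labels.items()},
            "de_genes": {str(k): v for k, v in self.de_genes.items()},
            "prognostic_betas": self.prognostic_betas,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# stage composition per cluster archetype: aggressive, intermediate, favorable
_STAGE_PROBS = {
    "aggressive": {"1": 0.02, "2": 0.05, "3": 0.18, "4": 0.70, "4S": 0.05},
    "intermediate": {"1": 0.15, "2": 0.15, "3": 0.25, "4": 0.35, "4S": 0.10},
    "favorable": {"1": 0.35, "2": 0.25, "3": 0.15, "4": 0.10, "4S": 0.15},
}


def _cluster_archetype(idx: int, n_clusters: int) -> str:
    if idx == 0:
        return "aggressive"
    if idx == n_clusters - 1:
        return "favorable"
    return "intermediate"


def _base_expression(
    cfg: SyntheticConfig, rng: np.random.Generator, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log2 expression background: per-gene level plus log-normal noise."""
    lo, hi = cfg.base_log2_range
    mu = rng.uniform(lo, hi, size=cfg.n_genes)
    log2 = mu[None, :] + rng.normal(0.0, cfg.noise_sd_log2, size=(n_samples, cfg.n_genes))
    return log2, mu


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Generate an expression matrix, clinical table, and truth record.

    Cluster-specific genes are shifted by ``de_log2fc`` in their cluster;
    survival times follow a Weibull whose log hazard is shifted by
    sum(beta * centered log2 expression) over the planted prognostic genes,
    with independent uniform censoring on [0, censor_time_max].
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names()
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    weights = cfg.cluster_weights or tuple([1.0 / cfg.n_clusters] * cfg.n_clusters)
    labels = rng.choice(cfg.n_clusters, size=cfg.n_samples, p=np.asarray(weights) / np.sum(weights))

    log2, _ = _base_expression(cfg, rng, cfg.n_samples)

    de_genes: dict[int, list[str]] = {}
    for c in range(cfg.n_clusters):
        start = c * cfg.de_genes_per_cluster
        idx = np.arange(start, start + cfg.de_genes_per_cluster)
        de_genes[c + 1] = [genes[i] for i in idx]
        log2[np.ix_(labels == c, idx)] += cfg.de_log2fc

    betas = dict(cfg.prognostic_genes)
    unknown = [g for g in betas if g not in genes]
    if unknown:
        raise ValueError(f"prognostic genes not in cohort: {unknown}")

    gene_pos_all = {g: j for j, g in enumerate(genes)}
    if cfg.module_loading > 0 and betas:
        # prognostic genes of the same sign form a co-regulated program:
        # they share a latent per-sample activity, as co-expressed modules do
        a_pos = rng.normal(size=cfg.n_samples)
        a_neg = rng.normal(size=cfg.n_samples)
        for g, beta in betas.items():
            factor = a_pos if beta > 0 else a_neg
            log2[:, gene_pos_all[g]] += cfg.module_loading * factor

    # proportional-hazards linear predictor on centered log2 expression
    lp = np.zeros(cfg.n_samples)
    for g, beta in betas.items():
        col = log2[:, gene_pos_all[g]]
        lp += beta * (col - col.mean())

    u = rng.uniform(size=cfg.n_samples)
    t_event = cfg.baseline_scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / cfg.weibull_shape)
    t_cens = rng.uniform(0.0, cfg.censor_time_max, size=cfg.n_samples)
    os_time = np.minimum(t_event, t_cens)
    os_event = t_event <= t_cens

    mycn = np.where(
        rng.uniform(size=cfg.n_samples) < np.asarray(cfg.frac_mycn_amp)[labels],
        "amplified",
        "non_amplified",
    )
    stages = []
    for c in labels:
        probs = _STAGE_PROBS[_cluster_archetype(int(c), cfg.n_clusters)]
        stages.append(rng.choice(list(probs), p=list(probs.values())))
    stages = np.asarray(stages)
    metastasis = np.where(
        rng.uniform(size=cfg.n_samples) < np.where(stages == "4", 0.9, 0.1),
        "yes",
        "no",
    )
    # poor therapy response tracks the planted hazard (base rate ~30%)
    p_poor = expit(lp + np.log(0.3 / 0.7))
    response = np.where(rng.uniform(size=cfg.n_samples) < p_poor, "poor", "good")

    expr = ExpressionMatrix(
        data=pd.DataFrame(np.exp2(log2), index=samples, columns=genes),
        norm_state="raw",
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "mycn": mycn,
                "inss_stage": stages,
                "metastasis": metastasis,
                "response": response,
            },
            index=samples,
        )
    )
    truth = CohortTruth(
        cluster_labels=pd.Series(labels + 1, index=samples, name="cluster"),
        de_genes=de_genes,
        prognostic_betas=betas,
    )
    return expr, clinical, truth


def default_prognostic_genes(
    cfg: SyntheticConfig, n: int = 10, beta: float = 1.0
) -> tuple[tuple[str, float], ...]:
    """Pick `n` non-DE genes and assign alternating +/- beta hazard effects."""
    genes = cfg.gene_names()
    start = cfg.de_genes_per_cluster * cfg.n_clusters
    if start + n > cfg.n_genes:
        raise ValueError("not enough non-DE genes for prognostic planting")
    chosen = genes[start : start + n]
    return tuple((g, beta if i % 2 == 0 else -beta) for i, g in enumerate(chosen))


def generate_pathway_db(
    cfg: SyntheticConfig,
) -> tuple[list[PathwayDef], pd.Series, ExpressionMatrix]:
    """Build pathways with planted group-wise activation differences.

    Returns the pathway definitions, a boolean per-sample group label
    (True = "case" group A) and a fresh background cohort in which each
    pathway's activator members were shifted up by ``shift_log2`` (and
    repressors down) in group A.  Member genes must exist in the cohort.
    """
    if not cfg.pathway_specs:
        raise ValueError("pathway_specs is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = cfg.gene_names()
    gene_pos = {g: j for j, g in enumerate(genes)}
    samples = [f"P{i:04d}" for i in range(1, cfg.n_samples + 1)]
    log2, _ = _base_expression(cfg, rng, cfg.n_samples)

    group_a = np.zeros(cfg.n_samples, dtype=bool)
    group_a[: cfg.n_samples // 2] = True

    pathways = []
    for spec in cfg.pathway_specs:
        missing = [g for g in spec.members if g not in gene_pos]
        if missing:
            raise ValueError(
                f"pathway {spec.name!r}: member genes not in cohort: {missing[:5]}"
            )
        pathways.append(PathwayDef(spec.name, dict(spec.members)))
        if spec.shift_log2:
            for g, arr in spec.members.items():
                if arr > 0:
                    log2[group_a, gene_pos[g]] += spec.shift_log2
                elif arr < 0:
                    log2[group_a, gene_pos[g]] -= spec.shift_log2
    expr = ExpressionMatrix(
        data=pd.DataFrame(np.exp2(log2), index=samples, columns=genes),
        norm_state="raw",
    )
    labels = pd.Series(group_a, index=samples, name="group_a")
    return pathways, labels, expr


def generate_dose_response(
    ic50_a: float,
    hill_a: float,
    ic50_b: float,
    hill_b: float,
    bliss_excess: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    conc_a: Sequence[float] | None = None,
    conc_b: Sequence[float] | None = None,
) -> DoseResponseGrid:
    """Viability grid whose combination wells follow Bliss independence plus
    a constant planted excess and Gaussian noise, clipped to [0, 1]."""
    if ic50_a <= 0 or ic50_b <= 0 or hill_a <= 0 or hill_b <= 0:
        raise ValueError("IC50s and hill slopes must be positive")
    rng = np.random.default_rng(seed)

    def default_axis(ic50):
        # up to 4x IC50: combination wells stay below full inhibition, so
        # the [0, 1] clip rarely erases the planted excess
        return np.r_[0.0, ic50 * np.exp2(np.arange(-4.0, 3.0))]

    ca = np.asarray(conc_a, dtype=float) if conc_a is not None else default_axis(ic50_a)
    cb = np.asarray(conc_b, dtype=float) if conc_b is not None else default_axis(ic50_b)

    def inhibition(c, ic50, hill):
        out = np.zeros_like(c)
        pos = c > 0
        out[pos] = 1.0 / (1.0 + (ic50 / c[pos]) ** hill)
        return out

    f_a = inhibition(ca, ic50_a, hill_a)
    f_b = inhibition(cb, ic50_b, hill_b)
    f = f_a[:, None] + f_b[None, :] - f_a[:, None] * f_b[None, :]
    # planted synergy applies to true combinations only
    f[1:, 1:] += bliss_excess
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    f = np.clip(f, 0.0, 1.0)
    f[0, 0] = 0.0
    return DoseResponseGrid(conc_a=ca, conc_b=cb, viability=1.0 - f)


def save_cohort(
    outdir,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    truth: CohortTruth,
) -> None:
    """Write expression TSV, clinical CSV, and truth JSON into `outdir`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(out / "expression.tsv")
    clinical.to_csv(out / "clinical.csv")
    truth.to_json(out / "truth.json")
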