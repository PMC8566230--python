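"""Shared fixtures: small deterministic cohorts plus the two expensive
session-scoped artifacts (a clustered 600-sample cohort and a trained
two-round survival model) reused by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nbgf.matrix import ClinicalTable, ExpressionMatrix, normalize_fold_from_mean
from nbgf.simulate import (
    PathwaySpec,
    SyntheticConfig,
    default_prognostic_genes,
    generate_cohort,
    generate_pathway_db,
)
from nbgf.subtyping import ClusterParams, embed_and_cluster


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SyntheticConfig(
        n_samples=120, n_genes=60, de_genes_per_cluster=10, de_log2fc=2.0, seed=3
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clustered_cohort():
    """600-sample, 3-cluster cohort embedded and clustered once per session."""
    cfg = SyntheticConfig(n_samples=600, seed=7)
    expr, clinical, truth = generate_cohort(cfg)
    folded = normalize_fold_from_mean(expr)
    params = ClusterParams(min_cluster_size=50, min_samples=15, seed=7)
    model = embed_and_cluster(folded, params)
    return folded, clinical, truth, model


def survival_training_config() -> SyntheticConfig:
    """Study conditions for model-recovery checks: 500 samples, 150 candidate
    genes, 10 planted prognostic genes with strong hazard effects (log HR of
    2 per unit log2 expression, i.e. hazard ratio 4 per doubling — chosen so
    the true predictor's own discrimination, AUC ~0.95, leaves headroom for
    estimation loss)."""
    base = SyntheticConfig(n_samples=500, n_genes=150, de_genes_per_cluster=20, seed=11)
    return SyntheticConfig(
        n_samples=500,
        n_genes=150,
        de_genes_per_cluster=20,
        prognostic_genes=default_prognostic_genes(base, n=10, beta=2.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def trained_survival_model():
    from nbgf.survival import TrainConfig, train_two_round

    cfg = survival_training_config()
    expr, clinical, truth = generate_cohort(cfg)
    folded = normalize_fold_from_mean(expr)
    genes = folded.gene_ids
    model = train_two_round(folded, clinical, genes, TrainConfig(seed=11))
    return cfg, folded, clinical, truth, model


def gpscore_cohort_config(seed: int) -> SyntheticConfig:
    """Study conditions for prognostic-set recovery: 300 samples, 200 genes,
    a 20-gene poor-prognosis program and a 20-gene protective program, each
    co-regulated (module loading 0.6) with per-gene log HR +/-0.1."""
    base = SyntheticConfig(n_samples=300, n_genes=200, de_genes_per_cluster=0)
    genes = base.gene_names()
    prog = tuple(
        [(g, 0.1) for g in genes[:20]] + [(g, -0.1) for g in genes[20:40]]
    )
    return SyntheticConfig(
        n_samples=300,
        n_genes=200,
        de_genes_per_cluster=0,
        prognostic_genes=prog,
        module_loading=0.6,
        seed=seed,
    )


def pathway_cohort_config(shift: float = 1.0, seed: int = 5) -> SyntheticConfig:
    """60-sample two-group cohort with one planted pathway shift among nulls."""
    base = SyntheticConfig(n_samples=60, n_genes=120, de_genes_per_cluster=0)
    genes = base.gene_names()
    specs = [
        PathwaySpec(
            "PLANTED_GF",
            {**{g: 1.0 for g in genes[:6]}, **{g: -1.0 for g in genes[6:10]}},
            shift_log2=shift,
        )
    ]
    for k in range(8):
        members = genes[10 + 10 * k : 20 + 10 * k]
        specs.append(
            PathwaySpec(
                f"NULL_{k}",
                {g: (1.0 if i % 2 == 0 else -0.5) for i, g in enumerate(members)},
                shift_log2=0.0,
            )
        )
    return SyntheticConfig(
        n_samples=60,
        n_genes=120,
        de_genes_per_cluster=0,
        pathway_specs=tuple(specs),
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_pathway_cohort():
    return generate_pathway_db(pathway_cohort_config())


def toy_expression(values: np.ndarray, norm_state: str = "raw") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[0])]
    genes = [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=samples, columns=genes), norm_state=norm_state
    )


def toy_clinical(times, events, index=None, **overrides) -> ClinicalTable:
    n = len(times)
    index = index if index is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "os_time": np.asarray(times, dtype=float),
            "os_event": np.asarray(events, dtype=bool),
            "mycn": overrides.get("mycn", ["non_amplified"] * n),
            "inss_stage": overrides.get("inss_stage", ["4"] * n),
            "metastasis": overrides.get("metastasis", ["no"] * n),
            "response": overrides.get("response", ["good"] * n),
        },
        index=index,
    )
    return ClinicalTable(df)
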