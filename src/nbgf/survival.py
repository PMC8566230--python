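"""MYCN-stratified survival-probability model on growth-factor-gene expression.

The model is an elastic-net-penalized logistic regression fitted separately
for MYCN-amplified and MYCN-non-amplified tumors on fold-from-mean
normalized expression:

    p(z) = 1 / (1 + exp(-z)),    z = y0 + sum_i w_i * exp_i

Training runs in two rounds.  Round 1 fits all candidate genes, with the
penalty strength alpha and the L1 mixing ratio chosen by 5-fold
cross-validation on a 70% training split.  Round 2 refits on the top
fraction of genes by absolute weight, scanning keep fractions from 10% to
50% and choosing the one with the best F1 on the held-out 30% split.  The
outcome label is survival past a landmark time (default 5 years): samples
censored before the landmark carry no label and are excluded from fitting.
Predicted probabilities are binned into the five conventional risk groups
(>95%, 85-95%, 60-80%, 40-60%, <40% survival).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import f1_score, precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .matrix import ClinicalTable, ExpressionMatrix

RISK_BINS = (
    (0.95, ">95%"),
    (0.85, "85-95%"),
    (0.60, "60-80%"),
    (0.40, "40-60%"),
    (0.0, "<40%"),
)

STRATA = ("amplified", "non_amplified")


@dataclass(frozen=True)
class TrainConfig:
    landmark_days: float = 1825.0
    test_fraction: float = 0.3
    cv_folds: int = 5
    alphas: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))
    l1_ratios: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
    keep_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    seed: int = 0


@dataclass(frozen=True)
class StratumModel:
    intercept: float
    weights: Mapping[str, float]
    alpha: float
    l1_ratio: float

    def linear_predictor(self, expr: pd.DataFrame) -> np.ndarray:
        genes = list(self.weights)
        w = np.array([self.weights[g] for g in genes])
        return self.intercept + expr[genes].to_numpy(dtype=float) @ w


@dataclass(frozen=True)
class SurvivalModelParams:
    """Final two-stratum model plus training metadata."""

    strata: Mapping[str, StratumModel]
    panel: tuple[str, ...]
    config: TrainConfig

    def to_json(self, path) -> None:
        payload = {
            "landmark_days": self.config.landmark_days,
            "normalization": "fold_from_mean",
            "strata": {
                name: {
                    "intercept": sm.intercept,
                    "weights": dict(sm.weights),
                    "alpha": sm.alpha,
                    "l1_ratio": sm.l1_ratio,
                }
                for name, sm in self.strata.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SurvivalModelParams":
        payload = json.loads(Path(path).read_text())
        strata = {
            name: StratumModel(
                intercept=d["intercept"],
                weights=d["weights"],
                alpha=d["alpha"],
                l1_ratio=d["l1_ratio"],
            )
            for name, d in payload["strata"].items()
        }
        panel = tuple(
            dict.fromkeys(g for d in payload["strata"].values() for g in d["weights"])
        )
        return cls(
            strata=strata,
            panel=panel,
            config=TrainConfig(landmark_days=payload["landmark_days"]),
        )


def select_model_genes(degs_by_stratum: Mapping[str, Sequence[str]]) -> list[str]:
    """Union of stratum-specific cluster marker genes, order-stable."""
    union = list(dict.fromkeys(g for genes in degs_by_stratum.values() for g in genes))
    if not union:
        raise ValueError("empty gene union")
    return union


def derive_labels(clinical: ClinicalTable, landmark_days: float) -> pd.Series:
    """Binary outcome: 1 = survived past the landmark, 0 = died before it.

    Samples censored before the landmark are dropped (label unknowable).
    """
    df = clinical.df
    died_early = df["os_event"].astype(bool) & (df["os_time"] < landmark_days)
    survived = df["os_time"] >= landmark_days
    labels = pd.Series(np.nan, index=df.index)
    labels[died_early] = 0.0
    labels[survived] = 1.0
    return labels.dropna().astype(int)


def keep_count(fraction: float, n_genes: int) -> int:
    """Panel size for a keep fraction: floor(fraction * n), at least 1."""
    return max(1, min(n_genes, math.floor(fraction * n_genes)))


def _fit_enet(x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> LogisticRegressionCV:
    model = LogisticRegressionCV(
        Cs=[1.0 / a for a in cfg.alphas],
        l1_ratios=list(cfg.l1_ratios),
        penalty="elasticnet",
        solver="saga",
        cv=StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed),
        scoring="f1",
        max_iter=5000,
        tol=1e-3,
        random_state=cfg.seed,
        n_jobs=1,
        use_legacy_attributes=True,
    )
    model.fit(x, y)
    return model


def _train_stratum(
    expr: pd.DataFrame, y: pd.Series, genes: Sequence[str], cfg: TrainConfig
) -> StratumModel:
    if len(y) < 20:
        raise ValueError(f"stratum has only {len(y)} usable samples (need >= 20)")
    if y.nunique() < 2:
        raise ValueError("stratum has a single outcome class")
    x = expr.loc[y.index, genes].to_numpy(dtype=float)
    yv = y.to_numpy()
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, yv, test_size=cfg.test_fraction, stratify=yv, random_state=cfg.seed
    )
    # round 1: all candidate genes
    m1 = _fit_enet(x_tr, y_tr, cfg)
    coefs = m1.coef_.ravel()
    order = np.argsort(-np.abs(coefs), kind="stable")

    best = None
    for frac in cfg.keep_fractions:
        k = keep_count(frac, len(genes))
        idx = order[:k]
        m2 = _fit_enet(x_tr[:, idx], y_tr, cfg)
        f1 = f1_score(y_te, m2.predict(x_te[:, idx]))
        # ties favor the smaller panel (fractions scanned in increasing order)
        if best is None or f1 > best[0]:
            best = (f1, idx, m2)
    _, idx, m2 = best
    kept = [genes[i] for i in sorted(idx)]
    weights = {
        genes[i]: float(w) for i, w in zip(idx, m2.coef_.ravel())
    }
    weights = {g: weights[g] for g in kept}
    return StratumModel(
        intercept=float(m2.intercept_[0]),
        weights=weights,
        alpha=float(1.0 / m2.C_[0]),
        l1_ratio=float(m2.l1_ratio_[0]),
    )


def train_two_round(
    m: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: Sequence[str],
    cfg: TrainConfig | None = None,
) -> SurvivalModelParams:
    """Fit the two-round elastic-net logistic model per MYCN stratum."""
    cfg = cfg or TrainConfig()
    if m.norm_state != "fold_from_mean":
        raise ValueError("expression must be fold_from_mean normalized")
    missing = [g for g in genes if g not in m.data.columns]
    if missing:
        raise KeyError(f"candidate genes missing from expression: {missing[:5]}")
    clinical = clinical.aligned_to(m)
    labels = derive_labels(clinical, cfg.landmark_days)
    strata: dict[str, StratumModel] = {}
    for stratum in STRATA:
        in_stratum = clinical.df.index[clinical.df["mycn"] == stratum]
        y = labels[labels.index.intersection(in_stratum)]
        strata[stratum] = _train_stratum(m.data, y, list(genes), cfg)
    panel = tuple(dict.fromkeys(g for sm in strata.values() for g in sm.weights))
    return SurvivalModelParams(strata=strata, panel=panel, config=cfg)


def predict_survival(
    model: SurvivalModelParams, m: ExpressionMatrix, mycn: pd.Series
) -> pd.Series:
    """Per-sample survival probability p = sigmoid(y0 + w . exp).

    Samples with unknown MYCN status use the non-amplified parameters.
    """
    if m.norm_state != "fold_from_mean":
        raise ValueError("expression must be fold_from_mean normalized")
    missing = [g for g in model.panel if g not in m.data.columns]
    if missing:
        raise KeyError(f"panel genes missing from expression: {missing}")
    mycn = mycn.loc[m.data.index]
    out = pd.Series(np.nan, index=m.data.index, name="p_survival")
    for stratum in STRATA:
        use = mycn == stratum
        if stratum == "non_amplified":
            use = use | (mycn == "unknown")
        if use.any():
            z = model.strata[stratum].linear_predictor(m.data.loc[use])
            out[use] = expit(z)
    return out


def stratify_risk(p: float) -> str:
    """Map a survival probability to its risk-group label.

    Bins are contiguous: [0, 0.40) "<40%", [0.40, 0.60) "40-60%",
    [0.60, 0.85) "60-80%", [0.85, 0.95) "85-95%", [0.95, 1] ">95%".
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    for lo, label in RISK_BINS:
        if p >= lo:
            return label
    return RISK_BINS[-1][1]


def evaluate_scores(y_true, p) -> dict:
    """ROC AUC, precision-recall curve, and F1 at the 0.5 threshold."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    precision, recall, thresholds = precision_recall_curve(y, p)
    return {
        "roc_auc": float(roc_auc_score(y, p)),
        "f1": float(f1_score(y, (p >= 0.5).astype(int))),
        "pr_curve": pd.DataFrame(
            {"precision": precision[:-1], "recall": recall[:-1], "threshold": thresholds}
        ),
    }


def evaluate(
    model: SurvivalModelParams, m: ExpressionMatrix, clinical: ClinicalTable
) -> dict:
    clinical = clinical.aligned_to(m)
    labels = derive_labels(clinical, model.config.landmark_days)
    p = predict_survival(model, m, clinical.df["mycn"])[labels.index]
    return evaluate_scores(labels.to_numpy(), p.to_numpy())
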