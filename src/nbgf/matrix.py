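"""Expression matrices, clinical tables, and shared normalisation utilities.

The central container is :class:`ExpressionMatrix`: a samples x genes table of
non-negative, linear-scale values (microarray intensities or TPM-like
quantities) together with a normalisation-state flag.  Two normalisations are
supported:

``fold_from_mean``
    每 gene is divided by its mean across all samples of its dataset, so a
    value of 2.0 means "twice the cohort-average expression".  This is the
    input expected by the subtype clustering and the survival model.

``quantile``
    every sample is forced onto the same empirical distribution (rank ->
    mean-of-sorted-values), the usual preprocessing for case-to-normal
    pathway scoring on array data.

Clinical annotations (overall survival, MYCN status, INSS stage, metastasis,
therapy response) live in :class:`ClinicalTable`, keyed by sample id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NORM_STATES = ("raw", "fold_from_mean", "quantile")

MYCN_VALUES = ("amplified", "non_amplified", "unknown")
INSS_STAGES = ("1", "2", "3", "4", "4S", "unknown")
METASTASIS_VALUES = ("yes", "no", "unknown")
RESPONSE_VALUES = ("good", "poor", "unknown")

_FOLD_MEAN_TOL = 1e-9


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes expression values on a linear scale.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with gene ids as columns.  Values must
        be finite and non-negative.
    norm_state
        One of ``raw``, ``fold_from_mean`` or ``quantile``.
    dataset_ids
        Optional per-sample dataset label.  Required when samples from more
        than one source are merged; normalisation is then applied per dataset.
    """

    data: pd.DataFrame
    norm_state: str = "raw"
    dataset_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.norm_state not in NORM_STATES:
            raise ValueError(f"unknown norm_state {self.norm_state!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.dataset_ids is not None and not self.dataset_ids.index.equals(
            self.data.index
        ):
            raise ValueError("dataset_ids must be indexed by the sample ids")
        if self.norm_state == "fold_from_mean":
            for _, block in self._iter_dataset_blocks():
                means = block.mean(axis=0).to_numpy()
                if np.abs(means - 1.0).max() > 1e-6:
                    raise ValueError(
                        "fold_from_mean state requires per-gene means of 1"
                    )

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def _iter_dataset_blocks(self):
        if self.dataset_ids is None:
            yield None, self.data
        else:
            for name in pd.unique(self.dataset_ids):
                yield name, self.data.loc[self.dataset_ids == name]

    # -- I/O (TSV, genes as rows, samples as columns) --------------------

    @classmethod
    def read_tsv(cls, path, norm_state: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=df.T, norm_state=norm_state)

    def to_tsv(self, path) -> None:
        out = self.data.T
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def normalize_fold_from_mean(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene by its mean expression across the dataset's samples.

    When ``dataset_ids`` are present the mean is taken within each dataset, so
    merged cohorts from different platforms become comparable.  A gene whose
    mean is zero in any dataset cannot be normalised and raises an error
    naming the gene.
    """
    if m.norm_state != "raw":
        raise ValueError(f"expected raw matrix, got norm_state={m.norm_state!r}")
    pieces = []
    for name, block in m._iter_dataset_blocks():
        means = block.mean(axis=0)
        bad = means.index[means.to_numpy() <= 0]
        if len(bad):
            where = f" in dataset {name!r}" if name is not None else ""
            raise ValueError(
                f"gene(s) with zero mean expression{where}: {', '.join(map(str, bad[:5]))}"
            )
        pieces.append(block / means)
    data = pd.concat(pieces).loc[m.data.index]
    return replace(m, data=data, norm_state="fold_from_mean")


def _quantile_map_sample(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map one sample's values onto `target` (sorted); ties get the average
    of the tied target positions, preserving the sample's total signal."""
    order = np.argsort(x, kind="mergesort")
    out = np.empty_like(target)
    sorted_x = x[order]
    # boundaries of runs of equal values
    starts = np.flatnonzero(np.r_[True, sorted_x[1:] != sorted_x[:-1]])
    ends = np.r_[starts[1:], len(x)]
    for s, e in zip(starts, ends):
        out[order[s:e]] = target[s:e].mean()
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common rank -> mean-of-sorted distribution."""
    if m.norm_state != "raw":
        raise ValueError(f"expected raw matrix, got norm_state={m.norm_state!r}")
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = m.data.to_numpy(dtype=float)
    target = np.sort(values, axis=1).mean(axis=0)
    normed = np.vstack([_quantile_map_sample(row, target) for row in values])
    data = pd.DataFrame(normed, index=m.data.index, columns=m.data.columns)
    return replace(m, data=data, norm_state="quantile")


def merge_datasets(datasets: Mapping[str, ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate per-dataset matrices on the genes present in *all* of them.

    Genes missing from any dataset are dropped (intersection semantics) and
    the dropped count is logged.  Normalisation states must agree.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    mats = list(datasets.values())
    states = {m.norm_state for m in mats}
    if len(states) > 1:
        raise ValueError(f"mixed normalisation states: {sorted(states)}")
    common = list(mats[0].data.columns)
    universe: set[str] = set()
    for m in mats:
        universe |= set(m.data.columns)
        present = set(m.data.columns)
        common = [g for g in common if g in present]
    dropped = len(universe) - len(common)
    if dropped:
        logger.info(
            "merge_datasets: keeping %d genes present in all %d datasets "
            "(%d dropped)", len(common), len(mats), dropped,
        )
    if not common:
        raise ValueError("datasets share no genes")
    data = pd.concat([m.data[common] for m in mats])
    if data.index.has_duplicates:
        raise ValueError("duplicate sample ids across datasets")
    ids = pd.concat(
        [pd.Series(name, index=m.data.index) for name, m in datasets.items()]
    )
    return ExpressionMatrix(data=data, norm_state=mats[0].norm_state, dataset_ids=ids)


def adjust_pvalues(pvalues: Iterable[float], method: str = "bh_fdr") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg q-values or Bonferroni."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh_fdr":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotations.

    ``df`` is indexed by sample id and carries: ``os_time`` (days, >= 0),
    ``os_event`` (bool, death observed), ``mycn`` (amplified / non_amplified /
    unknown), ``inss_stage`` (1, 2, 3, 4, 4S, unknown), ``metastasis``
    (yes / no / unknown) and ``response`` (good / poor / unknown; relapse,
    partial and no response all count as poor).
    """

    df: pd.DataFrame

    REQUIRED = ("os_time", "os_event", "mycn", "inss_stage", "metastasis", "response")

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        t = df["os_time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("os_time must be finite and >= 0")
        for col, allowed in (
            ("mycn", MYCN_VALUES),
            ("inss_stage", INSS_STAGES),
            ("metastasis", METASTASIS_VALUES),
            ("response", RESPONSE_VALUES),
        ):
            bad = set(df[col].astype(str)) - set(allowed)
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def aligned_to(self, m: ExpressionMatrix) -> "ClinicalTable":
        """Reorder to the matrix's samples; every sample must be annotated."""
        missing = [s for s in m.sample_ids if s not in self.df.index]
        if missing:
            raise ValueError(f"samples without clinical rows: {missing[:5]}")
        return ClinicalTable(self.df.loc[m.sample_ids])

    @classmethod
    def read_csv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, index_col=0)
        df["os_event"] = df["os_event"].astype(bool)
        for col in ("mycn", "inss_stage", "metastasis", "response"):
            df[col] = df[col].astype(str)
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.index.name = "sample_id"
        out.to_csv(path)
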