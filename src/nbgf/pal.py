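"""Pathway activation level (PAL) scoring.

A pathway is a set of member genes, each annotated with an activator /
repressor role ARR in {-1, -0.5, 0, 0.5, 1} (negative: the gene product
represses signal flow; positive: it activates it; 0: ambivalent or neutral).
For a case sample, each gene's case-to-normal ratio (CNR) is its expression
divided by the mean expression in a control ("norm") group.  The pathway
activation level is the role-weighted mean of log2 CNR:

    PAL = sum_n ARR_n * log2(CNR_n) / sum_n |ARR_n|

so PAL > 0 means the pathway's signalling output is up in the case sample
relative to the norms.  Differential activation between phenotype groups
(poor vs good therapy response, metastatic vs localized) is assessed with an
unpaired t-test on per-sample PALs, with Benjamini-Hochberg correction over
pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix, adjust_pvalues

logger = logging.getLogger(__name__)

ARR_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: pseudocount guarding CNR against zero expression values
CNR_EPS = 1e-6


@dataclass(frozen=True)
class PathwayDef:
    """Named pathway with activator/repressor roles per member gene.

    The membership index NII is implicit: 1 for listed members, 0 for all
    other genes.  A pathway whose members are all ambivalent (ARR = 0)
    carries no directional information; it is constructed with a warning and
    ``usable`` is False.
    """

    name: str
    members: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        bad = {g: a for g, a in self.members.items() if a not in ARR_VALUES}
        if bad:
            raise ValueError(f"pathway {self.name!r}: invalid ARR values {bad}")
        if not self.usable:
            warnings.warn(
                f"pathway {self.name!r} has only ARR=0 members; unusable for PAL",
                stacklevel=2,
            )

    @property
    def usable(self) -> bool:
        return any(a != 0 for a in self.members.values())

    @property
    def genes(self) -> list[str]:
        return list(self.members)


def read_pathways(path) -> list[PathwayDef]:
    """Read the 3-column tab-delimited pathway dialect: pathway, gene, ARR."""
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = [c.lower() for c in df.columns]
    out = []
    for name, grp in df.groupby("pathway", sort=False):
        members = dict(zip(grp["gene"].astype(str), grp["arr"].astype(float)))
        if len(members) != len(grp):
            raise ValueError(f"pathway {name!r}: duplicate member genes")
        out.append(PathwayDef(str(name), members))
    return out


def write_pathways(pathways: Sequence[PathwayDef], path) -> None:
    rows = [
        {"pathway": pw.name, "gene": g, "arr": a}
        for pw in pathways
        for g, a in pw.members.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_cnr(case_expr: pd.Series, control_expr: pd.DataFrame) -> pd.Series:
    """Case-to-normal ratio: case value over control-group mean, per gene."""
    if control_expr.shape[0] < 3:
        raise ValueError("control group needs >= 3 samples")
    genes = case_expr.index
    control_mean = control_expr[genes].mean(axis=0)
    cnr = (case_expr + CNR_EPS) / (control_mean + CNR_EPS)
    if (cnr <= 0).any() or not np.isfinite(cnr).all():
        raise ValueError("CNR must be positive and finite")
    return cnr


def compute_pal(cnr: pd.Series, pathway: PathwayDef) -> float:
    """Role-weighted mean of log2 CNR over the pathway's members."""
    missing = [g for g in pathway.members if g not in cnr.index]
    if missing:
        raise KeyError(f"pathway {pathway.name!r}: genes missing from CNR: {missing[:5]}")
    arr = np.array([pathway.members[g] for g in pathway.members])
    denom = np.abs(arr).sum()
    if denom == 0:
        raise ValueError(f"ambivalent-only pathway {pathway.name!r}")
    logs = np.log2(cnr[list(pathway.members)].to_numpy(dtype=float))
    return float(np.sum(arr * logs) / denom)


@dataclass(frozen=True)
class PALResult:
    pathway: str
    pal_case: float
    pal_ref: float
    pal_diff: float
    t: float
    p: float
    q: float = np.nan


def differential_pal(
    m: ExpressionMatrix,
    case_mask: Sequence[bool] | pd.Series,
    pathways: Sequence[PathwayDef],
    prefilter_p: float = 0.05,
) -> pd.DataFrame:
    """Contrast pathway activation between a case and a reference group.

    Genes are prefiltered by a two-sided t-test between the groups at
    ``prefilter_p``; PAL is then computed for every sample against the
    reference-group mean (using the surviving member genes) and the two
    groups of per-sample PALs compared with an unpaired t-test, BH-corrected
    over pathways.  Returns a DataFrame with one row per scored pathway.
    """
    mask = np.asarray(case_mask, dtype=bool)
    if mask.size != m.n_samples:
        raise ValueError("case_mask length must match sample count")
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    case = m.data.loc[mask]
    ref = m.data.loc[~mask]

    tstat, pvals = sps.ttest_ind(case.to_numpy(), ref.to_numpy(), axis=0)
    keep = pd.Index(m.gene_ids)[np.nan_to_num(pvals, nan=1.0) < prefilter_p]
    if keep.empty:
        warnings.warn("no genes pass the differential-expression prefilter")
        return pd.DataFrame(
            columns=["pathway", "pal_case", "pal_ref", "pal_diff", "t", "p", "q"]
        )
    keep_set = set(keep)

    control_mean = ref.mean(axis=0)
    rows = []
    for pw in pathways:
        genes = [g for g in pw.members if g in keep_set]
        if not genes:
            continue
        arr = np.array([pw.members[g] for g in genes])
        denom = np.abs(arr).sum()
        if denom == 0:
            continue
        logs = np.log2(
            (m.data[genes].to_numpy(dtype=float) + CNR_EPS)
            / (control_mean[genes].to_numpy(dtype=float) + CNR_EPS)
        )
        pal = logs @ arr / denom
        pal_case, pal_ref = pal[mask], pal[~mask]
        t, p = sps.ttest_ind(pal_case, pal_ref)
        rows.append(
            {
                "pathway": pw.name,
                "pal_case": float(pal_case.mean()),
                "pal_ref": float(pal_ref.mean()),
                "pal_diff": float(pal_case.mean() - pal_ref.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = adjust_pvalues(out["p"], "bh_fdr")
    else:
        warnings.warn("no pathway retained any prefiltered genes")
        out = pd.DataFrame(
            columns=["pathway", "pal_case", "pal_ref", "pal_diff", "t", "p", "q"]
        )
    return out


def association_table(
    contrast_response: pd.DataFrame, contrast_metastasis: pd.DataFrame
) -> pd.DataFrame:
    """Pair each pathway's PAL in two contrasts for 2D scatter rendering.

    Rows are sorted by joint magnitude sqrt(x^2 + y^2), descending, so the
    pathways most associated with either phenotype come first.
    """
    a = contrast_response.set_index("pathway")["pal_diff"]
    b = contrast_metastasis.set_index("pathway")["pal_diff"]
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("contrasts share no pathways")
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(f"pathways present in only one contrast: {list(missing)[:5]}")
    out = pd.DataFrame(
        {"pal_response": a[common], "pal_metastasis": b[common]}, index=common
    )
    out["magnitude"] = np.hypot(out["pal_response"], out["pal_metastasis"])
    return out.sort_values("magnitude", ascending=False)
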