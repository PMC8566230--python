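"""Dose-response analysis: viability normalisation, 4PL IC50 fits, Bliss
synergy, and growth-factor protection statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stats import friedman_test


@dataclass(frozen=True)
class DoseResponseGrid:
    """Viability fractions on a drug A x drug B concentration grid.

    Both concentration axes must start at 0 (single-agent rows/column and the
    untreated control at (0, 0)) and increase strictly.
    """

    conc_a: np.ndarray
    conc_b: np.ndarray
    viability: np.ndarray  # shape (len(conc_a), len(conc_b))

    def __post_init__(self) -> None:
        ca = np.asarray(self.conc_a, dtype=float)
        cb = np.asarray(self.conc_b, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if ca[0] != 0 or cb[0] != 0:
            raise ValueError("concentration axes must include 0 (control)")
        if (np.diff(ca) <= 0).any() or (np.diff(cb) <= 0).any():
            raise ValueError("concentrations must increase strictly")
        if v.shape != (ca.size, cb.size):
            raise ValueError("viability shape must match the concentration axes")
        if not np.isfinite(v).all():
            raise ValueError("viability must be finite")

    @classmethod
    def read_csv(cls, path) -> "DoseResponseGrid":
        df = pd.read_csv(path, index_col=0)
        return cls(
            conc_a=df.index.to_numpy(dtype=float),
            conc_b=df.columns.to_numpy(dtype=float),
            viability=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.viability, index=self.conc_a, columns=self.conc_b)
        df.index.name = "conc_a"
        df.to_csv(path)


def normalize_viability(raw_signals, blank_signals, control_signals) -> np.ndarray:
    """Blank-subtracted viability fractions relative to mock (DMSO) treatment.

    Values are clipped to [0, 1.5]; the upper slack tolerates growth
    stimulation above the control without breaking inhibition arithmetic.
    """
    raw = np.asarray(raw_signals, dtype=float)
    blank = float(np.mean(blank_signals))
    control = float(np.mean(control_signals))
    if control <= blank:
        raise ValueError("control signal must exceed blank signal")
    frac = (raw - blank) / (control - blank)
    if (frac < 0).any():
        warnings.warn("signals below blank clipped to 0 viability")
    return np.clip(frac, 0.0, 1.5)


def four_pl(conc, top, bottom, ic50, hill):
    """Four-parameter logistic viability curve, v(0) = top."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, conc / ic50, 0.0)
        return np.where(
            conc > 0, bottom + (top - bottom) / (1.0 + ratio**hill), top
        )


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    residual_rms: float
    n_points: int

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.top, self.bottom, self.ic50, self.hill)


def fit_ic50(conc, viability, robust: bool = True) -> FourPLFit:
    """Fit a 4PL curve; robust soft-L1 loss damps gross outliers."""
    c = np.asarray(conc, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.size < 5:
        raise ValueError("need >= 5 concentrations for a 4PL fit")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive for fitting")
    # parametrise IC50 on the log scale to keep it positive
    pos = c > 0

    def resid(theta):
        top, bottom, log_ic50, hill = theta
        return four_pl(c[pos], top, bottom, np.exp(log_ic50), hill) - v[pos]

    x0 = np.array([v.max(), v.min(), np.log(np.median(c[pos])), 1.0])
    sol = least_squares(
        resid,
        x0,
        loss="soft_l1" if robust else "linear",
        f_scale=0.03,  # residuals beyond ~3% viability count roughly linearly
        bounds=([0, 0, np.log(c[pos].min() / 100), 0.1],
                [2.0, 1.5, np.log(c[pos].max() * 100), 10.0]),
    )
    if not sol.success:
        raise RuntimeError(f"4PL fit did not converge: {sol.message}")
    top, bottom, log_ic50, hill = sol.x
    if top < bottom:
        top, bottom = bottom, top
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(np.exp(log_ic50)),
        hill=float(hill),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        n_points=int(c.size),
    )


def bliss_synergy(grid: DoseResponseGrid) -> tuple[np.ndarray, float]:
    """Excess inhibition over Bliss independence, and the mean score x 100.

    For fractional inhibitions f_a and f_b of the single agents, independence
    predicts f_ab = f_a + f_b - f_a * f_b; synergy is the observed excess
    over that expectation, averaged over the non-trivial dose combinations
    and reported on the conventional x100 scale.
    """
    v = np.asarray(grid.viability, dtype=float)
    f = 1.0 - v
    f_a = f[:, 0]  # drug A alone (column where conc_b == 0)
    f_b = f[0, :]  # drug B alone
    expected = f_a[:, None] + f_b[None, :] - f_a[:, None] * f_b[None, :]
    excess = f - expected
    score = 100.0 * float(excess[1:, 1:].mean())
    return excess, score


def gf_protection(
    viab_drug_gf, viab_drug, viab_dmso_gf, viab_dmso
) -> tuple[pd.DataFrame, float, float]:
    """Growth-factor protection across a cell-line panel.

    Inputs are matched per-cell-line viability measurements (arrays of shape
    (n_lines, n_replicates) or (n_lines,)): drug plus growth factor, drug
    alone, DMSO plus growth factor, DMSO alone.  For each line the fold
    change viab(drug+GF)/viab(drug) quantifies protection; it is compared to
    the matching DMSO fold with a Friedman test blocked by cell line, which
    separates protection under drug pressure from plain growth stimulation.
    """
    def line_means(x):
        x = np.asarray(x, dtype=float)
        return x if x.ndim == 1 else x.mean(axis=1)

    a = line_means(viab_drug_gf)
    b = line_means(viab_drug)
    c = line_means(viab_dmso_gf)
    d = line_means(viab_dmso)
    if not (a.size == b.size == c.size == d.size):
        raise ValueError("all four arms must cover the same cell lines")
    if a.size < 3:
        raise ValueError("need >= 3 cell lines")
    if (b <= 0).any() or (d <= 0).any():
        raise ValueError("missing or zero drug/DMSO reference arm")
    folds = pd.DataFrame({"fold_drug": a / b, "fold_dmso": c / d})
    stat, p = friedman_test(folds.to_numpy())
    return folds, float(stat), float(p)
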