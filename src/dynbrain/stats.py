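"""Group labeling, nonparametric group comparisons, and partial correlations.

MHE labeling follows the psychometric-norm convention: ordinary least
squares models of NCT-A and DST on age and education are fitted in the
healthy-control group; a patient is labeled MHE when the observed score
deviates from the prediction by more than 2 residual standard deviations
in the impaired direction (DST below prediction, NCT-A above prediction)
on *either* test.

Group comparisons use the Kruskal-Wallis H test (tie-corrected) per unit
(network or node), with pairwise two-sided Mann-Whitney post hoc tests run
only where the omnibus p < 0.05, and Benjamini-Hochberg FDR adjustment
across the units of one analysis family.

Partial correlation between a metric and a clinical score given covariates
(age, sex, education, mean FD) is the Pearson correlation of the OLS
residuals of both variables on the covariate design (intercept included),
with the p-value from the t transform at ``df = n - n_covariates - 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas_io import SubjectRecord

logger = logging.getLogger("dynbrain")

IMPAIRED_DIRECTION = {"nct_a": +1, "dst": -1}  # sign of (observed - predicted) when impaired


# ---------------------------------------------------------------------------
# MHE labeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelModel:
    """HC-normed linear models of the two cognitive tests.

    ``coef[test]`` holds (intercept, age, education) OLS coefficients;
    ``residual_sd[test]`` the HC residual standard deviation.
    """

    coef: Mapping[str, np.ndarray]
    residual_sd: Mapping[str, float]
    threshold_sd: float = 2.0

    def predict(self, test: str, age: float, education: float) -> float:
        b = self.coef[test]
        return float(b[0] + b[1] * age + b[2] * education)


def fit_label_model(hc_subjects: Sequence[SubjectRecord]) -> LabelModel:
    """Fit the NCT-A and DST norm models on healthy controls only."""
    hc = [s for s in hc_subjects if s.group == "HC"]
    if len(hc) < 3:
        raise ValueError("need at least 3 HC subjects to fit the norm models")
    X = np.column_stack([
        np.ones(len(hc)),
        [s.age for s in hc],
        [s.education for s in hc],
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (age/education collinear)")
    coef: dict[str, np.ndarray] = {}
    residual_sd: dict[str, float] = {}
    for test in ("nct_a", "dst"):
        y = np.array([getattr(s, test) for s in hc], dtype=float)
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ b
        sd = float(np.sqrt(resid @ resid / (len(hc) - X.shape[1])))
        if sd <= 0:
            raise ValueError(f"zero residual SD for {test}; norms degenerate")
        coef[test] = b
        residual_sd[test] = sd
    return LabelModel(coef=coef, residual_sd=residual_sd)


def apply_labels(model: LabelModel, patients: Sequence[SubjectRecord]) -> list[str]:
    """Label each patient MHE/noHE by the 2-SD residual rule (either test)."""
    labels = []
    for s in patients:
        flagged = False
        for test, sign in IMPAIRED_DIRECTION.items():
            deviation = getattr(s, test) - model.predict(test, s.age, s.education)
            if sign * deviation > model.threshold_sd * model.residual_sd[test]:
                flagged = True
        labels.append("MHE" if flagged else "noHE")
    return labels


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

PAIRS = (("MHE", "noHE"), ("MHE", "HC"), ("noHE", "HC"))


def compare_groups(
    values: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis omnibus + Mann-Whitney post hoc per unit, BH-FDR across units.

    ``values`` is subjects x units; ``labels`` the per-subject group.  Post
    hoc pairs are tested only where the omnibus p < ``alpha``; BH adjustment
    runs across all units for the omnibus p, and across the post-hoc-tested
    units within each pair.
    """
    labels = np.asarray(labels)
    groups = [g for g in ("MHE", "noHE", "HC") if (labels == g).sum() > 0]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    rows = []
    for unit in values.columns:
        samples = [values.loc[labels == g, unit].to_numpy() for g in groups]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
        row: dict[str, object] = {"unit": unit, "H": float(h), "p": float(p)}
        for g, sample in zip(groups, samples):
            row[f"median_{g}"] = float(np.median(sample))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("unit")
    table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    # post hoc only where the omnibus is nominally significant
    tested = table.index[table["p"] < alpha]
    for a, b in PAIRS:
        if a not in groups or b not in groups:
            continue
        col, col_adj = f"p_{a}_vs_{b}", f"p_{a}_vs_{b}_fdr"
        table[col] = np.nan
        table[col_adj] = np.nan
        pvals = []
        for unit in tested:
            ua = values.loc[labels == a, unit].to_numpy()
            ub = values.loc[labels == b, unit].to_numpy()
            if np.all(np.concatenate([ua, ub]) == ua[0]):
                pvals.append(1.0)
            else:
                pvals.append(float(sps.mannwhitneyu(ua, ub, alternative="two-sided").pvalue))
        if len(pvals):
            table.loc[tested, col] = pvals
            table.loc[tested, col_adj] = multipletests(pvals, method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p: float
    n: int
    dof: int
    covariates: tuple[str, ...] = ()


def partial_corr(
    metric: np.ndarray,
    score: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
) -> PartialCorrResult:
    """Residual-Pearson partial correlation with a t-based p-value.

    With no covariates this reduces to the plain Pearson correlation.
    Constant residuals leave r undefined (returned as NaN).
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(score, dtype=float)
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
        k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} subjects for {k} covariates")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        logger.warning("constant residuals; partial correlation undefined")
        return PartialCorrResult(np.nan, np.nan, n, n - k - 2, tuple(covariate_names))
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    r_clipped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clipped * np.sqrt(dof / (1.0 - r_clipped**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(r, p, n, dof, tuple(covariate_names))
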