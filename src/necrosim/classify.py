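"""ROC analysis of the growth exponent as a necrosis-vs-recurrence classifier.

Simulated lesions fall into three response groups: pure relapse (R, no
healthy-tissue damage), relapse with inflammation (R&I, damage present but a
substantial tumor remnant) and inflammation (I, damage present and at most
10% maximal tumor survival — the radiation-necrosis analogue).  Inflammatory
lesions grow superlinearly (beta > 1), relapses sublinearly, so the median
growth exponent beta-hat separates progression (R, R&I) from inflammation
(I).  This module quantifies that separation: rank-based AUC, the
Youden-optimal decision threshold beta*, the sensitivity/specificity there,
a one-way ANOVA across the three groups, and the sweep of the S_f bound
that defines the I group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "AnovaResult",
    "roc_analysis",
    "group_comparison",
    "sf_bound_sweep",
    "label_groups",
]

PROGRESSION_GROUPS = ("R", "R&I")
INFLAMMATION_GROUP = "I"


@dataclass(frozen=True)
class RocResult:
    """ROC of "beta_hat > threshold => inflammation" over a cohort."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA of beta_hat across response groups."""

    F: float
    p_value: float
    group_summary: pd.DataFrame


def label_groups(
    Sn: np.ndarray, Sf_hat: np.ndarray, sf_bound: float = 0.1
) -> np.ndarray:
    """Response-group labels from the survival fractions of each simulation.

    R when healthy tissue is undamaged (Sn == 1); with damage present, I when
    the maximal tumor survival is at or below ``sf_bound`` (volume regrowth
    is inflammatory) and R&I above it.
    """
    Sn = np.asarray(Sn, dtype=float)
    Sf_hat = np.asarray(Sf_hat, dtype=float)
    damage = Sn < 1.0
    out = np.where(damage, np.where(Sf_hat <= sf_bound, "I", "R&I"), "R")
    return out.astype(object)


def roc_analysis(
    beta_hat: np.ndarray, labels: np.ndarray
) -> RocResult:
    """ROC of the growth exponent with inflammation as the positive class.

    AUC uses the rank (Mann-Whitney) formulation with midrank tie
    correction.  The operating threshold maximises Youden's
    J = sensitivity + specificity - 1 over midpoints between adjacent
    observed beta_hat values, ties broken toward the larger threshold (the
    more progression-specific rule, progression being the graver call).
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    labels = np.asarray(labels)
    if beta_hat.shape != labels.shape:
        raise ValueError("beta_hat and labels must have equal shape")
    if not np.all(np.isfinite(beta_hat)):
        raise ValueError("beta_hat must be finite")
    y = labels == INFLAMMATION_GROUP
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")

    ranks = stats.rankdata(beta_hat)  # midranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # candidate thresholds: midpoints between adjacent distinct scores,
    # plus one below and one above everything
    u = np.unique(beta_hat)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.array([])
    candidates = np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))
    pos, neg = beta_hat[y], beta_hat[~y]
    sens = (pos[:, None] > candidates[None, :]).mean(axis=0)
    spec = (neg[:, None] <= candidates[None, :]).mean(axis=0)
    J = sens + spec - 1.0
    best = np.flatnonzero(J == J.max())[-1]  # ties -> larger threshold

    fpr, tpr, thr = roc_curve(y.astype(int), beta_hat)
    return RocResult(
        auc=float(auc),
        threshold=float(candidates[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def group_comparison(beta_hat: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """One-way ANOVA of the growth exponent across response groups.

    Returns the F statistic, p-value and a per-group summary (n, median,
    quartiles) ready for box-plot export.  Degenerate all-identical input
    yields F = 0.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    labels = np.asarray(labels)
    groups = [beta_hat[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(beta_hat) == 0:
        F, p = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*groups)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    rows = []
    for g in np.unique(labels):
        vals = beta_hat[labels == g]
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "median": np.median(vals),
                "q1": np.percentile(vals, 25),
                "q3": np.percentile(vals, 75),
            }
        )
    return AnovaResult(F=float(F), p_value=float(p), group_summary=pd.DataFrame(rows))


def sf_bound_sweep(
    records: pd.DataFrame, bounds: np.ndarray | None = None
) -> pd.DataFrame:
    """Re-derive the I / R&I split at varying S_f bounds and re-run the ROC.

    ``records`` needs columns ``beta_hat``, ``Sn`` and ``Sf_hat``.  Bounds
    producing an empty class are skipped.  Returns one row per usable bound
    with the AUC, optimal threshold, sensitivity and specificity.
    """
    if bounds is None:
        bounds = np.linspace(0.04, 0.4, 10)
    required = {"beta_hat", "Sn", "Sf_hat"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rows = []
    for b in np.asarray(bounds, dtype=float):
        labels = label_groups(records["Sn"].to_numpy(),
                              records["Sf_hat"].to_numpy(), sf_bound=b)
        try:
            roc = roc_analysis(records["beta_hat"].to_numpy(), labels)
        except ValueError:
            continue  # a class emptied out at this bound
        rows.append(
            {
                "sf_bound": b,
                "auc": roc.auc,
                "threshold": roc.threshold,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "n_inflammation": roc.n_positive,
                "n_progression": roc.n_negative,
            }
        )
    return pd.DataFrame(rows)
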