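"""Extended-LOS discrimination: c-statistic and IDI.

An extended stay (LOS >= 10 days by default) is treated as a binary
endpoint and the stratifiers are assessed as its predictors:

* the c-statistic (AUC) — probability that a randomly chosen extended-stay
  record outranks a randomly chosen ordinary one, ties counted 1/2 —
  computed by the rank method with a DeLong-style paired-placement
  variance for the CI;
* the integrated discrimination improvement (IDI) between two probability
  models — the difference of their discrimination slopes.  Categorical
  classifiers are put on the probability scale by mapping each category to
  its observed event proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pcilos.schema import EstimationError

__all__ = [
    "DiscriminationResult",
    "IDIResult",
    "extended_los",
    "c_statistic",
    "category_probabilities",
    "idi",
]


def extended_los(los, threshold: int = 10) -> np.ndarray:
    """Binary extended-stay endpoint: LOS >= threshold (default 10 days)."""
    los = np.asarray(los)
    if np.any(los < 1):
        raise ValueError("LOS has a floor of one day")
    return los >= threshold


@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    ci_lo: float
    ci_hi: float
    se: float
    model: str = ""


@dataclass(frozen=True)
class IDIResult:
    idi: float
    ci_lo: float
    ci_hi: float
    se: float
    event_diff: float
    nonevent_diff: float


def c_statistic(predictor, outcome, model: str = "") -> DiscriminationResult:
    """c-statistic with a DeLong-style 95% CI.

    ``predictor`` is any ordinal score (invariant to strictly increasing
    transforms); ``outcome`` is binary.  The AUC is computed from midranks
    in O(n log n); its variance from the per-record placement values
    (variance of event placements over events plus variance of non-event
    placements over non-events).
    """
    x = np.asarray(predictor, dtype=float).ravel()
    d = np.asarray(outcome).astype(bool).ravel()
    if x.shape != d.shape:
        raise ValueError("predictor and outcome must have equal length")
    m = int(d.sum())
    n0 = int((~d).sum())
    if m == 0 or n0 == 0:
        raise EstimationError("AUC undefined: outcome has a single class")
    r_all = stats.rankdata(x)  # midranks
    r_ev = stats.rankdata(x[d])
    r_ne = stats.rankdata(x[~d])
    # placement of event i among non-events, and vice versa
    v10 = (r_all[d] - r_ev) / n0
    v01 = 1.0 - (r_all[~d] - r_ne) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = float(np.sqrt(var))
    return DiscriminationResult(
        auc=auc,
        ci_lo=max(0.0, auc - 1.96 * se),
        ci_hi=min(1.0, auc + 1.96 * se),
        se=se,
        model=model,
    )


def category_probabilities(categories, outcome, train_outcome=None, train_categories=None) -> np.ndarray:
    """Map each record to its category's event proportion.

    Puts a category-valued classifier on the probability scale for IDI.
    By default the proportions are estimated on the same records
    (training = evaluation cohort); pass ``train_categories``/
    ``train_outcome`` to estimate them on a separate split.
    """
    cats = pd.Categorical(categories)
    if (train_categories is None) != (train_outcome is None):
        raise ValueError("provide both train_categories and train_outcome, or neither")
    if train_categories is None:
        t_cats, t_out = cats, np.asarray(outcome).astype(float)
    else:
        t_cats = pd.Categorical(train_categories, categories=cats.categories)
        t_out = np.asarray(train_outcome).astype(float)
    rates: dict = {}
    for lev in cats.categories:
        if not (cats == lev).any():
            continue  # declared but unused on evaluation side
        mask = t_cats == lev
        if not mask.any():
            raise EstimationError(f"category {lev!r} has no training records")
        rates[lev] = float(t_out[mask].mean())
    return np.asarray([rates[c] for c in np.asarray(cats)], dtype=float)


def idi(p_new, p_old, outcome) -> IDIResult:
    """Integrated discrimination improvement of model *new* over *old*.

    ``IDI = [mean(p_new | event) - mean(p_old | event)]
          - [mean(p_new | non-event) - mean(p_old | non-event)]``,
    equivalently the difference in discrimination slopes.  The SE combines
    the variances of the per-record probability differences within the two
    outcome groups; the 95% CI is normal-based.
    """
    p_new = np.asarray(p_new, dtype=float).ravel()
    p_old = np.asarray(p_old, dtype=float).ravel()
    d = np.asarray(outcome).astype(bool).ravel()
    if not (p_new.shape == p_old.shape == d.shape):
        raise ValueError("p_new, p_old and outcome must have equal length")
    if np.any((p_new < 0) | (p_new > 1) | (p_old < 0) | (p_old > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    m = int(d.sum())
    n0 = int((~d).sum())
    if m == 0 or n0 == 0:
        raise EstimationError("IDI undefined: outcome has a single class")
    diff = p_new - p_old
    ev, ne = diff[d], diff[~d]
    event_diff = float(ev.mean())
    nonevent_diff = float(ne.mean())
    value = event_diff - nonevent_diff
    var = (np.var(ev, ddof=1) / m if m > 1 else 0.0) + (
        np.var(ne, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = float(np.sqrt(var))
    return IDIResult(
        idi=value,
        ci_lo=value - 1.96 * se,
        ci_hi=value + 1.96 * se,
        se=se,
        event_diff=event_diff,
        nonevent_diff=nonevent_diff,
    )
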