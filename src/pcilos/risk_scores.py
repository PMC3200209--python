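"""Additive clinical risk scores and the elective-procedure filter.

Two published additive scores are implemented as fixed lookup rules:

* the Mayo Clinic Risk Score (MCRS) — integer points for age (one per
  decade past 30), cardiogenic shock, renal failure, urgent/emergent
  status, NYHA class III/IV heart failure, angiographic thrombus, left
  main and multivessel disease, with an *elective mode* that zeroes the
  shock and urgent/emergent terms;
* the Wu et al. score — a 0–40 point score over age bands, sex,
  hemodynamic state, ejection fraction, MI timing, peripheral arterial
  disease, heart failure status, renal failure status and left main
  disease, derived originally from a logistic model by the Sullivan
  points method.

Both map to the shared five-level ordered risk categories through fixed
cutpoints; for the Wu score (whose original publication gives no
cutpoints) an ordinal cutpoint search over LOS is provided.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from pcilos.schema import (
    EstimationError,
    HEMO_LEVELS,
    HF_LEVELS,
    MI_LEVELS,
    RISK_CLASSES,
    SchemaError,
    risk_categorical,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RiskAssignment",
    "CutpointSet",
    "MCRS_CUTPOINTS",
    "WU_CUTPOINTS",
    "elective_filter",
    "mcrs_score",
    "mcrs_components",
    "mcrs_category",
    "wu_score",
    "wu_components",
    "wu_category",
    "cutpoint_search",
    "SearchInfeasibleError",
]


@dataclass(frozen=True)
class RiskAssignment:
    """A scored record: total points, ordered category, component breakdown."""

    score: int | None
    category: str
    components: dict[str, int]

    def __post_init__(self):
        if self.score is not None and self.score != sum(self.components.values()):
            raise ValueError("score must equal the sum of its components")


@dataclass(frozen=True)
class CutpointSet:
    """Four strictly increasing inclusive upper bounds defining five categories.

    Category k (ordered very_low .. very_high) holds scores in
    ``(uppers[k-1], uppers[k]]`` with ``uppers[-1] = -inf`` implied and the
    top category unbounded.
    """

    uppers: tuple[int, int, int, int]

    def __post_init__(self):
        if len(self.uppers) != 4 or any(
            b <= a for a, b in zip(self.uppers, self.uppers[1:])
        ):
            raise ValueError(f"cutpoints must be 4 strictly increasing values, got {self.uppers}")

    def assign(self, scores) -> pd.Categorical:
        scores = np.asarray(scores)
        # number of (inclusive) upper bounds strictly below the score
        idx = np.sum(scores[:, None] > np.asarray(self.uppers)[None, :], axis=1)
        return risk_categorical(np.asarray(RISK_CLASSES)[idx])


#: Published MCRS category bounds: 0–5, 6–8, 9–11, 12–14, >=15.
MCRS_CUTPOINTS = CutpointSet((5, 8, 11, 14))
#: Learning-set-derived Wu category bounds: 0–5, 6–10, 11–12, 13–15, >=16.
WU_CUTPOINTS = CutpointSet((5, 10, 12, 15))


# ---------------------------------------------------------------------------
# Elective filter
# ---------------------------------------------------------------------------

_ACUTE_MI = ("lt6h_no_st", "6_23h_no_st", "lt24h_stent_thrombosis")


def elective_filter(
    cohort: pd.DataFrame, return_counts: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, int]]:
    """Restrict a cohort to elective procedures.

    Excludes urgent/emergent procedures, records in shock or hemodynamic
    instability, and PCI within 24 hours of MI.  Input order is preserved
    and the operation is idempotent.  Per-reason exclusion counts (a record
    may contribute to several) are logged and optionally returned.
    """
    required = ("hemodynamic_state", "urgent_emergent", "mi_timing")
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise SchemaError(f"elective_filter: missing columns {missing}")
    urgent = cohort["urgent_emergent"].astype(bool)
    unstable = cohort["hemodynamic_state"].isin(("unstable", "shock"))
    acute_mi = cohort["mi_timing"].isin(_ACUTE_MI)
    counts = {
        "urgent_emergent": int(urgent.sum()),
        "hemodynamic_unstable_or_shock": int(unstable.sum()),
        "mi_within_24h": int(acute_mi.sum()),
        "excluded_total": int((urgent | unstable | acute_mi).sum()),
    }
    logger.info("elective_filter exclusions: %s", counts)
    kept = cohort.loc[~(urgent | unstable | acute_mi)]
    return (kept, counts) if return_counts else kept


# ---------------------------------------------------------------------------
# Mayo Clinic Risk Score
# ---------------------------------------------------------------------------


def mcrs_components(record: Mapping, elective_mode: bool = False) -> dict[str, int]:
    """MCRS point breakdown for one record.

    Missing optional flags count as absent (reference level).  The age term
    is ``floor(max(0, age - 30) / 10)`` — one point per completed decade
    past 30.  Renal failure (creatinine >2.5 mg/dL or dialysis) is a single
    +3 criterion, never doubled.
    """
    age = float(record["age"])
    comp = {
        "age": int(max(0.0, age - 30.0) // 10),
        "shock": 5 if (not elective_mode and record.get("hemodynamic_state") == "shock") else 0,
        "renal_failure": 3
        if (bool(record.get("creatinine_gt_2_5", 0)) or bool(record.get("dialysis", 0)))
        else 0,
        "urgent_emergent": 2
        if (not elective_mode and bool(record.get("urgent_emergent", 0)))
        else 0,
        "nyha_class_3_4": 2 if bool(record.get("nyha_class_3_4", 0)) else 0,
        "angiographic_thrombus": 2 if bool(record.get("angiographic_thrombus", 0)) else 0,
        "left_main_disease": 5 if bool(record.get("left_main_disease", 0)) else 0,
        "multivessel_disease": 2 if bool(record.get("multivessel_disease", 0)) else 0,
    }
    return comp


def mcrs_category(score: int) -> str:
    """Category for an MCRS total (0–5, 6–8, 9–11, 12–14, >=15)."""
    if score < 0:
        raise ValueError(f"MCRS score must be >= 0, got {score}")
    return str(MCRS_CUTPOINTS.assign([score])[0])


def mcrs_score(record: Mapping, elective_mode: bool = False) -> RiskAssignment:
    """Score one record with the MCRS."""
    comp = mcrs_components(record, elective_mode=elective_mode)
    total = sum(comp.values())
    return RiskAssignment(score=total, category=mcrs_category(total), components=comp)


def mcrs_score_frame(cohort: pd.DataFrame, elective_mode: bool = False) -> pd.Series:
    """Vectorised MCRS totals for a cohort."""
    score = (np.maximum(0.0, cohort["age"].to_numpy(float) - 30.0) // 10).astype(np.int64)
    score += 3 * (
        cohort["creatinine_gt_2_5"].astype(bool) | cohort["dialysis"].astype(bool)
    ).to_numpy()
    score += 2 * cohort["nyha_class_3_4"].astype(bool).to_numpy()
    score += 2 * cohort["angiographic_thrombus"].astype(bool).to_numpy()
    score += 5 * cohort["left_main_disease"].astype(bool).to_numpy()
    score += 2 * cohort["multivessel_disease"].astype(bool).to_numpy()
    if not elective_mode:
        score += 5 * (cohort["hemodynamic_state"] == "shock").to_numpy()
        score += 2 * cohort["urgent_emergent"].astype(bool).to_numpy()
    return pd.Series(score, index=cohort.index, name="mcrs_score")


# ---------------------------------------------------------------------------
# Wu et al. score
# ---------------------------------------------------------------------------

# Point table.  Within each mutually exclusive group exactly one level fires;
# precedence (dialysis over creatinine-only, current over past HF) is
# enforced by evaluation order.
_WU_AGE_BANDS = ((75.0, 5), (65.0, 3), (56.0, 1))  # lower bound inclusive -> points
_WU_HEMO = {"stable": 0, "unstable": 6, "shock": 9}
_WU_MI = {
    "none": 0,
    "lt24h_stent_thrombosis": 9,
    "lt6h_no_st": 7,
    "6_23h_no_st": 6,
    "d1_14": 4,
    "gt14d": 2,
}
_WU_HF = {"none": 0, "current": 4, "past": 3}


def wu_components(record: Mapping) -> dict[str, int]:
    """Wu et al. point breakdown for one record.

    Mutually exclusive groups: age band, sex, hemodynamic state, ejection
    fraction band, MI timing, heart failure status, renal failure status.
    A missing ejection fraction scores as the reference (>= 30%) level.
    """
    age = float(record["age"])
    age_pts = 0
    for lo, pts in _WU_AGE_BANDS:
        if age >= lo:
            age_pts = pts
            break
    hemo = record.get("hemodynamic_state", "stable")
    if hemo not in _WU_HEMO:
        raise SchemaError(f"unknown hemodynamic_state {hemo!r} (allowed {HEMO_LEVELS})")
    mi = record.get("mi_timing", "none")
    if mi not in _WU_MI:
        raise SchemaError(f"unknown mi_timing {mi!r} (allowed {MI_LEVELS})")
    hf = record.get("heart_failure", "none")
    if hf not in _WU_HF:
        raise SchemaError(f"unknown heart_failure {hf!r} (allowed {HF_LEVELS})")
    ef = record.get("ejection_fraction")
    if ef is None or (isinstance(ef, float) and np.isnan(ef)):
        ef_pts = 0
    elif ef < 20.0:
        ef_pts = 3
    elif ef < 30.0:
        ef_pts = 2
    else:
        ef_pts = 0
    if bool(record.get("dialysis", 0)):
        renal_pts = 4
    elif bool(record.get("creatinine_gt_2_5", 0)):
        renal_pts = 3
    else:
        renal_pts = 0
    return {
        "age": age_pts,
        "female": 1 if record.get("sex") == "female" else 0,
        "hemodynamic_state": _WU_HEMO[hemo],
        "ejection_fraction": ef_pts,
        "mi_timing": _WU_MI[mi],
        "peripheral_arterial_disease": 2
        if bool(record.get("peripheral_arterial_disease", 0))
        else 0,
        "heart_failure": _WU_HF[hf],
        "renal_failure": renal_pts,
        "left_main_disease": 3 if bool(record.get("left_main_disease", 0)) else 0,
    }


def wu_score(record: Mapping) -> RiskAssignment:
    """Score one record with the Wu et al. 0–40 point score."""
    comp = wu_components(record)
    total = sum(comp.values())
    return RiskAssignment(score=total, category=wu_category(total), components=comp)


def wu_category(score: int, cutpoints: CutpointSet = WU_CUTPOINTS) -> str:
    """Category for a Wu total under a cutpoint set (default 0–5/6–10/11–12/13–15/>=16)."""
    if not 0 <= score <= 40:
        raise ValueError(f"Wu score must be in [0, 40], got {score}")
    return str(cutpoints.assign([score])[0])


def wu_score_frame(cohort: pd.DataFrame) -> pd.Series:
    """Vectorised Wu totals for a cohort."""
    age = cohort["age"].to_numpy(float)
    score = np.select([age >= 75, age >= 65, age >= 56], [5, 3, 1], default=0).astype(np.int64)
    score += (cohort["sex"] == "female").to_numpy()
    score += cohort["hemodynamic_state"].map(_WU_HEMO).to_numpy(np.int64)
    ef = cohort["ejection_fraction"].to_numpy(float)
    score += np.select([ef < 20, ef < 30], [3, 2], default=0)  # NaN -> reference
    score += cohort["mi_timing"].map(_WU_MI).to_numpy(np.int64)
    score += 2 * cohort["peripheral_arterial_disease"].astype(bool).to_numpy()
    score += cohort["heart_failure"].map(_WU_HF).to_numpy(np.int64)
    score += np.where(
        cohort["dialysis"].astype(bool),
        4,
        np.where(cohort["creatinine_gt_2_5"].astype(bool), 3, 0),
    )
    score += 3 * cohort["left_main_disease"].astype(bool).to_numpy()
    return pd.Series(score, index=cohort.index, name="wu_score")


def wu_enumerate() -> np.ndarray:
    """Totals of every admissible combination of Wu factor levels (brute force)."""
    groups = [
        [0, 1, 3, 5],  # age band
        [0, 1],  # sex
        list(_WU_HEMO.values()),
        [0, 2, 3],  # ejection fraction
        list(_WU_MI.values()),
        [0, 2],  # peripheral arterial disease
        list(_WU_HF.values()),
        [0, 3, 4],  # renal failure
        [0, 3],  # left main
    ]
    return np.array([sum(c) for c in itertools.product(*groups)])


# ---------------------------------------------------------------------------
# Ordinal cutpoint search
# ---------------------------------------------------------------------------


class SearchInfeasibleError(EstimationError):
    """No admissible cutpoint set satisfies the search constraints."""


def _ztnb_interval_loglik(counts: np.ndarray, values: np.ndarray, alpha: float) -> float:
    """Profile ZTNB log-likelihood of one pooled score interval.

    ``counts[k]`` records with LOS ``values[k]``; the interval's mu is
    profiled out by a bounded scalar search at fixed dispersion.
    """
    from pcilos.ztnb import ztnb_logpmf

    n = counts.sum()
    if n == 0:
        return 0.0

    def neg(log_mu: float) -> float:
        return -float(np.dot(counts, ztnb_logpmf(values, np.exp(log_mu), alpha)))

    res = optimize.minimize_scalar(neg, bounds=(-5.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    return -res.fun


def cutpoint_search(
    scores,
    los,
    n_categories: int = 5,
    objective: str = "ztnb",
    min_fraction: float = 0.005,
) -> CutpointSet:
    """Search ordinal score cutpoints that best stratify LOS.

    The objective is additive over the score intervals that form the
    categories, so the optimum over all cutpoint sets is found exactly by
    dynamic programming over interval values — equivalent to exhaustive
    enumeration of every admissible 4-tuple but linear in practice.

    Objectives
    ----------
    ``"ztnb"`` (default)
        Profile log-likelihood of a ZTNB with category-specific means and a
        shared dispersion (estimated once from an intercept-only fit).
    ``"logvar"``
        Fast surrogate: between-category sum of squares of log LOS.

    Each category must hold at least ``min_fraction`` of the records.

    Raises
    ------
    SearchInfeasibleError
        If fewer than ``n_categories`` distinct scores are present or the
        minimum-fraction constraint cannot be met.
    """
    scores = np.asarray(scores)
    los = np.asarray(los)
    if scores.shape != los.shape:
        raise ValueError("scores and los must have equal length")
    values = np.unique(scores)
    if len(values) < n_categories:
        raise SearchInfeasibleError(
            f"need >= {n_categories} distinct scores, got {len(values)}"
        )
    n = len(scores)
    min_count = max(1, int(np.ceil(min_fraction * n)))
    s_idx = np.searchsorted(values, scores)
    counts = np.bincount(s_idx, minlength=len(values))

    nv = len(values)
    if objective == "ztnb":
        from pcilos.ztnb import fit_ztnb

        base = fit_ztnb(np.ones((n, 1)), los, start_beta=np.array([np.log(los.mean())]))
        alpha = base.alpha
        y_vals = np.unique(los)
        # histogram of LOS per score value -> per-interval pooled histograms
        y_idx = np.searchsorted(y_vals, los)
        hist = np.zeros((nv, len(y_vals)))
        np.add.at(hist, (s_idx, y_idx), 1.0)
        cum = np.vstack([np.zeros(len(y_vals)), np.cumsum(hist, axis=0)])

        def interval_value(i: int, j: int) -> float:  # scores values[i..j] incl.
            return _ztnb_interval_loglik(cum[j + 1] - cum[i], y_vals, alpha)

    elif objective == "logvar":
        ll = np.log(los)
        sums = np.bincount(s_idx, weights=ll, minlength=nv)
        cnt = counts.astype(float)
        csum = np.concatenate([[0.0], np.cumsum(sums)])
        ccnt = np.concatenate([[0.0], np.cumsum(cnt)])

        def interval_value(i: int, j: int) -> float:
            s = csum[j + 1] - csum[i]
            c = ccnt[j + 1] - ccnt[i]
            return s * s / c if c > 0 else 0.0

    else:
        raise ValueError(f"unknown objective {objective!r}")

    ccount = np.concatenate([[0], np.cumsum(counts)])

    def interval_n(i: int, j: int) -> int:
        return int(ccount[j + 1] - ccount[i])

    NEG = -np.inf
    val = np.full((nv, nv), NEG)
    for i in range(nv):
        for j in range(i, nv):
            if interval_n(i, j) >= min_count:
                val[i, j] = interval_value(i, j)

    # DP over ordered partitions into n_categories contiguous intervals
    best = np.full((n_categories + 1, nv + 1), NEG)
    arg = np.full((n_categories + 1, nv + 1), -1, dtype=int)
    best[0, 0] = 0.0
    for k in range(1, n_categories + 1):
        for j in range(1, nv + 1):
            for i in range(k - 1, j):
                if best[k - 1, i] == NEG or val[i, j - 1] == NEG:
                    continue
                cand = best[k - 1, i] + val[i, j - 1]
                if cand > best[k, j]:
                    best[k, j] = cand
                    arg[k, j] = i
    if best[n_categories, nv] == NEG:
        raise SearchInfeasibleError(
            f"no partition into {n_categories} categories with >= {min_count} records each"
        )
    bounds = []
    j = nv
    for k in range(n_categories, 0, -1):
        i = arg[k, j]
        bounds.append(values[j - 1])
        j = i
    bounds = bounds[::-1]  # inclusive upper score of each category
    return CutpointSet(tuple(int(b) for b in bounds[:-1]))


def cutpoint_objective(
    scores, los, cutpoints: CutpointSet, objective: str = "ztnb"
) -> float:
    """Objective value of a given cutpoint set (same scale as the search)."""
    scores = np.asarray(scores)
    los = np.asarray(los)
    cats = cutpoints.assign(scores)
    codes = pd.Categorical(cats).codes
    if objective == "logvar":
        ll = np.log(los)
        tot = 0.0
        for c in np.unique(codes):
            sub = ll[codes == c]
            tot += sub.sum() ** 2 / len(sub)
        return tot
    from pcilos.ztnb import fit_ztnb

    n = len(scores)
    base = fit_ztnb(np.ones((n, 1)), los, start_beta=np.array([np.log(los.mean())]))
    y_vals = np.unique(los)
    tot = 0.0
    for c in np.unique(codes):
        sub = los[codes == c]
        counts = np.bincount(np.searchsorted(y_vals, sub), minlength=len(y_vals)).astype(float)
        tot += _ztnb_interval_loglik(counts, y_vals, base.alpha)
    return tot
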