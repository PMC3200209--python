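"""Nonnested model comparison via per-observation log-likelihoods.

Two LOS models fitted to the same records (say, one stratified by an
additive risk score, one by the prognostic tree) are not nested, so their
fits are compared with a Vuong-style z-test on the per-record
log-likelihood differences ``m_i = l_i^A - l_i^B``:

    z = sqrt(n) * mean(m) / sd(m)       (sample sd, n-1 denominator)

referred to the standard normal.  When patients cluster within providers
the contributions can first be summed within cluster and the test run on
cluster units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pcilos.ztnb import ZTNBFit

__all__ = ["ComparisonResult", "vuong_test", "loglik_report"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a Vuong-style nonnested comparison.

    ``direction`` names the favored model ("A" if mean difference > 0,
    "B" if < 0, "none" when degenerate); ``degenerate`` flags zero-variance
    differences.
    """

    z_statistic: float
    p_value: float
    mean_diff: float
    n_units: int
    direction: str
    degenerate: bool = False


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def vuong_test(
    loglik_a,
    loglik_b,
    cluster_ids=None,
    correction: str | None = None,
    dim_a: int = 0,
    dim_b: int = 0,
) -> ComparisonResult:
    """Vuong test for nonnested models on per-unit log-likelihoods.

    Parameters
    ----------
    loglik_a, loglik_b : arrays
        Per-record log-likelihood contributions of the two models over the
        same records, equal length.
    cluster_ids : array, optional
        If given, contributions are summed within cluster first and the
        test runs on cluster units.
    correction : {None, "aic", "bic"}
        Optional dimension correction subtracted from the numerator sum:
        ``dim_a - dim_b`` (aic) or ``(dim_a - dim_b)/2 * log n`` (bic).
        Off by default — the basic statistic.

    Swapping the models negates z and preserves p exactly.  A zero-variance
    difference vector is flagged degenerate: p = 1 at zero mean, p = 0
    (infinite z) otherwise.
    """
    la = np.asarray(loglik_a, dtype=float).ravel()
    lb = np.asarray(loglik_b, dtype=float).ravel()
    if la.shape != lb.shape:
        raise ValueError(f"log-likelihood vectors differ in length: {la.shape} vs {lb.shape}")
    m = la - lb
    if cluster_ids is not None:
        cluster_ids = np.asarray(cluster_ids)
        if len(cluster_ids) != len(m):
            raise ValueError("cluster_ids must match the record count")
        codes, _ = pd.factorize(cluster_ids)
        m = np.bincount(codes, weights=m)
    n = len(m)
    total = float(m.sum())
    if correction == "aic":
        total -= dim_a - dim_b
    elif correction == "bic":
        total -= (dim_a - dim_b) / 2.0 * math.log(n)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    mean = total / n
    sd = float(np.std(m, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        if mean == 0.0:
            return ComparisonResult(0.0, 1.0, 0.0, n, "none", degenerate=True)
        z = math.inf if mean > 0 else -math.inf
        return ComparisonResult(z, 0.0, mean, n, "A" if mean > 0 else "B", degenerate=True)
    z = math.sqrt(n) * mean / sd
    p = 2.0 * _norm_sf(abs(z))
    direction = "A" if z > 0 else ("B" if z < 0 else "none")
    return ComparisonResult(z, p, mean, n, direction)


def loglik_report(fits: dict[str, ZTNBFit]) -> pd.DataFrame:
    """Total log-likelihood table for models fitted to the same records.

    Ordered by log-likelihood descending (best fit first).  Raises if the
    models were not fitted on the same number of records, since their
    likelihoods would not be comparable.
    """
    ns = {name: fit.n for name, fit in fits.items()}
    if len(set(ns.values())) > 1:
        raise ValueError(f"models fitted on differing record counts: {ns}")
    rows = [
        {
            "model": name,
            "loglik": fit.loglik_total,
            "n": fit.n,
            "n_params": len(fit.param_names),
        }
        for name, fit in fits.items()
    ]
    return pd.DataFrame(rows).sort_values("loglik", ascending=False).reset_index(drop=True)
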