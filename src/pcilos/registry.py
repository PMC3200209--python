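"""Synthetic PCI registry generator.

The real study population (a state-wide PCI reporting system) is not
publicly available, so every downstream stage of the pipeline is exercised
on synthetic cohorts drawn here.  The generator emulates the published
summary structure of the registry's *testing* years:

* covariate marginals (age mean/SD, prevalence of heart failure, renal
  failure, left main disease, ...) match the printed cohort table;
* length of stay (LOS) is drawn from a zero-truncated negative binomial
  (ZTNB) whose log-mean is the sum of a baseline, a risk-class effect and a
  provider-level random intercept, so that class-specific rate ratios and
  conditional means can be planted exactly;
* a binary in-hospital complication endpoint carries tree-structured risk
  (probability depends only on the TSPC leaf), so that recursive
  partitioning can rediscover the planted partition.

Covariates are independent by default — only marginals are published — with
an optional Gaussian-copula hook for correlated sensitivity runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from pcilos.schema import (
    CalibrationError,
    ConfigError,
    RISK_CLASSES,
    risk_categorical,
    validate_cohort,
)

__all__ = [
    "GeneratorConfig",
    "truncated_mean",
    "inverse_truncated_mean",
    "joint_calibrate",
    "draw_ztnb",
    "generate_cohort",
    "resolve_calibration",
    "write_cohort",
    "named_rngs",
]

# Treat the dispersion as exactly Poisson below this value: the NB2 zero
# probability (1+a*mu)^(-1/a) loses all precision long before a reaches 0.
_ALPHA_POISSON = 1e-10


def named_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent, reproducible random streams derived from one seed.

    Each name gets its own :class:`numpy.random.Generator` seeded by
    ``SeedSequence([seed, index])``, so adding a stream never perturbs the
    draws of existing ones listed before it.
    """
    return {
        name: np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        for i, name in enumerate(names)
    }


def _log_p0(mu: np.ndarray, alpha: float) -> np.ndarray:
    """log P(Y=0) for NB2(mu, alpha); Poisson limit -mu as alpha -> 0."""
    if alpha < _ALPHA_POISSON:
        return -mu
    return -np.log1p(alpha * mu) / alpha


def truncated_mean(mu, alpha: float):
    """Expected LOS under the zero-truncated NB2: E[Y | Y >= 1].

    ``mu / (1 - (1 + alpha*mu)**(-1/alpha))``, continuous in ``alpha`` at 0
    where it reduces to the truncated-Poisson form ``mu / (1 - exp(-mu))``.
    At ``alpha = 1`` (geometric) it collapses to ``1 + mu``.

    Parameters
    ----------
    mu : float or array
        Untruncated NB mean, must be > 0.
    alpha : float
        NB2 dispersion, must be >= 0.
    """
    mu = np.asarray(mu, dtype=float)
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    out = mu / -np.expm1(_log_p0(mu, alpha))
    return out if out.ndim else float(out)


def inverse_truncated_mean(target: float, alpha: float) -> float:
    """Untruncated NB mean whose truncated mean equals ``target``.

    The truncated mean is strictly increasing in mu with infimum 1 (as
    mu -> 0), so any ``target > 1`` has a unique preimage; it always
    exceeds mu, so the root lies in (0, target).
    """
    if target <= 1:
        raise ValueError(
            f"target truncated mean must exceed 1 (the LOS floor), got {target}"
        )
    return float(
        optimize.brentq(
            lambda m: truncated_mean(m, alpha) - target, 1e-12, target, xtol=1e-12
        )
    )


def joint_calibrate(
    ref_truncated_mean: float,
    target_truncated_mean: float,
    rate_ratio: float,
    alpha_bracket: tuple[float, float] = (1e-6, 10.0),
) -> tuple[float, float]:
    """Solve for (mu_base, alpha) matching two conditional means and a ratio.

    Finds the baseline NB mean ``mu_base`` and dispersion ``alpha`` such
    that the reference class has truncated mean ``ref_truncated_mean`` and
    the contrasted class — whose untruncated mean is ``rate_ratio *
    mu_base`` — has truncated mean ``target_truncated_mean``.  This is the
    two-equation system that reconciles a table of model-based conditional
    means with a table of mu-scale rate ratios.

    Raises
    ------
    CalibrationError
        If the system has no root for alpha inside ``alpha_bracket`` (for
        instance ``rate_ratio = 1`` with distinct means, which leaves alpha
        unidentified).
    """
    if ref_truncated_mean <= 1:
        raise CalibrationError(f"reference truncated mean must exceed 1, got {ref_truncated_mean}")
    if target_truncated_mean <= ref_truncated_mean:
        raise CalibrationError(
            "target truncated mean must exceed the reference mean "
            f"(got ref={ref_truncated_mean}, target={target_truncated_mean})"
        )
    if rate_ratio <= 1:
        raise CalibrationError(f"rate ratio must exceed 1, got {rate_ratio}")

    def gap(alpha: float) -> float:
        mu_base = inverse_truncated_mean(ref_truncated_mean, alpha)
        return truncated_mean(rate_ratio * mu_base, alpha) - target_truncated_mean

    lo, hi = alpha_bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        raise CalibrationError(
            "no dispersion in bracket "
            f"{alpha_bracket} satisfies ref={ref_truncated_mean}, "
            f"target={target_truncated_mean}, rate_ratio={rate_ratio} "
            f"(gap at ends: {g_lo:.4g}, {g_hi:.4g})"
        )
    alpha = float(optimize.brentq(gap, lo, hi, xtol=1e-10))
    mu_base = inverse_truncated_mean(ref_truncated_mean, alpha)
    return mu_base, alpha


def draw_ztnb(mu, alpha: float, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw zero-truncated NB2 counts (support {1, 2, ...}).

    Implemented by rejection: draw from the untruncated NB2 and redraw any
    zeros.  The acceptance probability per draw is ``1 - P(Y=0)`` which for
    LOS-scale means (mu of a few days) is close to 1, so rejection beats the
    inverse-CDF alternative (tabulating the truncated CDF per distinct mu)
    both in code and in time; the inverse-CDF path would only win for
    mu << 1.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if size is not None:
        mu = np.broadcast_to(mu, (size,)).copy()
    elif mu.ndim == 0:
        mu = mu.reshape(1)

    def sample(m: np.ndarray) -> np.ndarray:
        if alpha < _ALPHA_POISSON:
            return rng.poisson(m)
        n_shape = 1.0 / alpha
        p = 1.0 / (1.0 + alpha * m)
        return rng.negative_binomial(n_shape, p)

    y = sample(mu)
    zero = y == 0
    # P(accept) >= 1 - P0 > 0 for every mu > 0, so this terminates a.s.;
    # the iteration cap only guards pathological mu ~ 0.
    for _ in range(10_000):
        if not zero.any():
            break
        y[zero] = sample(mu[zero])
        zero = y == 0
    else:  # pragma: no cover
        raise RuntimeError("zero-rejection sampling failed to terminate")
    return y.astype(np.int64)


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

#: Covariate prevalences for the registry's testing years (cohort table).
#: Keys absent from the published table carry documented emulation defaults.
DEFAULT_PREVALENCES: dict[str, float] = {
    "female": 0.326,
    "heart_failure": 0.055,
    "renal_failure": 0.028,
    "left_main_disease": 0.029,
    "multivessel_disease": 0.470,
    "peripheral_arterial_disease": 0.094,
    "prior_mi": 0.069,
    # below: not in the published marginals; emulation defaults
    "angiographic_thrombus": 0.05,
    "nyha_class_3_4": 0.04,
    "unstable": 0.0,
    "shock": 0.0,
    "urgent_emergent": 0.0,
}

#: Planted mu-scale rate ratios per TSPC class (published RR table).
DEFAULT_RATE_RATIOS: dict[str, float] = {
    "very_low": 1.0,
    "low": 1.26,
    "moderate": 1.48,
    "high": 2.29,
    "very_high": 3.20,
}

#: Complication probability per TSPC leaf.  Monotone in risk class and of
#: realistic magnitude for a death/stroke/CABG composite after elective
#: PCI; the spacing is chosen so the planted tree is greedily
#: identifiable at registry scale (each true split's impurity gain clears
#: both competing split orderings and threshold-selection noise).  Freely
#: overridable.
DEFAULT_COMPLICATION_PROBS: dict[str, float] = {
    "very_low": 0.005,
    "low": 0.015,
    "moderate": 0.025,
    "high": 0.045,
    "very_high": 0.080,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic registry.

    Defaults emulate the published *testing*-years cohort: marginal
    prevalences and age moments from the cohort table, class rate ratios
    from the TSPC relative-risk table, and (under the default ``joint``
    calibration) a baseline mean and dispersion solved so the very-low and
    very-high conditional LOS means match the printed 3.2 and 8.7 days.

    Attributes
    ----------
    n : int
        Cohort size.
    seed : int
        Master seed; all streams (covariates, providers, LOS, complications)
        are derived from it.
    prevalences : dict
        Marginal probabilities, see :data:`DEFAULT_PREVALENCES`.
    age_mean, age_sd : float
        Age distribution (years), truncated normal on ``age_bounds``.
    age_bounds : tuple
        Support of age; ties at the 70-year TSPC split go to the older
        branch (the rule is ``age >= 70``).
    n_providers : int
        Number of provider clusters; records are assigned uniformly.
    provider_frailty_sd : float
        SD of the provider random intercept on the log-mean LOS scale.
    calibration_mode : str
        ``"joint"`` (solve mu_base and alpha from two conditional means and
        the very-high rate ratio), ``"rate_ratio"`` (``los_effects`` are
        mu-scale ratios; ``mu_base`` and ``alpha`` must be given) or
        ``"truncated_mean"`` (``los_effects`` are per-class target truncated
        means; ``alpha`` must be given).
    los_effects : dict
        Per-class rate ratios or target means, keyed by TSPC class.
    ref_truncated_mean, target_truncated_mean : float
        The two conditional means used by ``joint`` calibration.
    mu_base, alpha : float or None
        Baseline NB mean and NB2 dispersion; filled by calibration when the
        mode computes them.
    hf_current_share : float
        Share of heart-failure patients with *current* (vs past) HF.
    renal_dialysis_share : float
        Share of renal-failure patients on dialysis (the rest are coded
        creatinine >2.5 mg/dL only).
    mi_recent_share : float
        Share of prior-MI patients in the 1–14 day band (the rest >14 days).
    ef_mean, ef_sd, ef_missing : float
        Ejection fraction distribution (percent) and missingness rate.
    complication_leaf_probs : dict
        Bernoulli complication probability per TSPC leaf.
    copula_corr : dict or None
        Optional Gaussian-copula correlations, keyed by frozenset pairs of
        covariate names (``"age"`` plus prevalence keys); None = independent.
    """

    n: int = 79_545
    seed: int = 20110718
    prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_mean: float = 64.7
    age_sd: float = 11.8
    age_bounds: tuple[float, float] = (18.0, 100.0)
    n_providers: int = 40
    provider_frailty_sd: float = 0.1
    calibration_mode: str = "joint"
    los_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATE_RATIOS))
    ref_truncated_mean: float = 3.2
    target_truncated_mean: float = 8.7
    mu_base: float | None = None
    alpha: float | None = None
    hf_current_share: float = 0.6
    renal_dialysis_share: float = 0.3
    mi_recent_share: float = 0.4
    ef_mean: float = 50.0
    ef_sd: float = 10.0
    ef_missing: float = 0.03
    complication_leaf_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLICATION_PROBS)
    )
    copula_corr: dict | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.n_providers < 1:
            raise ConfigError(f"n_providers must be >= 1, got {self.n_providers}")
        if self.provider_frailty_sd < 0:
            raise ConfigError("provider_frailty_sd must be >= 0")
        for name, p in {**self.prevalences, **self.complication_leaf_probs,
                        "hf_current_share": self.hf_current_share,
                        "renal_dialysis_share": self.renal_dialysis_share,
                        "mi_recent_share": self.mi_recent_share,
                        "ef_missing": self.ef_missing}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {name!r}={p} outside [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigError(f"alpha must be > 0, got {self.alpha}")
        if self.calibration_mode not in ("joint", "rate_ratio", "truncated_mean"):
            raise ConfigError(f"unknown calibration_mode {self.calibration_mode!r}")
        missing = [c for c in RISK_CLASSES if c not in self.los_effects]
        if missing:
            raise ConfigError(f"los_effects missing classes {missing}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["copula_corr"] is not None:
            d["copula_corr"] = {"|".join(sorted(k)): v for k, v in d["copula_corr"].items()}
        return d


def resolve_calibration(config: GeneratorConfig) -> tuple[dict[str, float], float]:
    """Per-class untruncated NB means and the dispersion implied by a config."""
    config.validate()
    mode = config.calibration_mode
    if mode == "joint":
        mu_base, alpha = joint_calibrate(
            config.ref_truncated_mean,
            config.target_truncated_mean,
            config.los_effects["very_high"],
        )
        class_mu = {c: mu_base * config.los_effects[c] for c in RISK_CLASSES}
    elif mode == "rate_ratio":
        if config.mu_base is None or config.alpha is None:
            raise ConfigError("rate_ratio calibration requires explicit mu_base and alpha")
        alpha = config.alpha
        class_mu = {c: config.mu_base * config.los_effects[c] for c in RISK_CLASSES}
    else:  # truncated_mean
        if config.alpha is None:
            raise ConfigError("truncated_mean calibration requires explicit alpha")
        alpha = config.alpha
        class_mu = {
            c: inverse_truncated_mean(config.los_effects[c], alpha) for c in RISK_CLASSES
        }
    return class_mu, alpha


# ---------------------------------------------------------------------------
# Covariate draws
# ---------------------------------------------------------------------------

_COPULA_VARS = (
    "age",
    "female",
    "heart_failure",
    "renal_failure",
    "left_main_disease",
    "multivessel_disease",
    "peripheral_arterial_disease",
    "prior_mi",
    "angiographic_thrombus",
    "nyha_class_3_4",
)


def _draw_base_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Age plus the binary covariates, independent or via a Gaussian copula."""
    n = config.n
    prev = config.prevalences
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    trunc = stats.truncnorm(a, b, loc=config.age_mean, scale=config.age_sd)

    if config.copula_corr is None:
        cols = {"age": trunc.rvs(size=n, random_state=rng)}
        for name in _COPULA_VARS[1:]:
            cols[name] = rng.random(n) < prev.get(name, 0.0)
        return pd.DataFrame(cols)

    corr = np.eye(len(_COPULA_VARS))
    index = {name: i for i, name in enumerate(_COPULA_VARS)}
    for pair, rho in config.copula_corr.items():
        x, y = tuple(pair)
        if x not in index or y not in index:
            raise ConfigError(f"unknown copula variables {pair}")
        if not -1.0 < rho < 1.0:
            raise ConfigError(f"copula correlation {pair}={rho} outside (-1, 1)")
        corr[index[x], index[y]] = corr[index[y], index[x]] = rho
    # nudge to PSD if the user-specified pairwise entries are inconsistent
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        corr = (v * np.clip(w, 1e-10, None)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(len(_COPULA_VARS)), corr, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    cols = {"age": trunc.ppf(np.clip(u[:, 0], 1e-12, 1 - 1e-12))}
    for name in _COPULA_VARS[1:]:
        # flags fire in the *upper* tail of the latent normal so a positive
        # copula correlation with age yields a positive observed correlation
        cols[name] = u[:, index[name]] >= 1.0 - prev.get(name, 0.0)
    return pd.DataFrame(cols)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic elective-PCI cohort.

    Covariates are drawn from the configured marginals; each record is
    routed through the fixed TSPC rule; LOS is drawn from the ZTNB with
    log-mean ``log(mu_class) + provider intercept``; the complication flag
    is Bernoulli with the record's leaf probability.  Bit-for-bit
    reproducible for a fixed config.
    """
    from pcilos.tree import tspc_classify  # local import: tree has no registry dep

    class_mu, alpha = resolve_calibration(config)
    rngs = named_rngs(config.seed, ["covariates", "providers", "los", "complications"])

    base = _draw_base_covariates(config, rngs["covariates"])
    n = config.n
    rng_cov = rngs["covariates"]
    prev = config.prevalences

    cohort = pd.DataFrame(index=pd.RangeIndex(n))
    # registries record age in completed years; rounding the continuous
    # draw keeps the configured mean and leaves the >=70 rule well defined
    cohort["age"] = np.clip(np.round(base["age"]), config.age_bounds[0], config.age_bounds[1])
    cohort["sex"] = np.where(base["female"], "female", "male")

    hf = base["heart_failure"].to_numpy()
    hf_current = rng_cov.random(n) < config.hf_current_share
    cohort["heart_failure"] = np.select(
        [hf & hf_current, hf & ~hf_current], ["current", "past"], default="none"
    )
    cohort["nyha_class_3_4"] = base["nyha_class_3_4"].astype(np.int64)

    renal = base["renal_failure"].to_numpy()
    dialysis = renal & (rng_cov.random(n) < config.renal_dialysis_share)
    cohort["creatinine_gt_2_5"] = (renal & ~dialysis).astype(np.int64)
    cohort["dialysis"] = dialysis.astype(np.int64)

    ef = np.clip(rng_cov.normal(config.ef_mean, config.ef_sd, n), 5.0, 85.0)
    ef[rng_cov.random(n) < config.ef_missing] = np.nan
    cohort["ejection_fraction"] = ef

    prior_mi = base["prior_mi"].to_numpy()
    mi_recent = rng_cov.random(n) < config.mi_recent_share
    # acute (<24 h) categories are excluded by the elective restriction and
    # only appear if their prevalences are explicitly configured
    u = rng_cov.random(n)
    p_acute = prev.get("mi_lt6h_no_st", 0.0)
    acute6 = u < p_acute
    acute23 = (u >= p_acute) & (u < p_acute + prev.get("mi_6_23h_no_st", 0.0))
    cohort["mi_timing"] = np.select(
        [acute6, acute23, prior_mi & mi_recent, prior_mi & ~mi_recent],
        ["lt6h_no_st", "6_23h_no_st", "d1_14", "gt14d"],
        default="none",
    )

    cohort["peripheral_arterial_disease"] = base["peripheral_arterial_disease"].astype(np.int64)
    cohort["left_main_disease"] = base["left_main_disease"].astype(np.int64)
    cohort["multivessel_disease"] = base["multivessel_disease"].astype(np.int64)
    cohort["angiographic_thrombus"] = base["angiographic_thrombus"].astype(np.int64)

    u = rng_cov.random(n)
    p_shock = prev.get("shock", 0.0)
    cohort["hemodynamic_state"] = np.select(
        [u < p_shock, u < p_shock + prev.get("unstable", 0.0)],
        ["shock", "unstable"],
        default="stable",
    )
    cohort["urgent_emergent"] = (rng_cov.random(n) < prev.get("urgent_emergent", 0.0)).astype(
        np.int64
    )

    providers = rngs["providers"].integers(0, config.n_providers, size=n)
    cohort["provider_id"] = providers
    frailty = (
        rngs["providers"].normal(0.0, config.provider_frailty_sd, size=config.n_providers)
        if config.provider_frailty_sd > 0
        else np.zeros(config.n_providers)
    )

    tspc = tspc_classify(cohort)
    mu_class = np.array([class_mu[c] for c in RISK_CLASSES])
    class_codes = pd.Categorical(tspc).codes
    mu = mu_class[class_codes] * np.exp(frailty[providers])
    cohort["los_days"] = draw_ztnb(mu, alpha, rngs["los"])

    leaf_p = np.array([config.complication_leaf_probs[c] for c in RISK_CLASSES])
    cohort["complication"] = (
        rngs["complications"].random(n) < leaf_p[class_codes]
    ).astype(np.int64)

    validate_cohort(cohort, context="generated cohort")
    return cohort


def generate_stratified_los(
    n: int,
    seed: int,
    class_shares: Mapping[str, float],
    rate_ratios: Mapping[str, float],
    mu_base: float,
    alpha: float,
    n_providers: int = 40,
    provider_frailty_sd: float = 0.1,
) -> pd.DataFrame:
    """LOS draws for a directly planted risk-category structure.

    Unlike :func:`generate_cohort` (where categories arise from covariates
    through the TSPC rule), categories are drawn multinomially with the
    given shares and the per-category mu-scale rate ratios are planted
    exactly — the setup for validating category-indicator regressions whose
    stratifier (e.g. an additive score) is not the generator's risk truth.

    Returns a frame with ``category`` (ordered categorical), ``provider_id``
    and ``los_days``.
    """
    cats = [c for c in RISK_CLASSES if c in class_shares]
    shares = np.array([class_shares[c] for c in cats], dtype=float)
    if not np.isclose(shares.sum(), 1.0, atol=1e-6):
        raise ConfigError(f"class shares must sum to 1, got {shares.sum()}")
    rngs = named_rngs(seed, ["classes", "providers", "los"])
    codes = rngs["classes"].choice(len(cats), size=n, p=shares / shares.sum())
    providers = rngs["providers"].integers(0, n_providers, size=n)
    frailty = (
        rngs["providers"].normal(0.0, provider_frailty_sd, size=n_providers)
        if provider_frailty_sd > 0
        else np.zeros(n_providers)
    )
    rr = np.array([rate_ratios[c] for c in cats], dtype=float)
    mu = mu_base * rr[codes] * np.exp(frailty[providers])
    los = draw_ztnb(mu, alpha, rngs["los"])
    return pd.DataFrame(
        {
            "category": risk_categorical(np.asarray(cats, dtype=object)[codes]),
            "provider_id": providers,
            "los_days": los,
        }
    )


def write_cohort(
    cohort: pd.DataFrame, path: str | Path, config: GeneratorConfig | None = None
) -> None:
    """Write a cohort CSV (UTF-8, booleans as 0/1) plus a run-manifest sidecar."""
    path = Path(path)
    out = cohort.copy()
    out["age"] = out["age"].round(3)
    out["ejection_fraction"] = out["ejection_fraction"].round(1)
    out.to_csv(path, index=False)
    if config is not None:
        manifest = {
            "n": int(len(cohort)),
            "seed": config.seed,
            "config": config.to_dict(),
            "columns": list(cohort.columns),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
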