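"""Post-fit quantities: predictions, first-return curve, variance
components, covariate sensitivities, effect de-standardization and the
fledging-mass ANOVA."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .data import StandardizedCovariate
from .model import CMRResults

__all__ = [
    "predict_survival",
    "cumulative_first_return",
    "ProcessVariance",
    "variance_components",
    "annual_survival_estimates",
    "sensitivity",
    "sensitivity_table",
    "destandardize_slope",
    "mass_year_anova",
]

#: an annual estimate whose logit-scale SE exceeds this is non-identifiable
#: and excluded from variance-component analysis
NONIDENTIFIABLE_LOGIT_SE = 3.0


def _phi_design_row(fit: CMRResults, age_class: int, covariate_z: Mapping[str, float]) -> np.ndarray:
    """Design row of the survival linear predictor for one age class with
    year factors at reference and covariates at the given z values."""
    x = np.zeros(fit.k)
    names = fit.names
    intercept = f"phi:int:c{age_class}"
    if intercept not in names:
        raise KeyError(f"no age class {age_class} in this model")
    x[names.index(intercept)] = 1.0
    for name, z in covariate_z.items():
        col_add = f"phi:{name}"
        col_int = f"phi:{name}:c{age_class}"
        if col_int in names:
            x[names.index(col_int)] = z
        elif col_add in names:
            x[names.index(col_add)] = z
        else:
            raise KeyError(f"covariate {name!r} not in the fitted model")
    return x


def predict_survival(
    fit: CMRResults,
    age_class: int,
    covariate_values: Optional[Mapping[str, float]] = None,
    standardizers: Optional[Mapping[str, StandardizedCovariate]] = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Survival probability with delta-method CI at given covariate values.

    ``covariate_values`` are on the raw scale when a standardizer is
    supplied for the covariate, otherwise they are taken as already
    standardized (z) values; omitted covariates sit at their means (z=0).
    """
    standardizers = standardizers or {}
    z = {}
    for name, value in (covariate_values or {}).items():
        if name in standardizers:
            z[name] = float(standardizers[name].standardize_value(value))
        else:
            z[name] = float(value)
    x = _phi_design_row(fit, age_class, z)
    eta = float(x @ fit.params)
    var_eta = float(x @ fit.cov_params() @ x)
    phi = float(expit(eta))
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var_eta, 0.0))
    return phi, float(expit(eta - half)), float(expit(eta + half))


def cumulative_first_return(psi_by_age: Sequence[float]) -> np.ndarray:
    """C(a) = 1 - prod_{i<=a}(1 - psi_i): probability a surviving bird has
    returned to the colony at least once by age a."""
    psi = np.asarray(psi_by_age, dtype=float)
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("psi entries must lie in [0, 1]")
    return 1.0 - np.cumprod(1.0 - psi)


@dataclass
class ProcessVariance:
    """Random-effects decomposition of annual estimates."""

    mean: float
    sigma2_process: float
    shrunken: np.ndarray
    n_used: int
    excluded: tuple[int, ...] = ()

    @property
    def sigma_process(self) -> float:
        return float(np.sqrt(self.sigma2_process))


def variance_components(
    annual_estimates: Sequence[float],
    annual_variances: Sequence[float],
    max_iter: int = 200,
    tol: float = 1e-12,
) -> ProcessVariance:
    """Moment estimator of temporal process variance.

    Finds sigma2 >= 0 and the weighted mean mu (weights 1/(sigma2+v_t))
    such that the weighted sum of squares equals T-1; truncates at zero
    when the estimates are less variable than their sampling noise.
    """
    theta = np.asarray(annual_estimates, dtype=float)
    v = np.asarray(annual_variances, dtype=float)
    if theta.size < 3:
        raise ValueError("variance components need at least 3 annual estimates")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    Tn = theta.size

    def wss(sig2: float) -> float:
        w = 1.0 / (sig2 + v)
        mu = float(np.sum(w * theta) / np.sum(w))
        return float(np.sum(w * (theta - mu) ** 2)) - (Tn - 1)

    if wss(0.0) <= 0:
        sig2 = 0.0
    else:
        hi = float(np.var(theta, ddof=1)) + float(v.max())
        it = 0
        while wss(hi) > 0:
            hi *= 2.0
            it += 1
            if it > max_iter:
                raise RuntimeError("variance-component bracketing failed")
        sig2 = float(optimize.brentq(wss, 0.0, hi, xtol=tol, maxiter=max_iter))
    w = 1.0 / (sig2 + v)
    mu = float(np.sum(w * theta) / np.sum(w))
    shrink = sig2 / (sig2 + v)
    shrunken = mu + shrink * (theta - mu)
    return ProcessVariance(mean=mu, sigma2_process=sig2, shrunken=shrunken, n_used=Tn)


def annual_survival_estimates(
    fit: CMRResults, age_class: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-interval survival of one age class from an additive-time fit.

    Returns (estimates, variances, intervals) on the probability scale
    with delta-method variances; intervals whose logit-scale SE exceeds
    :data:`NONIDENTIFIABLE_LOGIT_SE` are excluded (flagged
    non-identifiable, e.g. terminal or sparse cohort-years).
    """
    if fit.structure.survival.time_effect != "additive":
        raise ValueError("annual estimates require an additive-time survival structure")
    T = fit.design.n_occasions
    names = fit.names
    V = fit.cov_params()
    ests, variances, intervals = [], [], []
    for t in range(1, T):
        x = np.zeros(fit.k)
        x[names.index(f"phi:int:c{age_class}")] = 1.0
        if t >= 2:
            x[names.index(f"phi:t{t}")] = 1.0
        eta = float(x @ fit.params)
        var_eta = float(x @ V @ x)
        if np.sqrt(var_eta) > NONIDENTIFIABLE_LOGIT_SE:
            continue
        phi = float(expit(eta))
        ests.append(phi)
        variances.append((phi * (1 - phi)) ** 2 * var_eta)
        intervals.append(t)
    return np.asarray(ests), np.asarray(variances), intervals


def sensitivity(
    fit: CMRResults,
    age_class: int,
    covariate: str,
    covariate_z: Optional[Mapping[str, float]] = None,
) -> float:
    """Sensitivity of survival to a covariate: S = beta * phi * (1 - phi).

    The partial derivative of survival with respect to the covariate (per
    1 SD), evaluated by default with all standardized covariates at their
    means (z = 0) and survival at the age class's fitted value.
    """
    names = fit.names
    col_int = f"phi:{covariate}:c{age_class}"
    col_add = f"phi:{covariate}"
    if col_int in names:
        beta = fit.params[names.index(col_int)]
    elif col_add in names:
        beta = fit.params[names.index(col_add)]
        if covariate == "mass" and age_class != 0:
            raise KeyError("individual mass enters the fledgling class only")
    else:
        raise KeyError(f"covariate {covariate!r} absent for age class {age_class}")
    phi, _, _ = predict_survival(fit, age_class, covariate_z)
    return float(beta * phi * (1.0 - phi))


def sensitivity_table(fit: CMRResults, age_classes: Sequence[int], covariates: Sequence[str]) -> pd.DataFrame:
    """Table of S = beta * phi(1-phi) by age class and covariate; entries
    structurally absent from the model are NaN."""
    rows = []
    for c in age_classes:
        row: dict = {"age_class": c}
        for name in covariates:
            try:
                row[name] = sensitivity(fit, c, name)
            except KeyError:
                row[name] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def destandardize_slope(beta_per_sd: float, standardizer: StandardizedCovariate) -> float:
    """Convert a per-SD logit slope to per-raw-unit."""
    if standardizer.scale <= 0:
        raise ValueError("zero scale cannot be de-standardized")
    return beta_per_sd / standardizer.scale


def mass_year_anova(masses_by_cohort: Mapping[int, Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of fledging mass across cohort years.

    Returns (F, df_between, df_within, p).
    """
    groups = [np.asarray(v, dtype=float) for v in masses_by_cohort.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 cohorts with >= 2 masses each")
    F, _ = stats.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(g.size for g in groups) - len(groups)
    F = max(float(F), 0.0)  # guard the exactly-degenerate all-means-equal case
    return F, df_between, df_within, float(stats.f.sf(F, df_between, df_within))
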