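"""Model ranking, likelihood-ratio tests, ANODEV and step-up selection.

Ranking uses QAICc with the parsimony rule: among models within 2 units
of the best, the one with fewest parameters wins.  Covariate inference
follows the step-up protocol: individual covariates first (LRT), then one
annual covariate per step, judged by the fraction of temporal deviance it
explains, R2_DEV = [DEV(.) - DEV(cov)] / [DEV(.) - DEV(t)], with the
model retained from the previous step acting as the "constant" reference.
A covariate explaining more than 20% of the remaining temporal deviance
is considered influential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .model import CMRResults, EstimationError, MultistateCMR, information_criteria
from .structure import ModelStructure, SurvivalSpec

__all__ = [
    "RankingTable",
    "SelectionRecord",
    "rank_models",
    "likelihood_ratio_test",
    "anodev",
    "step_up_selection",
    "verify_coefficient",
]


@dataclass
class RankingTable:
    """Models sorted by the selection criterion, winner flagged."""

    frame: pd.DataFrame  # columns: label, criterion, delta, k, deviance
    criterion: str  # "qaicc" or "aicc"
    selected_label: str

    @property
    def best_label(self) -> str:
        return str(self.frame.iloc[0]["label"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.2f}")


def rank_models(fits: Sequence[CMRResults], c_hat: float = 1.0) -> RankingTable:
    """Rank fits by QAICc (AICc when c_hat = 1) and apply the parsimony rule."""
    if not fits:
        raise ValueError("no fits to rank")
    ess = {f.ess for f in fits}
    if len(ess) != 1:
        raise ValueError("fits come from different datasets (mixed ess)")
    crit_name = "aicc" if c_hat == 1.0 else "qaicc"
    rows = []
    for f in fits:
        crit = information_criteria(f, c_hat)[crit_name]
        rows.append(
            {
                "label": f.structure.label,
                crit_name: crit,
                "k": f.k,
                "deviance": f.deviance,
            }
        )
    frame = pd.DataFrame(rows).sort_values([crit_name, "k", "label"]).reset_index(drop=True)
    frame["delta"] = frame[crit_name] - frame[crit_name].iloc[0]
    frame = frame[["label", crit_name, "delta", "k", "deviance"]]
    close = frame[frame["delta"] <= 2.0]
    pick = close.sort_values(["k", "label"]).iloc[0]
    frame["selected"] = frame["label"] == pick["label"]
    return RankingTable(frame=frame, criterion=crit_name, selected_label=str(pick["label"]))


def likelihood_ratio_test(
    nested_fit: CMRResults, general_fit: CMRResults
) -> tuple[float, int, float]:
    """chi2 = DEV(nested) - DEV(general), df = k difference, upper-tail p."""
    df = general_fit.k - nested_fit.k
    chi2 = nested_fit.deviance - general_fit.deviance
    if df < 0:
        raise ValueError("general model must have at least as many parameters")
    if df == 0:
        # identical structures: no test, the statistic is trivially zero
        if abs(chi2) > 1e-6:
            raise ValueError("equal parameter counts but different deviances: not nested")
        return 0.0, 0, 1.0
    if chi2 < -1e-6:
        raise EstimationError(
            f"negative LRT statistic ({chi2:.3g}): an optimum was missed; refit advised"
        )
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def anodev(
    fit_constant: CMRResults, fit_covariate: CMRResults, fit_timedep: CMRResults
) -> tuple[float, int, int, float, float]:
    """Analysis of deviance for one covariate against full temporal variation.

    Returns (F, df1, df2, p, r2_dev) with
    r2_dev = [DEV(.) - DEV(cov)] / [DEV(.) - DEV(t)].
    """
    d0, dc, dt = fit_constant.deviance, fit_covariate.deviance, fit_timedep.deviance
    df1 = fit_covariate.k - fit_constant.k
    df2 = fit_timedep.k - fit_covariate.k
    denom = d0 - dt
    if abs(denom) < 1e-9:
        raise EstimationError("degenerate ANODEV: constant and time models have equal deviance")
    r2 = (d0 - dc) / denom
    if df1 <= 0 or df2 <= 0:
        raise ValueError("ANODEV needs strictly nested constant < covariate < time models")
    num = max(d0 - dc, 0.0) / df1
    den = max(dc - dt, 0.0) / df2
    if den == 0.0:
        F = float("inf")
        p = 0.0
    else:
        F = num / den
        p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p, float(r2)


@dataclass
class SelectionRecord:
    """One step of the step-up covariate-selection procedure."""

    step: int
    covariate: Optional[str]
    scope: Optional[str]
    test: Optional[str]  # "LRT" | "ANODEV"
    statistic: Optional[float]
    df: Optional[tuple[int, ...]]
    p: Optional[float]
    r2_dev: Optional[float]
    retained: bool
    model_label: str
    deviance: float
    k: int
    qaicc: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["df"] = None if self.df is None else list(self.df)
        return d


def _with_covariate(structure: ModelStructure, name: str, scope: str) -> ModelStructure:
    surv = structure.survival
    return replace(
        structure,
        survival=SurvivalSpec(
            surv.age_structure, surv.time_effect, surv.covariates + ((name, scope),)
        ),
    )


def _with_additive_time(structure: ModelStructure) -> ModelStructure:
    surv = structure.survival
    return replace(
        structure,
        survival=SurvivalSpec(surv.age_structure, "additive", surv.covariates),
    )


def step_up_selection(
    dataset: Dataset,
    base_structure: ModelStructure,
    individual_covariates: Sequence[str] = ("mass",),
    annual_covariates: Sequence[str] = (),
    c_hat: float = 1.0,
    r2_threshold: float = 0.20,
    alpha: float = 0.05,
    scopes: Sequence[str] = ("additive", "interactive"),
    forced_scopes: Optional[dict] = None,
    n_restarts: int = 2,
    seed: int = 0,
    max_steps: int = 10,
) -> list[SelectionRecord]:
    """The step-up covariate-selection procedure.

    Step 1 fits the constant base structure (age-class intercepts only on
    survival).  Step 2 adds individual covariates, each judged by LRT.
    Every later step fits all remaining annual covariates on top of the
    current model, computes ANODEV against the current model (the
    "constant" reference) and the current model with full additive year
    effects (the time reference), and retains the covariate with the
    largest R2_DEV provided it clears ``r2_threshold``; otherwise the
    procedure stops.  The entry form (additive vs interactive with age
    class) is chosen by QAICc unless forced via ``forced_scopes``.
    """
    if base_structure.survival.time_effect != "none" or base_structure.survival.covariates:
        raise ValueError("base structure must have constant (intercept-only) survival")
    forced_scopes = dict(forced_scopes or {})
    records: list[SelectionRecord] = []

    def _fit(structure: ModelStructure, warm: Optional[CMRResults] = None) -> CMRResults:
        model = MultistateCMR(dataset, structure)
        start = None
        if warm is not None:
            # warm-start shared coefficients at the current model's estimates
            start = np.zeros(model.design.k)
            for j, nm in enumerate(model.design.names):
                if nm in warm.names:
                    start[j] = warm.param(nm)
        return model.fit(n_restarts=n_restarts, seed=seed, start=start, compute_vcov=False)

    current = _fit(base_structure)
    records.append(
        SelectionRecord(
            step=1,
            covariate=None,
            scope=None,
            test=None,
            statistic=None,
            df=None,
            p=None,
            r2_dev=None,
            retained=True,
            model_label=current.structure.label,
            deviance=current.deviance,
            k=current.k,
            qaicc=information_criteria(current, c_hat)["qaicc"],
        )
    )

    # step 2: individual covariates in isolation, by LRT
    step = 2
    for name in individual_covariates:
        cand_structure = _with_covariate(current.structure, name, "individual")
        cand = _fit(cand_structure, warm=current)
        chi2, df, p = likelihood_ratio_test(current, cand)
        retained = p < alpha
        records.append(
            SelectionRecord(
                step=step,
                covariate=name,
                scope="individual",
                test="LRT",
                statistic=chi2,
                df=(df,),
                p=p,
                r2_dev=None,
                retained=retained,
                model_label=cand.structure.label,
                deviance=cand.deviance,
                k=cand.k,
                qaicc=information_criteria(cand, c_hat)["qaicc"],
            )
        )
        if retained:
            current = cand
        step += 1

    remaining = list(annual_covariates)
    while remaining and step <= max_steps:
        fit_t = _fit(_with_additive_time(current.structure), warm=current)
        candidates = []
        for name in remaining:
            use_scopes = [forced_scopes[name]] if name in forced_scopes else list(scopes)
            if current.structure.survival.age_structure.n_classes == 1:
                use_scopes = ["additive"]
            best = None
            for scope in use_scopes:
                try:
                    cand = _fit(_with_covariate(current.structure, name, scope), warm=current)
                except EstimationError:
                    continue
                q = information_criteria(cand, c_hat)["qaicc"]
                if best is None or q < best[1]:
                    best = (cand, q, scope)
            if best is None:
                continue
            cand, q, scope = best
            try:
                F, df1, df2, p, r2 = anodev(current, cand, fit_t)
            except EstimationError:
                continue
            candidates.append((r2, cand.k, name, scope, cand, F, df1, df2, p, q))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        r2, _, name, scope, cand, F, df1, df2, p, q = candidates[0]
        retained = r2 > r2_threshold
        records.append(
            SelectionRecord(
                step=step,
                covariate=name,
                scope=scope,
                test="ANODEV",
                statistic=F,
                df=(df1, df2),
                p=p,
                r2_dev=r2,
                retained=retained,
                model_label=cand.structure.label,
                deviance=cand.deviance,
                k=cand.k,
                qaicc=q,
            )
        )
        if not retained:
            break
        current = cand
        remaining.remove(name)
        step += 1
    return records


def verify_coefficient(
    fit: CMRResults, coefficient: str, level: float = 0.95
) -> tuple[float, float, float, bool]:
    """Wald CI of a logit-scale coefficient using the c-hat-inflated vcov."""
    j = fit.design.index_of(coefficient)
    est = float(fit.params[j])
    se = float(fit.bse[j])
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = est - z * se, est + z * se
    return est, lo, hi, bool(lo > 0 or hi < 0)


def selection_records_frame(records: Sequence[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
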