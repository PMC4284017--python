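"""End-to-end analysis protocol.

The protocol mirrors the standard multistate CMR workflow: fit a global
model, assess its fit with median c-hat, simplify the structural
components (first return, then recapture, then survival age/time) by
QAICc with the parsimony rule, run step-up covariate selection on the
winning structure, verify retained coefficients by Wald CI, and compute
derived quantities (variance components, sensitivities, cumulative
first-return curve)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import Dataset, filter_missing_mass
from .derived import (
    annual_survival_estimates,
    cumulative_first_return,
    sensitivity_table,
    variance_components,
)
from .model import (
    CMRResults,
    EstimationError,
    MultistateCMR,
    estimate_median_chat,
    inflate_by_chat,
)
from .selection import (
    rank_models,
    selection_records_frame,
    step_up_selection,
    verify_coefficient,
)
from .structure import (
    ModelStructure,
    RecaptureSpec,
    SurvivalSpec,
    TransitionSpec,
    parse_label,
)

__all__ = ["ProtocolConfig", "ProtocolReport", "run_protocol", "psi_curve"]

ANNUAL_CANDIDATES = (
    "pred_pressure",
    "lsst_lag0",
    "lsst_lag1",
    "enso_lag2",
    "enso_lag3",
    "sam_lag0",
    "sam_lag1",
    "mean_fledging_mass",
)


@dataclass
class ProtocolConfig:
    global_label: str = "phi(a3 a*t) p(t) psi(5)"
    psi_variants: tuple[str, ...] = ("3", "4", "5", "4 linear", "4 ln")
    p_variants: tuple[str, ...] = ("t", "T3", ".")
    age_time_variants: tuple[str, ...] = (
        "a1", "a1 t", "a2", "a2 a+t", "a2 a*t", "a3", "a3 a+t", "a3 a*t",
    )
    annual_covariates: Optional[tuple[str, ...]] = None  # default: available candidates
    individual_covariates: tuple[str, ...] = ("mass",)
    forced_scopes: dict = field(default_factory=dict)
    r2_threshold: float = 0.20
    alpha: float = 0.05
    chat_replicates: int = 100
    chat_bounds: tuple[float, float] = (1.0, 4.0)
    c_hat: Optional[float] = None  # skip estimation when given
    n_restarts: int = 2


def psi_curve(fit: CMRResults) -> np.ndarray:
    """First-return probabilities by age, 1..max+1 (the last is fixed 1)."""
    trans = fit.structure.transition
    ages = np.arange(1, trans.max_first_return_age + 2)
    out = np.ones(ages.size)
    for i, a in enumerate(ages[:-1]):
        if trans.trend == "free":
            out[i] = expit(fit.param(f"psi:a{a}"))
        else:
            x = float(a) if trans.trend == "linear" else np.log(a)
            out[i] = expit(fit.param("psi:b0") + fit.param("psi:b1") * x)
    return out


@dataclass
class ProtocolReport:
    seed: int
    n_removed_missing_mass: int
    global_summary: Optional[dict] = None
    chat: Optional[dict] = None
    lack_of_fit: Optional[bool] = None
    ranking: Optional[list] = None
    selected_structure: Optional[str] = None
    step_up: Optional[list] = None
    final_structure: Optional[str] = None
    coefficients: Optional[list] = None
    process_variance: Optional[dict] = None
    sensitivities: Optional[list] = None
    first_return_curve: Optional[list] = None
    failures: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def render_text(self) -> str:
        out = []
        if self.ranking:
            out.append("Structural model ranking (QAICc):")
            for r in self.ranking:
                mark = "*" if r["label"] == self.selected_structure else " "
                out.append(
                    f" {mark} {r['label']:<42} {r.get('qaicc', r.get('aicc', float('nan'))):10.2f}"
                    f" d={r['delta']:8.2f} k={r['k']:3d} dev={r['deviance']:9.2f}"
                )
        if self.step_up:
            out.append("\nStep-up covariate selection:")
            for s in self.step_up:
                stat = "" if s["statistic"] is None else f" stat={s['statistic']:.2f} p={s['p']:.3g}"
                r2 = "" if s["r2_dev"] is None else f" R2_DEV={s['r2_dev']:.2f}"
                out.append(
                    f"  step {s['step']}: {s['covariate'] or '(base)'}"
                    f" [{s['test'] or '-'}]{stat}{r2} -> "
                    + ("retained" if s["retained"] else "stop")
                )
        if self.sensitivities:
            out.append("\nSensitivities S = beta * phi(1-phi):")
            for row in self.sensitivities:
                out.append("  " + json.dumps(row))
        return "\n".join(out)


def _structure_with(base: ModelStructure, *, psi=None, p=None, phi=None) -> ModelStructure:
    s = base
    if psi is not None:
        toks = psi.split()
        s = replace(s, transition=TransitionSpec(int(toks[0]), toks[1] if len(toks) > 1 else "free"))
    if p is not None:
        s = replace(s, recapture=RecaptureSpec({".": "constant", "T3": "effort", "t": "time"}[p]))
    if phi is not None:
        parsed = parse_label(f"phi({phi}) p(.) psi(4)").survival
        s = replace(s, survival=parsed)
    return s


def run_protocol(dataset: Dataset, config: Optional[ProtocolConfig] = None, seed: int = 0) -> ProtocolReport:
    """Run the full analysis protocol on a validated dataset."""
    config = config or ProtocolConfig()
    dataset, removed = filter_missing_mass(dataset)
    report = ProtocolReport(seed=seed, n_removed_missing_mass=removed)
    rng = np.random.default_rng(seed)

    fits: dict[str, CMRResults] = {}

    def fit_structure(structure: ModelStructure, warm: Optional[CMRResults] = None, vcov=False) -> CMRResults:
        label = structure.label
        if label in fits and not vcov:
            return fits[label]
        model = MultistateCMR(dataset, structure)
        start = None
        if warm is not None:
            start = np.zeros(model.design.k)
            for j, nm in enumerate(model.design.names):
                if nm in warm.names:
                    start[j] = warm.param(nm)
        res = model.fit(
            n_restarts=config.n_restarts,
            seed=int(rng.integers(2**31 - 1)),
            start=start,
            compute_vcov=vcov,
        )
        fits[label] = res
        return res

    # (1) global model
    try:
        global_structure = parse_label(config.global_label)
        global_fit = fit_structure(global_structure, vcov=True)
        report.global_summary = {
            "label": global_fit.structure.label,
            "deviance": global_fit.deviance,
            "k": global_fit.k,
            "aicc": global_fit.aicc,
            "converged": global_fit.converged,
        }
    except EstimationError as exc:
        report.failures.append(f"global fit: {exc}")
        return report

    # (2) median c-hat
    c_hat = config.c_hat
    if c_hat is None:
        try:
            chat = estimate_median_chat(
                global_fit,
                bounds=config.chat_bounds,
                replicates=config.chat_replicates,
                seed=seed,
            )
            c_hat = chat.c_hat
            report.chat = {
                "c_hat": chat.c_hat,
                "se": chat.se,
                "replicates": chat.replicates,
                "n_dropped": chat.n_dropped,
            }
            report.lack_of_fit = chat.lack_of_fit
        except EstimationError as exc:
            report.failures.append(f"median c-hat: {exc}")
            c_hat = 1.0
    else:
        report.chat = {"c_hat": c_hat, "se": None, "replicates": 0, "n_dropped": 0}
        report.lack_of_fit = c_hat > 3.0
    c_hat = max(float(c_hat), 1.0)

    # (3) structural selection: psi, then p, then survival age/time
    current = global_fit.structure
    try:
        for attr, variants in (
            ("psi", config.psi_variants),
            ("p", config.p_variants),
            ("phi", config.age_time_variants),
        ):
            stage = [fit_structure(_structure_with(current, **{attr: v}), warm=fits[current.label]) for v in variants]
            if fits[current.label] not in stage:
                stage.append(fits[current.label])
            table = rank_models(stage, c_hat)
            current = next(f.structure for f in stage if f.structure.label == table.selected_label)
        ranking_all = rank_models(list(fits.values()), c_hat)
        report.ranking = ranking_all.frame.to_dict(orient="records")
        report.selected_structure = current.label
    except (EstimationError, ValueError) as exc:
        report.failures.append(f"structural selection: {exc}")
        report.selected_structure = current.label

    # (4) step-up covariate selection on the winning age structure
    base = replace(
        current,
        survival=SurvivalSpec(current.survival.age_structure, "none", ()),
    )
    annual = config.annual_covariates
    if annual is None:
        avail = () if dataset.year_covariates is None else dataset.year_covariates.available
        annual = tuple(c for c in ANNUAL_CANDIDATES if c in avail and c != "gateway_days")
    try:
        records = step_up_selection(
            dataset,
            base,
            individual_covariates=config.individual_covariates if len(dataset.fledglings) else (),
            annual_covariates=annual,
            c_hat=c_hat,
            r2_threshold=config.r2_threshold,
            alpha=config.alpha,
            forced_scopes=config.forced_scopes,
            n_restarts=config.n_restarts,
            seed=seed,
        )
        report.step_up = selection_records_frame(records).to_dict(orient="records")
        final_label = [r.model_label for r in records if r.retained][-1]
    except (EstimationError, ValueError) as exc:
        report.failures.append(f"step-up: {exc}")
        return report

    # (5) final model with covariance; coefficient verification
    try:
        final_fit = fit_structure(parse_label(final_label), warm=fits.get(final_label), vcov=True)
        final_fit = inflate_by_chat(final_fit, c_hat)
        report.final_structure = final_label
        coefs = []
        for nm in final_fit.names:
            est, lo, hi, excl = verify_coefficient(final_fit, nm)
            coefs.append({"name": nm, "estimate": est, "ci_low": lo, "ci_high": hi, "excludes_zero": excl})
        report.coefficients = coefs
    except EstimationError as exc:
        report.failures.append(f"final fit: {exc}")
        return report

    # (6) derived quantities
    try:
        time_fit = fit_structure(
            replace(base, survival=SurvivalSpec(base.survival.age_structure, "additive", ())),
            warm=fits.get(base.label),
            vcov=True,
        )
        time_fit = inflate_by_chat(time_fit, c_hat)
        pv = {}
        for c in range(base.survival.age_structure.n_classes):
            ests, variances, intervals = annual_survival_estimates(time_fit, c)
            if len(ests) >= 3:
                comp = variance_components(ests, variances)
                pv[f"class{c}"] = {
                    "mean": comp.mean,
                    "sigma_process": comp.sigma_process,
                    "n_years": comp.n_used,
                    "intervals": intervals,
                }
        report.process_variance = pv
    except (EstimationError, ValueError, RuntimeError) as exc:
        report.failures.append(f"variance components: {exc}")

    try:
        covs = [r["covariate"] for r in report.step_up if r["retained"] and r["covariate"]]
        nclass = final_fit.structure.survival.age_structure.n_classes
        report.sensitivities = sensitivity_table(final_fit, range(nclass), covs).to_dict(orient="records")
    except (EstimationError, KeyError) as exc:
        report.failures.append(f"sensitivities: {exc}")

    try:
        report.first_return_curve = cumulative_first_return(psi_curve(final_fit)).tolist()
    except (EstimationError, KeyError, ValueError) as exc:
        report.failures.append(f"first-return curve: {exc}")

    return report
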