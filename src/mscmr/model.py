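"""Maximum-likelihood fitting of multistate capture-mark-recapture models.

The public surface follows the statsmodels idiom: a :class:`MultistateCMR`
model object is built from a :class:`~mscmr.data.Dataset` and a
:class:`~mscmr.structure.ModelStructure`; :meth:`MultistateCMR.fit`
maximizes the exact likelihood by quasi-Newton iteration from several
jittered starts and returns a :class:`CMRResults` carrying the coefficient
estimates, their covariance (inverse observed information), the deviance,
information criteria and a ``summary()`` table.

Overdispersion is handled by the median-c-hat procedure
(:func:`estimate_median_chat`): parametric-bootstrap datasets with known
variance inflation are generated from the fitted model, each is refitted,
and a binary regression of the simulated deviance-c-hat exceeding the
observed one on the true c locates the median.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .data import Dataset
from .likelihood import loglik_batch
from .structure import DesignMap, ModelStructure, build_design, parse_label

__all__ = [
    "MultistateCMR",
    "CMRResults",
    "ChatEstimate",
    "EstimationError",
    "fit_model",
    "information_criteria",
    "inflate_by_chat",
    "deviance_chat",
    "saturated_deviance",
    "estimate_median_chat",
]


class EstimationError(RuntimeError):
    pass


class MultistateCMR:
    """Multistate (unobservable pre-return / observable / dead) CMR model.

    Parameters
    ----------
    dataset : Dataset
        Validated encounter histories plus annual covariates.
    structure : ModelStructure or str
        The (phi, p, psi) specification, or its canonical label.
    """

    def __init__(self, dataset: Dataset, structure: ModelStructure | str):
        if isinstance(structure, str):
            structure = parse_label(structure)
        self.dataset = dataset
        self.structure = structure
        self.design: DesignMap = build_design(structure, dataset)

    @classmethod
    def from_files(cls, inp_path, structure, calendar=None, covariates_path=None) -> "MultistateCMR":
        from .data import StudyCalendar, read_inp, read_year_covariates

        calendar = calendar or StudyCalendar()
        ds = read_inp(inp_path, calendar)
        if covariates_path is not None:
            ds.year_covariates = read_year_covariates(covariates_path, calendar)
        return cls(ds, structure)

    @property
    def k(self) -> int:
        return self.design.k

    @property
    def ess(self) -> int:
        """Effective sample size: number of encounter histories."""
        return len(self.dataset.histories)

    # -- objective ---------------------------------------------------------

    def loglike(self, beta: np.ndarray) -> float:
        return float(loglik_batch(np.atleast_2d(beta), self.design)[0])

    def deviance(self, beta: np.ndarray) -> float:
        return -2.0 * self.loglike(beta)

    def _negll_batch(self, betas: np.ndarray) -> np.ndarray:
        return -loglik_batch(betas, self.design)

    def _value_and_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        k = self.k
        h = 1e-5 * (1.0 + np.abs(beta))
        pts = np.vstack([beta, beta + np.diag(h), beta - np.diag(h)])
        vals = self._negll_batch(pts)
        grad = (vals[1 : k + 1] - vals[k + 1 :]) / (2.0 * h)
        return float(vals[0]), grad

    def _hessian(self, beta: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Central-difference Hessian of the negative log-likelihood."""
        k = self.k
        h = 1e-4 * (1.0 + np.abs(beta))
        pts = [beta]
        for j in range(k):
            e = np.zeros(k)
            e[j] = h[j]
            pts += [beta + e, beta - e]
        pairs = [(j, l) for j in range(k) for l in range(j + 1, k)]
        for j, l in pairs:
            e = np.zeros(k)
            e[j], e[l] = h[j], h[l]
            f = np.zeros(k)
            f[j], f[l] = h[j], -h[l]
            pts += [beta + e, beta - e, beta + f, beta - f]
        pts = np.asarray(pts)
        vals = np.concatenate(
            [self._negll_batch(pts[i : i + chunk]) for i in range(0, len(pts), chunk)]
        )
        f0 = vals[0]
        H = np.zeros((k, k))
        for j in range(k):
            H[j, j] = (vals[1 + 2 * j] - 2 * f0 + vals[2 + 2 * j]) / h[j] ** 2
        base = 1 + 2 * k
        for idx, (j, l) in enumerate(pairs):
            fpp, fmm, fpm, fmp = vals[base + 4 * idx : base + 4 * idx + 4]
            H[j, l] = H[l, j] = (fpp + fmm - fpm - fmp) / (4 * h[j] * h[l])
        return H

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 5,
        tol: float = 1e-5,
        seed: int = 0,
        start: Optional[np.ndarray] = None,
        maxiter: int = 500,
        compute_vcov: bool = True,
    ) -> "CMRResults":
        """Maximize the likelihood from ``n_restarts`` starts, keep the best.

        The first start is the zero vector (or ``start``); the others are
        N(0, 0.5) jitters around it.  ``converged`` requires the relative
        sup-norm of the finite-difference gradient to fall below ``tol``
        and, when requested, an invertible observed information.
        """
        k = self.k
        rng = np.random.default_rng(seed)
        base = np.zeros(k) if start is None else np.asarray(start, dtype=float)
        starts = [base] + [base + rng.normal(0, 0.5, k) for _ in range(max(0, n_restarts - 1))]
        best = None
        n_ok = 0
        for s in starts:
            try:
                res = optimize.minimize(
                    self._value_and_grad,
                    s,
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
                )
            except FloatingPointError:  # pragma: no cover - defensive
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise EstimationError("all optimizer restarts failed")
        beta_hat = best.x
        f, grad = self._value_and_grad(beta_hat)
        grad_norm = float(np.max(np.abs(grad)))
        converged = grad_norm <= tol * max(1.0, abs(f))
        vcov = None
        if compute_vcov:
            H = self._hessian(beta_hat)
            try:
                vcov = np.linalg.inv(H)
                if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                    raise np.linalg.LinAlgError
                vcov = (vcov + vcov.T) / 2.0
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv((H + H.T) / 2.0)
                converged = False
        return CMRResults(
            model=self,
            params=beta_hat,
            vcov_unscaled=vcov,
            llf=-f,
            converged=bool(converged),
            grad_norm=grad_norm,
            n_restarts_used=n_ok,
        )


@dataclass
class CMRResults:
    """Fit results: estimates, uncertainty, information criteria."""

    model: MultistateCMR
    params: np.ndarray
    vcov_unscaled: Optional[np.ndarray]
    llf: float
    converged: bool
    grad_norm: float
    n_restarts_used: int
    c_hat: float = 1.0

    # -- basic accessors ---------------------------------------------------

    @property
    def design(self) -> DesignMap:
        return self.model.design

    @property
    def structure(self) -> ModelStructure:
        return self.model.structure

    @property
    def names(self) -> list[str]:
        return self.design.names

    @property
    def k(self) -> int:
        return self.design.k

    @property
    def ess(self) -> int:
        return self.model.ess

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    def cov_params(self) -> np.ndarray:
        """Coefficient covariance, inflated by c-hat when one is attached."""
        if self.vcov_unscaled is None:
            raise EstimationError("fit was run without covariance computation")
        return self.c_hat * self.vcov_unscaled

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    # -- information criteria ----------------------------------------------

    @property
    def aicc(self) -> float:
        return information_criteria(self)["aicc"]

    @property
    def qaicc(self) -> float:
        return information_criteria(self, self.c_hat)["qaicc"]

    # -- utilities ---------------------------------------------------------

    def param(self, name: str) -> float:
        return float(self.params[self.design.index_of(name)])

    def summary(self) -> str:
        lines = [
            f"Multistate CMR model: {self.structure.label}",
            f"histories: {self.ess}   k: {self.k}   converged: {self.converged}",
            f"log-likelihood: {self.llf:.3f}   deviance: {self.deviance:.3f}",
            f"AICc: {self.aicc:.3f}   c-hat: {self.c_hat:.3f}   QAICc: {self.qaicc:.3f}",
            "",
            f"{'coefficient':<18}{'estimate':>10}{'SE':>9}{'[0.025':>9}{'0.975]':>9}",
        ]
        ci = self.conf_int() if self.vcov_unscaled is not None else None
        for j, nm in enumerate(self.names):
            se = self.bse[j] if ci is not None else float("nan")
            lo, hi = (ci[j] if ci is not None else (float("nan"),) * 2)
            lines.append(f"{nm:<18}{self.params[j]:>10.4f}{se:>9.4f}{lo:>9.3f}{hi:>9.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.label,
            "beta": self.params.tolist(),
            "names": self.names,
            "vcov": None if self.vcov_unscaled is None else self.vcov_unscaled.tolist(),
            "deviance": self.deviance,
            "k": self.k,
            "ess": self.ess,
            "c_hat": self.c_hat,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fit_model(
    structure: ModelStructure | str,
    dataset: Dataset,
    n_restarts: int = 5,
    tol: float = 1e-5,
    seed: int = 0,
    **kwargs,
) -> CMRResults:
    """Functional wrapper: build the model and fit it."""
    return MultistateCMR(dataset, structure).fit(
        n_restarts=n_restarts, tol=tol, seed=seed, **kwargs
    )


def information_criteria(fit: CMRResults, c_hat: Optional[float] = None) -> dict:
    """AICc and QAICc of a fit.

    AICc = dev + 2k + 2k(k+1)/(ess-k-1); QAICc divides the deviance by
    c-hat and charges one extra parameter for estimating it.
    """
    dev, k, ess = fit.deviance, fit.k, fit.ess
    if ess <= k + 1:
        raise EstimationError(f"effective sample size {ess} too small for k={k}")
    aicc = dev + 2 * k + 2 * k * (k + 1) / (ess - k - 1)
    c = 1.0 if c_hat is None else max(float(c_hat), 1.0)
    kq = k + 1
    if ess <= kq + 1:
        raise EstimationError(f"effective sample size {ess} too small for k+1={kq}")
    qaicc = dev / c + 2 * kq + 2 * kq * (kq + 1) / (ess - kq - 1)
    return {"aicc": aicc, "qaicc": qaicc}


def inflate_by_chat(fit: CMRResults, c_hat: float) -> CMRResults:
    """Attach an overdispersion factor: SEs scale by sqrt(c-hat), QAICc is
    used downstream; point estimates are unchanged.  c-hat below 1 clamps
    to 1 (with a warning)."""
    if c_hat < 1.0:
        import warnings

        warnings.warn(f"c_hat {c_hat} < 1 clamped to 1", stacklevel=2)
        c_hat = 1.0
    return replace(fit, c_hat=float(c_hat))


# ---------------------------------------------------------------------------
# median c-hat
# ---------------------------------------------------------------------------


@dataclass
class ChatEstimate:
    c_hat: float
    lower_bound: float
    upper_bound: float
    replicates: int
    se: float
    n_dropped: int = 0

    @property
    def lack_of_fit(self) -> bool:
        """The global model fails when c-hat exceeds 3."""
        return self.c_hat > 3.0


def saturated_deviance(design: DesignMap) -> float:
    """Deviance of the saturated multinomial over (class, cohort, history)
    cells; individual covariates are ignored (a GOF baseline)."""
    from collections import Counter

    cohorts: dict = {}
    for i in range(design.n_animals):
        ck = (bool(design.is_fledgling[i]), int(design.mark_occasion[i]))
        hk = tuple(design.detections[i])
        cohorts.setdefault(ck, Counter())[hk] += 1
    ll = 0.0
    for counts in cohorts.values():
        N = sum(counts.values())
        for n_h in counts.values():
            ll += n_h * math.log(n_h / N)
    return -2.0 * ll


def deviance_chat(fit: CMRResults) -> float:
    """Deviance-based overdispersion: GOF deviance over its df."""
    df = max(fit.ess - fit.k, 1)
    return (fit.deviance - saturated_deviance(fit.design)) / df


def _logistic_crossing(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit P(y=1) = expit(b0 + b1 x); return (-b0/b1, delta-method SE).

    Falls back to linear interpolation of grouped means under separation
    or a non-positive slope.
    """

    def negll(b):
        eta = b[0] + b[1] * x
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    res = optimize.minimize(negll, np.array([0.0, 1.0]), method="Nelder-Mead")
    b0, b1 = res.x
    ok = res.success and b1 > 1e-6
    if ok:
        mu = expit(b0 + b1 * x)
        w = mu * (1 - mu)
        X = np.column_stack([np.ones_like(x), x])
        info = X.T @ (w[:, None] * X)
        try:
            cov = np.linalg.inv(info)
            g = np.array([-1.0 / b1, b0 / b1**2])
            se = float(np.sqrt(g @ cov @ g))
        except np.linalg.LinAlgError:
            se = float("nan")
        return float(-b0 / b1), se
    # fallback: isotonic-ish linear interpolation of per-level means
    xs = np.unique(x)
    means = np.array([y[x == v].mean() for v in xs])
    if means[-1] <= 0.5:
        return float(xs[-1]), float("nan")
    if means[0] >= 0.5:
        return float(xs[0]), float("nan")
    j = int(np.argmax(means >= 0.5))
    x0, x1, m0, m1 = xs[j - 1], xs[j], means[j - 1], means[j]
    if m1 == m0:
        return float(x1), float("nan")
    return float(x0 + (0.5 - m0) * (x1 - x0) / (m1 - m0)), float("nan")


def estimate_median_chat(
    global_fit: CMRResults,
    bounds: tuple[float, float] = (1.0, 4.0),
    replicates: int = 100,
    seed: int = 0,
    grid_points: int = 7,
    n_restarts: int = 1,
) -> ChatEstimate:
    """Simulation-based median estimate of the overdispersion factor c-hat.

    Datasets are simulated from the fitted global model at a grid of true
    c values spanning ``bounds`` (overdispersion injected by cluster-shared
    fates), each is refitted (warm-started at the global MLE) and its
    deviance-c-hat recorded; a logistic regression of the event
    "simulated c-hat exceeds the observed c-hat" on true c is solved for
    the 0.5 crossing, clamped to the bounds.
    """
    from .simulate import simulate_from_results

    if not global_fit.converged:
        raise EstimationError("median c-hat requires a converged global fit")
    lo, hi = bounds
    c_obs = deviance_chat(global_fit)
    grid = np.linspace(lo, hi, grid_points)
    per = [replicates // grid_points] * grid_points
    for i in range(replicates - sum(per)):
        per[i] += 1
    xs: list[float] = []
    ys: list[float] = []
    dropped = 0
    rep_id = 0
    for c_true, m in zip(grid, per):
        for _ in range(m):
            rep_id += 1
            sim = simulate_from_results(
                global_fit, cluster_size=float(c_true), seed=seed * 100003 + rep_id
            )
            model = MultistateCMR(sim, global_fit.structure)
            try:
                refit = model.fit(
                    n_restarts=n_restarts,
                    seed=seed + rep_id,
                    start=global_fit.params,
                    compute_vcov=False,
                )
            except EstimationError:
                dropped += 1
                continue
            if not refit.converged:
                dropped += 1
                continue
            xs.append(float(c_true))
            ys.append(1.0 if deviance_chat(refit) > c_obs else 0.0)
    if dropped > replicates / 2:
        raise EstimationError(f"{dropped}/{replicates} c-hat replicates failed to refit")
    c_hat, se = _logistic_crossing(np.asarray(xs), np.asarray(ys))
    c_hat = float(np.clip(c_hat, lo, hi))
    return ChatEstimate(
        c_hat=c_hat,
        lower_bound=lo,
        upper_bound=hi,
        replicates=replicates,
        se=se,
        n_dropped=dropped,
    )
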