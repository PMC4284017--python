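"""Declarative model structures for survival, recapture and first return.

A :class:`ModelStructure` names the three components of the multistate
model in MARK-style shorthand, e.g. ``phi(a2 a+t) p(T3) psi(4 ln)``:

* ``phi`` — survival: an age-class structure (``a1``/``a2``/``a3``), an
  optional time effect (``t``, ``a+t`` additive or ``a*t`` interactive with
  age class) and covariate terms (``mass`` individual, ``pred`` additive
  with age class, ``pred*a`` interactive).
* ``p`` — recapture of observable birds: ``.`` constant, ``T3`` grouped by
  gateway-reader effort, or ``t`` fully time dependent.  Recapture in the
  unobservable state is structurally zero and never estimated.
* ``psi`` — first return: free age effects up to a maximum age (3/4/5),
  or a 2-parameter ``linear``/``ln`` age trend on the logit scale; the
  probability above the maximum age is fixed to one and the reverse
  transition to zero.

:func:`build_design` turns a structure plus a dataset into the dense
design tensors consumed by the likelihood engine.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import Dataset

__all__ = [
    "AgeClassStructure",
    "SurvivalSpec",
    "RecaptureSpec",
    "TransitionSpec",
    "ModelStructure",
    "DesignMap",
    "SpecificationError",
    "parse_label",
    "build_design",
    "count_parameters",
    "enumerate_candidates",
    "effort_group_of",
]

#: individual-scope covariates (enter the fledgling age class only)
INDIVIDUAL_COVARIATES = frozenset({"mass"})

#: gateway effort thresholds (days of PIT-reader operation)
EFFORT_GROUPS = ("none", "mid", "high")  # 0 days; 1-100; >100


class SpecificationError(ValueError):
    """A model structure that cannot be built on the given dataset."""


def effort_group_of(gateway_days: float) -> str:
    if gateway_days <= 0:
        return "none"
    if gateway_days <= 100:
        return "mid"
    return "high"


@dataclass(frozen=True)
class AgeClassStructure:
    """Age classes for survival: a1 none, a2 fledging year vs older,
    a3 fledging year / second year / thereafter."""

    n_classes: int

    def __post_init__(self) -> None:
        if self.n_classes not in (1, 2, 3):
            raise ValueError("n_classes must be 1, 2 or 3")

    def class_of(self, age: int) -> int:
        """Class index of a fledgling-marked bird at integer age.

        Adults (marked at age 1+, true age unknown) always take the oldest
        class; callers pass a large age for them.
        """
        if self.n_classes == 1:
            return 0
        if self.n_classes == 2:
            return 0 if age <= 0 else 1
        return min(max(age, 0), 2)

    @property
    def label(self) -> str:
        return f"a{self.n_classes}"


@dataclass(frozen=True)
class SurvivalSpec:
    age_structure: AgeClassStructure
    time_effect: str = "none"  # none | additive | interactive
    covariates: tuple[tuple[str, str], ...] = ()  # (name, scope)

    def __post_init__(self) -> None:
        if self.time_effect not in ("none", "additive", "interactive"):
            raise ValueError(f"bad time_effect {self.time_effect!r}")
        if self.time_effect == "interactive" and self.age_structure.n_classes < 2:
            raise SpecificationError("interactive time needs >= 2 age classes")
        for name, scope in self.covariates:
            if scope not in ("individual", "additive", "interactive"):
                raise ValueError(f"bad covariate scope {scope!r}")
            if (name in INDIVIDUAL_COVARIATES) != (scope == "individual"):
                raise SpecificationError(
                    f"covariate {name!r} cannot enter with scope {scope!r}"
                )

    @property
    def label(self) -> str:
        toks = [self.age_structure.label]
        if self.time_effect == "additive":
            toks.append("t" if self.age_structure.n_classes == 1 else "a+t")
        elif self.time_effect == "interactive":
            toks.append("a*t")
        for name, scope in self.covariates:
            toks.append(f"{name}*a" if scope == "interactive" else name)
        return " ".join(toks)


@dataclass(frozen=True)
class RecaptureSpec:
    structure: str = "effort"  # constant | effort | time | fixed
    fixed_value: Optional[float] = None  # only with structure == "fixed"

    def __post_init__(self) -> None:
        if self.structure not in ("constant", "effort", "time", "fixed"):
            raise ValueError(f"bad recapture structure {self.structure!r}")
        if (self.structure == "fixed") != (self.fixed_value is not None):
            raise ValueError("fixed recapture needs (exactly then) a fixed_value")
        if self.fixed_value is not None and not 0 <= self.fixed_value <= 1:
            raise ValueError("fixed recapture value must lie in [0, 1]")

    @property
    def label(self) -> str:
        if self.structure == "fixed":
            return f"={self.fixed_value:g}"
        return {"constant": ".", "effort": "T3", "time": "t"}[self.structure]


@dataclass(frozen=True)
class TransitionSpec:
    max_first_return_age: int = 4
    trend: str = "free"  # free | linear | ln

    def __post_init__(self) -> None:
        # max age 0 means no estimated transition: first return is certain
        # at age 1 (the single-observable-state / CJS reduction)
        if self.max_first_return_age not in (0, 3, 4, 5):
            raise ValueError("max first-return age must be 3, 4 or 5 (0: all fixed)")
        if self.trend not in ("free", "linear", "ln"):
            raise ValueError(f"bad trend {self.trend!r}")
        if self.max_first_return_age == 0 and self.trend != "free":
            raise ValueError("a trend needs estimable transition ages")

    @property
    def label(self) -> str:
        if self.trend == "free":
            return str(self.max_first_return_age)
        return f"{self.max_first_return_age} {self.trend}"


@dataclass(frozen=True)
class ModelStructure:
    survival: SurvivalSpec
    recapture: RecaptureSpec
    transition: TransitionSpec

    @property
    def label(self) -> str:
        return (
            f"phi({self.survival.label}) p({self.recapture.label}) "
            f"psi({self.transition.label})"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_LABEL_RE = re.compile(r"phi\(([^)]*)\)\s+p\(([^)]*)\)\s+psi\(([^)]*)\)\s*$")


def parse_label(label: str) -> ModelStructure:
    """Parse the canonical label notation back into a ModelStructure."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable model label {label!r}")
    phi_s, p_s, psi_s = m.groups()

    toks = phi_s.split()
    if not toks or not re.fullmatch(r"a[123]", toks[0]):
        raise ValueError(f"phi must start with a1/a2/a3 in {label!r}")
    age = AgeClassStructure(int(toks[0][1]))
    time_effect = "none"
    covs: list[tuple[str, str]] = []
    for tok in toks[1:]:
        if tok == "t":
            time_effect = "additive"
        elif tok == "a+t":
            time_effect = "additive"
        elif tok == "a*t":
            time_effect = "interactive"
        elif tok.endswith("*a"):
            covs.append((tok[:-2], "interactive"))
        else:
            scope = "individual" if tok in INDIVIDUAL_COVARIATES else "additive"
            covs.append((tok, scope))
    survival = SurvivalSpec(age, time_effect, tuple(covs))

    p_map = {".": "constant", "T3": "effort", "t": "time"}
    p_tok = p_s.strip()
    if p_tok.startswith("="):
        recapture = RecaptureSpec("fixed", float(p_tok[1:]))
    elif p_tok in p_map:
        recapture = RecaptureSpec(p_map[p_tok])
    else:
        raise ValueError(f"bad p() component in {label!r}")

    psi_toks = psi_s.split()
    max_age = int(psi_toks[0])
    trend = psi_toks[1] if len(psi_toks) > 1 else "free"
    transition = TransitionSpec(max_age, trend)
    return ModelStructure(survival, recapture, transition)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignMap:
    """Dense coefficient-to-real-parameter mapping for one dataset.

    Every estimable real parameter (survival per animal-interval, recapture
    per animal-occasion, first return per animal-interval) maps to one
    logit-linear predictor row over the shared coefficient vector beta;
    fixed parameters (psi above the maximum age, recapture in the
    unobservable state, the reverse transition) map to none and are applied
    as overrides in the likelihood.
    """

    structure: ModelStructure
    names: list[str]
    X_phi: np.ndarray  # (n, T-1, k)
    X_p: np.ndarray  # (n, T, k); row 0 (marking occasion 1) is unused
    X_psi: np.ndarray  # (n, T-1, k)
    psi_fixed_one: np.ndarray  # (n, T-1) bool: first return forced certain
    is_fledgling: np.ndarray  # (n,) bool
    mark_occasion: np.ndarray  # (n,) 1-based
    detections: np.ndarray  # (n, T) int8
    p_fixed: Optional[float] = None  # recapture fixed to this value when set

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_animals(self) -> int:
        return self.X_phi.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.X_p.shape[1]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def stacked_rows(self) -> np.ndarray:
        """All design rows that actually enter the likelihood (for rank checks)."""
        n, T = self.X_p.shape[:2]
        rows = []
        occ = np.arange(1, T + 1)
        for i in range(n):
            m = self.mark_occasion[i]
            rows.append(self.X_phi[i, m - 1 :, :])
            rows.append(self.X_p[i, occ > m, :])
            if self.is_fledgling[i]:
                active = ~self.psi_fixed_one[i, m - 1 :]
                rows.append(self.X_psi[i, m - 1 :, :][active])
        return np.vstack(rows) if rows else np.zeros((0, self.k))

    def numeric_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.stacked_rows()))


def _annual_z(dataset: Dataset, name: str) -> np.ndarray:
    if dataset.year_covariates is None:
        raise SpecificationError(f"dataset has no annual covariates (need {name!r})")
    try:
        return np.asarray(dataset.year_covariates.standardized(name).z)
    except KeyError:
        raise SpecificationError(f"annual covariate {name!r} missing from dataset") from None


def build_design(structure: ModelStructure, dataset: Dataset) -> DesignMap:
    """Build the design tensors for a model structure on a dataset.

    Factors are reference-coded (interval 1 / the first occurring effort
    group as reference where a separate intercept exists); annual covariates
    enter as standardized values; individual mass enters standardized
    against the pooled fledgling mass distribution and only in the
    fledgling age class.
    """
    cal = dataset.calendar
    T = cal.n_occasions
    n = len(dataset.histories)
    surv = structure.survival
    nc = surv.age_structure.n_classes

    names: list[str] = []

    # --- phi block
    phi_cols: list[str] = [f"phi:int:c{j}" for j in range(nc)]
    if surv.time_effect == "additive":
        phi_cols += [f"phi:t{t}" for t in range(2, T)]
    elif surv.time_effect == "interactive":
        phi_cols += [f"phi:c{j}:t{t}" for j in range(nc) for t in range(2, T)]
    for name, scope in surv.covariates:
        if scope == "individual":
            phi_cols.append(f"phi:{name}")
        elif scope == "additive":
            phi_cols.append(f"phi:{name}")
        else:
            phi_cols += [f"phi:{name}:c{j}" for j in range(nc)]
    names += phi_cols

    # --- p block
    if structure.recapture.structure == "fixed":
        p_cols = []
        occ_group = {}
    elif structure.recapture.structure == "constant":
        p_cols = ["p:int"]
        occ_group = {t: "p:int" for t in range(2, T + 1)}
    elif structure.recapture.structure == "time":
        p_cols = [f"p:occ{t}" for t in range(2, T + 1)]
        occ_group = {t: f"p:occ{t}" for t in range(2, T + 1)}
    else:
        if dataset.year_covariates is None or "gateway_days" not in dataset.year_covariates.available:
            raise SpecificationError("effort-grouped p needs the gateway_days covariate")
        gdays = dataset.year_covariates.values("gateway_days")
        occ_to_grp = {t: effort_group_of(gdays[t - 1]) for t in range(2, T + 1)}
        present = [g for g in EFFORT_GROUPS if g in set(occ_to_grp.values())]
        p_cols = [f"p:{g}" for g in present]
        occ_group = {t: f"p:{occ_to_grp[t]}" for t in range(2, T + 1)}
    names += p_cols

    # --- psi block
    trans = structure.transition
    max_age = trans.max_first_return_age
    if max_age == 0:
        psi_cols = []
    elif trans.trend == "free":
        psi_cols = [f"psi:a{a}" for a in range(1, max_age + 1)]
    else:
        psi_cols = ["psi:b0", "psi:b1"]
    names += psi_cols

    k = len(names)
    col = {nm: i for i, nm in enumerate(names)}

    X_phi = np.zeros((n, T - 1, k))
    X_p = np.zeros((n, T, k))
    X_psi = np.zeros((n, T - 1, k))
    psi_fixed_one = np.zeros((n, T - 1), dtype=bool)
    is_fledgling = np.zeros(n, dtype=bool)
    mark = np.zeros(n, dtype=np.int64)
    det = np.zeros((n, T), dtype=np.int8)

    annual_z = {
        name: _annual_z(dataset, name)
        for name, scope in surv.covariates
        if scope != "individual"
    }
    need_mass = any(scope == "individual" for _, scope in surv.covariates)
    mass_std = dataset.mass_standardizer if need_mass else None

    for i, h in enumerate(dataset.histories):
        is_fledgling[i] = h.is_fledgling
        mark[i] = h.mark_occasion
        det[i, :] = h.detections
        for t in range(h.mark_occasion, T):  # interval t: occasion t -> t+1
            it = t - 1
            age = t - h.mark_occasion if h.is_fledgling else 10**6
            c = surv.age_structure.class_of(age)
            X_phi[i, it, col[f"phi:int:c{c}"]] = 1.0
            if surv.time_effect == "additive" and t >= 2:
                X_phi[i, it, col[f"phi:t{t}"]] = 1.0
            elif surv.time_effect == "interactive" and t >= 2:
                X_phi[i, it, col[f"phi:c{c}:t{t}"]] = 1.0
            for name, scope in surv.covariates:
                if scope == "individual":
                    if c == 0 and h.is_fledgling and h.fledging_mass_kg is not None:
                        X_phi[i, it, col[f"phi:{name}"]] = mass_std.standardize_value(
                            h.fledging_mass_kg
                        )
                elif scope == "additive":
                    X_phi[i, it, col[f"phi:{name}"]] = annual_z[name][t - 1]
                else:
                    X_phi[i, it, col[f"phi:{name}:c{c}"]] = annual_z[name][t - 1]
            # first-return transition during interval t (arrival age below)
            if h.is_fledgling:
                a = t + 1 - h.mark_occasion
                if a > max_age:
                    psi_fixed_one[i, it] = True
                elif trans.trend == "free":
                    X_psi[i, it, col[f"psi:a{a}"]] = 1.0
                else:
                    X_psi[i, it, col["psi:b0"]] = 1.0
                    X_psi[i, it, col["psi:b1"]] = float(a) if trans.trend == "linear" else math.log(a)
        if occ_group:
            for t in range(h.mark_occasion + 1, T + 1):
                X_p[i, t - 1, col[occ_group[t]]] = 1.0

    return DesignMap(
        structure=structure,
        names=names,
        X_phi=X_phi,
        X_p=X_p,
        X_psi=X_psi,
        psi_fixed_one=psi_fixed_one,
        is_fledgling=is_fledgling,
        mark_occasion=mark,
        detections=det,
        p_fixed=structure.recapture.fixed_value,
    )


def count_parameters(structure: ModelStructure, dataset: Dataset) -> int:
    """Structural coefficient count k (fixed parameters excluded)."""
    return build_design(structure, dataset).k


def enumerate_candidates(
    age_structures: Sequence[int] = (1, 2, 3),
    time_effects: Sequence[str] = ("none", "additive", "interactive"),
    p_structures: Sequence[str] = ("time", "effort", "constant"),
    psi_max_ages: Sequence[int] = (3, 4, 5),
    psi_trends: Sequence[str] = ("free", "linear", "ln"),
) -> list[ModelStructure]:
    """The structural candidate set: cross of age/time, p and psi variants.

    Deterministic order; structures invalid under their own rules (e.g.
    interactive time with a1) are skipped.
    """
    out: list[ModelStructure] = []
    for na, te, ps, ma, tr in itertools.product(
        age_structures, time_effects, p_structures, psi_max_ages, psi_trends
    ):
        try:
            surv = SurvivalSpec(AgeClassStructure(na), te)
        except SpecificationError:
            continue
        out.append(ModelStructure(surv, RecaptureSpec(ps), TransitionSpec(ma, tr)))
    # a1 additive and a1 "interactive" would collide; dedupe on labels
    seen: set[str] = set()
    unique = []
    for s in out:
        if s.label not in seen:
            seen.add(s.label)
            unique.append(s)
    return unique
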