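"""Exact likelihood of encounter histories under the two-live-state model.

Latent states are *pre-return* (alive, never yet visited the colony since
fledging; detection probability structurally zero), *returned* (alive and
available for detection) and *dead* (absorbing).  Conditional on marking,
each interval applies survival first, then the first-return transition,
then detection at the arrival occasion — the MARK multistate convention.

The workhorse is a forward recursion vectorized over animals and over a
batch of coefficient vectors (the batch axis makes finite-difference
gradients a single array pass).  A brute-force latent-path enumeration is
provided as an independent testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.special import expit

from .data import EncounterHistory
from .structure import DesignMap

__all__ = [
    "RealParameterSet",
    "realize_parameters",
    "realize_arrays",
    "loglik_vector",
    "loglik_batch",
    "individual_loglik",
    "brute_force_loglik",
    "dataset_loglik",
    "dataset_deviance",
]

_TINY = 1e-300


@dataclass
class RealParameterSet:
    """Interval/occasion-resolved real parameters for one animal.

    ``phi[t-1]`` is survival over interval t (occasion t -> t+1);
    ``p[t-1]`` is detection at occasion t in the returned state (entry 0 is
    unused: occasion 1 has no recapture); ``psi_by_age[a]`` is the
    first-return probability at arrival age a (1 beyond the maximum age).
    """

    phi: np.ndarray
    p: np.ndarray
    psi_by_age: dict[int, float]
    mark_occasion: int
    is_fledgling: bool

    def psi_for_interval(self, t: int) -> float:
        """First-return probability during interval t (arrival occasion t+1)."""
        if not self.is_fledgling:
            return 0.0
        age = t + 1 - self.mark_occasion
        return self.psi_by_age.get(age, 1.0)

    def validate(self) -> None:
        for arrname, arr in (("phi", self.phi), ("p", self.p)):
            a = np.asarray(arr, dtype=float)
            if np.any((a < 0) | (a > 1)):
                raise ValueError(f"{arrname} outside [0, 1]")
        for a, v in self.psi_by_age.items():
            if not 0 <= v <= 1:
                raise ValueError(f"psi[{a}] outside [0, 1]")


def realize_arrays(
    beta: np.ndarray, design: DesignMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-logit real parameters for a batch of coefficient vectors.

    ``beta`` has shape (k,) or (B, k); returns (Phi, P, Psi) with leading
    batch axis, shapes (B, n, T-1), (B, n, T), (B, n, T-1).  Fixed
    overrides (psi = 1 above the maximum first-return age) are applied
    after link inversion.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if beta.shape[1] != design.k:
        raise ValueError(f"beta length {beta.shape[1]} != design k {design.k}")
    n, Tm1, k = design.X_phi.shape

    def lin(X: np.ndarray) -> np.ndarray:
        flat = X.reshape(-1, k) @ beta.T  # (n*T, B)
        return np.moveaxis(flat.reshape(X.shape[0], X.shape[1], -1), 2, 0)

    Phi = expit(lin(design.X_phi))
    P = expit(lin(design.X_p))
    if design.p_fixed is not None:
        P[:] = design.p_fixed
    Psi = expit(lin(design.X_psi))
    Psi[:, design.psi_fixed_one] = 1.0
    Psi[:, ~design.is_fledgling, :] = 0.0
    return Phi, P, Psi


def realize_parameters(
    beta: np.ndarray, design: DesignMap, animal_index: int
) -> RealParameterSet:
    """Real parameters for one animal of the design's dataset."""
    Phi, P, Psi = realize_arrays(beta, design)
    i = animal_index
    T = design.n_occasions
    m = int(design.mark_occasion[i])
    psi_by_age = {}
    if design.is_fledgling[i]:
        for t in range(m, T):
            a = t + 1 - m
            psi_by_age[a] = float(Psi[0, i, t - 1])
    return RealParameterSet(
        phi=Phi[0, i],
        p=P[0, i],
        psi_by_age=psi_by_age,
        mark_occasion=m,
        is_fledgling=bool(design.is_fledgling[i]),
    )


def _forward(
    Phi: np.ndarray,
    P: np.ndarray,
    Psi: np.ndarray,
    det: np.ndarray,
    mark: np.ndarray,
    is_fledgling: np.ndarray,
) -> np.ndarray:
    """Forward recursion; returns per-animal log-likelihoods (B, n)."""
    B, n, T = P.shape
    a_pre = np.broadcast_to(is_fledgling.astype(float), (B, n)).copy()
    a_ret = 1.0 - a_pre
    a_dead = np.zeros((B, n))
    for t in range(1, T):  # interval t: occasion t -> t+1 (0-based idx t-1)
        active = mark <= t
        if not active.any():
            continue
        phi_t = Phi[:, :, t - 1]
        psi_t = Psi[:, :, t - 1]
        p_next = P[:, :, t]
        y = det[:, t]  # detection at occasion t+1
        sp = a_pre * phi_t
        n_pre = sp * (1.0 - psi_t)
        n_ret = sp * psi_t + a_ret * phi_t
        n_dead = a_dead + (a_pre + a_ret) * (1.0 - phi_t)
        not_det = (y == 0).astype(float)
        obs_ret = np.where(y == 1, p_next, 1.0 - p_next)
        n_pre *= not_det
        n_dead *= not_det
        n_ret *= obs_ret
        a_pre = np.where(active, n_pre, a_pre)
        a_ret = np.where(active, n_ret, a_ret)
        a_dead = np.where(active, n_dead, a_dead)
    return np.log(np.maximum(a_pre + a_ret + a_dead, _TINY))


def loglik_batch(beta: np.ndarray, design: DesignMap) -> np.ndarray:
    """Total dataset log-likelihood for a (B, k) batch of coefficients."""
    Phi, P, Psi = realize_arrays(beta, design)
    ll = _forward(Phi, P, Psi, design.detections, design.mark_occasion, design.is_fledgling)
    return ll.sum(axis=1)


def loglik_vector(beta: np.ndarray, design: DesignMap) -> np.ndarray:
    """Per-animal log-likelihoods at a single coefficient vector."""
    Phi, P, Psi = realize_arrays(beta, design)
    return _forward(Phi, P, Psi, design.detections, design.mark_occasion, design.is_fledgling)[0]


def dataset_loglik(beta: np.ndarray, design: DesignMap) -> float:
    return float(loglik_batch(np.atleast_2d(beta), design)[0])


def dataset_deviance(beta: np.ndarray, design: DesignMap) -> float:
    """-2 x total log-likelihood (not relative to a saturated model)."""
    return -2.0 * dataset_loglik(beta, design)


def individual_loglik(animal: EncounterHistory, params: RealParameterSet) -> float:
    """Forward-recursion log-likelihood of one history given real parameters.

    Conditions on marking: fledglings start in pre-return, adults in
    returned; the marking detection itself carries no contribution.
    """
    params.validate()
    T = len(animal.detections)
    m = animal.mark_occasion
    a_pre = 1.0 if animal.is_fledgling else 0.0
    a_ret = 1.0 - a_pre
    a_dead = 0.0
    for t in range(m, T):
        phi = float(params.phi[t - 1])
        psi = params.psi_for_interval(t)
        p = float(params.p[t])
        y = animal.detections[t]
        sp = a_pre * phi
        n_pre = sp * (1.0 - psi)
        n_ret = sp * psi + a_ret * phi
        n_dead = a_dead + (a_pre + a_ret) * (1.0 - phi)
        if y == 1:
            a_pre, a_ret, a_dead = 0.0, n_ret * p, 0.0
        else:
            a_pre, a_ret, a_dead = n_pre, n_ret * (1.0 - p), n_dead
    return float(np.log(max(a_pre + a_ret + a_dead, _TINY)))


_PRE, _RET, _DEAD = 0, 1, 2


def brute_force_loglik(animal: EncounterHistory, params: RealParameterSet) -> float:
    """Enumeration oracle: sum the probability of every latent state path.

    Tractable only for short post-marking spans (refuses beyond 12
    occasions); intended for tests, never for fitting.
    """
    params.validate()
    T = len(animal.detections)
    m = animal.mark_occasion
    span = T - m
    if span > 12:
        raise ValueError("history too long for enumeration (span > 12)")
    start = _PRE if animal.is_fledgling else _RET
    total = 0.0
    # paths over occasions m+1 .. T
    for path in np.ndindex(*([3] * span)):
        prob = 1.0
        prev = start
        for j, state in enumerate(path):
            t = m + j  # interval t: occasion t -> t+1
            phi = float(params.phi[t - 1])
            psi = params.psi_for_interval(t)
            p = float(params.p[t])
            # transition prev -> state
            if prev == _DEAD:
                tp = 1.0 if state == _DEAD else 0.0
            elif prev == _PRE:
                tp = {_PRE: phi * (1 - psi), _RET: phi * psi, _DEAD: 1 - phi}[state]
            else:
                tp = {_PRE: 0.0, _RET: phi, _DEAD: 1 - phi}[state]
            # emission at occasion t+1
            y = animal.detections[t]
            if state == _RET:
                em = p if y == 1 else 1 - p
            else:
                em = 0.0 if y == 1 else 1.0
            prob *= tp * em
            if prob == 0.0:
                break
            prev = state
        total += prob
    return float(np.log(max(total, _TINY)))
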