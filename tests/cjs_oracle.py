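"""Independent Cormack-Jolly-Seber oracle built on m-array sufficient
statistics (never touches the package's forward recursion)."""

import numpy as np
from scipy import optimize
from scipy.special import expit, logit


def m_array(histories: list[tuple[int, ...]]) -> tuple[np.ndarray, np.ndarray]:
    """Releases-by-next-recapture counts.

    Returns (M, R): M[i, j] = number of animals released at occasion i+1
    next recaptured at occasion j+1; R[i] = releases at occasion i+1.
    """
    T = len(histories[0])
    M = np.zeros((T - 1, T), dtype=np.int64)
    R = np.zeros(T - 1, dtype=np.int64)
    for h in histories:
        seen = [t for t, d in enumerate(h) if d == 1]
        for a, b in zip(seen, seen[1:]):
            R[a] += 1
            M[a, b] += 1
        if seen[-1] < T - 1:
            R[seen[-1]] += 1
    return M, R


def negll_constant(phi: float, p: float, M: np.ndarray, R: np.ndarray) -> float:
    """Multinomial negative log-likelihood for constant-(phi, p) CJS."""
    T = M.shape[1]
    ll = 0.0
    for i in range(T - 1):
        if R[i] == 0:
            continue
        probs = np.zeros(T)
        for j in range(i + 1, T):
            probs[j] = phi ** (j - i) * p * (1 - p) ** (j - i - 1)
        chi = 1.0 - probs.sum()
        recaptured = M[i].sum()
        with np.errstate(divide="ignore"):
            ll += np.sum(M[i, i + 1 :] * np.log(np.maximum(probs[i + 1 :], 1e-300)))
            ll += (R[i] - recaptured) * np.log(max(chi, 1e-300))
    return -ll


def fit_cjs_constant(histories: list[tuple[int, ...]]) -> tuple[float, float]:
    """Grid scan plus high-precision polish of the constant CJS MLE."""
    M, R = m_array(histories)

    def f(x):
        return negll_constant(float(expit(x[0])), float(expit(x[1])), M, R)

    grid = np.linspace(0.05, 0.95, 19)
    best = min(
        ((f([logit(a), logit(b)]), (a, b)) for a in grid for b in grid),
        key=lambda t: t[0],
    )
    # Nelder-Mead can stall on a collapsed simplex; several starts, each
    # polished by a restarted run, make the oracle reliably sharp
    starts = [np.array([logit(best[1][0]), logit(best[1][1])]), np.zeros(2)]
    best_res = None
    for x0 in starts:
        res = x0
        for _ in range(2):
            res = optimize.minimize(
                f, res, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000, "maxfev": 5000},
            ).x
        if best_res is None or f(res) < f(best_res):
            best_res = res
    return float(expit(best_res[0])), float(expit(best_res[1]))
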