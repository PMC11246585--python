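"""Multi-component REML: Average-Information updates with an EM fallback.

Model: y = 1 mu + sum_s g_s + e, g_s ~ N(0, G_s sigma_s^2), e ~ N(0, I sigma_e^2).
The restricted likelihood profiles out the intercept.  Fitting runs the AI
(Newton-type) algorithm — with one opening EM step for stability and
step-halving when a proposal would decrease the likelihood — and restarts
with pure EM-REML (capped at 500 iterations) if AI fails or stalls, recording
which path succeeded.  Variance components are kept non-negative by projecting
updates onto a small positive floor.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from .grm import GrmSet


@dataclasses.dataclass
class GremlFit:
    """Converged (or flagged) variance-component estimates."""

    variances: dict[str, float]  # per-group sigma_s^2
    sigma_e2: float
    shares: dict[str, float]  # percent of sigma_g^2 per group
    loglik: float
    loglik_trace: list[float]
    converged: bool
    algorithm: str  # "AI" or "AI->EM"
    n_iter_ai: int
    n_iter_em: int

    @property
    def sigma_g2(self) -> float:
        return sum(self.variances.values())

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else float("nan")


class _RemlWork:
    """Per-iteration REML quantities for a fixed component set.

    Components are the K GRMs plus an implicit identity for the residual;
    ``theta`` stacks (sigma_1^2, ..., sigma_K^2, sigma_e^2).
    """

    def __init__(self, y: np.ndarray, grms: list[np.ndarray]):
        self.y = np.asarray(y, dtype=np.float64)
        self.n = self.y.shape[0]
        self.grms = grms
        self.K = len(grms)
        self.ones = np.ones(self.n)

    def v_matrix(self, theta: np.ndarray) -> np.ndarray:
        V = np.eye(self.n) * theta[-1]
        for k, G in enumerate(self.grms):
            V += theta[k] * G
        return V

    def quantities(self, theta: np.ndarray):
        """Return (loglik, P, Py) or raise LinAlgError if V is not PD."""
        V = self.v_matrix(theta)
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(self.n), check_finite=False)
        u = Vinv @ self.ones
        s = float(self.ones @ u)
        P = Vinv - np.outer(u, u) / s
        Py = P @ self.y
        ll = -0.5 * (logdet_v + np.log(s) + float(self.y @ Py))
        return ll, P, Py

    def loglik(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood via vector solves (no full inverse)."""
        V = self.v_matrix(theta)
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Viy = linalg.cho_solve((c, low), self.y, check_finite=False)
        Vi1 = linalg.cho_solve((c, low), self.ones, check_finite=False)
        s = float(self.ones @ Vi1)
        yPy = float(self.y @ Viy) - float(self.ones @ Viy) ** 2 / s
        return -0.5 * (logdet_v + np.log(s) + yPy)

    def gradient_and_ai(self, theta: np.ndarray):
        """REML gradient and average-information matrix over all components."""
        ll, P, Py = self.quantities(theta)
        K1 = self.K + 1
        grad = np.empty(K1)
        a = np.empty((K1, self.n))  # a_k = G_k P y
        for k in range(self.K):
            G = self.grms[k]
            grad[k] = -0.5 * (float(np.sum(P * G)) - float(Py @ G @ Py))
            a[k] = G @ Py
        grad[-1] = -0.5 * (float(np.trace(P)) - float(Py @ Py))
        a[-1] = Py
        AI = 0.5 * (a @ P @ a.T)
        return ll, grad, AI


def reml_loglik(
    y: np.ndarray,
    grms: GrmSet | list[np.ndarray],
    variances: np.ndarray | list[float],
    sigma_e2: float | None = None,
) -> float:
    """Restricted log-likelihood (intercept profiled out, up to a constant).

    ``variances`` holds the per-GRM components; the residual variance comes
    last if ``sigma_e2`` is None.
    """
    mats = list(grms.matrices.values()) if isinstance(grms, GrmSet) else list(grms)
    theta = np.asarray(list(variances) + ([sigma_e2] if sigma_e2 is not None else []), dtype=float)
    if theta.size != len(mats) + 1:
        raise ValueError("need one variance per GRM plus the residual variance")
    work = _RemlWork(y, mats)
    try:
        return work.loglik(theta)
    except linalg.LinAlgError as err:
        raise ValueError(f"V not positive definite at variances {theta}") from err


def ai_reml_step(
    theta: np.ndarray,
    y: np.ndarray,
    grms: list[np.ndarray],
    floor: float = 0.0,
    max_halvings: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One AI update with step-halving; returns (theta_new, AI, loglik_at_theta).

    Raises ``np.linalg.LinAlgError`` if the AI matrix is singular (callers
    fall back to EM).
    """
    work = _RemlWork(y, grms)
    ll0, grad, AI = work.gradient_and_ai(theta)
    delta = np.linalg.solve(AI, grad)
    step = 1.0
    for _ in range(max_halvings + 1):
        cand = np.maximum(theta + step * delta, floor)
        try:
            ll1 = work.loglik(cand)
        except linalg.LinAlgError:
            step *= 0.5
            continue
        if ll1 >= ll0 - 1e-10:
            return cand, AI, ll0
        step *= 0.5
    return np.maximum(theta, floor), AI, ll0  # no improving step found


def em_reml_step(theta: np.ndarray, y: np.ndarray, grms: list[np.ndarray],
                 floor: float = 0.0) -> np.ndarray:
    """Classic EM-REML update, monotone in the restricted likelihood:
    sigma_k^2 <- sigma_k^2 + sigma_k^4 (y'P G_k P y - tr(P G_k)) / n."""
    work = _RemlWork(y, grms)
    _, P, Py = work.quantities(theta)
    n = work.n
    new = np.empty_like(theta)
    for k in range(work.K):
        G = grms[k]
        new[k] = theta[k] + theta[k] ** 2 * (float(Py @ G @ Py) - float(np.sum(P * G))) / n
    new[-1] = theta[-1] + theta[-1] ** 2 * (float(Py @ Py) - float(np.trace(P))) / n
    return np.maximum(new, floor)


def fit_greml(
    y: np.ndarray,
    grms: GrmSet | list[np.ndarray],
    names: list[str] | None = None,
    max_ai: int = 100,
    max_em: int = 500,
    tol: float = 1e-4,
    floor_frac: float = 1e-6,
) -> GremlFit:
    """Fit the multi-component model; never raises on non-convergence.

    AI-REML runs first (opening EM step, then AI updates until the relative
    log-likelihood change drops below ``tol``); on AI failure or stalling the
    fit restarts with EM-REML for up to ``max_em`` iterations.  A fit that
    still has not converged is returned with ``converged=False`` so the
    evaluation layer can tally it.
    """
    if isinstance(grms, GrmSet):
        names = grms.names
        mats = [grms.matrices[n] for n in names]
    else:
        mats = list(grms)
        names = names or [f"g{k}" for k in range(len(mats))]
    if len(mats) < 1:
        raise ValueError("need at least one GRM plus the residual")
    y = np.asarray(y, dtype=np.float64)
    vary = float(y.var())
    floor = floor_frac * vary
    K1 = len(mats) + 1
    theta0 = np.full(K1, vary / K1)

    work = _RemlWork(y, mats)

    def run_ai() -> tuple[np.ndarray, list[float], bool, int]:
        theta = theta0.copy()
        trace: list[float] = []
        theta = em_reml_step(theta, y, mats, floor=floor)  # stabilizing opener
        prev_ll = None
        for it in range(1, max_ai + 1):
            theta_new, _, ll = ai_reml_step(theta, y, mats, floor=floor)
            trace.append(ll)
            if np.array_equal(theta_new, np.maximum(theta, floor)):
                # AI found no improving step (common at the variance floor,
                # where the Newton direction points outside the feasible
                # region).  A zero step must not masquerade as convergence:
                # rescue with one monotone EM step and declare convergence
                # only if EM confirms stationarity.
                theta_em = em_reml_step(theta, y, mats, floor=floor)
                ll_em = work.loglik(theta_em)
                trace.append(ll_em)
                if abs(ll_em - ll) / max(1.0, abs(ll)) < tol:
                    return theta_em, trace, True, it
                prev_ll = ll_em
                theta = theta_em
                continue
            if prev_ll is not None and abs(ll - prev_ll) / max(1.0, abs(prev_ll)) < tol:
                return theta, trace, True, it
            prev_ll = ll
            theta = theta_new
        return theta, trace, False, max_ai

    def run_em() -> tuple[np.ndarray, list[float], bool, int]:
        theta = theta0.copy()
        trace: list[float] = []
        prev_ll = None
        for it in range(1, max_em + 1):
            ll = work.loglik(theta)
            trace.append(ll)
            if prev_ll is not None and abs(ll - prev_ll) / max(1.0, abs(prev_ll)) < tol:
                return theta, trace, True, it
            prev_ll = ll
            theta = em_reml_step(theta, y, mats, floor=floor)
        return theta, trace, False, max_em

    algorithm = "AI"
    n_em = 0
    try:
        theta, trace, converged, n_ai = run_ai()
    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
        theta, trace, converged, n_ai = theta0, [], False, 0
    if not converged:
        algorithm = "AI->EM"
        try:
            theta, em_trace, converged, n_em = run_em()
            trace = trace + em_trace
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            converged = False

    try:
        final_ll = work.loglik(theta)
    except linalg.LinAlgError:
        final_ll = float("nan")
    variances = {n: float(v) for n, v in zip(names, theta[:-1])}
    sigma_g2 = float(np.sum(theta[:-1]))
    shares = {
        n: (100.0 * v / sigma_g2 if sigma_g2 > 0 else float("nan"))
        for n, v in variances.items()
    }
    return GremlFit(
        variances=variances,
        sigma_e2=float(theta[-1]),
        shares=shares,
        loglik=final_ll,
        loglik_trace=trace,
        converged=converged,
        algorithm=algorithm,
        n_iter_ai=n_ai,
        n_iter_em=n_em,
    )
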