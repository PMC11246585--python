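"""BayesRR-RC: annotation-stratified spike-plus-Gaussian-mixture regression.

Marker effects in annotation group s follow
``pi_0s delta_0 + sum_l pi_ls N(0, c_l sigma_s^2)`` with a shared scale grid
``c = (0.0001, 0.001, 0.01)`` multiplying the group variance sigma_s^2.
All conditionals are conjugate: categorical indicator and Normal effect per
variant (the spike handled analytically, no pseudo-draws at zero), Dirichlet
mixture proportions per group, scaled-inverse-chi^2 group and error
variances, Normal intercept.  The residual and per-group genetic-value
vectors are maintained incrementally after every accepted effect change.

Reported %SNP-heritability shares are computed from per-draw genetic-value
variances Var(X_s beta_s) rather than from sigma_s^2 alone, because the two
differ under LD between markers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit

from .annotate import Partition


@dataclasses.dataclass
class MixturePrior:
    """Mixture structure and hyper-parameters of the sampler.

    ``scales`` multiply the per-group variance sigma_s^2 to give the mixture
    component variances; ``pi_init`` is the starting (spike, components...)
    probability vector per group, updated by a symmetric Dirichlet(1)
    conditional unless ``fix_pi``.  ``nu0``/``s0_frac`` parameterize the weak
    scaled-inverse-chi^2 priors (scale = ``s0_frac * var(y)``).
    """

    scales: tuple[float, ...] = (0.0001, 0.001, 0.01)
    pi_init: tuple[float, ...] = (0.95, 0.02, 0.02, 0.01)
    nu0: float = 4.0
    s0_frac: float = 0.5
    fix_pi: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("mixture scales must be positive and strictly increasing")
        p = np.asarray(self.pi_init, dtype=float)
        if p.size != s.size + 1 or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ValueError("pi_init must have L+1 non-negative entries summing to 1")

    @property
    def n_components(self) -> int:
        return len(self.scales)


@dataclasses.dataclass
class ChainState:
    """Stored Gibbs chain: full-length scalar/group traces plus final state."""

    group_names: list[str]
    n_iter: int
    burn_in: int
    sigma_s2: np.ndarray  # (n_iter, S)
    sigma_e2: np.ndarray  # (n_iter,)
    mu: np.ndarray  # (n_iter,)
    gvar: np.ndarray  # (n_iter, S) per-group genetic-value variance
    nonspike_kept: np.ndarray  # (m,) kept-draw counts of non-spike indicators
    online_share_mean: np.ndarray  # (S,) running mean of per-draw shares
    beta: np.ndarray  # final effects (m,)
    comp: np.ndarray  # final indicators (m,)
    residual: np.ndarray  # final maintained residual
    mu_final: float

    @property
    def n_kept(self) -> int:
        return self.n_iter - self.burn_in

    def kept_shares(self) -> np.ndarray:
        """(n_kept, S) per-draw %SNP-heritability shares from stored draws."""
        g = self.gvar[self.burn_in:]
        return 100.0 * g / g.sum(axis=1, keepdims=True)


@dataclasses.dataclass
class PosteriorSummary:
    """Post-burn-in posterior summaries mirroring the GREML fit fields."""

    shares: dict[str, float]  # posterior-mean %h2 per group
    share_sd: dict[str, float]
    share_ci: dict[str, tuple[float, float]]  # 2.5/97.5% quantiles
    variances: dict[str, float]  # posterior-mean sigma_s^2
    sigma_e2: float
    h2: float
    pip: np.ndarray
    chain: ChainState


@njit(cache=True)
def _run_chain(
    y, Xt, xtx, group, S, cvec, pi, fix_pi, sigma_s2_init, sigma_e2_init, nu0, s0_g, s0_e,
    n_iter, burn_in, seed,
    tr_sigma_s2, tr_sigma_e2, tr_mu, tr_gvar, nonspike_kept, share_mean,
    beta, comp,
):
    np.random.seed(seed)
    m, n = Xt.shape
    L = cvec.shape[0]
    sigma_s2 = sigma_s2_init.copy()
    sigma_e2 = sigma_e2_init
    mu = 0.0
    r = y.copy()
    gmat = np.zeros((S, n))
    logw = np.empty(L + 1)
    counts = np.zeros((S, L + 1))
    kept = 0

    for it in range(n_iter):
        order = np.random.permutation(m)
        for jj in range(m):
            j = order[jj]
            s = group[j]
            bj = beta[j]
            rhs = np.dot(Xt[j], r) + xtx[j] * bj
            logw[0] = np.log(max(pi[s, 0], 1e-300))
            for l in range(L):
                om = cvec[l] * sigma_s2[s]
                d = xtx[j] + sigma_e2 / om
                logw[l + 1] = (
                    np.log(max(pi[s, l + 1], 1e-300))
                    - 0.5 * np.log1p(xtx[j] * om / sigma_e2)
                    + rhs * rhs / (2.0 * sigma_e2 * d)
                )
            mx = logw[0]
            for l in range(1, L + 1):
                if logw[l] > mx:
                    mx = logw[l]
            tot = 0.0
            for l in range(L + 1):
                logw[l] = np.exp(logw[l] - mx)
                tot += logw[l]
            u = np.random.random() * tot
            new_c = L
            acc = 0.0
            for l in range(L + 1):
                acc += logw[l]
                if u <= acc:
                    new_c = l
                    break
            if new_c == 0:
                b_new = 0.0
            else:
                om = cvec[new_c - 1] * sigma_s2[s]
                d = xtx[j] + sigma_e2 / om
                b_new = rhs / d + np.random.standard_normal() * np.sqrt(sigma_e2 / d)
            if b_new != bj:
                diff = bj - b_new
                for i in range(n):
                    r[i] += Xt[j, i] * diff
                    gmat[s, i] -= Xt[j, i] * diff
            beta[j] = b_new
            comp[j] = new_c

        # intercept
        rsum = 0.0
        for i in range(n):
            rsum += r[i]
        mu_new = (rsum / n + mu) + np.random.standard_normal() * np.sqrt(sigma_e2 / n)
        shift = mu - mu_new
        for i in range(n):
            r[i] += shift
        mu = mu_new

        # mixture proportions and group variances
        counts[:, :] = 0.0
        ss = np.zeros(S)
        for j in range(m):
            counts[group[j], comp[j]] += 1.0
            if comp[j] > 0:
                ss[group[j]] += beta[j] * beta[j] / cvec[comp[j] - 1]
        if not fix_pi:
            for s in range(S):
                tot = 0.0
                for l in range(L + 1):
                    g = np.random.gamma(1.0 + counts[s, l], 1.0)
                    pi[s, l] = g
                    tot += g
                for l in range(L + 1):
                    pi[s, l] /= tot
        for s in range(S):
            k_s = 0.0
            for l in range(1, L + 1):
                k_s += counts[s, l]
            df = nu0 + k_s
            sigma_s2[s] = max((nu0 * s0_g[s] + ss[s]) / np.random.chisquare(df), 1e-12)

        # error variance
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        sigma_e2 = (nu0 * s0_e + rss) / np.random.chisquare(nu0 + n)

        # record
        tr_sigma_e2[it] = sigma_e2
        tr_mu[it] = mu
        gtot = 0.0
        for s in range(S):
            tr_sigma_s2[it, s] = sigma_s2[s]
            gm = 0.0
            for i in range(n):
                gm += gmat[s, i]
            gm /= n
            v = 0.0
            for i in range(n):
                dv = gmat[s, i] - gm
                v += dv * dv
            v /= n
            tr_gvar[it, s] = v
            gtot += v
        if it >= burn_in:
            kept += 1
            for j in range(m):
                if comp[j] > 0:
                    nonspike_kept[j] += 1
            if gtot > 0:
                for s in range(S):
                    share = 100.0 * tr_gvar[it, s] / gtot
                    share_mean[s] += (share - share_mean[s]) / kept
    return r, mu


def gibbs_fit(
    y: np.ndarray,
    genotypes: np.ndarray,
    groups: Partition,
    prior: MixturePrior | None = None,
    n_iter: int = 5000,
    burn_in: int = 2000,
    seed: int = 0,
) -> PosteriorSummary:
    """Run the Gibbs sampler and summarize the post-burn-in draws.

    ``genotypes`` is an individuals x variants dosage (or already
    centered/scaled) matrix; columns are standardized here and monomorphic
    columns are excluded from sampling.  ``groups`` assigns every variant to
    one annotation group.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    prior = prior or MixturePrior()
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(genotypes, dtype=np.float64)
    n, m = X.shape
    if y.shape[0] != n:
        raise ValueError("phenotype / genotype dimension mismatch")

    group_idx = np.full(m, -1, dtype=np.int64)
    for g_i, idx in enumerate(groups.groups):
        group_idx[idx] = g_i
    if np.any(group_idx < 0):
        raise ValueError("partition does not cover all genotype columns")
    S = len(groups.groups)

    sd = X.std(axis=0)
    poly = sd > 0
    Xs = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
    Xt = np.ascontiguousarray(Xs.T)
    xtx = np.einsum("ji,ji->j", Xt, Xt)
    grp = group_idx[poly]
    m_used = Xt.shape[0]

    vary = float(y.var())
    L = prior.n_components
    pi = np.tile(np.asarray(prior.pi_init, dtype=float), (S, 1))
    cvec = np.asarray(prior.scales, dtype=float)
    s0_g = np.full(S, prior.s0_frac * vary / S)
    sigma_s2_init = np.full(S, vary / S)

    tr_sigma_s2 = np.zeros((n_iter, S))
    tr_sigma_e2 = np.zeros(n_iter)
    tr_mu = np.zeros(n_iter)
    tr_gvar = np.zeros((n_iter, S))
    nonspike_kept = np.zeros(m_used, dtype=np.int64)
    share_mean = np.zeros(S)
    beta = np.zeros(m_used)
    comp = np.zeros(m_used, dtype=np.int64)

    resid, mu_final = _run_chain(
        y, Xt, xtx, grp, S, cvec, pi, prior.fix_pi,
        sigma_s2_init, 0.5 * vary if vary > 0 else 1.0, prior.nu0, s0_g,
        prior.s0_frac * vary if vary > 0 else 1.0,
        n_iter, burn_in, seed,
        tr_sigma_s2, tr_sigma_e2, tr_mu, tr_gvar, nonspike_kept, share_mean,
        beta, comp,
    )

    pip = np.zeros(m)
    pip[poly] = nonspike_kept / (n_iter - burn_in)
    beta_full = np.zeros(m)
    beta_full[poly] = beta
    comp_full = np.zeros(m, dtype=np.int64)
    comp_full[poly] = comp

    chain = ChainState(
        group_names=list(groups.names),
        n_iter=n_iter,
        burn_in=burn_in,
        sigma_s2=tr_sigma_s2,
        sigma_e2=tr_sigma_e2,
        mu=tr_mu,
        gvar=tr_gvar,
        nonspike_kept=nonspike_kept,
        online_share_mean=share_mean,
        beta=beta_full,
        comp=comp_full,
        residual=resid,
        mu_final=float(mu_final),
    )
    return summarize_chain(chain, pip=pip)


def summarize_chain(chain: ChainState, pip: np.ndarray | None = None) -> PosteriorSummary:
    shares = chain.kept_shares()
    names = chain.group_names
    kept = slice(chain.burn_in, chain.n_iter)
    g_mean = chain.gvar[kept].sum(axis=1).mean()
    e_mean = chain.sigma_e2[kept].mean()
    return PosteriorSummary(
        shares={n: float(v) for n, v in zip(names, shares.mean(axis=0))},
        share_sd={n: float(v) for n, v in zip(names, shares.std(axis=0))},
        share_ci={
            n: (float(lo), float(hi))
            for n, lo, hi in zip(
                names,
                np.quantile(shares, 0.025, axis=0),
                np.quantile(shares, 0.975, axis=0),
            )
        },
        variances={n: float(v) for n, v in zip(names, chain.sigma_s2[kept].mean(axis=0))},
        sigma_e2=float(e_mean),
        h2=float(g_mean / (g_mean + e_mean)),
        pip=pip if pip is not None else chain.nonspike_kept / chain.n_kept,
        chain=chain,
    )


def pip_and_shares(chain: ChainState):
    """Posterior inclusion probabilities and per-group share summaries,
    recomputed by an independent pass over the stored draws."""
    if chain.n_kept < 100:
        raise ValueError("need at least 100 kept draws")
    pip = chain.nonspike_kept / chain.n_kept
    shares = chain.kept_shares()
    table = pd.DataFrame(
        {
            "group": chain.group_names,
            "share_mean": shares.mean(axis=0),
            "share_sd": shares.std(axis=0),
            "share_q025": np.quantile(shares, 0.025, axis=0),
            "share_q975": np.quantile(shares, 0.975, axis=0),
        }
    )
    return pip, table


def trace_diagnostics(
    chain: ChainState,
    splits: list[tuple[int, int]] | None = None,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Split-range agreement of the chain's parameter traces.

    For each parameter (per-group share, sigma_s^2, sigma_e^2, mu) and each
    pair of consecutive iteration ranges, reports the range means and flags
    |difference| above ``threshold`` times the combined naive standard error
    — a cheap stationarity screen for short chains.
    """
    if splits is None:
        lo, hi = chain.burn_in, chain.n_iter
        mid = (lo + hi) // 2
        splits = [(lo, mid), (mid, hi)]
    for (a0, a1), (b0, b1) in zip(splits, splits[1:]):
        if a1 > b0:
            raise ValueError("iteration ranges overlap")
    for s0, s1 in splits:
        if not (0 <= s0 < s1 <= chain.n_iter):
            raise ValueError(f"invalid iteration range ({s0}, {s1})")

    all_shares = 100.0 * chain.gvar / np.maximum(chain.gvar.sum(axis=1, keepdims=True), 1e-300)
    params: dict[str, np.ndarray] = {"sigma_e2": chain.sigma_e2, "mu": chain.mu}
    for s_i, name in enumerate(chain.group_names):
        params[f"share[{name}]"] = all_shares[:, s_i]
        params[f"sigma_s2[{name}]"] = chain.sigma_s2[:, s_i]

    rows = []
    for pname, trace in params.items():
        stats = []
        for s0, s1 in splits:
            seg = trace[s0:s1]
            stats.append((seg.mean(), seg.std() / np.sqrt(max(seg.size, 1))))
        for r_i in range(len(splits) - 1):
            (m1, se1), (m2, se2) = stats[r_i], stats[r_i + 1]
            se = np.sqrt(se1**2 + se2**2)
            z = abs(m1 - m2) / se if se > 0 else 0.0
            rows.append(
                {
                    "parameter": pname,
                    "range_a": splits[r_i],
                    "range_b": splits[r_i + 1],
                    "mean_a": m1,
                    "mean_b": m2,
                    "abs_diff": abs(m1 - m2),
                    "z": z,
                    "flagged": z > threshold,
                }
            )
    return pd.DataFrame(rows)
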