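"""Scenario orchestration and evaluation metrics for the estimator study.

For each scenario x method x stratification mode, replicate phenotypes are
simulated on a fixed annotated panel, fitted, and the per-class
%SNP-heritability estimates summarized into bias, RMSE, dispersion and
convergence tallies.  Non-converged fits enter the convergence tallies but
are excluded from the summary statistics, with both counts reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .annotate import AnnotationMap, Partition, collapse_to_class, make_partition
from .bayesrrc import MixturePrior, gibbs_fit
from .grm import GrmSet, build_grms
from .greml import fit_greml
from .phenosim import ScenarioSpec, assemble_phenotypes
from .synthpop import GenotypePanel


@dataclasses.dataclass
class MethodSpec:
    """One estimator configuration to run against a scenario."""

    method: str = "greml"  # "greml" or "bayes"
    mode: str = "noLDMS"
    design: str = "MC"
    focal: str | None = None
    rule: str = "yang"
    n_iter: int = 1500
    burn_in: int = 500

    @property
    def label(self) -> str:
        tail = f"-TC({self.focal})" if self.design == "TC" else "-MC"
        return f"{self.method}-{self.mode}{tail}"


def pct_snp_heritability(variances: dict[str, float] | np.ndarray) -> dict[str, float] | np.ndarray:
    """Per-class share of the genetic variance: sigma_s^2 / sigma_g^2 * 100."""
    if isinstance(variances, dict):
        vals = np.array(list(variances.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("variance components must be non-negative")
        tot = vals.sum()
        if tot == 0:
            raise ValueError("all variance components are zero; shares undefined")
        return {k: 100.0 * v / tot for k, v in zip(variances, vals)}
    vals = np.asarray(variances, dtype=float)
    if np.any(vals < 0):
        raise ValueError("variance components must be non-negative")
    tot = vals.sum()
    if tot == 0:
        raise ValueError("all variance components are zero; shares undefined")
    return 100.0 * vals / tot


def enrichment(share_pct: float, variant_fraction_pct: float) -> float:
    """Heritability enrichment: %h2 share over % of variants in the class."""
    if variant_fraction_pct <= 0:
        raise ValueError("variant fraction must be positive")
    return share_pct / variant_fraction_pct


def summarize_replicates(
    estimates: np.ndarray,
    truth: float,
    n_nonconverged_ai: int = 0,
    n_nonconverged_after_em: int = 0,
) -> dict[str, float]:
    """Summary-statistics row over replicate estimates of one quantity.

    RMSE and bias are on the same (percent) scale as the estimates; by
    construction RMSE^2 = bias^2 + variance (population variance over the
    same replicate set).
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 replicates")
    bias = est.mean() - truth
    rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
    return {
        "mean": float(est.mean()),
        "median": float(np.median(est)),
        "sd": float(est.std()),
        "q025": float(np.quantile(est, 0.025)),
        "q975": float(np.quantile(est, 0.975)),
        "min": float(est.min()),
        "max": float(est.max()),
        "bias": float(bias),
        "rmse": rmse,
        "n_reps": int(est.size),
        "n_nonconverged_AI": int(n_nonconverged_ai),
        "n_nonconverged_after_EM": int(n_nonconverged_after_em),
    }


def replicate_seed(master_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2^31, parallel-safe."""
    ss = np.random.SeedSequence([master_seed, rep])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def class_shares_from_fit(partition: Partition, variances: dict[str, float]) -> dict[str, float]:
    """Collapse fitted per-group variances to per-class %h2 shares."""
    by_class = collapse_to_class(partition, np.array(list(variances.values())))
    tot = sum(by_class.values())
    if tot <= 0:
        return {k: float("nan") for k in by_class}
    return {k: 100.0 * v / tot for k, v in by_class.items()}


def run_scenario(
    panel: GenotypePanel,
    annotation: AnnotationMap,
    scenario: ScenarioSpec,
    methods: list[MethodSpec],
    n_reps: int = 20,
    seed: int = 0,
    grm_cache: dict | None = None,
    prior: MixturePrior | None = None,
) -> pd.DataFrame:
    """Replicate loop: simulate, fit every method, collect per-class shares.

    Returns a tidy replicate-level table (scenario, method, class, rep,
    estimate, truth, h2_hat, converged).  GRMs are built once per unique
    (mode, design, focal, rule) and cached across replicates (and across
    calls if ``grm_cache`` is shared).  Partial fit failures are recorded,
    not fatal.
    """
    grm_cache = {} if grm_cache is None else grm_cache
    parts: dict[str, tuple[Partition, GrmSet | None]] = {}
    for ms in methods:
        key = (ms.mode, ms.design, ms.focal, ms.rule, ms.method)
        if key not in grm_cache:
            part = make_partition(annotation, mode=ms.mode, design=ms.design, focal=ms.focal)
            grms = build_grms(panel, part, rule=ms.rule) if ms.method == "greml" else None
            grm_cache[key] = (part, grms)
        parts[ms.label] = grm_cache[key]

    truth = dict(scenario.shares)
    rows = []
    for rep in range(n_reps):
        rep_seed = replicate_seed(seed, rep)
        y, causal = assemble_phenotypes(panel, annotation, scenario, seed=rep_seed)
        for ms in methods:
            part, grms = parts[ms.label]
            if ms.method == "greml":
                fit = fit_greml(y, grms)
                shares = class_shares_from_fit(part, fit.variances)
                converged = fit.converged
                ai_fail = fit.algorithm == "AI->EM"
                h2_hat = fit.h2
            else:
                summ = gibbs_fit(
                    y, panel.dosages, part, prior=prior,
                    n_iter=ms.n_iter, burn_in=ms.burn_in, seed=rep_seed,
                )
                by_class = collapse_to_class(part, np.array(list(summ.shares.values())))
                shares = by_class
                converged, ai_fail = True, False
                h2_hat = summ.h2
            for cls, est in shares.items():
                if cls == "rest" and "rest" not in truth:
                    truth_val = 100.0 - truth.get(ms.focal, 0.0)
                else:
                    truth_val = truth.get(cls, 0.0)
                rows.append(
                    {
                        "scenario": scenario.name,
                        "method": ms.label,
                        "class": cls,
                        "rep": rep,
                        "estimate": est,
                        "truth": truth_val,
                        "h2_hat": h2_hat,
                        "converged": converged,
                        "ai_failed": ai_fail,
                    }
                )
    return pd.DataFrame(rows)


def metrics_table(replicates: pd.DataFrame) -> pd.DataFrame:
    """MetricsTable: one summary row per scenario x method x class.

    Only converged replicates enter the statistics; convergence tallies
    count the others.
    """
    rows = []
    for (scen, meth, cls), sub in replicates.groupby(["scenario", "method", "class"]):
        ok = sub[sub["converged"]]
        n_ai = int(sub["ai_failed"].sum())
        n_fail = int((~sub["converged"]).sum())
        if len(ok) < 2:
            continue
        row = summarize_replicates(
            ok["estimate"].to_numpy(), float(ok["truth"].iloc[0]),
            n_nonconverged_ai=n_ai, n_nonconverged_after_em=n_fail,
        )
        row.update({"scenario": scen, "method": meth, "class": cls,
                    "truth": float(ok["truth"].iloc[0])})
        rows.append(row)
    return pd.DataFrame(rows)


def estimated_vs_true_regression(
    estimates: np.ndarray, truths: np.ndarray
) -> tuple[float, float, float]:
    """OLS of per-scenario mean estimates on simulated truths: (slope,
    intercept, R^2)."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.size < 3 or est.size != tru.size:
        raise ValueError("need at least 3 matched scenario points")
    A = np.column_stack([tru, np.ones_like(tru)])
    coef, *_ = np.linalg.lstsq(A, est, rcond=None)
    fitted = A @ coef
    ss_res = float(np.sum((est - fitted) ** 2))
    ss_tot = float(np.sum((est - est.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(coef[0]), float(coef[1]), r2
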