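"""Scenario-driven phenotype simulation with annotation-enriched causal variants.

A phenotype is y = sum_s g_s + e where g_s = sum_j x_sj beta_sj over the
causal variants (CVs) of annotation class s, with centered dosages x.  CV
counts per class are proportional to the class's target share of the
genetic variance; effects follow either the equal-contribution rule
(variance [2 p (1-p)]^-1, rare alleles have larger effects) or the
MAF-independent rule (unit variance, common alleles contribute more).
After simulation each g_s is deterministically rescaled so its realized
variance share hits the target exactly, making the simulated %SNP
heritability a fixed per-replicate truth; the error variance is then set
from the realized genetic variance so the realized heritability is exact
as well.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .annotate import AnnotationMap
from .synthpop import COMPLEX_SCENARIO_SHARES, GenotypePanel

EFFECT_RULES = ("equal_contribution", "maf_independent")
ENRICHMENT_FLAGS = ("low_maf", "high_maf", "low_ld", "high_ld")


@dataclasses.dataclass
class ScenarioSpec:
    """Target architecture of one simulation scenario.

    ``shares`` are per-class percentages of the genetic variance (sum 100);
    ``enrichment`` lists MAF/LD strata in which CVs are concentrated, with
    ``enrich_in_frac`` of each class's CVs drawn inside the (intersection)
    stratum and the rest outside — mirroring the 3,000-in / 2,000-out split
    of the stratified designs.
    """

    shares: dict[str, float]
    m_causal: int = 10_000
    h2: float = 0.50
    effect_rule: str = "equal_contribution"
    enrichment: tuple[str, ...] = ()
    enrich_in_frac: float = 0.6
    name: str = ""

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"class shares must sum to 100, got {total}")
        if self.m_causal < 1:
            raise ValueError("need at least one causal variant")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("heritability must be in (0, 1]")
        if self.effect_rule not in EFFECT_RULES:
            raise ValueError(f"unknown effect rule {self.effect_rule!r}")
        bad = set(self.enrichment) - set(ENRICHMENT_FLAGS)
        if bad:
            raise ValueError(f"unknown enrichment flags {sorted(bad)}")


@dataclasses.dataclass
class CausalSet:
    """Realized causal architecture of one replicate."""

    variant_index: dict[str, np.ndarray]  # class -> CV panel indices
    effects: dict[str, np.ndarray]  # class -> rescaled effects
    genetic_values: dict[str, np.ndarray]  # class -> g_s vector
    error: np.ndarray
    realized_shares: dict[str, float]  # percent, exact by construction
    sigma_g2: float
    sigma_e2: float


def ocr50_scenario(
    m_causal: int = 10_000,
    h2: float = 0.50,
    effect_rule: str = "equal_contribution",
    enrichment: tuple[str, ...] = (),
) -> ScenarioSpec:
    """Open chromatin contributes half the genetic variance, the rest is
    spread over the non-OCR classes in proportion to nothing in particular:
    the non-OCR half is a single 'rest' pool sampled across all other classes."""
    return ScenarioSpec(
        shares={"OCR": 50.0, "rest": 50.0},
        m_causal=m_causal,
        h2=h2,
        effect_rule=effect_rule,
        enrichment=enrichment,
        name="OCR-50" + ("+" + "+".join(enrichment) if enrichment else ""),
    )


def complex_scenario(which: str, m_causal: int = 2_000, h2: float = 0.70) -> ScenarioSpec:
    """The three multi-class scenarios with variable class contributions."""
    shares = {k: float(v) for k, v in COMPLEX_SCENARIO_SHARES[which].items() if v > 0}
    return ScenarioSpec(shares=shares, m_causal=m_causal, h2=h2, name=f"complex-{which}")


def single_class_scenario(cls: str, m_causal: int = 500, h2: float = 0.70) -> ScenarioSpec:
    """All genetic variance from one functional class (reduced CV count)."""
    return ScenarioSpec(shares={cls: 100.0}, m_causal=m_causal, h2=h2, name=f"single-{cls}")


def no_enrichment_scenario(
    annotation: AnnotationMap, m_causal: int = 2_000, h2: float = 0.70
) -> ScenarioSpec:
    """Every class contributes proportionally to its number of variants."""
    fracs = annotation.class_fractions()
    shares = {k: 100.0 * v for k, v in fracs.items()}
    # exact-100 normalization against float dust
    total = sum(shares.values())
    shares = {k: v * 100.0 / total for k, v in shares.items()}
    return ScenarioSpec(shares=shares, m_causal=m_causal, h2=h2, name="no-enrichment")


def _class_mask(annotation: AnnotationMap, cls: str) -> np.ndarray:
    if cls == "rest":
        return annotation.functional_class != "OCR"
    return annotation.functional_class == cls


def _enrich_mask(annotation: AnnotationMap, flags: tuple[str, ...]) -> np.ndarray:
    """Intersection of the requested MAF/LD enrichment strata."""
    mask = np.ones(annotation.n_variants, dtype=bool)
    for flag in flags:
        if flag == "low_maf":
            mask &= annotation.maf <= 0.05
        elif flag == "high_maf":
            mask &= annotation.maf > 0.20
        elif flag == "low_ld":
            mask &= annotation.ld_bin == 1
        elif flag == "high_ld":
            mask &= annotation.ld_bin == 4
        else:
            raise ValueError(f"unknown enrichment flag {flag!r}")
    return mask


def _apportion(total: int, weights: dict[str, float]) -> dict[str, int]:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    raw = total * w / w.sum()
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(raw - counts)[::-1]
        counts[order[:short]] += 1
    return dict(zip(keys, counts.tolist()))


def sample_causal_variants(
    annotation: AnnotationMap,
    spec: ScenarioSpec,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Sample CV indices per class, without replacement.

    CV counts are proportional to the target shares.  Under enrichment,
    ``enrich_in_frac`` of each class's CVs come from the class's intersection
    with the enriched stratum and the remainder from its complement.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _apportion(spec.m_causal, spec.shares)
    stratum = _enrich_mask(annotation, spec.enrichment) if spec.enrichment else None

    out: dict[str, np.ndarray] = {}
    for cls, m_s in counts.items():
        if m_s == 0:
            continue
        mask = _class_mask(annotation, cls)
        pool = np.flatnonzero(mask)
        if stratum is None:
            if pool.size < m_s:
                raise ValueError(f"class {cls}: {pool.size} variants < {m_s} CVs requested")
            out[cls] = np.sort(rng.choice(pool, size=m_s, replace=False))
        else:
            n_in = int(round(spec.enrich_in_frac * m_s))
            n_out = m_s - n_in
            pool_in = np.flatnonzero(mask & stratum)
            pool_out = np.flatnonzero(mask & ~stratum)
            if pool_in.size < n_in or pool_out.size < n_out:
                raise ValueError(
                    f"class {cls}: enrichment stratum too small "
                    f"({pool_in.size} in / {pool_out.size} out for {n_in}/{n_out} CVs)"
                )
            chosen = np.concatenate(
                [rng.choice(pool_in, size=n_in, replace=False),
                 rng.choice(pool_out, size=n_out, replace=False)]
            )
            out[cls] = np.sort(chosen)
    return out


def draw_effects(
    freq: np.ndarray,
    rule: str = "equal_contribution",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """CV effects: N(0, [2p(1-p)]^-1) under ``equal_contribution`` (each CV
    contributes equally in expectation), N(0, 1) under ``maf_independent``."""
    if rule not in EFFECT_RULES:
        raise ValueError(f"unknown effect rule {rule!r}")
    p = np.asarray(freq, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(p.shape)
    if rule == "equal_contribution":
        return z / np.sqrt(2.0 * p * (1.0 - p))
    return z


def assemble_phenotypes(
    panel: GenotypePanel,
    annotation: AnnotationMap,
    spec: ScenarioSpec,
    seed: int = 0,
) -> tuple[np.ndarray, CausalSet]:
    """Simulate one phenotype replicate.

    Per class: g_s = X_c beta with panel-frequency-centered dosages, then
    rescaled so Var(g_s) = share_s / 100 exactly (total class variance 1).
    The error is rescaled so Var(e) = sigma_g^2 (1 - h2) / h2 exactly, with
    sigma_g^2 = Var(sum_s g_s) (which includes the small cross-class
    covariances of a finite panel).
    """
    rng = np.random.default_rng(seed)
    cvs = sample_causal_variants(annotation, spec, rng)
    freq = panel.freq
    n = panel.n_individuals

    genetic: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    for cls, idx in cvs.items():
        beta = draw_effects(freq[idx], spec.effect_rule, rng)
        Xc = panel.dosages[:, idx].astype(np.float64) - 2.0 * freq[idx]
        g = Xc @ beta
        v = g.var()
        target = spec.shares[cls] / 100.0
        if v == 0 and target > 0:
            raise ValueError(f"class {cls}: zero genetic variance with positive target share")
        scale = np.sqrt(target / v)
        genetic[cls] = g * scale
        effects[cls] = beta * scale

    g_total = np.sum(list(genetic.values()), axis=0)
    sigma_g2 = float(g_total.var())
    sigma_e2 = sigma_g2 * (1.0 - spec.h2) / spec.h2
    if sigma_e2 > 0:
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std() * np.sqrt(sigma_e2)
    else:
        e = np.zeros(n)
    y = g_total + e

    realized = {cls: float(spec.shares[cls]) for cls in genetic}
    causal = CausalSet(
        variant_index=cvs,
        effects=effects,
        genetic_values=genetic,
        error=e,
        realized_shares=realized,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
    )
    return y, causal
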