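"""Schema-validated run configuration (unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PanelConfig(_Strict):
    n_founders: int = 1100
    n_variants: int = 20_000
    chrom_lengths: list[int] = Field(default_factory=lambda: [100_000_000, 100_000_000])
    ld_block_mean_kb: float = 50.0
    maf_alpha: float = 1.0
    n_generations: int = 2
    n_sires: int = 25
    n_dams: int = 500
    offspring_per_dam: int = 3
    cm_per_mb: float = 1.0
    min_maf: float = 0.01


class LayoutConfig(_Strict):
    class_proportions: dict[str, float] | None = None  # None -> genome-wide defaults
    flank_bp: int = 1000
    mean_peak_bp: int = 2000


class AnnotateConfig(_Strict):
    window_kb: float = 200.0


class ScenarioConfig(_Strict):
    shares: dict[str, float]
    m_causal: int = 200
    h2: float = 0.5
    effect_rule: str = "equal_contribution"
    enrichment: list[str] = Field(default_factory=list)
    enrich_in_frac: float = 0.6
    name: str = ""


class MethodConfig(_Strict):
    method: str = "greml"
    mode: str = "noLDMS"
    design: str = "MC"
    focal: str | None = None
    rule: str = "yang"
    n_iter: int = 1500
    burn_in: int = 500


class RunConfig(_Strict):
    """Top-level configuration for the end-to-end pipeline."""

    seed: int = 0
    scale: str = "desk"  # desk | full
    panel: PanelConfig = Field(default_factory=PanelConfig)
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    annotate: AnnotateConfig = Field(default_factory=AnnotateConfig)
    scenario: ScenarioConfig | None = None
    methods: list[MethodConfig] = Field(default_factory=lambda: [MethodConfig()])
    n_reps: int = 20
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(out_path: str | Path, cfg: RunConfig, stage: str) -> None:
    """Provenance record next to the outputs: enough to reproduce them."""
    from . import __version__

    record = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "config": cfg.model_dump(),
        "version": __version__,
    }
    Path(out_path).write_text(json.dumps(record, indent=2, default=str))
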