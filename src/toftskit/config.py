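"""YAML/JSON configuration: one schema shared by simulator and fitters.

A single config file describes the acquisition, the AIF, the phantom or
cohort study, the physiological filter rules and the statistics options,
so a phantom study is self-describing and reproducible from the file
plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aif import AIFModel
from .geometry import GridGeometry
from .pharmacokinetics import FilterRules
from .phantom import CohortSpec, PhantomSpec
from .relaxometry import AcquisitionParams, RelaxometryConfig

__all__ = ["PipelineConfig", "load_config", "config_from_dict"]

_KNOWN_SECTIONS = {
    "seed", "acquisition", "grid", "aif", "relaxometry", "phantom",
    "cohort", "filters", "stats",
}


@dataclass(frozen=True)
class PipelineConfig:
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    aif: AIFModel = field(default_factory=AIFModel)
    relax: RelaxometryConfig = field(default_factory=RelaxometryConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec | None = None
    rules: FilterRules = field(default_factory=FilterRules)
    stats: dict = field(default_factory=lambda: {"alpha": 0.05, "force_branch": None})
    seed: int = 0


def _build(cls, section: dict, what: str, **extra):
    try:
        return cls(**{**section, **extra})
    except TypeError as err:
        raise ValueError(f"invalid {what} config: {err}") from None


def config_from_dict(cfg: dict) -> PipelineConfig:
    """Validate a config mapping and build the typed configuration.

    Unknown top-level sections and invalid field values raise with a
    message naming the offending entry.
    """
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")

    grid = _build(GridGeometry, cfg.get("grid", {}), "grid")
    acq_section = dict(cfg.get("acquisition", {}))
    for key in ("vfa_angles_deg", "b_values"):
        if key in acq_section:
            acq_section[key] = tuple(acq_section[key])
    acq = _build(AcquisitionParams, acq_section, "acquisition", grid=grid)

    aif_section = dict(cfg.get("aif", {}))
    for key in ("amplitudes", "rates"):
        if key in aif_section:
            aif_section[key] = tuple(aif_section[key])
    aif = _build(AIFModel, aif_section, "aif")

    relax = _build(RelaxometryConfig, cfg.get("relaxometry", {}), "relaxometry")
    rules = _build(FilterRules, cfg.get("filters", {}), "filters")

    ph_section = dict(cfg.get("phantom", {}))
    for key in ("semi_axes_mm", "center_mm"):
        if ph_section.get(key) is not None:
            ph_section[key] = tuple(ph_section[key])
    phantom = _build(PhantomSpec, ph_section, "phantom", grid=grid)

    cohort = None
    if "cohort" in cfg:
        co = dict(cfg["cohort"])
        for key in ("groups", "days"):
            if key in co:
                co[key] = tuple(co[key])
        cohort = _build(CohortSpec, co, "cohort")

    stats = {"alpha": 0.05, "force_branch": None, **cfg.get("stats", {})}
    return PipelineConfig(acq=acq, aif=aif, relax=relax, phantom=phantom,
                          cohort=cohort, rules=rules, stats=stats,
                          seed=int(cfg.get("seed", 0)))


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON) config file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return config_from_dict(cfg)
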