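"""Run configuration: YAML in, fully-built :class:`CEModel` out.

A run config declares the country, the fitted (or illustrative) OS/PFS
curves per arm, optional PD-L1 subgroup multipliers, the strategy set,
price scenarios, and DSA/PSA settings.  Economic inputs default to the
shipped country tables and can be overridden field-by-field under
``economic_overrides``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .scenarios import Scenario
from .strategies import CEModel, CurveSet, StrategySpec
from .survival import CYCLE_LENGTH_MONTHS, SurvivalDistribution
from .synthetic import default_inputs

__all__ = ["RunConfig", "load_config", "build_model", "example_config_path"]


@dataclass
class RunConfig:
    country: str
    curves: dict[str, CurveSet]
    strategies: list[StrategySpec]
    subgroup_multipliers: dict[str, dict[str, float]] | None = None
    scenarios: list[Scenario] = field(default_factory=list)
    horizon_years: float = 20.0
    cycle_length: float = CYCLE_LENGTH_MONTHS
    half_cycle_correction: bool = False
    psa_n: int = 1000
    psa_seed: int = 20200116
    wtp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0, 200_001, 2_000, dtype=float))
    economic_overrides: dict = field(default_factory=dict)
    output_dir: Path = Path("out")
    source_digest: str | None = None


def _parse_curveset(d: dict) -> CurveSet:
    return CurveSet(os=SurvivalDistribution.from_dict(d["os"]),
                    pfs=SurvivalDistribution.from_dict(d["pfs"]))


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; raises with a field-level message."""
    path = Path(path)
    raw = path.read_bytes()
    try:
        doc = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: not valid YAML: {exc}") from exc
    try:
        curves = {arm: _parse_curveset(d) for arm, d in doc["curves"].items()}
        strategies = [StrategySpec(name=s["name"], kind=s["kind"],
                                   cutoff=s.get("cutoff"))
                      for s in doc["strategies"]]
        scenarios = [Scenario(name=s["name"],
                              multipliers=dict(s.get("multipliers", {})),
                              disable_cn_donation=bool(s.get("disable_cn_donation", False)))
                     for s in doc.get("scenarios", [])]
        wtp = doc.get("wtp_grid", {})
        grid = np.arange(float(wtp.get("start", 0)),
                         float(wtp.get("stop", 200_000)) + 1e-9,
                         float(wtp.get("step", 2_000)))
        psa = doc.get("psa", {})
        cfg = RunConfig(
            country=str(doc["country"]),
            curves=curves,
            strategies=strategies,
            subgroup_multipliers=doc.get("subgroup_multipliers"),
            scenarios=scenarios,
            horizon_years=float(doc.get("horizon_years", 20.0)),
            half_cycle_correction=bool(doc.get("half_cycle_correction", False)),
            psa_n=int(psa.get("n", 1000)),
            psa_seed=int(psa.get("seed", 20200116)),
            wtp_grid=grid,
            economic_overrides=dict(doc.get("economic_overrides", {})),
            output_dir=Path(doc.get("output_dir", "out")),
            source_digest=hashlib.sha256(raw).hexdigest(),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing required config field {exc}") from exc
    names = [s.name for s in cfg.strategies]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: strategy names must be unique, got {names}")
    return cfg


def build_model(cfg: RunConfig) -> CEModel:
    """Materialize the model: country defaults + config overrides."""
    inputs = default_inputs(cfg.country)
    for key, value in cfg.economic_overrides.items():
        if not hasattr(inputs, key):
            raise ValueError(f"unknown economic_overrides field {key!r}")
        current = getattr(inputs, key)
        if isinstance(current, dict) and isinstance(value, dict):
            current.update(value)
        else:
            setattr(inputs, key, value)
    inputs.validate()
    return CEModel(
        inputs=inputs,
        arm_curves=dict(cfg.curves),
        strategies=list(cfg.strategies),
        subgroup_multipliers=cfg.subgroup_multipliers,
        horizon_years=cfg.horizon_years,
        cycle_length=cfg.cycle_length,
        half_cycle_correction=cfg.half_cycle_correction,
    )


def example_config_path(country: str) -> Path:
    """Path of the shipped example run config for ``US`` or ``CN``."""
    name = f"run_{country.lower()}.yaml"
    ref = resources.files("nsclc_cea").joinpath("data", name)
    with resources.as_file(ref) as p:
        return Path(p)
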