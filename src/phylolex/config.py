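"""Run configuration: YAML schema, validation, and object construction.

The configuration mirrors the analysis pipeline: data sources, the
substitution model, the clock, the FBD tree prior, parameter priors,
calibrations, monophyly constraints, and the MCMC settings.  Unknown keys
are rejected so that typos fail before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .clock import ClockModel
from .fbd import FBDParams
from .mcmc import MCMCConfig
from .priors import Calibration, MonophylyConstraint, PriorSpec
from .substitution import (CovarionParams, GammaHeterogeneity, M1pParams,
                           SubstModel)

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config"]


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{where}: expected a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


@dataclass
class DataConfig:
    cognates_csv: Optional[str] = None
    format: str = "csv"
    tip_dates: dict[str, float] = field(default_factory=dict)
    exclude: list[str] = field(default_factory=list)


@dataclass
class SteppingStoneConfig:
    steps: int = 30
    shape: float = 0.3
    samples_per_step: int = 1000


@dataclass
class RunConfig:
    seed: int = 1
    output_dir: str = "out"
    data: DataConfig = field(default_factory=DataConfig)
    model: SubstModel = field(default_factory=SubstModel)
    ascertainment: bool = False
    clock: ClockModel = field(default_factory=ClockModel)
    fbd: FBDParams = field(default_factory=FBDParams)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    stepping_stone: SteppingStoneConfig = field(
        default_factory=SteppingStoneConfig)
    clades: dict[str, list[str]] = field(default_factory=dict)
    resolved: dict[str, Any] = field(default_factory=dict)


def _parse_model(block: dict) -> SubstModel:
    _check_keys(block, {"kind", "gain", "loss", "switch_on", "switch_off",
                        "shape", "n_categories", "normalize"}, "model")
    kind = block.get("kind", "m1p")
    try:
        m1p = M1pParams(float(block.get("gain", 1.0)),
                        float(block.get("loss", 1.0)))
        gamma = covarion = None
        if kind == "m1p+G4":
            gamma = GammaHeterogeneity(float(block.get("shape", 1.0)),
                                       int(block.get("n_categories", 4)))
        elif kind == "m1p+CV":
            covarion = CovarionParams(float(block.get("switch_on", 1.0)),
                                      float(block.get("switch_off", 1.0)))
        return SubstModel(kind=kind, m1p=m1p, gamma=gamma, covarion=covarion,
                          normalize=bool(block.get("normalize", True)))
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"model: {exc}") from exc


def _parse_calibration(block: dict, i: int) -> Calibration:
    kind = block.get("type")
    if kind == "tip_date":
        _check_keys(block, {"type", "taxon", "age_ka"}, f"calibrations[{i}]")
        return Calibration("tip_date", frozenset([block["taxon"]]),
                           float(block["age_ka"]))
    if kind == "mrca_min_age":
        _check_keys(block, {"type", "taxa", "min_age_ka"},
                    f"calibrations[{i}]")
        return Calibration("mrca_min_age", frozenset(block["taxa"]),
                           float(block["min_age_ka"]))
    raise ConfigError(f"calibrations[{i}]: unknown type {kind!r}")


def parse_config(raw: dict) -> RunConfig:
    _check_keys(raw, {"seed", "output_dir", "data", "model", "ascertainment",
                      "clock", "fbd", "priors", "calibrations", "constraints",
                      "mcmc", "stepping_stone", "clades"}, "config")
    try:
        data_block = raw.get("data", {}) or {}
        _check_keys(data_block, {"cognates_csv", "format", "tip_dates",
                                 "exclude"}, "data")
        data = DataConfig(
            cognates_csv=data_block.get("cognates_csv"),
            format=data_block.get("format", "csv"),
            tip_dates={k: float(v) for k, v in
                       (data_block.get("tip_dates") or {}).items()},
            exclude=list(data_block.get("exclude") or []),
        )
        model = _parse_model(raw.get("model", {}) or {})

        clock_block = raw.get("clock", {}) or {}
        _check_keys(clock_block, {"kind", "clock_rate", "mu", "sigma"},
                    "clock")
        clock = ClockModel(kind=clock_block.get("kind", "strict"),
                           clock_rate=float(clock_block.get("clock_rate", 1.0)),
                           mu=float(clock_block.get("mu", 1.0)),
                           sigma=float(clock_block.get("sigma", 0.1)))

        fbd_block = raw.get("fbd", {}) or {}
        _check_keys(fbd_block, {"birth", "death", "psi", "rho"}, "fbd")
        fbd = FBDParams(birth=float(fbd_block.get("birth", 1.0)),
                        death=float(fbd_block.get("death", 0.0)),
                        psi=float(fbd_block.get("psi", 0.0)),
                        rho=float(fbd_block.get("rho", 1.0)))

        priors_block = raw.get("priors", {}) or {}
        _check_keys(priors_block,
                    {"transition_rate_mean", "switch_rate_mean",
                     "gamma_shape_mean", "clock_rate_mean", "birth_mean",
                     "death_mean", "psi_mean", "root_age_mean"}, "priors")
        priors = PriorSpec(**{k: (None if v is None else float(v))
                              for k, v in priors_block.items()})
        priors.calibrations = [
            _parse_calibration(c, i)
            for i, c in enumerate(raw.get("calibrations") or [])]
        constraints = []
        for i, c in enumerate(raw.get("constraints") or []):
            _check_keys(c, {"taxa", "outgroup"}, f"constraints[{i}]")
            constraints.append(MonophylyConstraint(
                frozenset(c["taxa"]), bool(c.get("outgroup", False))))
        priors.constraints = constraints

        mcmc_block = raw.get("mcmc", {}) or {}
        _check_keys(mcmc_block, {"chain_length", "burn_in", "sample_every",
                                 "n_chains", "kappa", "rho_window"}, "mcmc")
        mcmc = MCMCConfig(
            chain_length=int(mcmc_block.get("chain_length", 100_000)),
            burn_in=int(mcmc_block.get("burn_in", 10_000)),
            sample_every=int(mcmc_block.get("sample_every", 100)),
            n_chains=int(mcmc_block.get("n_chains", 1)),
            seed=int(raw.get("seed", 1)),
            kappa=float(mcmc_block.get("kappa", 1.5)),
            rho_window=float(mcmc_block.get("rho_window", 0.1)),
            ascertainment=bool(raw.get("ascertainment", False)),
        )

        ss_block = raw.get("stepping_stone", {}) or {}
        _check_keys(ss_block, {"steps", "shape", "samples_per_step"},
                    "stepping_stone")
        ss = SteppingStoneConfig(
            steps=int(ss_block.get("steps", 30)),
            shape=float(ss_block.get("shape", 0.3)),
            samples_per_step=int(ss_block.get("samples_per_step", 1000)))

        clades = {str(k): list(v)
                  for k, v in (raw.get("clades") or {}).items()}
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(seed=int(raw.get("seed", 1)),
                     output_dir=str(raw.get("output_dir", "out")),
                     data=data, model=model,
                     ascertainment=bool(raw.get("ascertainment", False)),
                     clock=clock, fbd=fbd, priors=priors, mcmc=mcmc,
                     stepping_stone=ss, clades=clades, resolved=dict(raw))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(raw)
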