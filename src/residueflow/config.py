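"""Run configuration: a single structured text file holds every constant.

All screening thresholds, conversion factors and market/land constants live
in the configuration, none in code; packaged defaults encode the three
model bioprocesses (adipic acid from lignin, C6/C8 carboxylic acids from
NFC, citric acid and α-ketoglutarate from waste oils and glycerol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .market_land import DemandSpec, LandUseSpec
from .material_flow import ProcessChain, ProcessStep, idealized_variant
from .resource_matrix import FRACTIONS
from .screening import ScreeningRule


class ConfigError(ValueError):
    """Raised for structurally invalid run configurations."""


@dataclass(frozen=True)
class StepSpec:
    """One configured conversion step; ``idealized`` overrides the factor."""

    name: str
    input_label: str
    output_label: str
    factor: float
    idealized: float | None = None


@dataclass(frozen=True)
class ChainSpec:
    name: str
    target_fraction: str
    steps: tuple[StepSpec, ...]

    def baseline_chain(self) -> ProcessChain:
        return ProcessChain(
            name=self.name,
            target_fraction=self.target_fraction,
            steps=tuple(
                ProcessStep(s.name, s.input_label, s.output_label, s.factor)
                for s in self.steps
            ),
            scenario="baseline",
        )

    def idealized_chain(self) -> ProcessChain:
        overrides = {
            s.name: s.idealized for s in self.steps if s.idealized is not None
        }
        return idealized_variant(self.baseline_chain(), overrides)

    def chain(self, scenario: str) -> ProcessChain:
        if scenario == "baseline":
            return self.baseline_chain()
        if scenario == "idealized":
            return self.idealized_chain()
        raise ConfigError(f"unknown scenario {scenario!r}")

    @property
    def has_idealized(self) -> bool:
        return any(s.idealized is not None for s in self.steps)


@dataclass(frozen=True)
class LandSpec:
    crop: str
    areal_yield: float
    content_factor: float = 1.0
    feedstock_fraction_content: float = 1.0

    def land_use(self) -> LandUseSpec:
        return LandUseSpec(
            crop=self.crop,
            areal_yield=self.areal_yield,
            content_factor=self.content_factor,
        )


@dataclass(frozen=True)
class ProcessSpec:
    """One configured bioprocess: screening rule, chains, market and land data."""

    name: str
    fraction: str
    rule: ScreeningRule
    chains: tuple[ChainSpec, ...]
    restrict_to: tuple[str, ...] | None = None
    market: DemandSpec | None = None
    land: LandSpec | None = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ConfigError(f"unknown fraction {self.fraction!r}")
        if not self.chains:
            raise ConfigError(f"process {self.name!r} defines no chain")


@dataclass(frozen=True)
class RunConfig:
    """Everything an assessment run needs besides the matrix itself."""

    processes: tuple[ProcessSpec, ...]
    cutoff: float = 250_000.0
    reference_year: int = 2025
    report_significant_figures: int = 3
    national_gdp_share: float = 0.03
    not_exploitable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ConfigError(f"cutoff must be ≥ 0, got {self.cutoff}")
        names = [p.name for p in self.processes]
        if len(names) != len(set(names)):
            raise ConfigError("process names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_mapping(raw)

    @classmethod
    def default(cls) -> "RunConfig":
        """Packaged defaults for the three model bioprocesses."""
        with resources.as_file(
            resources.files("residueflow.data") / "defaults.yaml"
        ) as path:
            return cls.from_yaml(path)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict) or "processes" not in raw:
            raise ConfigError("configuration must be a mapping with 'processes'")
        gdp_share = float(raw.get("national_gdp_share", 0.03))
        processes = []
        for name, spec in raw["processes"].items():
            try:
                screening = spec["screening"]
                rule = ScreeningRule(
                    fraction_name=spec["fraction"],
                    favorable_threshold=float(screening["favorable"]),
                    possible_threshold=float(screening["possible"]),
                    comparison=screening.get("comparison", "geq"),
                )
                chains = tuple(
                    ChainSpec(
                        name=chain_name,
                        target_fraction=spec["fraction"],
                        steps=tuple(
                            StepSpec(
                                name=step["name"],
                                input_label=step["input"],
                                output_label=step["output"],
                                factor=float(step["factor"]),
                                idealized=(
                                    float(step["idealized"])
                                    if "idealized" in step
                                    else None
                                ),
                            )
                            for step in chain_spec["steps"]
                        ),
                    )
                    for chain_name, chain_spec in spec["chains"].items()
                )
                market = None
                if "market" in spec:
                    market = DemandSpec(
                        product=spec["market"]["product"],
                        global_production=float(
                            spec["market"]["global_production_Mg_a"]
                        ),
                        national_gdp_share=float(
                            spec["market"].get("gdp_share", gdp_share)
                        ),
                    )
                land = None
                if "land" in spec:
                    land = LandSpec(
                        crop=spec["land"]["crop"],
                        areal_yield=float(spec["land"]["areal_yield_Mg_ha_a"]),
                        content_factor=float(spec["land"].get("content_factor", 1.0)),
                        feedstock_fraction_content=float(
                            spec["land"].get("feedstock_fraction_content", 1.0)
                        ),
                    )
                restrict = spec.get("restrict_to")
                processes.append(
                    ProcessSpec(
                        name=name,
                        fraction=spec["fraction"],
                        rule=rule,
                        chains=chains,
                        restrict_to=tuple(restrict) if restrict else None,
                        market=market,
                        land=land,
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"process {name!r}: missing key {exc}") from exc
        return cls(
            processes=tuple(processes),
            cutoff=float(raw.get("cutoff_Mg_DM_a", 250_000.0)),
            reference_year=int(raw.get("reference_year", 2025)),
            report_significant_figures=int(raw.get("report_significant_figures", 3)),
            national_gdp_share=gdp_share,
            not_exploitable=tuple(raw.get("not_exploitable", ())),
        )


def round_sig(value: float, sig_figs: int = 3) -> float:
    """Round to the given number of significant figures (reporting only)."""
    if value == 0 or not (value == value):  # 0 or NaN
        return value
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig_figs - 1))
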