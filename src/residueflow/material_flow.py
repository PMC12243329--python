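"""Conversion chains: push fraction pools through multi-step bioprocesses.

A model bioprocess converts raw material into product and side stream
through an ordered list of steps (fractionation, depolymerization,
electrochemical and microbial conversion, ...), each characterised by a
dimensionless mass-per-mass conversion factor.  Factors may exceed 1 when
co-substrates (water, oxygen) are incorporated into the product, e.g. 1.32
for citric acid from waste oil.

The flow engine is linear: the product equals the input pool times the
product of the step factors, and the per-step ledger records input, output
and delta mass for every step, so side streams (positive deltas) and
co-substrate uptake (negative deltas) can be reported Sankey-style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

SCENARIOS = ("baseline", "idealized")


@dataclass(frozen=True)
class ProcessStep:
    """One conversion step with a mass-per-mass factor (> 0, may exceed 1)."""

    name: str
    input_label: str
    output_label: str
    conversion_factor: float

    def __post_init__(self) -> None:
        if not self.conversion_factor > 0:
            raise ValueError(
                f"conversion_factor must be > 0, got {self.conversion_factor}"
            )


@dataclass(frozen=True)
class ProcessChain:
    """Ordered, non-empty conversion cascade from a target fraction to a product."""

    name: str
    target_fraction: str
    steps: tuple[ProcessStep, ...]
    scenario: str = "baseline"

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise ValueError("chain must have at least one step")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )


def idealized_variant(
    chain: ProcessChain, factor_overrides: Mapping[str, float]
) -> ProcessChain:
    """Chain with the named steps' factors replaced (prospected improvements).

    Only the steps named in ``factor_overrides`` change; all others keep
    their baseline factor.
    """
    unknown = set(factor_overrides) - {s.name for s in chain.steps}
    if unknown:
        raise ValueError(f"overrides name unknown steps: {sorted(unknown)}")
    steps = tuple(
        replace(s, conversion_factor=factor_overrides.get(s.name, s.conversion_factor))
        for s in chain.steps
    )
    return replace(chain, steps=steps, scenario="idealized")


def chain_factor(chain: ProcessChain) -> float:
    """Product of the step conversion factors (empty product would be 1)."""
    return math.prod(s.conversion_factor for s in chain.steps)


@dataclass(frozen=True)
class StepFlow:
    """Ledger entry: masses entering/leaving one step, Mg a⁻¹."""

    name: str
    input_mass: float
    output_mass: float

    @property
    def delta(self) -> float:
        """input − output; positive = side stream, negative = co-substrate uptake."""
        return self.input_mass - self.output_mass


@dataclass(frozen=True)
class FlowResult:
    """Full mass ledger of one chain run."""

    chain_name: str
    scenario: str
    input_pool: float
    ledger: tuple[StepFlow, ...]
    product: float

    @property
    def side_stream_total(self) -> float:
        return sum(max(0.0, s.delta) for s in self.ledger)

    @property
    def co_substrate_total(self) -> float:
        return sum(max(0.0, -s.delta) for s in self.ledger)


def run_chain(input_pool: float, chain: ProcessChain) -> FlowResult:
    """Convert an input pool (Mg a⁻¹) through the chain, step by step.

    The ledger is contiguous (step *i* output = step *i*+1 input) and the
    result is linear in the input pool.
    """
    if input_pool < 0:
        raise ValueError(f"input_pool must be ≥ 0, got {input_pool}")
    ledger: list[StepFlow] = []
    mass = input_pool
    for step in chain.steps:
        out = mass * step.conversion_factor
        ledger.append(StepFlow(step.name, mass, out))
        mass = out
    return FlowResult(
        chain_name=chain.name,
        scenario=chain.scenario,
        input_pool=input_pool,
        ledger=tuple(ledger),
        product=mass,
    )


@dataclass(frozen=True)
class UtilizationRatio:
    """η_RM = m_P / m_RM — Mg product per Mg raw material."""

    eta_rm: float
    m_p: float
    m_rm: float


def utilization_ratio(product: float, raw_pool: float) -> UtilizationRatio:
    """Utilization ratio of the raw material, η_RM = product / raw pool."""
    if raw_pool <= 0:
        raise ZeroDivisionError(
            f"utilization ratio undefined for raw_pool = {raw_pool}"
        )
    return UtilizationRatio(eta_rm=product / raw_pool, m_p=product, m_rm=raw_pool)


def nfc_yield_basis(raw_mass: float, nfc_mass: float, acid_mass: float) -> float:
    """Per-NFC conversion factor extrapolated from a feeding experiment.

    E.g. an anaerobic fermentation fed 1000 kg silage containing 345 kg NFC
    that yields 32 kg carboxylic acids has a per-NFC factor 32/345 ≈ 0.093.
    """
    if raw_mass <= 0 or acid_mass <= 0:
        raise ValueError("masses must be > 0")
    if nfc_mass <= 0:
        raise ValueError(f"nfc_mass must be > 0, got {nfc_mass}")
    if nfc_mass > raw_mass:
        raise ValueError(f"nfc_mass {nfc_mass} exceeds raw_mass {raw_mass}")
    return acid_mass / nfc_mass


def mass_ledger_report(result: FlowResult) -> pd.DataFrame:
    """Per-step mass table plus a totals row.

    The totals row carries the chain input, the product, and the net delta;
    side-stream and co-substrate totals are attached as frame attrs.
    """
    rows = [
        {
            "step": s.name,
            "input_Mg_a": s.input_mass,
            "output_Mg_a": s.output_mass,
            "delta_Mg_a": s.delta,
        }
        for s in result.ledger
    ]
    rows.append(
        {
            "step": "total",
            "input_Mg_a": result.input_pool,
            "output_Mg_a": result.product,
            "delta_Mg_a": result.side_stream_total - result.co_substrate_total,
        }
    )
    frame = pd.DataFrame(rows, columns=["step", "input_Mg_a", "output_Mg_a", "delta_Mg_a"])
    frame.attrs["product_Mg_a"] = result.product
    frame.attrs["side_stream_total_Mg_a"] = result.side_stream_total
    frame.attrs["co_substrate_total_Mg_a"] = result.co_substrate_total
    return frame


def flow_to_nodelink(result: FlowResult, chain: ProcessChain) -> dict:
    """Node-link JSON structure (Sankey-ready) for one chain run.

    Nodes are the step input/output labels plus one side-stream or
    co-substrate node per step with non-zero delta; links carry masses in
    Mg a⁻¹.
    """
    if len(result.ledger) != len(chain.steps):
        raise ValueError("flow result does not match the chain definition")
    nodes: list[dict] = [{"name": chain.steps[0].input_label}]
    links: list[dict] = []
    for step, flow in zip(chain.steps, result.ledger):
        source = len(nodes) - 1
        nodes.append({"name": step.output_label})
        target = len(nodes) - 1
        links.append({"source": source, "target": target, "value": flow.output_mass})
        if flow.delta > 0:
            nodes.append({"name": f"side stream ({step.name})"})
            links.append(
                {"source": source, "target": len(nodes) - 1, "value": flow.delta}
            )
        elif flow.delta < 0:
            nodes.append({"name": f"co-substrate ({step.name})"})
            links.append(
                {"source": len(nodes) - 1, "target": target, "value": -flow.delta}
            )
    return {
        "chain": result.chain_name,
        "scenario": result.scenario,
        "unit": "Mg a-1",
        "nodes": nodes,
        "links": links,
    }
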