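"""End-to-end assessment: cutoff → screening → pooling → chains → market/land.

Runs every configured bioprocess over a resource matrix and collects, per
process, chain, tier (favorable / with_possible) and scenario (baseline /
idealized): the mass pools, product potential, utilization ratio η_RM,
national demand, coverage and required-feedstock shares, and the land-use
saving.  Reports are deterministic for a given config and matrix; written
artifacts (summary table, flow JSON, run log) are byte-identical on re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import ProcessSpec, RunConfig, round_sig
from .market_land import (
    demand_coverage_share,
    land_saving,
    national_demand,
    required_fraction_share,
)
from .material_flow import (
    FlowResult,
    chain_factor,
    flow_to_nodelink,
    run_chain,
    utilization_ratio,
)
from .resource_matrix import (
    ResourceMatrix,
    apply_potential_cutoff,
    score_data_quality,
    suitability_summary,
)
from .screening import MassPools, TieredSelection, pool_masses, screen_feedstocks
from .synthetic_data import reference_fixture

logger = logging.getLogger(__name__)

TIERS = ("favorable", "with_possible")


@dataclass(frozen=True)
class ChainOutcome:
    """One chain × tier × scenario result with its derived market quantities."""

    process: str
    chain_name: str
    tier: str
    scenario: str
    factor: float
    raw_pool: float
    fraction_pool: float
    product: float
    eta_rm: float | None
    demand: float | None
    coverage_share: float | None
    required_share: float | None
    land_saving_ha: float | None
    flow: FlowResult


@dataclass(frozen=True)
class ProcessReport:
    name: str
    fraction: str
    selection: TieredSelection
    pools: dict[str, MassPools]
    outcomes: tuple[ChainOutcome, ...]


@dataclass(frozen=True)
class AssessmentReport:
    processes: tuple[ProcessReport, ...]
    suitability: pd.DataFrame | None
    quality_tally: dict[int, int]
    total_selected_raw_pool: float
    cutoff: float
    n_input: int
    n_after_cutoff: int

    def summary_frame(self, sig_figs: int | None = None) -> pd.DataFrame:
        """Flat table mirroring the tonnage-summary layout of the assessment."""

        def rnd(x: float | None) -> float | None:
            if x is None or sig_figs is None:
                return x
            return round_sig(x, sig_figs)

        rows = []
        for proc in self.processes:
            for o in proc.outcomes:
                rows.append(
                    {
                        "process": o.process,
                        "chain": o.chain_name,
                        "tier": o.tier,
                        "scenario": o.scenario,
                        "raw_pool_Mg_a": rnd(o.raw_pool),
                        "fraction_pool_Mg_a": rnd(o.fraction_pool),
                        "chain_factor": rnd(o.factor),
                        "product_Mg_a": rnd(o.product),
                        "eta_rm": rnd(o.eta_rm),
                        "national_demand_Mg_a": rnd(o.demand),
                        "coverage_share": rnd(o.coverage_share),
                        "required_fraction_share": rnd(o.required_share),
                        "land_saving_ha": rnd(o.land_saving_ha),
                    }
                )
        return pd.DataFrame(rows)


def _assess_process(
    matrix: ResourceMatrix, spec: ProcessSpec
) -> ProcessReport:
    if spec.restrict_to:
        # restriction ids absent from this matrix are simply not available
        present = [i for i in spec.restrict_to if i in set(matrix.ids)]
        scope = matrix.subset(present)
    else:
        scope = matrix
    selection = screen_feedstocks(scope, spec.rule)
    pools = {
        "favorable": pool_masses(matrix, selection.favorable, spec.fraction),
        "with_possible": pool_masses(matrix, selection.all_ids, spec.fraction),
    }
    outcomes: list[ChainOutcome] = []
    for chain_spec in spec.chains:
        scenarios = ["baseline"] + (
            ["idealized"] if chain_spec.has_idealized else []
        )
        for scenario in scenarios:
            chain = chain_spec.chain(scenario)
            factor = chain_factor(chain)
            for tier in TIERS:
                pool = pools[tier]
                if pool.fraction_pool <= 0:
                    continue  # nothing selected: no chain run
                flow = run_chain(pool.fraction_pool, chain)
                eta = utilization_ratio(flow.product, pool.raw_pool).eta_rm
                demand = coverage = required = None
                if spec.market is not None:
                    demand = national_demand(
                        spec.market.global_production, spec.market.national_gdp_share
                    )
                    coverage = demand_coverage_share(demand, flow.product)
                    required = required_fraction_share(
                        demand, chain, pool.fraction_pool
                    )
                land_ha = None
                if spec.land is not None:
                    land_ha = land_saving(
                        flow.product,
                        chain,
                        spec.land.feedstock_fraction_content,
                        spec.land.land_use(),
                    )
                outcomes.append(
                    ChainOutcome(
                        process=spec.name,
                        chain_name=chain_spec.name,
                        tier=tier,
                        scenario=scenario,
                        factor=factor,
                        raw_pool=pool.raw_pool,
                        fraction_pool=pool.fraction_pool,
                        product=flow.product,
                        eta_rm=eta,
                        demand=demand,
                        coverage_share=coverage,
                        required_share=required,
                        land_saving_ha=land_ha,
                        flow=flow,
                    )
                )
    return ProcessReport(
        name=spec.name,
        fraction=spec.fraction,
        selection=selection,
        pools=pools,
        outcomes=tuple(outcomes),
    )


def run_assessment(
    config: RunConfig,
    matrix: ResourceMatrix | None = None,
    out_dir: str | Path | None = None,
) -> AssessmentReport:
    """Run the full assessment; optionally write report artifacts to ``out_dir``."""
    if matrix is None:
        matrix = reference_fixture().matrix
    kept = apply_potential_cutoff(matrix, config.cutoff)
    below_cutoff = set(matrix.ids) - set(kept.ids)

    process_reports = tuple(_assess_process(kept, p) for p in config.processes)

    selected_ids: set[str] = set()
    for proc in process_reports:
        selected_ids.update(proc.selection.all_ids)

    suitability = None
    if matrix.total_technical_potential > 0:
        assignments = {}
        for r in matrix:
            if r.id in below_cutoff:
                assignments[r.id] = "below_cutoff"
            elif r.id in selected_ids:
                assignments[r.id] = "model_process"
            elif r.id in config.not_exploitable:
                assignments[r.id] = "not_exploitable"
            else:
                assignments[r.id] = "principal_feasibility"
        suitability = suitability_summary(matrix, assignments)

    tally: dict[int, int] = {}
    for r in kept:
        level = score_data_quality(r.quality)
        tally[level] = tally.get(level, 0) + 1

    total_selected = sum(
        p.pools["with_possible"].raw_pool for p in process_reports
    )
    report = AssessmentReport(
        processes=process_reports,
        suitability=suitability,
        quality_tally=dict(sorted(tally.items())),
        total_selected_raw_pool=total_selected,
        cutoff=config.cutoff,
        n_input=len(matrix),
        n_after_cutoff=len(kept),
    )
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def _report_payload(report: AssessmentReport) -> dict:
    payload: dict = {
        "cutoff_Mg_DM_a": report.cutoff,
        "n_input_residues": report.n_input,
        "n_after_cutoff": report.n_after_cutoff,
        "total_selected_raw_pool_Mg_a": report.total_selected_raw_pool,
        "quality_tally": {str(k): v for k, v in report.quality_tally.items()},
        "processes": [],
    }
    if report.suitability is not None:
        payload["suitability"] = {
            cls: {
                "mass_Mg_DM_a": float(row["mass_Mg_DM_a"]),
                "share": float(row["share"]),
            }
            for cls, row in report.suitability.iterrows()
        }
    for proc in report.processes:
        payload["processes"].append(
            {
                "name": proc.name,
                "fraction": proc.fraction,
                "favorable_ids": list(proc.selection.favorable),
                "possible_ids": list(proc.selection.possible),
                "pools": {
                    tier: dataclasses.asdict(pool)
                    for tier, pool in proc.pools.items()
                },
                "outcomes": [
                    {
                        k: v
                        for k, v in dataclasses.asdict(o).items()
                        if k != "flow"
                    }
                    for o in proc.outcomes
                ],
            }
        )
    return payload


def write_report(
    report: AssessmentReport, config: RunConfig, out_dir: str | Path
) -> None:
    """Write summary.csv, report.json, per-flow node-link JSON and a run log.

    Output is deterministic (stable ordering, fixed rounding, no timestamps),
    so re-running with the same config and matrix is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = config.report_significant_figures

    report.summary_frame(sig_figs=sig).to_csv(
        out / "summary.csv", index=False, lineterminator="\n"
    )
    (out / "report.json").write_text(
        json.dumps(_report_payload(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    flows = out / "flows"
    flows.mkdir(exist_ok=True)
    spec_by_name = {p.name: p for p in config.processes}
    for proc in report.processes:
        for o in proc.outcomes:
            chain_spec = next(
                c for c in spec_by_name[proc.name].chains if c.name == o.chain_name
            )
            chain = chain_spec.chain(o.scenario)
            payload = flow_to_nodelink(o.flow, chain)
            name = f"{proc.name}__{o.chain_name}__{o.tier}__{o.scenario}.json"
            (flows / name).write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )

    lines = [
        "residueflow run log (constants echoed for auditability)",
        f"cutoff_Mg_DM_a = {config.cutoff}",
        f"national_gdp_share = {config.national_gdp_share}",
        f"report_significant_figures = {sig}",
    ]
    for p in config.processes:
        lines.append(f"[process {p.name}] fraction = {p.fraction}")
        lines.append(
            f"  screening: favorable {p.rule.comparison} "
            f"{p.rule.favorable_threshold}, possible {p.rule.comparison} "
            f"{p.rule.possible_threshold}"
        )
        if p.restrict_to:
            lines.append(f"  restricted to: {', '.join(p.restrict_to)}")
        for c in p.chains:
            factors = ", ".join(
                f"{s.name}={s.factor}"
                + (f" (idealized {s.idealized})" if s.idealized is not None else "")
                for s in c.steps
            )
            lines.append(f"  chain {c.name}: {factors}")
        if p.market is not None:
            lines.append(
                f"  market: {p.market.product} global "
                f"{p.market.global_production} Mg a-1, gdp share "
                f"{p.market.national_gdp_share}"
            )
        if p.land is not None:
            lines.append(
                f"  land: {p.land.crop} {p.land.areal_yield} Mg ha-1 a-1 x "
                f"{p.land.content_factor}, feedstock content "
                f"{p.land.feedstock_fraction_content}"
            )
    (out / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
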