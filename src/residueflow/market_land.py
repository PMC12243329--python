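"""Market demand breakdown and land-use substitution accounting.

National demand for a product is approximated by scaling global production
with the national share of global GDP (default 3% for Germany).  Coverage
quantities relate that demand to the biogenic product potential and to the
feedstock pools; land savings translate a residue-based product amount into
the cropland or woodland area that dedicated cultivation would need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .material_flow import ProcessChain, chain_factor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemandSpec:
    """Global production of a product and the national GDP-share breakdown."""

    product: str
    global_production: float  # Mg a⁻¹
    national_gdp_share: float = 0.03

    def __post_init__(self) -> None:
        if self.global_production <= 0:
            raise ValueError(
                f"global_production must be > 0, got {self.global_production}"
            )
        if not (0.0 < self.national_gdp_share < 1.0):
            raise ValueError(
                f"national_gdp_share must lie in (0, 1), got {self.national_gdp_share}"
            )

    @property
    def national_demand(self) -> float:
        return national_demand(self.global_production, self.national_gdp_share)


@dataclass(frozen=True)
class LandUseSpec:
    """Areal yield of the displaced crop/biomass with an optional content factor.

    ``content_factor`` converts the stated areal yield to the relevant mass
    basis (e.g. dry-matter share 0.35 for corn silage, oil content 0.446 for
    rapeseed); ``effective_yield`` = areal_yield × content_factor.
    """

    crop: str
    areal_yield: float  # Mg ha⁻¹ a⁻¹
    content_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.areal_yield <= 0:
            raise ValueError(f"areal_yield must be > 0, got {self.areal_yield}")
        if not (0.0 < self.content_factor <= 1.0):
            raise ValueError(
                f"content_factor must lie in (0, 1], got {self.content_factor}"
            )

    @property
    def effective_yield(self) -> float:
        return self.areal_yield * self.content_factor


@dataclass(frozen=True)
class CoverageResult:
    """Demand vs. biogenic potential; shares are reported unclamped."""

    demand: float
    available_product_potential: float
    coverage_share: float
    required_feedstock_share: float | None = None

    def __post_init__(self) -> None:
        for name in ("demand", "available_product_potential", "coverage_share"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


def national_demand(global_production: float, gdp_share: float) -> float:
    """Break global production down to national level via the GDP share."""
    if global_production <= 0:
        raise ValueError(f"global_production must be > 0, got {global_production}")
    if gdp_share <= 0:
        raise ValueError(f"gdp_share must be > 0, got {gdp_share}")
    return global_production * gdp_share


def required_fraction_share(
    demand: float, chain: ProcessChain, fraction_pool: float
) -> float:
    """Share of the fraction pool needed to meet the demand through the chain.

    Returns (demand / chain factor) / fraction pool; may exceed 1 when the
    demand outgrows the pool (reported, not clamped).
    """
    factor = chain_factor(chain)
    if fraction_pool <= 0:
        raise ValueError(f"fraction_pool must be > 0, got {fraction_pool}")
    if factor <= 0:
        raise ValueError(f"chain factor must be > 0, got {factor}")
    share = (demand / factor) / fraction_pool
    if share > 1:
        logger.warning(
            "required fraction share %.3f exceeds 1: demand outgrows the pool", share
        )
    return share


def demand_coverage_share(demand: float, product_potential: float) -> float:
    """Fraction of the biogenic product potential needed to cover the demand."""
    if product_potential <= 0:
        raise ValueError(
            f"product_potential must be > 0, got {product_potential}"
        )
    share = demand / product_potential
    if share > 1:
        logger.warning(
            "demand coverage share %.3f exceeds 1: demand exceeds the potential",
            share,
        )
    return share


def land_saving(
    product_demand: float,
    chain: ProcessChain,
    feedstock_content: float,
    land: LandUseSpec,
) -> float:
    """Cultivation area (ha) displaced by producing ``product_demand`` from residues.

    ``feedstock_content`` is the relevant fraction of the displaced biomass
    (e.g. average lignin share 0.25 of trunk wood); pass 1.0 when the
    content factor is already folded into ``land.effective_yield``.
    """
    if product_demand < 0:
        raise ValueError(f"product_demand must be ≥ 0, got {product_demand}")
    if not (0.0 < feedstock_content <= 1.0):
        raise ValueError(
            f"feedstock_content must lie in (0, 1], got {feedstock_content}"
        )
    denominator = chain_factor(chain) * feedstock_content * land.effective_yield
    if denominator <= 0:
        raise ValueError("chain factor × content × yield must be > 0")
    return product_demand / denominator
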